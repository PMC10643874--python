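"""Targeted bisulfite-amplicon reference definitions.

An :class:`AmpliconReference` describes one PCR target on the forward
genomic strand *before* bisulfite conversion: its sequence, the positions
of the CpG cytosines whose methylation the assay reads out, and the primer
pair in bisulfite space (primers are designed against converted DNA, so
they are written post-conversion). Because CpG methylation is symmetric
across strands the assay amplifies only the forward strand; no
reverse-strand logic exists anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import edlib
import numpy as np
import yaml
from Bio.Seq import Seq

__all__ = [
    "AmpliconReference",
    "synthetic_chr3_amplicon",
    "synthetic_chr19_amplicon",
    "example_references",
    "load_references_yaml",
    "write_references_yaml",
]

#: IUPAC code used internally to mark a CpG cytosine in bisulfite space,
#: where it may legitimately read as C (methylated) or T (unmethylated).
CPG_TWO_STATE = "Y"


class AmpliconConfigError(ValueError):
    """An amplicon definition violates its invariants."""


@dataclass(frozen=True)
class AmpliconReference:
    """One targeted locus.

    Parameters
    ----------
    locus_id
        Short name, e.g. ``"chr3_42190778_42191048"``.
    chrom, start, end
        Genomic coordinates, 1-based inclusive. Treated as opaque metadata:
        nothing downstream depends on them.
    sequence
        Forward-strand sequence of the amplicon *before* bisulfite
        conversion, 5'->3', including the primer-binding ends.
    cpg_positions
        1-based offsets within ``sequence`` of the C of each CpG.
    forward_primer, reverse_primer
        Primer pair in bisulfite space, as ordered for synthesis. The
        reverse primer anneals to the 3' end of the forward amplicon, so
        its reverse complement terminates the expected read. Empty strings
        disable primer-based checks (useful for toy references in tests).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    cpg_positions: tuple[int, ...]
    forward_primer: str = ""
    reverse_primer: str = ""
    expected_length: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
        if not self.cpg_positions:
            raise AmpliconConfigError(
                f"{self.locus_id}: amplicon has no CpG positions"
            )
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise AmpliconConfigError(
                f"{self.locus_id}: cpg_positions must be strictly increasing"
            )
        for pos in self.cpg_positions:
            if not (1 <= pos < len(seq)):
                raise AmpliconConfigError(
                    f"{self.locus_id}: CpG offset {pos} outside sequence"
                )
            if seq[pos - 1] != "C" or seq[pos] != "G":
                raise AmpliconConfigError(
                    f"{self.locus_id}: offset {pos} is not the C of a CpG "
                    f"(found {seq[pos - 1]}{seq[pos]})"
                )
        if self.expected_length is None:
            object.__setattr__(self, "expected_length", len(seq))
        if self.forward_primer:
            object.__setattr__(
                self, "forward_primer", self.forward_primer.replace(" ", "").upper()
            )
            object.__setattr__(
                self, "reverse_primer", self.reverse_primer.replace(" ", "").upper()
            )
            self._check_primer_anchoring()

    def _check_primer_anchoring(self, max_edits: int = 2) -> None:
        bis = self.bisulfite_sequence_fully_methylated
        for name, primer, segment in (
            ("forward", self.forward_primer, bis[: len(self.forward_primer) + max_edits]),
            ("reverse", self.rc_reverse_primer, bis[-(len(self.reverse_primer) + max_edits):]),
        ):
            hit = edlib.align(primer, segment, mode="HW", task="distance", k=max_edits)
            if hit["editDistance"] < 0:
                raise AmpliconConfigError(
                    f"{self.locus_id}: {name} primer does not occur at the "
                    f"amplicon end in bisulfite space"
                )

    # -- derived sequences -------------------------------------------------

    @cached_property
    def rc_reverse_primer(self) -> str:
        """Reverse complement of the reverse primer: the expected read 3' end."""
        return str(Seq(self.reverse_primer).reverse_complement())

    @cached_property
    def cpg_index(self) -> np.ndarray:
        """0-based CpG C offsets."""
        return np.asarray(self.cpg_positions, dtype=np.int64) - 1

    @cached_property
    def non_cpg_c_index(self) -> np.ndarray:
        """0-based offsets of cytosines outside CpG context.

        After complete bisulfite conversion these read as T; a C observed
        here in a read signals a conversion failure.
        """
        cpg = set(self.cpg_index.tolist())
        return np.asarray(
            [i for i, b in enumerate(self.sequence) if b == "C" and i not in cpg],
            dtype=np.int64,
        )

    @cached_property
    def bisulfite_sequence_fully_methylated(self) -> str:
        """Converted forward strand with every CpG methylated (C retained)."""
        chars = list(self.sequence)
        for i in self.non_cpg_c_index:
            chars[i] = "T"
        return "".join(chars)

    @cached_property
    def alignment_target(self) -> str:
        """Bisulfite-space reference for alignment.

        Non-CpG Cs are written as T; each CpG C is written as the two-state
        code ``Y`` so the aligner treats both C (methylated) and T
        (unmethylated) as matches.
        """
        chars = list(self.bisulfite_sequence_fully_methylated)
        for i in self.cpg_index:
            chars[i] = CPG_TWO_STATE
        return "".join(chars)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def to_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "sequence": self.sequence,
            "cpg_positions": list(self.cpg_positions),
            "forward_primer": self.forward_primer,
            "reverse_primer": self.reverse_primer,
            "expected_length": self.expected_length,
        }


# -- example references ----------------------------------------------------

# Published primer pairs of the targeted assay, bisulfite space, 5'->3'
# (whitespace from typesetting removed). Both happen to contain no C, so the
# primer-proximal amplicon ends are identical before and after conversion.
CHR3_FORWARD_PRIMER = "TTTTATTGTTTTGGTTTTAGATTGT"
CHR3_REVERSE_PRIMER = "AAATAAACTTCACAACACCATCAAC"
CHR19_FORWARD_PRIMER = "GGTATTATTTAGGTTTGGTTTT"
CHR19_REVERSE_PRIMER = "TACCTTTAAATAAATATCTACTCCCTTAAC"


def _synthetic_interior(
    rng: np.random.Generator,
    length: int,
    n_cpgs: int,
    n_non_cpg_c: int,
    forbidden_last_c: bool,
) -> str:
    """Random C-free backbone with planted CpGs and non-CpG cytosines."""
    chars = rng.choice(list("ATG"), size=length).tolist()
    # CpGs need two adjacent slots; lay all planted features on a grid of
    # disjoint 2-base slots so they can never collide or create accidental CGs
    n_slots = length // 2 - 1
    if n_cpgs + n_non_cpg_c > n_slots:
        raise AmpliconConfigError("interior too short for requested features")
    slots = rng.choice(n_slots, size=n_cpgs + n_non_cpg_c, replace=False)
    cpg_slots, c_slots = np.sort(slots[:n_cpgs]), slots[n_cpgs:]
    for s in cpg_slots:
        chars[2 * s], chars[2 * s + 1] = "C", "G"
    for s in c_slots:
        chars[2 * s] = "C"
        if chars[2 * s + 1] == "G":
            chars[2 * s + 1] = "A"
    if forbidden_last_c and chars[-1] == "C":
        chars[-1] = "T"
    return "".join(chars)


def _make_synthetic_amplicon(
    locus_id: str,
    chrom: str,
    start: int,
    total_length: int,
    fwd: str,
    rev: str,
    n_cpgs: int,
    n_non_cpg_c: int,
    seed: int,
) -> AmpliconReference:
    rng = np.random.default_rng(seed)
    rc_rev = str(Seq(rev).reverse_complement())
    interior_len = total_length - len(fwd) - len(rc_rev)
    interior = _synthetic_interior(
        rng, interior_len, n_cpgs, n_non_cpg_c,
        forbidden_last_c=rc_rev.startswith("G"),
    )
    sequence = fwd + interior + rc_rev
    cpgs = tuple(
        i + 1 for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"
    )
    return AmpliconReference(
        locus_id=locus_id,
        chrom=chrom,
        start=start,
        end=start + total_length - 1,
        sequence=sequence,
        cpg_positions=cpgs,
        forward_primer=fwd,
        reverse_primer=rev,
    )


def synthetic_chr3_amplicon(seed: int = 33) -> AmpliconReference:
    """Synthetic stand-in for the chr3 target amplicon (271 bp, 9 CpGs).

    The primer-proximal ends are the real assay primers; the 221 bp interior
    is synthetic, generated from a fixed seed, since only the primers and
    locus name of the target are published. Assay behaviour downstream
    depends only on primer anchoring and CpG layout, both of which this
    reference reproduces.
    """
    return _make_synthetic_amplicon(
        "chr3_42190778_42191048", "chr3", 42190778, 271,
        CHR3_FORWARD_PRIMER, CHR3_REVERSE_PRIMER,
        n_cpgs=9, n_non_cpg_c=15, seed=seed,
    )


def synthetic_chr19_amplicon(seed: int = 1919) -> AmpliconReference:
    """Synthetic stand-in for the chr19 target amplicon (240 bp, 6 CpGs).

    The published locus string is a single CpG coordinate; amplicon bounds
    are defined here only by the printed primer pair, with a synthetic
    interior (fixed seed).
    """
    return _make_synthetic_amplicon(
        "chr19_3507867_3507868", "chr19", 3507867, 240,
        CHR19_FORWARD_PRIMER, CHR19_REVERSE_PRIMER,
        n_cpgs=6, n_non_cpg_c=10, seed=seed,
    )


def example_references() -> list[AmpliconReference]:
    return [synthetic_chr3_amplicon(), synthetic_chr19_amplicon()]


def load_references_yaml(path) -> list[AmpliconReference]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw.get("amplicons", [raw])
    refs = [AmpliconReference(**{**r, "cpg_positions": tuple(r["cpg_positions"])}) for r in raw]
    seen: dict[str, str] = {}
    for ref in refs:
        if ref.forward_primer in seen:
            raise AmpliconConfigError(
                f"references {seen[ref.forward_primer]} and {ref.locus_id} "
                f"share a forward primer; reads cannot be demultiplexed"
            )
        seen[ref.forward_primer] = ref.locus_id
    return refs


def write_references_yaml(refs: list[AmpliconReference], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"amplicons": [r.to_dict() for r in refs]}, fh, sort_keys=False)
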