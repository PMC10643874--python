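"""From amplicon FASTQ to per-read whole-molecule methylation calls.

Filter cascade, applied in a fixed order so that read accounting is
deterministic (each read is attributed to its first failing gate):

1. ``low_quality`` — mean per-base Phred below 9 (strict).
2. ``too_short`` — read shorter than 200 bp (strict).
3. ``no_locus_match`` — 5' end matches no (or more than one) amplicon
   forward primer within the edit budget, or global alignment fails.
4. ``not_full_molecule`` — the read does not represent a fully amplified
   molecule: forward primer at the 5' end, a reverse-primer match at the
   3' end, a span of at least 95% of the expected amplicon length, and
   every reference CpG callable are all required.
5. ``conversion_failure`` — cytosines observed outside CpG context
   (i.e. at reference positions that bisulfite conversion should have
   turned into T); any such C beyond the tolerance (default 0) drops the
   read, since it signals incomplete bisulfite conversion of the molecule.

Reads surviving all gates get per-CpG states by global alignment to the
bisulfite-space reference (non-CpG C written as T, CpG C as a two-state
C/T code) and a whole-molecule mean methylation over all reference CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .amplicon import CPG_TWO_STATE, AmpliconReference
from .errors import ConfigurationError

__all__ = [
    "SequencedRead",
    "ReadMethylation",
    "FILTER_ORDER",
    "read_fastq",
    "qc_filter",
    "assign_amplicon",
    "check_full_molecule",
    "align_and_call",
    "process_reads",
    "process_fastq",
    "calls_to_frame",
]

FILTER_ORDER = (
    "low_quality",
    "too_short",
    "no_locus_match",
    "not_full_molecule",
    "conversion_failure",
)

METHYLATED, UNMETHYLATED, MISSING = "methylated", "unmethylated", "missing"

#: global-alignment edit distance above this fraction of the reference
#: length means the read is not this locus at all
ALIGN_MAX_EDIT_FRACTION = 0.30


@dataclass(frozen=True)
class SequencedRead:
    read_id: str
    sequence: str
    quality: tuple[int, ...]  # per-base Phred

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        """Arithmetic mean of per-base Phred scores."""
        return float(np.mean(self.quality)) if self.quality else 0.0


@dataclass
class ReadMethylation:
    """Per-read call. ``mean_methylation`` is defined only for unflagged
    reads, where every reference CpG was callable (full-molecule
    contract)."""

    read_id: str
    locus_id: str | None
    per_cpg_state: tuple[str, ...] = ()
    n_called: int = 0
    mean_methylation: float | None = None
    filter_flags: frozenset[str] = frozenset()
    n_conversion_failures: int = 0

    @property
    def passed(self) -> bool:
        return not self.filter_flags

    @property
    def first_flag(self) -> str | None:
        for f in FILTER_ORDER:
            if f in self.filter_flags:
                return f
        return None


def read_fastq(path) -> list[SequencedRead]:
    """Parse Phred-33 FASTQ into :class:`SequencedRead` records."""
    return [
        SequencedRead(
            rec.id, str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------------------
# Individual gates
# ---------------------------------------------------------------------------

def qc_filter(
    read: SequencedRead, min_mean_quality: float = 9.0, min_length: int = 200
) -> frozenset[str]:
    """Quality and length gates; both strict inequalities, both flags can
    fire on one read. Empty set means pass."""
    flags = set()
    if read.mean_quality < min_mean_quality:
        flags.add("low_quality")
    if read.length < min_length:
        flags.add("too_short")
    return frozenset(flags)


def _primer_hit(primer: str, segment: str, max_edits: int):
    """Best infix match of primer in segment; None if beyond max_edits."""
    res = edlib.align(primer, segment, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    return res["editDistance"], res["locations"][0]


def assign_amplicon(
    read: SequencedRead,
    references: list[AmpliconReference],
    max_primer_edits: int = 2,
) -> str | None:
    """Demultiplex by forward primer at the 5' end.

    Returns the locus_id of the unique reference whose forward primer
    matches within ``max_primer_edits`` edits in the read's first
    ``len(primer) + max_primer_edits`` bases; ambiguous (more than one
    reference matches) or no match returns None.
    """
    if not references:
        raise ConfigurationError("references: list is empty")
    primers = [r.forward_primer for r in references]
    if len(set(primers)) != len(primers):
        raise ConfigurationError(
            "references: two amplicons share a forward primer"
        )
    hits = []
    for ref in references:
        window = read.sequence[: len(ref.forward_primer) + max_primer_edits]
        if _primer_hit(ref.forward_primer, window, max_primer_edits) is not None:
            hits.append(ref.locus_id)
    return hits[0] if len(hits) == 1 else None


def check_full_molecule(
    read: SequencedRead,
    ref: AmpliconReference,
    min_span_fraction: float = 0.95,
    max_primer_edits: int = 2,
) -> bool:
    """Does the read represent a fully amplified molecule?

    Requires the forward primer at the 5' end, the reverse-complemented
    reverse primer at the 3' end (each within ``max_primer_edits``), and a
    primer-to-primer span of at least ``min_span_fraction`` of the
    expected amplicon length.
    """
    fwd = _primer_hit(
        ref.forward_primer,
        read.sequence[: len(ref.forward_primer) + max_primer_edits],
        max_primer_edits,
    )
    if fwd is None:
        return False
    tail_len = len(ref.rc_reverse_primer) + max_primer_edits
    tail_off = max(0, read.length - tail_len)
    rev = _primer_hit(ref.rc_reverse_primer, read.sequence[tail_off:], max_primer_edits)
    if rev is None:
        return False
    span = (tail_off + rev[1][1] + 1) - fwd[1][0]
    return span >= min_span_fraction * ref.expected_length


def align_and_call(
    read: SequencedRead,
    ref: AmpliconReference,
    conversion_failure_tolerance: int = 0,
) -> ReadMethylation:
    """Globally align the read to the bisulfite-space reference and call
    per-CpG methylation states.

    At each reference CpG: aligned read base C -> methylated,
    T -> unmethylated, anything else (mismatch or gap) -> missing. Any
    missing CpG breaks the full-molecule contract (``not_full_molecule``).
    At reference positions holding a cytosine outside CpG context, an
    aligned read C is an unconverted cytosine; more than
    ``conversion_failure_tolerance`` of them flags ``conversion_failure``.
    A read whose best global alignment exceeds 30% edits is
    ``no_locus_match``.
    """
    target = ref.alignment_target
    res = edlib.align(
        read.sequence,
        target,
        mode="NW",
        task="path",
        additionalEqualities=[(CPG_TWO_STATE, "C"), (CPG_TWO_STATE, "T")],
    )
    if res["editDistance"] > ALIGN_MAX_EDIT_FRACTION * len(target):
        return ReadMethylation(
            read.read_id, None, filter_flags=frozenset({"no_locus_match"})
        )

    # walk the cigar: base of the read aligned to each reference position
    aligned = np.full(len(target), b"-", dtype="S1")
    q = np.frombuffer(read.sequence.encode(), dtype="S1")
    qi = ti = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            aligned[ti : ti + n] = q[qi : qi + n]
            qi += n
            ti += n
        elif ch == "I":  # extra read bases, no reference position
            qi += n
        elif ch == "D":  # reference positions with no read base
            ti += n

    cpg_bases = aligned[ref.cpg_index]
    states = tuple(
        METHYLATED if b == b"C" else UNMETHYLATED if b == b"T" else MISSING
        for b in cpg_bases
    )
    n_called = sum(s != MISSING for s in states)
    n_conv_fail = int((aligned[ref.non_cpg_c_index] == b"C").sum())

    flags = set()
    if n_called < ref.n_cpgs:
        flags.add("not_full_molecule")
    if n_conv_fail > conversion_failure_tolerance:
        flags.add("conversion_failure")

    mean = None
    if not flags:
        mean = sum(s == METHYLATED for s in states) / ref.n_cpgs
    return ReadMethylation(
        read_id=read.read_id,
        locus_id=ref.locus_id,
        per_cpg_state=states,
        n_called=n_called,
        mean_methylation=mean,
        filter_flags=frozenset(flags),
        n_conversion_failures=n_conv_fail,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def process_reads(
    reads: list[SequencedRead],
    references: list[AmpliconReference],
    min_mean_quality: float = 9.0,
    min_length: int = 200,
    max_primer_edits: int = 2,
    min_span_fraction: float = 0.95,
    conversion_failure_tolerance: int = 0,
) -> list[ReadMethylation]:
    """Run the full filter cascade and calling on a batch of reads.

    Returns one :class:`ReadMethylation` per input read (flagged or
    called), so that ``n_input = n_pass + sum(n per first_flag)``.
    """
    by_locus = {r.locus_id: r for r in references}
    out: list[ReadMethylation] = []
    for read in reads:
        qc = qc_filter(read, min_mean_quality, min_length)
        if qc:
            out.append(ReadMethylation(read.read_id, None, filter_flags=qc))
            continue
        locus = assign_amplicon(read, references, max_primer_edits)
        if locus is None:
            out.append(
                ReadMethylation(read.read_id, None,
                                filter_flags=frozenset({"no_locus_match"}))
            )
            continue
        ref = by_locus[locus]
        if not check_full_molecule(read, ref, min_span_fraction, max_primer_edits):
            out.append(
                ReadMethylation(read.read_id, locus,
                                filter_flags=frozenset({"not_full_molecule"}))
            )
            continue
        out.append(align_and_call(read, ref, conversion_failure_tolerance))
    return out


def process_fastq(path, references, **kwargs) -> list[ReadMethylation]:
    return process_reads(read_fastq(path), references, **kwargs)


def attrition_counts(calls: list[ReadMethylation]) -> dict[str, int]:
    """Reads per first-failing flag, plus 'passed' and 'input'."""
    counts = {f: 0 for f in FILTER_ORDER}
    passed = 0
    for c in calls:
        if c.passed:
            passed += 1
        else:
            counts[c.first_flag] += 1
    counts["passed"] = passed
    counts["input"] = len(calls)
    return counts


def calls_to_frame(calls: list[ReadMethylation]) -> pd.DataFrame:
    """Per-read call table (TSV-ready)."""
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "locus": [c.locus_id or "" for c in calls],
            "n_meth": [
                sum(s == METHYLATED for s in c.per_cpg_state) if c.passed else pd.NA
                for c in calls
            ],
            "n_cpg": [c.n_called if c.passed else pd.NA for c in calls],
            "mean_meth": [c.mean_methylation for c in calls],
            "flags": [";".join(sorted(c.filter_flags)) for c in calls],
        }
    )
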