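"""Synthetic data generation for the whole pipeline.

Two simulators with fully seeded randomness:

* :func:`simulate_beta_matrix` — methylation-array beta matrices contrasting
  purified cortical neurons against blood plasma, with planted
  differentially methylated regions (DMRs) of known effect size against a
  bimodal null background.
* :func:`simulate_amplicon_reads` — bisulfite-converted PCR-amplicon
  nanopore reads drawn from a mixture of neuron-derived molecules
  (completely unmethylated at every CpG) and blood-derived molecules
  (near-fully methylated), with substitution error, incomplete bisulfite
  conversion, truncated molecules and Phred quality strings.

:func:`simulate_cohort` composes the read simulator into a study-shaped
cohort (disease groups, planted per-sample neuron fractions, technical
replicate aliquots) and writes one FASTQ per sample-replicate plus a
planted-truth table.

Every simulator is a pure function of its config, including the seed:
identical configs give byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import AmpliconReference
from .arrays import GROUP_NEURON, GROUP_PLASMA, BetaMatrix
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "ArraySimConfig",
    "ReadSimConfig",
    "FractionDistribution",
    "GroupSpec",
    "CohortSpec",
    "ArraySimTruth",
    "simulate_beta_matrix",
    "simulate_amplicon_reads",
    "simulate_cohort",
    "write_fastq",
    "study_cohort",
    "COHORT_GROUPS",
]

COHORT_GROUPS = (
    "AD",
    "MCI_progressor",
    "MCI_stable",
    "aged_control",
    "young_control",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


# ---------------------------------------------------------------------------
# Array simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArraySimConfig:
    """Configuration for the beta-matrix simulator.

    Group means at planted probes differ by ``planted_delta`` (neuron minus
    plasma is negative, matching a target where neurons are unmethylated);
    null probes sit on a bimodal background shared by both groups, with a
    per-probe group offset bounded by ``null_delta_max``. Per-probe noise is
    truncated-normal: Gaussian with sd ``noise_sd``, clipped to [0, 1].
    """

    n_neuron_samples: int = 4
    n_plasma_samples: int = 8
    n_probes: int = 10_000
    n_planted_dmrs: int = 20
    planted_delta: float = 0.8
    noise_sd: float = 0.02
    null_delta_max: float = 0.0
    window_probe_count: int = 5
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_neuron_samples >= 2, "n_neuron_samples", "need >= 2 per group")
        _require(self.n_plasma_samples >= 2, "n_plasma_samples", "need >= 2 per group")
        _require(self.n_probes >= 1, "n_probes", "must be positive")
        _require(self.n_planted_dmrs >= 0, "n_planted_dmrs", "must be >= 0")
        _require(0.0 <= self.planted_delta <= 1.0, "planted_delta", "must be in [0, 1]")
        _require(0.0 <= self.null_delta_max <= 1.0, "null_delta_max", "must be in [0, 1]")
        _require(self.noise_sd >= 0.0, "noise_sd", "must be >= 0")
        _require(self.window_probe_count >= 1, "window_probe_count", "must be >= 1")
        _require(
            self.n_planted_dmrs * self.window_probe_count <= self.n_probes,
            "n_planted_dmrs",
            "planted probes exceed n_probes",
        )


@dataclass(frozen=True)
class ArraySimTruth:
    """Planted-truth annotation returned with a simulated beta matrix."""

    regions: pd.DataFrame  # chrom, start, end, planted_delta (1-based inclusive)
    planted_probe_ids: tuple[str, ...]

    def regions_to_bed(self, path) -> None:
        """BED-like TSV, 0-based half-open on write."""
        out = self.regions.copy()
        out["start"] = out["start"] - 1
        out.to_csv(path, sep="\t", index=False)


def simulate_beta_matrix(config: ArraySimConfig) -> tuple[BetaMatrix, ArraySimTruth]:
    """Simulate a neuron-vs-plasma beta matrix with planted DMRs.

    Layout: each planted region occupies its own contig (``dmr000001`` ...)
    of ``window_probe_count`` consecutive probes, so planted regions are
    non-overlapping by construction and window counts over the null
    background (a single ``null`` contig holding the remaining probes) are
    exact. Probe spacing is 100 bp.

    Null probes draw a bimodal baseline (low peak ~U(0.08, 0.18), high peak
    ~U(0.82, 0.92), equal weight — peaks kept at least 4 noise sd away from
    0 and 1 so that clipping never distorts the null distribution) shared
    by both groups up to a per-probe offset uniform in ±``null_delta_max``;
    planted probes put the neuron mean at (1 - delta)/2 and the plasma
    mean at (1 + delta)/2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_planted = config.n_planted_dmrs * config.window_probe_count
    n_null = config.n_probes - n_planted
    n_samples = config.n_neuron_samples + config.n_plasma_samples

    chroms: list[str] = []
    positions: list[int] = []
    for r in range(config.n_planted_dmrs):
        chroms.extend([f"dmr{r + 1:06d}"] * config.window_probe_count)
        positions.extend(100 * (i + 1) for i in range(config.window_probe_count))
    chroms.extend(["null"] * n_null)
    positions.extend(100 * (i + 1) for i in range(n_null))

    probe_ids = [f"cg{i:07d}" for i in range(config.n_probes)]
    sample_ids = [f"neuron{i + 1:02d}" for i in range(config.n_neuron_samples)] + [
        f"plasma{i + 1:02d}" for i in range(config.n_plasma_samples)
    ]
    groups = pd.Series(
        [GROUP_NEURON] * config.n_neuron_samples + [GROUP_PLASMA] * config.n_plasma_samples,
        index=sample_ids,
    )

    neuron_mean = np.empty(config.n_probes)
    plasma_mean = np.empty(config.n_probes)
    if n_planted:
        neuron_mean[:n_planted] = (1.0 - config.planted_delta) / 2.0
        plasma_mean[:n_planted] = (1.0 + config.planted_delta) / 2.0
    if n_null:
        low = rng.uniform(0.08, 0.18, size=n_null)
        high = rng.uniform(0.82, 0.92, size=n_null)
        base = np.where(rng.random(n_null) < 0.5, low, high)
        offset = rng.uniform(-config.null_delta_max, config.null_delta_max, size=n_null)
        neuron_mean[n_planted:] = np.clip(base + offset / 2.0, 0.0, 1.0)
        plasma_mean[n_planted:] = np.clip(base - offset / 2.0, 0.0, 1.0)

    means = np.empty((config.n_probes, n_samples))
    means[:, : config.n_neuron_samples] = neuron_mean[:, None]
    means[:, config.n_neuron_samples:] = plasma_mean[:, None]
    betas = np.clip(
        means + rng.normal(0.0, config.noise_sd, size=means.shape), 0.0, 1.0
    )

    probes = pd.DataFrame(
        {"chrom": chroms, "pos": positions}, index=pd.Index(probe_ids, name="probe_id")
    )
    matrix = BetaMatrix(
        pd.DataFrame(betas, index=probes.index, columns=sample_ids), probes, groups
    )

    w = config.window_probe_count
    regions = pd.DataFrame(
        {
            "chrom": [f"dmr{r + 1:06d}" for r in range(config.n_planted_dmrs)],
            "start": [100] * config.n_planted_dmrs,
            "end": [100 * w] * config.n_planted_dmrs,
            # neuron minus plasma: negative at planted regions
            "planted_delta": [-config.planted_delta] * config.n_planted_dmrs,
        }
    )
    truth = ArraySimTruth(regions, tuple(probe_ids[:n_planted]))
    return matrix, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Configuration for the bisulfite-amplicon read simulator.

    Each molecule is neuron-derived with probability ``neuron_fraction``;
    per-CpG methylation is Bernoulli with the cell-type probability
    (neurons completely unmethylated by default, blood nearly fully
    methylated at 0.95). Unmethylated Cs convert C->T except with
    probability ``conversion_failure_prob``; substitutions are applied
    uniformly at rate ``subst_error_rate``; per-base Phred qualities are
    i.i.d. normal, clipped to [2, 41]. A molecule is a truncated fragment
    (random length 30-90% of the amplicon, anchored at either end) with
    probability ``truncated_read_prob``.
    """

    amplicon: AmpliconReference = None  # type: ignore[assignment]
    neuron_fraction: float = 0.0
    n_reads: int = 1000
    blood_cpg_meth_prob: float = 0.95
    neuron_cpg_meth_prob: float = 0.0
    conversion_failure_prob: float = 0.0
    subst_error_rate: float = 0.0
    mean_quality: float = 12.0
    quality_sd: float = 3.0
    truncated_read_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.amplicon is not None, "amplicon", "is required")
        _require(self.amplicon.n_cpgs >= 1, "amplicon", "must contain at least one CpG")
        for name in (
            "neuron_fraction",
            "blood_cpg_meth_prob",
            "neuron_cpg_meth_prob",
            "conversion_failure_prob",
            "subst_error_rate",
            "truncated_read_prob",
        ):
            _require(0.0 <= getattr(self, name) <= 1.0, name, "must be in [0, 1]")
        _require(self.n_reads >= 1, "n_reads", "must be >= 1")
        _require(self.mean_quality >= 0, "mean_quality", "must be >= 0")
        _require(self.quality_sd >= 0, "quality_sd", "must be >= 0")


def simulate_amplicon_reads(
    config: ReadSimConfig, read_id_prefix: str = "read"
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate bisulfite-amplicon reads from a neuron/blood mixture.

    Returns
    -------
    records
        FASTQ-ready ``SeqRecord`` objects (forward strand only — the assay
        primers amplify only the forward strand) with Phred qualities in
        ``letter_annotations``.
    truth
        Per-read planted truth: read_id, molecule (neuron/blood),
        truncated flag, number of methylated CpGs planted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ref = config.amplicon
    n, L = config.n_reads, len(ref.sequence)
    cpg_idx = ref.cpg_index
    k = len(cpg_idx)

    is_neuron = rng.random(n) < config.neuron_fraction
    p_meth = np.where(is_neuron, config.neuron_cpg_meth_prob, config.blood_cpg_meth_prob)
    meth = rng.random((n, k)) < p_meth[:, None]

    # template: fully converted forward strand (all unmethylated Cs -> T)
    template = np.frombuffer(
        ref.bisulfite_sequence_fully_methylated.encode(), dtype="S1"
    ).copy()
    template[cpg_idx] = b"T"
    seqs = np.broadcast_to(template, (n, L)).copy()
    seqs[:, cpg_idx] = np.where(meth, b"C", b"T")

    # incomplete bisulfite conversion: unmethylated Cs that survive as C
    if config.conversion_failure_prob > 0:
        nc = ref.non_cpg_c_index
        fail = rng.random((n, len(nc))) < config.conversion_failure_prob
        seqs[:, nc] = np.where(fail, b"C", seqs[:, nc])
        fail_cpg = (~meth) & (rng.random((n, k)) < config.conversion_failure_prob)
        seqs[:, cpg_idx] = np.where(fail_cpg, b"C", seqs[:, cpg_idx])

    # uniform substitution errors
    if config.subst_error_rate > 0:
        err = rng.random((n, L)) < config.subst_error_rate
        shift = rng.integers(1, 4, size=(n, L))
        codes = np.searchsorted(_BASES, seqs.ravel()).reshape(n, L)
        seqs = np.where(err, _BASES[(codes + shift) % 4], seqs)

    quals = np.clip(
        np.rint(rng.normal(config.mean_quality, config.quality_sd, size=(n, L))),
        2, 41,
    ).astype(int)

    truncated = rng.random(n) < config.truncated_read_prob
    trunc_len = np.rint(rng.uniform(0.3, 0.9, size=n) * L).astype(int)
    anchor_5p = rng.random(n) < 0.5

    records: list[SeqRecord] = []
    rows = []
    for i in range(n):
        seq_b = seqs[i].tobytes().decode()
        q = quals[i]
        if truncated[i]:
            if anchor_5p[i]:
                seq_b, q = seq_b[: trunc_len[i]], q[: trunc_len[i]]
            else:
                seq_b, q = seq_b[-trunc_len[i]:], q[-trunc_len[i]:]
        rid = f"{read_id_prefix}{i:06d}"
        rec = SeqRecord(Seq(seq_b), id=rid, description="")
        rec.letter_annotations["phred_quality"] = q.tolist()
        records.append(rec)
        rows.append(
            (rid, "neuron" if is_neuron[i] else "blood", bool(truncated[i]), int(meth[i].sum()))
        )
    truth = pd.DataFrame(rows, columns=["read_id", "molecule", "truncated", "n_meth_planted"])
    return records, truth


def write_fastq(records: list[SeqRecord], path) -> int:
    """Write records as 4-line Phred-33 FASTQ; returns the record count.

    An empty record list yields an empty file (with a warning); a record
    whose quality length disagrees with its sequence raises with the
    offending read id.
    """
    records = list(records)
    if not records:
        logger.warning("write_fastq: no records; writing empty file %s", path)
        Path(path).write_text("")
        return 0
    for rec in records:
        q = rec.letter_annotations.get("phred_quality")
        if q is None or len(q) != len(rec.seq):
            raise ValueError(
                f"read {rec.id}: quality string length does not match sequence"
            )
    return SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FractionDistribution:
    """Named distribution for planted per-sample neuron fractions.

    kinds: ``constant`` (value), ``uniform`` (low, high), ``mixture``
    (components: list of (weight, FractionDistribution)).
    """

    kind: str
    value: float | None = None
    low: float | None = None
    high: float | None = None
    components: tuple = ()

    def validate(self) -> None:
        if self.kind == "constant":
            _require(self.value is not None and 0 <= self.value <= 1,
                     "fraction_distribution.value", "must be in [0, 1]")
        elif self.kind == "uniform":
            _require(
                self.low is not None and self.high is not None
                and 0 <= self.low <= self.high <= 1,
                "fraction_distribution", "need 0 <= low <= high <= 1",
            )
        elif self.kind == "mixture":
            _require(len(self.components) > 0, "fraction_distribution.components",
                     "mixture needs components")
            for w, d in self.components:
                _require(w >= 0, "fraction_distribution.components", "weights must be >= 0")
                d.validate()
        else:
            raise ConfigurationError(
                f"fraction_distribution.kind: unknown kind {self.kind!r}"
            )

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "constant":
            return float(self.value)
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        weights = np.array([w for w, _ in self.components], dtype=float)
        idx = rng.choice(len(self.components), p=weights / weights.sum())
        return self.components[idx][1].sample(rng)

    @classmethod
    def from_dict(cls, d: dict) -> "FractionDistribution":
        if d["kind"] == "mixture":
            comps = tuple((c["weight"], cls.from_dict(c["dist"])) for c in d["components"])
            return cls(kind="mixture", components=comps)
        return cls(**d)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_samples: int
    fraction_distribution: FractionDistribution


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    replicates_per_sample: int = 2
    seed: int = 0

    def validate(self) -> None:
        _require(len(self.groups) > 0, "groups", "cohort is empty")
        total = 0
        for g in self.groups:
            _require(g.label in COHORT_GROUPS, "groups.label",
                     f"unknown group {g.label!r}; expected one of {COHORT_GROUPS}")
            _require(g.n_samples >= 0, "groups.n_samples", "must be >= 0")
            g.fraction_distribution.validate()
            total += g.n_samples
        _require(total > 0, "groups", "cohort has zero samples")
        _require(self.replicates_per_sample >= 1, "replicates_per_sample", "must be >= 1")


def study_cohort(seed: int = 0) -> CohortSpec:
    """The study-shaped cohort: 25 aged controls, 13 AD, 6 MCI progressors,
    6 MCI stable, 10 young controls, two technical-replicate aliquots each
    (120 plasma FASTQs in total).

    Planted neuron fractions: AD and MCI progressors well above the 5%
    diagnostic cutoff; controls near zero; MCI-stable a 75/25 mixture of
    low and elevated, mirroring the observed split of that clinical group.
    """
    u = lambda lo, hi: FractionDistribution("uniform", low=lo, high=hi)
    mci_stable = FractionDistribution(
        "mixture",
        components=((0.75, u(0.0, 0.02)), (0.25, u(0.08, 0.20))),
    )
    return CohortSpec(
        groups=(
            GroupSpec("aged_control", 25, u(0.0, 0.02)),
            GroupSpec("AD", 13, u(0.08, 0.30)),
            GroupSpec("MCI_progressor", 6, u(0.08, 0.20)),
            GroupSpec("MCI_stable", 6, mci_stable),
            GroupSpec("young_control", 10, u(0.0, 0.01)),
        ),
        replicates_per_sample=2,
        seed=seed,
    )


def simulate_cohort(
    spec: CohortSpec,
    read_config_template: ReadSimConfig,
    out_dir,
) -> pd.DataFrame:
    """Simulate one FASTQ per sample-replicate into ``out_dir``.

    Replicates of a sample share its planted neuron fraction but use
    independent read draws. Returns the truth table (sample_id, replicate,
    group, planted_fraction, fastq, n_reads), also written to
    ``out_dir/truth.tsv``.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    sample_no = 0
    for g in spec.groups:
        for _ in range(g.n_samples):
            sample_no += 1
            sample_id = f"S{sample_no:03d}"
            f = g.fraction_distribution.sample(rng)
            for rep in range(1, spec.replicates_per_sample + 1):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                cfg = replace(read_config_template, neuron_fraction=f, seed=rep_seed)
                records, _ = simulate_amplicon_reads(
                    cfg, read_id_prefix=f"{sample_id}_r{rep}_"
                )
                fastq = out_dir / f"{sample_id}_rep{rep}.fastq"
                write_fastq(records, fastq)
                rows.append((sample_id, rep, g.label, f, fastq.name, len(records)))
    truth = pd.DataFrame(
        rows,
        columns=["sample_id", "replicate", "group", "planted_fraction", "fastq", "n_reads"],
    )
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth
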