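"""Whole-molecule classification, sample ratios, diagnostic calls and
cohort summaries.

Each called read is classified by its whole-molecule mean methylation:

* ``neuron`` — mean methylation exactly 0 (neuron-derived molecules are
  completely unmethylated at the target locus);
* ``blood`` — mean methylation strictly above 0.75 (blood-derived
  molecules are nearly fully methylated);
* ``unknown`` — anything in between, including exactly 0.75.

The neuron-derived cfDNA ratio of a sample is the neuron read count
divided by the total number of reads surviving all processing filters
(neuron + blood + unknown). A sample is called elevated when the ratio
strictly exceeds the diagnostic cutoff (default 5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .reads import ReadMethylation, attrition_counts

__all__ = [
    "NEURON", "BLOOD", "UNKNOWN",
    "SampleResult",
    "CohortReport",
    "classify_read",
    "compute_sample_ratio",
    "call_diagnosis",
    "replicate_concordance",
    "cohort_summary",
    "results_to_frame",
    "plot_ratios_by_group",
]

NEURON, BLOOD, UNKNOWN = "neuron", "blood", "unknown"

BLOOD_METHYLATION_THRESHOLD = 0.75
DIAGNOSTIC_CUTOFF = 0.05
MIN_READS_DEFAULT = 100


def classify_read(call: ReadMethylation) -> str:
    """Three-way whole-molecule class of one called read.

    neuron iff mean methylation == 0 exactly; blood iff > 0.75 strictly;
    unknown otherwise (0.75 itself is unknown). Flagged reads have no
    class and raise.
    """
    if not call.passed or call.mean_methylation is None:
        raise ValueError(
            f"read {call.read_id}: flagged read has no class "
            f"(flags: {sorted(call.filter_flags)})"
        )
    m = call.mean_methylation
    if m == 0.0:
        return NEURON
    if m > BLOOD_METHYLATION_THRESHOLD:
        return BLOOD
    return UNKNOWN


@dataclass(frozen=True)
class SampleResult:
    """Per sample-replicate read counts, ratio and diagnostic call."""

    sample_id: str
    replicate_id: int
    n_neuron: int
    n_blood: int
    n_unknown: int
    filter_attrition: dict = field(default_factory=dict, compare=False)

    min_reads: int = MIN_READS_DEFAULT
    cutoff: float = DIAGNOSTIC_CUTOFF

    @property
    def n_total_called(self) -> int:
        return self.n_neuron + self.n_blood + self.n_unknown

    @property
    def insufficient_depth(self) -> bool:
        return self.n_total_called < self.min_reads

    @property
    def neuron_ratio(self) -> float | None:
        """Neuron reads over all retained reads; None below the depth gate
        (never reported as 0)."""
        if self.insufficient_depth:
            return None
        return self.n_neuron / self.n_total_called

    @property
    def elevated(self) -> bool | None:
        ratio = self.neuron_ratio
        if ratio is None:
            return None
        return call_diagnosis_ratio(ratio, self.cutoff)


def compute_sample_ratio(
    calls: list[ReadMethylation],
    sample_id: str,
    replicate_id: int = 1,
    min_reads: int = MIN_READS_DEFAULT,
    cutoff: float = DIAGNOSTIC_CUTOFF,
) -> SampleResult:
    """Classify all surviving reads of one sample-replicate and compute
    its neuron-derived ratio. The denominator counts every read surviving
    the processing filters, whatever its class."""
    counts = {NEURON: 0, BLOOD: 0, UNKNOWN: 0}
    for c in calls:
        if c.passed:
            counts[classify_read(c)] += 1
    return SampleResult(
        sample_id=sample_id,
        replicate_id=replicate_id,
        n_neuron=counts[NEURON],
        n_blood=counts[BLOOD],
        n_unknown=counts[UNKNOWN],
        filter_attrition=attrition_counts(calls),
        min_reads=min_reads,
        cutoff=cutoff,
    )


def call_diagnosis_ratio(ratio: float, cutoff: float = DIAGNOSTIC_CUTOFF) -> bool:
    """Elevated iff the neuron-derived ratio strictly exceeds the cutoff."""
    return ratio > cutoff


def call_diagnosis(result: SampleResult, cutoff: float = DIAGNOSTIC_CUTOFF) -> bool:
    ratio = result.neuron_ratio
    if ratio is None:
        raise InsufficientDataError(
            f"sample {result.sample_id} rep {result.replicate_id}: "
            f"insufficient depth ({result.n_total_called} < {result.min_reads} reads), "
            f"no diagnostic call"
        )
    return call_diagnosis_ratio(ratio, cutoff)


def results_to_frame(
    results: list[SampleResult], groups: pd.Series | None = None
) -> pd.DataFrame:
    """Per sample-replicate table; ratio/elevated are NA below the depth
    gate."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "replicate": [r.replicate_id for r in results],
            "n_neuron": [r.n_neuron for r in results],
            "n_blood": [r.n_blood for r in results],
            "n_unknown": [r.n_unknown for r in results],
            "n_total_called": [r.n_total_called for r in results],
            "neuron_ratio": [r.neuron_ratio for r in results],
            "elevated": [r.elevated for r in results],
        }
    )
    if groups is not None:
        df.insert(2, "group", df["sample_id"].map(groups))
    return df


def replicate_concordance(results: list[SampleResult]) -> float:
    """Squared Pearson correlation between technical-replicate aliquots.

    Samples contribute one (replicate-1, replicate-2) ratio pair each, in
    fixed replicate_id order; samples without two defined ratios are
    excluded. Fewer than 3 complete pairs raise (the statistic would be
    unreliable).
    """
    by_sample: dict[str, dict[int, float]] = {}
    for r in results:
        if r.neuron_ratio is not None:
            by_sample.setdefault(r.sample_id, {})[r.replicate_id] = r.neuron_ratio
    pairs = [
        (reps[1], reps[2]) for reps in by_sample.values() if 1 in reps and 2 in reps
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"replicate concordance needs >= 3 complete replicate pairs, "
            f"have {len(pairs)}"
        )
    x, y = np.array(pairs).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError(
            "replicate concordance undefined: one replicate vector is constant"
        )
    r = stats.pearsonr(x, y).statistic
    return float(r**2)


@dataclass(frozen=True)
class CohortReport:
    per_sample: pd.DataFrame
    per_group: pd.DataFrame
    sensitivity_ad: float | None  # elevated fraction in the AD group
    specificity_young: float | None  # normal fraction among young controls
    replicate_r2: float | None

    def to_text(self) -> str:
        lines = ["Cohort summary", "=" * 40]
        for _, row in self.per_group.iterrows():
            lines.append(
                f"{row['group']:>15}: {row['n_elevated']}/{row['n_called']} "
                f"elevated ({row['elevated_fraction']:.1%})"
                + (f", {row['n_no_call']} without call" if row["n_no_call"] else "")
            )
        fmt = lambda v: "undefined" if v is None else f"{v:.1%}"
        lines.append(f"AD sensitivity:            {fmt(self.sensitivity_ad)}")
        lines.append(f"Young-control specificity: {fmt(self.specificity_young)}")
        if self.replicate_r2 is not None:
            lines.append(f"Technical-replicate r^2:   {self.replicate_r2:.3f}")
        return "\n".join(lines) + "\n"


def cohort_summary(
    results: list[SampleResult], groups: pd.Series
) -> CohortReport:
    """Group-wise elevated/normal proportions plus headline statistics.

    A sample counts as elevated if any of its replicates with a defined
    ratio is elevated would be one choice; here a sample's call is the
    call on its mean ratio across replicates with defined ratios, which is
    symmetric in the replicates and robust to a single noisy aliquot.
    """
    df = results_to_frame(results, groups)
    unknown = df[df["group"].isna()]["sample_id"].unique().tolist()
    if unknown:
        raise ValueError(f"samples without group label: {unknown}")

    per_sample_calls = []
    for sid, sub in df.groupby("sample_id"):
        ratios = sub["neuron_ratio"].dropna()
        per_sample_calls.append(
            {
                "sample_id": sid,
                "group": sub["group"].iloc[0],
                "mean_ratio": ratios.mean() if len(ratios) else None,
                "elevated": (
                    call_diagnosis_ratio(ratios.mean(), results[0].cutoff)
                    if len(ratios)
                    else None
                ),
            }
        )
    calls = pd.DataFrame(per_sample_calls)

    rows = []
    for grp, sub in calls.groupby("group"):
        called = sub.dropna(subset=["elevated"])
        n_elev = int(called["elevated"].sum())
        rows.append(
            {
                "group": grp,
                "n_samples": len(sub),
                "n_called": len(called),
                "n_elevated": n_elev,
                "n_normal": len(called) - n_elev,
                "n_no_call": len(sub) - len(called),
                "elevated_fraction": n_elev / len(called) if len(called) else np.nan,
            }
        )
    per_group = pd.DataFrame(rows)

    def _frac(group: str, elevated: bool) -> float | None:
        sub = per_group[per_group["group"] == group]
        if sub.empty or sub["n_called"].iloc[0] == 0:
            return None
        col = "n_elevated" if elevated else "n_normal"
        return float(sub[col].iloc[0] / sub["n_called"].iloc[0])

    try:
        r2 = replicate_concordance(results)
    except InsufficientDataError:
        r2 = None

    return CohortReport(
        per_sample=df,
        per_group=per_group,
        sensitivity_ad=_frac("AD", elevated=True),
        specificity_young=_frac("young_control", elevated=False),
        replicate_r2=r2,
    )


def plot_ratios_by_group(report: CohortReport, path) -> None:
    """Strip plot of per-replicate neuron-derived ratios by group, with
    the diagnostic cutoff marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.per_sample.dropna(subset=["neuron_ratio"])
    groups = [g for g in df["group"].unique()]
    fig, ax = plt.subplots(figsize=(7, 4))
    rng = np.random.default_rng(0)
    for i, g in enumerate(groups):
        y = df.loc[df["group"] == g, "neuron_ratio"]
        ax.scatter(i + rng.uniform(-0.15, 0.15, len(y)), y, s=12, alpha=0.7)
    ax.axhline(DIAGNOSTIC_CUTOFF, color="red", ls="--", lw=1, label="5% cutoff")
    ax.set_xticks(range(len(groups)), groups, rotation=20)
    ax.set_ylabel("neuron-derived cfDNA ratio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
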