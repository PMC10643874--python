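"""Sliding-window discovery of differentially methylated regions (DMRs).

The discovery contrast is purified cortical neurons versus blood plasma on
array beta values. Three steps:

1. :func:`qc_bimodality` — density QC: a good methylation-array sample has
   a bimodal beta distribution with prominent peaks in [0, 0.2] and
   [0.8, 1.0] and a flat valley between; deviating samples are excluded.
2. :func:`sliding_window_dmr` — windows of ``window_probe_count``
   consecutive probes advance one probe at a time within each chromosome.
   Each sample is summarised by its mean beta over the window's probes and
   the two groups are compared with a Welch two-sample t-test on those
   per-sample means. Overlapping significant windows are merged into
   maximal runs, each reported once with its minimum p and the delta of
   its best window.
3. :func:`refine_dmrs` — retain high-contrast candidates with
   |delta beta| at or above a threshold (default 0.6).

delta_beta is neuron mean minus plasma mean throughout; coordinates are
1-based inclusive in memory and converted to 0-based half-open BED on
write.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import GROUP_NEURON, GROUP_PLASMA, BetaMatrix
from .errors import InsufficientDataError

__all__ = [
    "GenomicWindow",
    "DMR",
    "qc_bimodality",
    "window_statistics",
    "sliding_window_dmr",
    "refine_dmrs",
    "dmrs_to_bed",
]


@dataclass(frozen=True)
class GenomicWindow:
    """A (merged) significant window: maximal run of overlapping
    single-step windows each passing the p threshold."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    member_probe_ids: tuple[str, ...]
    neuron_mean: float  # of the best (minimum-p) window in the run
    plasma_mean: float
    delta_beta: float  # neuron_mean - plasma_mean, in [-1, 1]
    p_value: float
    n_windows: int = 1  # single-step windows merged into this run


@dataclass(frozen=True)
class DMR(GenomicWindow):
    passes_delta_filter: bool = False


# ---------------------------------------------------------------------------

def qc_bimodality(
    matrix: BetaMatrix,
    peak_min_fraction: float = 0.70,
    valley_max_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-sample bimodality QC of the beta density.

    A sample passes iff the fraction of its betas in the two peaks
    [0, 0.2] u [0.8, 1.0] is at least ``peak_min_fraction`` AND the
    fraction in the valley (0.2, 0.8) is at most ``valley_max_fraction``.

    Returns a DataFrame indexed by sample with columns ``peak_fraction``,
    ``valley_fraction``, ``passed``. Raises if every sample fails.
    """
    vals = matrix.betas.to_numpy()
    in_peaks = (vals <= 0.2) | (vals >= 0.8)
    peak_frac = in_peaks.mean(axis=0)
    valley_frac = 1.0 - peak_frac
    passed = (peak_frac >= peak_min_fraction) & (valley_frac <= valley_max_fraction)
    report = pd.DataFrame(
        {"peak_fraction": peak_frac, "valley_fraction": valley_frac, "passed": passed},
        index=matrix.betas.columns,
    )
    if not passed.any():
        raise InsufficientDataError(
            "bimodality QC excluded every sample; nothing to analyse"
        )
    return report


def apply_qc(matrix: BetaMatrix, report: pd.DataFrame) -> BetaMatrix:
    """Drop samples failing the QC report."""
    keep = report.index[report["passed"]].tolist()
    return matrix.subset_samples(keep)


# ---------------------------------------------------------------------------

def _check_groups(matrix: BetaMatrix) -> tuple[list[str], list[str]]:
    neuron = matrix.samples_in_group(GROUP_NEURON)
    plasma = matrix.samples_in_group(GROUP_PLASMA)
    for name, g in ((GROUP_NEURON, neuron), (GROUP_PLASMA, plasma)):
        if len(g) < 2:
            raise InsufficientDataError(
                f"group {name!r} has {len(g)} sample(s); need >= 2 "
                f"(within-group variance undefined otherwise)"
            )
    return neuron, plasma


def window_statistics(matrix: BetaMatrix, window_probe_count: int) -> pd.DataFrame:
    """Per-window Welch test over all single-step sliding windows.

    Windows never span a chromosome boundary. Returns one row per window:
    chrom, start, end, start_idx (0-based probe index), neuron_mean,
    plasma_mean, delta_beta, p_value.
    """
    if window_probe_count < 1:
        raise ValueError("window_probe_count must be >= 1")
    neuron, plasma = _check_groups(matrix)
    w = window_probe_count
    n_probes = matrix.n_probes
    if n_probes < w:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "start_idx",
                     "neuron_mean", "plasma_mean", "delta_beta", "p_value"]
        )

    vals = matrix.betas.to_numpy()
    # rolling window means per sample via cumulative sums
    cs = np.vstack([np.zeros((1, vals.shape[1])), np.cumsum(vals, axis=0)])
    win_means = (cs[w:] - cs[:-w]) / w  # (n_windows_all, n_samples)

    chrom = matrix.probes["chrom"].to_numpy()
    pos = matrix.probes["pos"].to_numpy()
    valid = chrom[: n_probes - w + 1] == chrom[w - 1:]
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "start_idx",
                     "neuron_mean", "plasma_mean", "delta_beta", "p_value"]
        )

    cols = list(matrix.betas.columns)
    n_idx = [cols.index(s) for s in neuron]
    p_idx = [cols.index(s) for s in plasma]
    xn = win_means[np.ix_(idx, n_idx)]
    xp = win_means[np.ix_(idx, p_idx)]
    res = stats.ttest_ind(xn, xp, axis=1, equal_var=False)
    mn, mp = xn.mean(axis=1), xp.mean(axis=1)

    return pd.DataFrame(
        {
            "chrom": chrom[idx],
            "start": pos[idx],
            "end": pos[idx + w - 1],
            "start_idx": idx,
            "neuron_mean": mn,
            "plasma_mean": mp,
            "delta_beta": mn - mp,
            "p_value": res.pvalue,
        }
    )


def sliding_window_dmr(
    matrix: BetaMatrix,
    window_probe_count: int = 5,
    p_threshold: float = 1e-5,
) -> list[GenomicWindow]:
    """Detect DMRs: significant sliding windows merged into maximal runs.

    Two significant windows are merged when they share probes (their
    0-based start indices differ by less than ``window_probe_count`` on the
    same chromosome); a run is extended transitively and reported once,
    carrying the minimum p over its windows and the group means / delta of
    that best window.
    """
    table = window_statistics(matrix, window_probe_count)
    sig = table[table["p_value"] <= p_threshold]
    if sig.empty:
        return []

    probe_ids = matrix.probes.index.to_numpy()
    w = window_probe_count
    out: list[GenomicWindow] = []
    run: list[pd.Series] = []

    def flush(run: list[pd.Series]) -> None:
        best = min(run, key=lambda r: (r["p_value"], -abs(r["delta_beta"])))
        first, last = run[0], run[-1]
        members = probe_ids[int(first["start_idx"]): int(last["start_idx"]) + w]
        out.append(
            GenomicWindow(
                chrom=str(first["chrom"]),
                start=int(first["start"]),
                end=int(last["end"]),
                member_probe_ids=tuple(members),
                neuron_mean=float(best["neuron_mean"]),
                plasma_mean=float(best["plasma_mean"]),
                delta_beta=float(best["delta_beta"]),
                p_value=float(best["p_value"]),
                n_windows=len(run),
            )
        )

    for _, row in sig.iterrows():
        if run and (
            row["chrom"] != run[-1]["chrom"]
            or row["start_idx"] - run[-1]["start_idx"] >= w
        ):
            flush(run)
            run = []
        run.append(row)
    flush(run)
    return out


def refine_dmrs(
    windows: list[GenomicWindow], min_abs_delta: float = 0.6
) -> list[DMR]:
    """Flag high-contrast DMRs: |delta_beta| >= ``min_abs_delta``
    (inclusive). Output sorted by |delta| descending, ties broken by
    ascending p then by coordinate."""
    dmrs = [
        DMR(
            **{f: getattr(win, f) for f in (
                "chrom", "start", "end", "member_probe_ids", "neuron_mean",
                "plasma_mean", "delta_beta", "p_value", "n_windows")},
            passes_delta_filter=abs(win.delta_beta) >= min_abs_delta,
        )
        for win in windows
    ]
    dmrs.sort(key=lambda d: (-abs(d.delta_beta), d.p_value, d.chrom, d.start))
    return dmrs


def dmrs_to_bed(dmrs: list[DMR], path, passing_only: bool = False) -> pd.DataFrame:
    """Write DMRs as BED-compatible TSV (0-based half-open)."""
    rows = [
        {
            "chrom": d.chrom,
            "start": d.start - 1,
            "end": d.end,
            "name": f"{d.chrom}:{d.start}-{d.end}",
            "abs_delta": abs(d.delta_beta),
            "p_value": d.p_value,
            "delta_beta": d.delta_beta,
            "passes_delta_filter": d.passes_delta_filter,
        }
        for d in dmrs
        if d.passes_delta_filter or not passing_only
    ]
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "abs_delta", "p_value",
                 "delta_beta", "passes_delta_filter"],
    )
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
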