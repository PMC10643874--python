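"""Whole-molecule classification, ratio estimation, diagnostic cutoff,
replicate concordance and cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from neurocfdna.classify import (
    SampleResult,
    call_diagnosis,
    classify_read,
    cohort_summary,
    compute_sample_ratio,
    replicate_concordance,
)
from neurocfdna.errors import InsufficientDataError
from neurocfdna.reads import ReadMethylation, SequencedRead, process_reads
from neurocfdna.simulate import ReadSimConfig, simulate_amplicon_reads


def _call(mean: float | None, flags=frozenset()) -> ReadMethylation:
    return ReadMethylation(
        "r", "toy", ("methylated",), 1, mean_methylation=mean, filter_flags=flags
    )


def _result(n_neuron, n_total, **kw) -> SampleResult:
    return SampleResult(
        "S1", 1, n_neuron=n_neuron, n_blood=n_total - n_neuron, n_unknown=0, **kw
    )


# -- three-way classification ----------------------------------------------

@pytest.mark.parametrize(
    "mean,label",
    [
        (0.0, "neuron"),  # exactly zero methylation -> neuron-derived
        (0.8, "blood"),  # above 0.75 -> blood-derived
        (1.0, "blood"),
        (0.5, "unknown"),
        (0.75, "unknown"),  # boundary itself is unknown (strict >)
        (1e-9, "unknown"),  # any methylation at all disqualifies neuron
    ],
)
def test_classification_thresholds(mean, label):
    assert classify_read(_call(mean)) == label


def test_flagged_read_has_no_class():
    with pytest.raises(ValueError, match="flagged"):
        classify_read(_call(None, flags=frozenset({"low_quality"})))


# -- per-sample ratio ------------------------------------------------------

def test_ratio_arithmetic():
    res = SampleResult("S1", 1, n_neuron=10, n_blood=170, n_unknown=20)
    assert res.n_total_called == 200
    assert res.neuron_ratio == pytest.approx(0.05)


def test_zero_neuron_reads_give_zero_ratio():
    assert _result(0, 500).neuron_ratio == 0.0


def test_insufficient_depth_is_missing_not_zero():
    res = _result(0, 50)  # below the default 100-read gate
    assert res.insufficient_depth
    assert res.neuron_ratio is None and res.elevated is None
    with pytest.raises(InsufficientDataError, match="insufficient depth"):
        call_diagnosis(res)


def test_ratio_estimator_binomial_oracle(chr3_ref, references):
    """Planted f = 0.10, no error, 2000 reads: the end-to-end estimate is
    Binomial(n, f)/n, so it must land within 3 binomial SE of f."""
    cfg = ReadSimConfig(amplicon=chr3_ref, neuron_fraction=0.10, n_reads=2000, seed=31)
    records, _ = simulate_amplicon_reads(cfg)
    reads = [
        SequencedRead(r.id, str(r.seq), tuple(r.letter_annotations["phred_quality"]))
        for r in records
    ]
    res = compute_sample_ratio(process_reads(reads, references), "S1")
    assert res.n_total_called == 2000
    assert abs(res.neuron_ratio - 0.10) < 3 * np.sqrt(0.10 * 0.90 / 2000)


def test_ratio_invariant_to_read_order(chr3_ref, references):
    cfg = ReadSimConfig(amplicon=chr3_ref, neuron_fraction=0.2, n_reads=300, seed=5)
    records, _ = simulate_amplicon_reads(cfg)
    reads = [
        SequencedRead(r.id, str(r.seq), tuple(r.letter_annotations["phred_quality"]))
        for r in records
    ]
    fwd = compute_sample_ratio(process_reads(reads, references), "S1")
    rev = compute_sample_ratio(process_reads(reads[::-1], references), "S1")
    assert fwd.neuron_ratio == rev.neuron_ratio
    assert fwd.elevated == rev.elevated


# -- diagnostic cutoff -----------------------------------------------------

@pytest.mark.parametrize(
    "ratio_counts,expected",
    [
        ((51, 1000), True),  # 5.1% > 5% -> elevated
        ((50, 1000), False),  # exactly 5% is NOT elevated (strict >)
        ((300, 1000), True),  # AD-like sample far above cutoff
        ((0, 1000), False),
    ],
)
def test_diagnostic_cutoff(ratio_counts, expected):
    n_neuron, n_total = ratio_counts
    assert call_diagnosis(_result(n_neuron, n_total)) is expected


# -- replicate concordance -------------------------------------------------

def _results_from_pairs(pairs) -> list[SampleResult]:
    out = []
    for i, (r1, r2) in enumerate(pairs):
        for rep, ratio in ((1, r1), (2, r2)):
            n = 10_000
            out.append(
                SampleResult(f"S{i}", rep, n_neuron=int(round(ratio * n)),
                             n_blood=n - int(round(ratio * n)), n_unknown=0)
            )
    return out


def test_identical_replicates_have_r2_one():
    ratios = [0.01, 0.05, 0.12, 0.25, 0.30]
    r2 = replicate_concordance(_results_from_pairs(list(zip(ratios, ratios))))
    assert r2 == pytest.approx(1.0)


def test_shuffled_replicates_destroy_concordance():
    """Permutation oracle: independently shuffled replicate-2 ratios give
    near-zero r^2 in >= 95% of shuffles."""
    rng = np.random.default_rng(6)
    r1 = rng.uniform(0, 0.3, size=30)
    low = 0
    for _ in range(100):
        r2v = rng.permutation(r1)
        r2 = replicate_concordance(_results_from_pairs(list(zip(r1, r2v))))
        low += r2 < 0.2
    assert low >= 95


def test_too_few_pairs_rejected():
    with pytest.raises(InsufficientDataError, match="3"):
        replicate_concordance(_results_from_pairs([(0.1, 0.1), (0.2, 0.2)]))


def test_incomplete_pairs_excluded():
    results = _results_from_pairs([(0.1, 0.1), (0.2, 0.2), (0.3, 0.3)])
    results.append(SampleResult("S9", 1, n_neuron=5, n_blood=995, n_unknown=0))
    assert replicate_concordance(results) == pytest.approx(1.0)


# -- cohort summary --------------------------------------------------------

def _cohort(results_spec):
    results, labels = [], {}
    for sid, group, ratio in results_spec:
        labels[sid] = group
        n = 1000
        for rep in (1, 2):
            results.append(
                SampleResult(sid, rep, n_neuron=int(ratio * n),
                             n_blood=n - int(ratio * n), n_unknown=0)
            )
    return results, pd.Series(labels)


def test_cohort_sensitivity_and_specificity():
    results, groups = _cohort(
        [("A1", "AD", 0.2), ("A2", "AD", 0.1), ("A3", "AD", 0.08),
         ("Y1", "young_control", 0.0), ("Y2", "young_control", 0.01)]
    )
    report = cohort_summary(results, groups)
    assert report.sensitivity_ad == 1.0
    assert report.specificity_young == 1.0
    assert "AD" in report.to_text()


def test_cohort_empty_ad_group_sensitivity_undefined():
    results, groups = _cohort([("Y1", "young_control", 0.0),
                               ("Y2", "young_control", 0.0),
                               ("Y3", "young_control", 0.0)])
    report = cohort_summary(results, groups)
    assert report.sensitivity_ad is None


def test_cohort_unknown_group_label_rejected():
    results, groups = _cohort([("A1", "AD", 0.2)])
    results.append(SampleResult("ZZ", 1, n_neuron=0, n_blood=1000, n_unknown=0))
    with pytest.raises(ValueError, match="ZZ"):
        cohort_summary(results, groups)


# -- distributional properties --------------------------------------------

def test_ratio_monotone_in_planted_fraction(chr3_ref, references):
    """Averaged over seeds, the estimated ratio is non-decreasing in the
    planted neuron fraction."""
    grid = [0.0, 0.05, 0.1, 0.2, 0.4]
    means = []
    for f in grid:
        est = []
        for seed in range(3):
            cfg = ReadSimConfig(amplicon=chr3_ref, neuron_fraction=f,
                                n_reads=600, seed=100 + seed)
            records, _ = simulate_amplicon_reads(cfg)
            reads = [
                SequencedRead(r.id, str(r.seq),
                              tuple(r.letter_annotations["phred_quality"]))
                for r in records
            ]
            est.append(compute_sample_ratio(process_reads(reads, references), "S").neuron_ratio)
        means.append(np.mean(est))
    assert all(b >= a for a, b in zip(means, means[1:]))


def test_blood_reads_never_classified_neuron(chr3_ref, references):
    """With 9 CpGs at 95% methylation each, a blood molecule reading as
    all-unmethylated has probability 0.05^9; none in 10^4 reads."""
    cfg = ReadSimConfig(amplicon=chr3_ref, neuron_fraction=0.0, n_reads=10_000, seed=41)
    records, _ = simulate_amplicon_reads(cfg)
    reads = [
        SequencedRead(r.id, str(r.seq), tuple(r.letter_annotations["phred_quality"]))
        for r in records
    ]
    res = compute_sample_ratio(process_reads(reads, references), "S1")
    assert res.n_neuron == 0


def test_error_bias_is_one_sided(chr3_ref, references):
    """Substitution error can only move neuron reads to unknown (a single
    false C kills the exact-zero gate) — never create neuron reads — so the
    mean estimated ratio is non-increasing in the error rate."""
    means = []
    for eps in (0.0, 0.01, 0.05):
        est = []
        for seed in (1, 2, 3):
            cfg = ReadSimConfig(amplicon=chr3_ref, neuron_fraction=0.3,
                                n_reads=500, subst_error_rate=eps, seed=seed)
            records, _ = simulate_amplicon_reads(cfg)
            reads = [
                SequencedRead(r.id, str(r.seq),
                              tuple(r.letter_annotations["phred_quality"]))
                for r in records
            ]
            est.append(compute_sample_ratio(process_reads(reads, references), "S").neuron_ratio)
        means.append(np.mean(est))
    assert means[0] >= means[1] >= means[2]
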