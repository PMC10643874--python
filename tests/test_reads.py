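"""Read processing: QC gates, primer demultiplexing, full-molecule
selection, bisulfite-space alignment and per-CpG calling."""

import numpy as np
import pytest
from Bio.Seq import Seq

from neurocfdna.amplicon import AmpliconReference
from neurocfdna.errors import ConfigurationError
from neurocfdna.reads import (
    FILTER_ORDER,
    SequencedRead,
    align_and_call,
    assign_amplicon,
    attrition_counts,
    check_full_molecule,
    process_reads,
    qc_filter,
)
from neurocfdna.simulate import ReadSimConfig, simulate_amplicon_reads
from tests.conftest import make_read


def _bis_read(ref, meth=True):
    """Perfect read of a fully methylated (or unmethylated) molecule."""
    chars = list(ref.bisulfite_sequence_fully_methylated)
    if not meth:
        for i in ref.cpg_index:
            chars[i] = "T"
    return make_read("".join(chars))


# -- quality / length gates ------------------------------------------------

@pytest.mark.parametrize(
    "qual,length,expected",
    [
        (8, 250, {"low_quality"}),  # mean quality below 9 fails
        (12, 199, {"too_short"}),  # shorter than 200 bp fails
        (9, 200, set()),  # both boundaries pass: inequalities are strict
        (8, 199, {"low_quality", "too_short"}),  # both flags may fire
    ],
)
def test_qc_filter_boundaries(qual, length, expected):
    read = SequencedRead("r", "A" * length, (qual,) * length)
    assert qc_filter(read) == frozenset(expected)


def test_qc_filter_uses_mean_quality():
    # per-base scores 4 and 14 average to 9.0 -> passes the strict < 9 gate
    read = SequencedRead("r", "A" * 200, (4, 14) * 100)
    assert read.mean_quality == 9.0
    assert qc_filter(read) == frozenset()


# -- primer demultiplexing -------------------------------------------------

def test_assign_by_forward_primer(references, chr3_ref, chr19_ref):
    r3 = make_read(chr3_ref.forward_primer + "TTTAATT")
    r19 = make_read(chr19_ref.forward_primer + "TTTAATT")
    assert assign_amplicon(r3, references) == chr3_ref.locus_id
    assert assign_amplicon(r19, references) == chr19_ref.locus_id


def test_assign_random_sequence_no_match(references):
    rng = np.random.default_rng(0)
    read = make_read("".join(rng.choice(list("ACGT"), 250)))
    assert assign_amplicon(read, references) is None


def _edit_distance(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (test oracle)."""
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, 1):
            prev, dp[j] = dp[j], min(dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb))
    return dp[-1]


def test_assign_tolerates_primer_edits(references, chr3_ref):
    primer = chr3_ref.forward_primer
    mutated = "A" + primer[1:]  # one substitution (primer starts with T)
    assert _edit_distance(mutated, primer) == 1
    assert assign_amplicon(make_read(mutated + "TTAAT"), references) == chr3_ref.locus_id

    # three edits exceed the budget of 2
    broken = "AAA" + primer[3:]
    assert _edit_distance(broken, primer) == 3
    assert assign_amplicon(make_read(broken + "TTAAT"), references) is None


def test_assign_ambiguous_is_no_match(chr3_ref):
    twin = AmpliconReference(
        locus_id="twin", chrom="chrX", start=1, end=len(chr3_ref.sequence),
        sequence=chr3_ref.sequence[:-1] + "A",
        cpg_positions=chr3_ref.cpg_positions,
        forward_primer=chr3_ref.forward_primer[:-1] + "A",  # 1 edit away
        reverse_primer=chr3_ref.reverse_primer,
    )
    read = make_read(chr3_ref.forward_primer + "TTAAT")
    assert assign_amplicon(read, [chr3_ref, twin], max_primer_edits=2) is None


def test_duplicate_primers_rejected(chr3_ref):
    with pytest.raises(ConfigurationError, match="share a forward primer"):
        assign_amplicon(make_read("ACGT" * 60), [chr3_ref, chr3_ref])


# -- full-molecule selection -----------------------------------------------

def test_full_length_read_is_full_molecule(chr3_ref):
    assert check_full_molecule(_bis_read(chr3_ref), chr3_ref)


def test_five_prime_fragment_rejected(chr3_ref):
    full = _bis_read(chr3_ref).sequence
    frag = make_read(full[: int(0.6 * len(full))])
    assert not check_full_molecule(frag, chr3_ref)


def test_96_percent_span_with_both_primers_passes(chr3_ref):
    """Deleting 4% of interior bases keeps both primers and a span just
    above the 95% requirement."""
    full = _bis_read(chr3_ref).sequence
    n_del = int(0.04 * len(full))
    mid = len(full) // 2
    read = make_read(full[: mid - n_del // 2] + full[mid + (n_del - n_del // 2):])
    assert len(read.sequence) / chr3_ref.expected_length >= 0.95
    assert check_full_molecule(read, chr3_ref)


def test_93_percent_span_fails(chr3_ref):
    full = _bis_read(chr3_ref).sequence
    n_del = int(0.07 * len(full))
    mid = len(full) // 2
    read = make_read(full[: mid - n_del // 2] + full[mid + (n_del - n_del // 2):])
    assert not check_full_molecule(read, chr3_ref)


# -- alignment and calling (toy oracle) ------------------------------------

def test_fully_methylated_toy_read(toy_ref):
    """ACGATTCGT against ACGATCCGT: both CpGs read C -> methylated,
    the non-CpG C (offset 6) correctly converted to T."""
    call = align_and_call(make_read("ACGATTCGT"), toy_ref)
    assert call.per_cpg_state == ("methylated", "methylated")
    assert call.mean_methylation == 1.0
    assert call.passed


def test_fully_unmethylated_toy_read(toy_ref):
    call = align_and_call(make_read("ATGATTTGT"), toy_ref)
    assert call.per_cpg_state == ("unmethylated", "unmethylated")
    assert call.mean_methylation == 0.0


def test_unconverted_non_cpg_c_is_conversion_failure(toy_ref):
    """The raw genomic sequence still carries its non-CpG C at offset 6:
    bisulfite conversion failed, the read must be removed."""
    call = align_and_call(make_read("ACGATCCGT"), toy_ref)
    assert call.filter_flags == frozenset({"conversion_failure"})
    assert call.mean_methylation is None


def test_conversion_failure_tolerance_configurable(toy_ref):
    call = align_and_call(make_read("ACGATCCGT"), toy_ref, conversion_failure_tolerance=1)
    assert call.passed and call.mean_methylation == 1.0


def test_half_methylated_toy_read(toy_ref):
    call = align_and_call(make_read("ACGATTTGT"), toy_ref)
    assert call.per_cpg_state == ("methylated", "unmethylated")
    assert call.mean_methylation == 0.5


def test_gap_at_cpg_breaks_full_molecule_contract(toy_ref):
    # deletion removes the second CpG's C -> missing state -> flagged
    call = align_and_call(make_read("ACGATTGT"), toy_ref)
    assert "not_full_molecule" in call.filter_flags
    assert call.mean_methylation is None


def test_unrelated_sequence_is_no_locus_match(toy_ref):
    call = align_and_call(make_read("GGGGGGGGG"), toy_ref)
    assert call.filter_flags == frozenset({"no_locus_match"})


# -- batch processing ------------------------------------------------------

@pytest.fixture(scope="module")
def noisy_batch(chr3_ref):
    cfg = ReadSimConfig(
        amplicon=chr3_ref, neuron_fraction=0.2, n_reads=400,
        subst_error_rate=0.01, conversion_failure_prob=0.01,
        truncated_read_prob=0.25, mean_quality=10, quality_sd=4, seed=17,
    )
    records, truth = simulate_amplicon_reads(cfg)
    reads = [
        SequencedRead(r.id, str(r.seq), tuple(r.letter_annotations["phred_quality"]))
        for r in records
    ]
    return reads, truth


def test_filter_accounting_conserves_reads(noisy_batch, references):
    reads, _ = noisy_batch
    calls = process_reads(reads, references)
    counts = attrition_counts(calls)
    assert counts["input"] == len(reads)
    assert counts["passed"] + sum(counts[f] for f in FILTER_ORDER) == counts["input"]
    # at least some attrition at these noise settings, and most reads survive
    assert 0 < counts["passed"] < counts["input"]


def test_mean_methylation_on_cpg_grid(noisy_batch, references, chr3_ref):
    reads, _ = noisy_batch
    k = chr3_ref.n_cpgs
    grid = {i / k for i in range(k + 1)}
    for call in process_reads(reads, references):
        if call.passed:
            assert call.mean_methylation in grid


def test_error_free_calls_match_planted_truth(chr3_ref, references):
    """With no sequencing error and complete conversion, per-read calls
    reproduce the simulator's planted methylation exactly."""
    cfg = ReadSimConfig(
        amplicon=chr3_ref, neuron_fraction=0.3, n_reads=300,
        blood_cpg_meth_prob=0.95, seed=23,
    )
    records, truth = simulate_amplicon_reads(cfg)
    reads = [
        SequencedRead(r.id, str(r.seq), tuple(r.letter_annotations["phred_quality"]))
        for r in records
    ]
    calls = process_reads(reads, references)
    assert len(calls) == len(truth)
    for call, (_, row) in zip(calls, truth.iterrows()):
        assert call.passed
        assert call.read_id == row["read_id"]
        n_meth = sum(s == "methylated" for s in call.per_cpg_state)
        assert n_meth == row["n_meth_planted"]
        expect_neuron = row["molecule"] == "neuron"
        assert (call.mean_methylation == 0.0) == (row["n_meth_planted"] == 0)
        if expect_neuron:
            assert call.mean_methylation == 0.0


def test_reverse_complement_read_is_no_locus_match(chr3_ref, references):
    """Only forward-strand logic exists: a reverse-complemented read is
    rejected outright, never miscalled."""
    fwd = _bis_read(chr3_ref).sequence
    rc = make_read(str(Seq(fwd).reverse_complement()))
    calls = process_reads([rc], references)
    assert calls[0].filter_flags == frozenset({"no_locus_match"})
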