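# Methods

This note records the models, parameter choices and numerical decisions
behind `neurocfdna`, and what the simulation studies do and do not
demonstrate.

## The measurement model

The assay targets genomic loci where purified cortical neurons are
completely unmethylated at every CpG while blood plasma cfDNA is nearly
fully methylated. Plasma cfDNA is bisulfite-converted (unmethylated C →
T; methylated C protected), PCR-amplified with primers designed against
converted DNA, and nanopore-sequenced. Because CpG methylation is
symmetric across strands, the primers amplify only the forward strand;
the package therefore contains forward-strand logic only, and a
reverse-complemented read is rejected as not matching the locus rather
than risk a miscall.

Each sequenced molecule is summarised by its *whole-molecule* mean
methylation m over the locus's CpGs — the per-molecule methylation
haplotype collapsed to one number. The three-way rule (neuron iff m = 0
exactly; blood iff m > 0.75 strictly; unknown otherwise, including
m = 0.75) makes the neuron call maximally conservative: a single
methylated CpG disqualifies a molecule. Consequently sequencing error can
only *lose* neuron reads (a miscalled base at any CpG moves a neuron
molecule to unknown), never create them — the estimator's error-induced
bias is one-sided and downward, which the test suite asserts over error
rates 0–5%.

The per-sample **neuron-derived ratio** divides neuron reads by all reads
that survived processing (neuron + blood + unknown). Keeping unknown
reads in the denominator is the literal reading of "total reads in the
sample" after filtering; it makes the ratio slightly conservative.
A sample is **elevated** when the ratio strictly exceeds the 5% cutoff.

## Read filtering

Gates run in a fixed order — mean Phred < 9; length < 200 bp; no unique
forward-primer match within 2 edits; not a fully amplified molecule;
bisulfite-conversion failure — and each read is attributed to its first
failing gate, so the attrition log partitions the input exactly
(n_in = n_passed + Σ n_flag). "Quality score" is interpreted as the
arithmetic mean of per-base Phred scores. "Fully amplified molecule" is
operationalised as: forward primer at the 5′ end and
reverse-complemented reverse primer at the 3′ end (each within 2 edits),
primer-to-primer span ≥ 95% of the expected amplicon length, and every
reference CpG callable after alignment.

Calling aligns each read globally (edlib, unit edit costs) to the
bisulfite-space reference: non-CpG C written as T, each CpG C as a
two-state symbol matching both C and T, so methylation status never
biases the alignment. At a CpG, read C → methylated, T → unmethylated,
gap/other → missing. A read base C at a reference position whose genomic
base was a non-CpG C is an unconverted cytosine; more than the tolerance
(default 0, i.e. any) removes the read as a conversion failure. The
tolerance is configurable because at high nanopore error rates a strict
zero discards reads whose "unconverted C" is really a miscall. Alignments
worse than 30% edits are treated as not matching the locus at all.

## DMR discovery

Windows of `window_probe_count` (default 5) consecutive probes advance
one probe at a time and never span chromosomes. Each sample is summarised
by its mean beta over the window's probes and the neuron and plasma
groups are compared by a Welch two-sample t-test on those per-sample
means — the least-assumption two-group statistic, chosen because window
means need not share variance across groups. Overlapping significant
windows (p ≤ 10⁻⁵) are merged into maximal runs so one signal is not
counted once per overlapping window; a merged region reports its minimum
p and the group means of that best window. Refinement keeps regions with
|Δβ| ≥ 0.6, inclusive. Coordinates are 1-based inclusive in memory and
0-based half-open in BED output. Sample-level QC requires ≥ 70% of a
sample's betas in the bimodal peaks [0, 0.2] ∪ [0.8, 1.0] and ≤ 25% in
the valley; input betas are assumed already normalised (array
preprocessing and SWAN normalisation are upstream of this package).

**Calibration caveat.** With 4 neuron vs 8 plasma samples, the
Welch–Satterthwaite approximation is measurably liberal deep in the
tail: direct simulation of the statistic on exactly-normal data (4×10⁶
draws) shows ~1.35× the nominal rate at p = 10⁻³ and ~1.8× at 10⁻⁵.
This is a property of the approximation at these group sizes, not of the
implementation (window p-values match an independent closed-form oracle
to 10⁻¹⁰). At the scan's operating point it is immaterial — planted
effects of Δβ = 0.8 against noise sd 0.02 sit at t ≈ 65, and expected
null false positives in the recovery experiments are ≪ 1 — but the null
false-positive-rate test bounds the empirical rate at the order of the
nominal threshold (within a factor 2.5 at 10⁻³) rather than at exact
nominal.

## Simulators

The simulators are first-class, tested code; their defaults are the study
conditions, and every draw derives from the config seed
(`numpy.random.default_rng`), so identical configs give byte-identical
outputs.

**Beta matrices.** Null probes draw a bimodal baseline — low peak
U(0.08, 0.18), high peak U(0.82, 0.92), equal weight — shared by both
groups up to a per-probe offset uniform in ±`null_delta_max`; planted
probes put the neuron mean at (1−Δ)/2 and the plasma mean at (1+Δ)/2
(neuron minus plasma negative, as at the assay's chr3 marker). Per-probe
noise is Gaussian (sd 0.02 by default), clipped to [0, 1]; the peaks sit
at least 4 sd from the boundaries so clipping never distorts the null
distribution. Each planted region occupies its own contig of exactly one
window of probes, with all null probes on a single separate contig: this
makes planted regions non-overlapping by construction and the
planted/null window accounting exact, which is what the recovery
experiments (957-site refinement, 37,455-region scan) require. Real
arrays have irregular probe spacing, probe-specific variances and
correlated neighbours; these are deliberately not modelled, so the
recovery experiments demonstrate correctness of the statistics and
bookkeeping, not performance on real EPIC data.

**Amplicon reads.** A molecule is neuron-derived with probability f
(the planted truth), blood-derived otherwise. Per-CpG methylation is
Bernoulli: 0 for neurons ("complete unmethylation"), 0.95 for blood —
deliberately not 1.0, encoding "nearly full" methylation, which also
exercises the blood/unknown boundary (with 9 CpGs, a blood molecule
falls to unknown when ≥ 3 CpGs draw unmethylated, ~0.8% of molecules).
Unmethylated Cs convert to T except with probability
`conversion_failure_prob`; substitutions hit every base uniformly at rate
ε (uniform choice among the three other bases); per-base Phred qualities
are i.i.d. normal (default mean 12, sd 3), clipped to [2, 41] — enough
to exercise the quality gate, with no attempt to model nanopore's
error–quality correlation or indels (substitution-only by default).
Truncated molecules (probability 0.1 by default) are 5′- or 3′-anchored
fragments of 30–90% length, giving the full-molecule filter real
rejections. The published assay reports no error rate for its runs, so
ε defaults are free parameters; the cohort experiments use ε = 0.5%.

**Cohorts.** The study-shaped cohort plants per-sample neuron fractions
of AD ~ U(0.08, 0.30), MCI-progressors ~ U(0.08, 0.20), aged controls
~ U(0, 0.02), young controls ~ U(0, 0.01), and stable MCI as a 75/25
mixture of low and elevated (mirroring that group's observed split; with
6 patients the 75/25 proportion cannot be realised exactly and this group
anchors no headline number). Two aliquots per sample share the planted
fraction but draw reads independently — technical replication is modelled
as pure counting noise, without PCR or conversion batch effects, so the
simulated replicate r² (~0.99 at depth 2000, where between-sample
variance ≫ binomial noise) sits above, not at, an assay benchmark of
0.93.

With ε = 0 and complete conversion, every read survives and the ratio
estimate is exactly Binomial(n, f)/n; the suite verifies this binomial
oracle across f, the O(1/√depth) decay of the truth-vs-estimate error
over depths 500–8000, and monotonicity of the estimate in f.

## Other numerical and design choices

* Depth gate: ratios from fewer than 100 surviving reads are reported as
  missing (never 0) and excluded from cohort statistics — a 5% cutoff is
  meaningless on a handful of reads.
* Demultiplexing requires a *unique* primer match: a read matching two
  references within the edit budget is discarded rather than guessed.
* Replicate r² is the squared Pearson correlation of replicate-1 vs
  replicate-2 ratios in fixed replicate order; a cohort-level sample call
  is made on the mean ratio across its aliquots with defined ratios.
* Mean methylation of a called read lies on the grid {0, 1/k, …, 1} for
  k reference CpGs; classification boundaries (0, 0.75, 5%) are exact
  comparisons on that grid, with strict inequalities at 0.75 and at the
  cutoff.
* Pipeline outputs are written atomically (temp file + rename) and every
  run records a manifest with the config hash and seed; the filter
  attrition log lets the read-conservation invariant be audited from
  outputs alone.
* Problem sizes in the shipped experiments (2000 reads per aliquot,
  50,000-probe null backgrounds, 37,455-region recovery) were chosen as
  the smallest scales at which the binomial and Poisson error bounds are
  decisively informative for the quantities being reproduced.

## Known limitations

* The example amplicons' interiors are synthetic; only their primer ends
  and CpG-layout role match the published assay, so no conclusion about
  the real chr3/chr19 sequences follows from them.
* No indel model: nanopore indel errors would hit the exact-zero neuron
  gate harder than substitutions; whether that matters on real data is
  untested here.
* Planted-truth recovery on idealised arrays says nothing about how a
  sliding-window scan would behave on the original GEO array cohorts
  (GSE66351 neurons vs GSE108462 plasma); the 37,455/957 counts are
  reproduced as recovery experiments, not as a re-analysis.
* Single-locus classification only; multi-locus composite scoring is out
  of scope.
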