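# neurocfdna

Whole-molecule methylation analysis of **neuron-derived cell-free DNA
(cfDNA)** in blood plasma — a liquid-biopsy readout of neuronal cell death
aimed at early detection of neurodegenerative disease.

When neurons die, fragments of their DNA reach the bloodstream. Neuronal
DNA can be told apart from the overwhelming background of blood-derived
cfDNA by its methylation pattern: at suitable marker loci, cortical-neuron
DNA is completely unmethylated at every CpG while blood cfDNA is almost
fully methylated. This package implements the full analysis chain around
that idea, for researchers working with methylation arrays and targeted
bisulfite-amplicon nanopore sequencing:

1. **DMR discovery** (`neurocfdna.dmr`) — find differentially methylated
   regions between purified cortical neurons and blood plasma on array
   beta values β ∈ [0, 1]: per-sample bimodality QC, a sliding-window
   Welch *t*-test on per-sample window means (windows of 5 probes
   advancing one probe at a time, significant windows merged into maximal
   runs, p ≤ 10⁻⁵), and refinement to high-contrast sites with
   |Δβ| = |β̄_neuron − β̄_plasma| ≥ 0.6.
2. **Read processing** (`neurocfdna.reads`) — turn amplicon FASTQ into
   per-read whole-molecule methylation calls: mean-Phred ≥ 9 and length
   ≥ 200 bp gates, primer-based locus assignment (≤ 2 edits), selection of
   fully amplified molecules (both primers, ≥ 95% span, every CpG
   callable), rejection of reads with unconverted cytosines outside CpG
   context, and per-CpG C/T calling by global alignment in bisulfite
   space.
3. **Classification** (`neurocfdna.classify`) — each called molecule with
   mean methylation m over its CpGs is *neuron-derived* iff m = 0,
   *blood-derived* iff m > 0.75, *unknown* otherwise. Per sample,

   &nbsp;&nbsp;&nbsp;&nbsp;neuron ratio = n_neuron / (n_neuron + n_blood + n_unknown),

   and a sample is called **elevated** when the ratio exceeds the 5%
   diagnostic cutoff. Cohort summaries report group-wise calls, AD
   sensitivity, young-control specificity and technical-replicate r².
4. **Simulators** (`neurocfdna.simulate`) — fully seeded generators for
   every input: beta matrices with planted DMRs on a bimodal background,
   and bisulfite-amplicon nanopore reads from neuron/blood mixtures with
   substitution error, incomplete conversion, truncated molecules and
   quality strings — so every claim the pipeline makes can be checked
   against planted truth.

The shipped example amplicon references carry the published primer pairs
of the targeted assay (chr3 and chr19 loci); their interior sequences are
synthetic stand-ins generated from a fixed seed (see
`neurocfdna.amplicon.synthetic_chr3_amplicon`).

## Worked example

Simulate the study-shaped cohort — 25 aged controls (planted neuron
fraction f ~ U(0, 0.02)), 13 Alzheimer's patients (f ~ U(0.08, 0.30)),
6 MCI patients who later progressed (f ~ U(0.08, 0.20)), 6 stable MCI
patients (75/25 low/elevated mixture), 10 young controls (f ~ U(0, 0.01)),
two technical-replicate aliquots each, 2000 reads per aliquot with 0.5%
substitution error — and run the full pipeline:

```bash
neurocfdna simulate --seed 1 --out out/
cat out/cohort_report.txt
```

```
Cohort summary
========================================
             AD: 13/13 elevated (100.0%)
 MCI_progressor: 6/6 elevated (100.0%)
     MCI_stable: 0/6 elevated (0.0%)
   aged_control: 0/25 elevated (0.0%)
  young_control: 0/10 elevated (0.0%)
AD sensitivity:            100.0%
Young-control specificity: 100.0%
Technical-replicate r^2:   0.992
```

Every AD and MCI-progressor sample (planted above the cutoff) is called
elevated; every control (planted near zero) is called normal; the two
aliquots of each sample agree to r² = 0.99. `out/` also contains the
per-read call table, the filter-attrition log (each read attributed to
its first failing gate), per-sample ratios, the planted-truth table and a
truth-vs-estimate comparison.

The DMR scan runs the same way from TSV inputs:

```bash
neurocfdna dmr --betas betas.tsv --groups groups.tsv \
    --window 5 --pmax 1e-5 --min-delta 0.6 --out dmrs.tsv
```

or on simulated arrays via `neurocfdna run --config cfg.yaml` with
`mode: dmr_only`. All thresholds default to the values in
`src/neurocfdna/defaults.yaml`.

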