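# sigensemble

Ensemble classification of multi-gene prognostic signatures across
microarray pre-processing pipeline variants.

## The problem

Transcriptomic risk signatures are notoriously sensitive to how the raw
expression data were pre-processed: the same signature applied to the same
patients can assign different risk groups depending on the normalization
algorithm, the probe annotation, and whether cohorts were normalized
separately or merged. `sigensemble` treats that sensitivity as a signal
rather than a nuisance. Every variant of a factorial pre-processing design
(6 algorithms × 2 annotations × 2 dataset-handling modes = 24 variants)
classifies each patient as high or low risk; each classification is a
vote; only patients voted the same way by *every* variant receive a risk
group, and those unanimous groups are evaluated by survival analysis. The
package is aimed at researchers developing or validating prognostic
signatures who want classifications that are robust to pre-processing
choices, together with the machinery to study how ensemble composition and
size drive performance.

## The method

For a signature of N up-regulated genes, a patient's score under one
pipeline variant is

    Score = Σₙ genₑₓₚᵣ,ₙ ,  n = 1..N

where genₑₓₚᵣ,ₙ is +1 if the patient's expression of gene n lies strictly
above the cohort median and −1 otherwise. Patients are median-dichotomized
on these scores into high/low risk groups per variant. The **ensemble
score** of a patient is the count of variants voting high (0..24); only
ensemble scores 0 and 24 are classified (low / high), everything else is
left unclassified. Risk stratification is measured by the unadjusted Cox
proportional-hazards hazard ratio (high vs low, Efron tie correction) with
a Wald test against HR = 1, plus Kaplan-Meier curves. Because scoring uses
only ranks, a log₂-transformed variant classifies identically to its
normal-space partner — the 24-variant design yields exactly 16 distinct
classifications.

Supporting machinery: matched-count individual classification (comparing a
single pipeline against the ensemble at equal group sizes), intersect/union
combination of two signatures' ensembles, per-gene univariate Cox screens
with Benjamini-Hochberg FDR, a factorial linear model of significant-gene
counts with backward stepwise AIC refinement, random and exhaustive
ensemble-size sweeps, and paired t-tests between pipeline aspects. A
synthetic-cohort generator (latent risk → signature-gene expression and
exponential event times, with per-variant pipeline noise and exact log₂
pairs) makes the whole workflow testable without raw array data.

## Worked example

Simulate a 200-patient cohort with a 20-gene signature, render all 24
pipeline views, and run the full analysis:

```bash
sigensemble simulate --n-patients 200 --n-genes 100 --signature-size 20 \
    --seed 42 --out inputs
cat > run.yaml <<EOF
expression_dir: inputs
design_manifest: inputs/design.yaml
clinical: inputs/clinical.tsv
gmt: inputs/signatures.gmt
output_dir: results
reps: 200
sweep_sizes: [1, 2, 4, 8, 16, 24]
seed: 42
EOF
sigensemble run --config run.yaml
sigensemble evaluate --classification results/ensemble_synthetic_signature.tsv \
    --clinical inputs/clinical.tsv
```

which prints

```
HR = 8.881 (95% CI 4.649-16.965), Wald p = 3.75e-11, events = 55
high = 56, low = 65, unclassified = 79 (60.5% classified)
```

The unanimity ensemble classifies 60.5% of patients and separates their
hazards by a factor of 8.9. Compare the ensemble-size sweep summary
(`results/sweep_summary_synthetic_signature.tsv`):

```
n   mean_hr  mean_log2_hr  mean_pct_classified
1   4.12     2.04          100.0
2   5.13     2.35          88.6
4   6.10     2.60          79.2
8   7.21     2.84          69.9
```

Single pipelines classify everyone but stratify at HR ≈ 4.1 on average;
growing the ensemble trades coverage for progressively stronger risk
separation — the signature pattern of unanimity ensembles. Per-pipeline
and matched-count evaluations are in `results/evaluations.tsv`, and paired
aspect comparisons (annotation, handling) in
`results/aspect_comparisons.tsv`.

The same functionality is available as a library — see
`sigensemble.simulate_cohort`, `classify_views`, `unanimous_classify`,
`evaluate_classification`, `sweep_ensemble_size`, and
`sigensemble.assessment` for the per-gene screening and count modelling.

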