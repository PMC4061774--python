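# Methods

## Model and procedure

`sigensemble` implements unanimity-vote ensemble classification over a
factorial design of expression pre-processing pipelines.

**Design.** A pipeline variant is a triple (algorithm, annotation,
handling) drawn from 6 normalization algorithms (RMA, GCRMA, MAS5,
log₂MAS5, MBEI, log₂MBEI), 2 probe annotations (default, alternative) and
2 dataset-handling modes (separate, merged): 24 variants. log₂MAS5 and
log₂MBEI are *declared* monotone pairs of MAS5 and MBEI — their matrices
are exact elementwise log₂ transforms, never independently noisy. Because
all downstream classification is rank-based, a log₂ variant can never
disagree with its partner, so the 24 variants produce at most 16 distinct
classifications. The variants are nevertheless kept as 24 separate votes:
unanimity over 24 votes equals unanimity over the 16 effective ones, and
the bookkeeping mirrors the factorial design that sweeps and aspect
comparisons need.

**Scoring and classification.** For a signature of up-regulated genes, a
patient scores +1 per gene strictly above the cohort median and −1
otherwise, summed over the signature's genes present in the matrix (N
reported). Patients are split at the median score: strictly above →
high risk, otherwise low. The strict-greater rule at the gene level
defines ties-at-median as low; the same rule is applied at the score
level for consistency (the score-level tie rule is an implementation
choice — see "Open choices"). Scores have the parity of N and lie in
{−N, …, N}.

**Ensemble.** Each variant's high/low call is a vote; the ensemble score
is the per-patient count of high votes (0..24). Only unanimous patients
(score 0 or M) are classified; all others are deemed unreliable and
excluded. Matched-count classification re-labels a single pipeline's
patients by score rank — exactly as many high and low labels as the
ensemble assigned — so ensemble and single-pipeline evaluations compare at
equal group sizes (ties in score rank are broken by patient id,
lexicographically, for determinism). Two signatures' ensembles can be
combined by *intersect* (label only where both agree) or *union* (label
where at least one assigns a label and the other agrees or abstains);
conflicting labels are excluded in both modes.

**Evaluation.** Risk groups are compared with a univariate Cox
proportional-hazards model (binary covariate, high = 1), the Wald test of
log HR ≠ 0, a normal-approximation 95% CI on the log-HR scale, and
Kaplan-Meier curves. "Superior" classification means the higher HR point
estimate.

## Statistical machinery

**Binary Cox fit.** The single-binary-covariate Cox fit is implemented
in-package as a 1-D Newton-Raphson maximizer of the Efron-corrected
partial likelihood. With a binary covariate the Efron denominators reduce
to a0 + a1·e^β with constants (a0, a1) precomputable per (event time, tie
index), so each iteration is a few vectorized array operations; a fit
costs microseconds rather than the milliseconds of a general solver, which
is what makes per-gene screens (thousands of genes × 24 variants) and
ensemble-size sweeps (2000 replicates × 24 sizes) tractable. The fitter
is validated in the test suite against both a literal grid-search/golden-
section maximization of the partial likelihood (agreement to 1e-4 on a
fixed suite of ≤ 8-patient instances with ties) and lifelines'
`CoxPHFitter` (agreement to ~1e-5, limited by lifelines' own convergence
threshold). Degenerate inputs — an empty group, zero events, or a
monotone likelihood (all events in one group, complete separation of
event order, |β| diverging past 15) — return an explicit non-estimable
result object, never an exception or a silently huge coefficient.

**Bought components.** Kaplan-Meier estimation and the continuous-
covariate Cox fit (used to validate the generator's hazard model) come
from lifelines; BH-FDR from statsmodels `multipletests`; paired t-test and
Spearman correlation (midrank ties) from scipy. The factorial count model
is ordinary least squares via statsmodels.

**Count model.** Significant-gene counts per pipeline are modelled on the
treatment-coded factorial design — annotation, platform, handling, and
algorithm (5 dummies against the GCRMA baseline; baselines: alternative
annotation, HG-U133A platform, merged handling) — either main effects
only or with all pairwise interactions. Backward stepwise refinement uses
Gaussian AIC, n·ln(RSS/n) + 2(k+1) with the additive constant dropped
(only differences matter), removing whole interaction blocks (or main
effects once free of interactions — marginality is enforced) while any
removal lowers AIC. Adjusted R² is reported; with nearly as many
parameters as informative contrasts it can be negative. Note AIC is not a
consistent selector: a null 1-df interaction survives with probability
≈ P(χ²₁ > 2) ≈ 0.16, so on main-effects-only data the stepwise removes
*most* but not reliably *all* interactions; the tests assert the expected
count rather than all-or-nothing pruning.

**FDR scope.** q-values are computed within each pipeline variant
separately (each variant is its own multiple-testing family).
Non-estimable genes have no p-value and are excluded from the FDR input
m rather than imputed.

## Synthetic cohorts

The generator emulates the statistical structure the ensemble method
assumes, without raw array data:

- latent risk z ~ N(0, 1) per patient;
- signature genes = effect_size·z + N(0, noise_sd_gene²); other genes pure
  noise;
- event times exponential with rate baseline_hazard·exp(β·z);
  administrative censoring uniform on (0, censor_horizon]; observed time
  the minimum, event indicator accordingly;
- each non-log pipeline view = base matrix + independent N(0,
  noise_sd_pipeline²) noise, shifted by (1 − min) when needed so all
  values are strictly positive (rank-preserving, keeps log₂ defined);
  log views are exact log₂ of their partner;
- per-variant noise comes from a CRC-keyed substream of the master seed,
  so adding a variant to a design never perturbs the others; identical
  config + seed gives bit-identical cohorts.

Defaults describe one moderately sized breast-cancer-like cohort:
n_patients = 200 (roughly the per-cohort size when a ~2000-patient
meta-dataset spans ten cohorts), n_genes = 500 with a 20-gene signature,
effect_size = 1 and noise_sd_gene = 1 (signal-to-noise ≈ 0.7 per gene),
noise_sd_pipeline = 1 (pipeline noise comparable to biological noise — a
deliberately adversarial regime in which single pipelines disagree
often), β = 1 per unit latent risk, baseline hazard 0.05 per time unit
and a censoring horizon of 30 time units (≈ 30-40% censoring, typical of
long-running follow-up).

What the generator does *not* emulate: batch structure across cohorts,
platform-specific probe effects, heavy-tailed or correlated gene noise,
informative censoring, and any real biology of the signature genes. Tests
passing on these cohorts show that the pipeline-sensitivity and ensemble
mechanics behave as designed — not that any particular real signature
will stratify real patients.

Survival endpoint and censoring structure are deliberately generic
(exponential events, uniform administrative censoring): the framework
consumes any right-censored (time, event) pair in consistent units.

## Numerical choices

- Newton iterations: start β = 0, damped steps (halving until the
  likelihood does not decrease), convergence at |grad| < 1e-9, divergence
  flagged at |β| > 15; SE from the observed information at the optimum.
- Median ties: strict-greater rule throughout (gene level and score
  level); constant gene vectors map everyone to −1 and raise a
  diagnostic flag instead of erroring.
- Duplicate gene rows (one signature gene, several matrix rows): the row
  with the highest variance across patients is used.
- Ensemble-size sweeps: each replicate draws its subset without internal
  replacement; repeated subsets across replicates are allowed and not
  deduplicated. Replicates with non-estimable Cox fits are kept as NaN and
  excluded from means, with the exclusion count reported. Sweep summaries
  report mean HR both raw and on the log₂ scale.
- Positivity shift before log₂ uses the global matrix minimum, adding
  (1 − min) only when min ≤ 0.

## Open choices and limitations

- The score-level median tie rule (ties → low) and the matched-count tie
  rule (patient-id order) are implementation decisions; alternatives
  (ties → high, random tie-breaks) would change individual labels on tied
  boundaries but not the method's structure.
- Union combination keeps a patient labelled by one ensemble and
  unlabelled by the other; only explicit high/low conflicts are excluded.
- The aspect paired comparison surfaces a degenerate-input error when a
  level pair's HR differences have zero variance — which always happens
  for the MAS5 vs log₂MAS5 and MBEI vs log₂MBEI algorithm pairs, since
  log pairs classify identically. The full-analysis driver logs and skips
  such aspects.
- Strict unanimity is the only voting rule (no majority/weighted voting),
  mirroring the framework's conservative design; subsets of patients left
  unclassified are the price of robustness.
- On desk-scale cohorts the across-replicate HR *range* at fixed ensemble
  size is non-monotone in mid-range sizes (Cox sampling noise on the
  shrinking classified subset competes with subset-diversity tightening);
  the range reliably tightens approaching the full ensemble and is exactly
  zero at n = M. Test sizes throughout (cohorts of 60-400 patients,
  signatures of 6-20 genes, 200-replicate sweeps averaged over 50 seeds)
  were chosen as the smallest problems at which these qualitative shapes
  are stable.
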