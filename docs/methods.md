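# Methods

This note documents the models, rules and numerical choices behind
`ckdpipe`, in the order the pipeline applies them.

## Time and missingness conventions

All time is fractional patient age in years; windows are arithmetic on age
(30 days = 30/365.25 y ≈ 0.0821 y). Calendar dates, time zones and hospital
identifiers are out of scope. A missing value is the *absence* of an entry
(an empty field on disk, an absent key in memory); zero is never a missing
sentinel. The shipped analyte catalog lists 35 routine canine data types
(clinical chemistry, hematology, urinalysis) with literature-typical adult
reference intervals; reference intervals differ between laboratories, so the
catalog is fully user-overridable and only creatinine, BUN, USG and urine
protein are mandatory.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real hospital population.

* **Groups.** Latent `CKD`, `NO_CKD` and `PROBABLE` groups. Group moments at
  the evaluation age (mean (SD)): CKD creatinine 2.67 (1.86) mg/dL, BUN
  56.23 (32.72) mg/dL, USG 1.020 (0.011), urine protein 91.01 (180.81) mg/dL,
  age 11.56 (3.37) y, weight 13.04 (11.20) kg, ~15 visits; no-CKD 1.09
  (0.29), 17.38 (5.59), 1.039 (0.012), 49.52 (136.21), 7.19 (2.93) y,
  15.10 (12.42) kg, ~12 visits. Non-core analytes are stationary noise
  around the reference-interval midpoint (SD = interval/4) in both groups.
* **Trajectories.** Each CKD patient's analyte expectation interpolates
  linearly from the healthy mean to the CKD mean over the progression window
  (default 2 y before the diagnosis age); SDs interpolate the same way;
  weight declines ~10 % over the window. Only endpoint moments are
  specified by the study conditions, so linear-in-expectation is the minimal
  trajectory assumption; the window is configurable.
* **Sampling distributions.** An analyte whose interpolated mean is within
  five SDs of zero is drawn from a gamma distribution matched to that
  mean/SD (moment-exact, non-negative, right-skewed like real chemistry
  values); otherwise from a normal. USG is clipped to the physically
  meaningful [1.001, 1.065]; normals are floored at zero. Clipped-normal
  bias is negligible precisely because the normal branch only fires when the
  mean is ≥ 5 SDs from the boundary; the gamma branch avoids the substantial
  truncation bias a clipped normal would introduce for skewed analytes.
* **Visit schedule.** Visit counts are Poisson around the group mean (min 2);
  gaps are exponential (default mean 0.5 y, floor 0.02 y); CKD schedules
  anchor at the diagnosis visit with 0–2 shortly-after visits; no-CKD
  schedules anchor at the last visit, placed 2 y after the target evaluation
  age so labeling recovers it. Ages are confined to [1.5, 22] y.
* **Missingness.** Each blood analyte is masked independently per visit
  (default 10 %); the urinalysis panel is masked per visit as a single block
  (default 60 %), reflecting that urinalysis is simply not performed at most
  visits. Weight is missing at 5 % of visits.
* **Probable patients** carry no diagnosis code but receive 2–3 injected
  CKD-suggesting signals (a renal note phrase, a high creatinine, a low USG).
* **Determinism.** Every patient draws from its own spawned `SeedSequence`
  stream, so cohorts are bit-reproducible given the seed.

What the generator does **not** emulate: between-analyte correlation given
the trajectory mean (analytes are conditionally independent), breed effects,
comorbidities, seasonal patterns, or informative visit timing (in real data,
sick dogs are measured more often — here schedules are disease-independent).
Passing tests therefore demonstrate that the pipeline recovers structure it
assumes, not that the trained model would transfer to clinical data.

## Labeling rules

Diagnosis codes are matched case-insensitively against a configurable set
(default `{CKD}`). T0 for a diagnosed patient is the age at the *first*
diagnosed visit (diagnoses may repeat); visits more than 30 days after T0
are trimmed. "At least two CKD-suggesting data points" is read as two
*distinct criteria* (high creatinine anywhere, low USG anywhere, lexicon
note token anywhere, each counted once); the alternative per-measurement
reading is a config switch (`count_mode="measurements"`). A structured
CKD-risk flag is represented as the dedicated note token `CKD_RISK`. "At
least 2 years of data" for no-CKD validation is operationalised as visit
span ≥ 2 y. Probable-CKD records are labeled and counted but never trained
on and never enter headline sensitivity/specificity.

## Cohort construction

* **Outlier rule**: mask values above `normal_high + 6 × SD`, with the SD
  estimated per analyte from the cohort's observed values (overridable);
  only high extremes are masked, because low extremes (e.g. dilute urine)
  are clinically meaningful.
* **Lab-free visit removal**: a pre-T0 visit is dropped when it has neither
  blood nor urine values; the stricter both-required reading is available
  via `require_both=True` but would discard most visits at ~60 % urine
  missingness.
* **Eligibility**: ≥ 2 visits within 4 y before T0, with the share of those
  visits carrying ≥ 1 blood (urine) result strictly above 50 % (25 %).
  Fractions are per-visit presence shares, not per-cell completeness.
* **Split**: stratified by status, `round(0.67·n)` per group to training,
  deterministic given the seed.
* **Augmentation**: truncated copies (last *k* visits removed,
  k = 1..n−1) whose gap to T0 is ≤ 2 y, for CKD *and* no-CKD training
  records; copies carry `(origin id, k)` provenance and are never created
  for the test set. Keeping all truncations regardless of gap is available
  via `drop_long_gaps=False`.

## Imputation

Chained (MissForest-style) scheme: initialise missing cells at column means;
visit columns in order of ascending missingness; regress each analyte on all
others with a random-forest regressor (default 50 trees, `min_samples_leaf=5`;
a ridge-regression `method="linear"` exists for fast runs); update missing
cells; stop when the normalised squared change of imputed values falls below
`tol=1e-3` or after `max_iter=10` rounds. Per-column fits subsample at most
`max_fit_rows` rows (default 5000) to bound cost; predictions always cover
every missing cell. The fitted per-column regressors are retained so the
held-out partition is imputed by the training-fitted model — the imputer is
fitted on training data only by default (a `impute_before_split` flag
reproduces impute-then-split behaviour). Observed cells are preserved
bit-identically; imputed USG is clipped to [1.001, 1.065] and other analytes
to ≥ 0. The imputer's inputs contain no status, T0 or diagnosis fields, so
label leakage is structurally impossible.

## Recurrent classifier

Features per visit: creatinine, BUN, USG, urine protein, weight, age —
standardised by a scaler fitted on training data. Age is supplied per visit,
so truncated copies naturally look "younger"; missing weight is carried
forward from the most recent prior visit, else the training-cohort median.

Architecture: stacked tanh recurrent layers (default widths 5-3-3), final
two-unit softmax head; p(CKD) is component 0. Training: mean cross-entropy
minimised by full backpropagation through time with RMSprop
(lr 1e-3, decay 0.9, ε 1e-8), inverted dropout (rate 0.2) on hidden
activations during training only (the dropped activation feeds both the next
layer and the recurrence), 8 epochs, sequences processed unpadded in shuffled
mini-batches. Initialisation is fan-in-scaled uniform, fixed by the seed.

The batch size defaults to 8: with the epoch budget fixed at 8, larger
batches leave the loss still steeply descending and the classifier
over-reliant on the age feature; 8 gives roughly four times as many RMSprop
updates and brings training near plateau at the default cohort size. Batch
size, learning rate and decay are config-exposed.

Gradient correctness is the load-bearing test: analytic BPTT gradients are
compared to central finite differences (relative error ≤ 1e-4, observed
~1e-8) on small random nets.

**Model selection.** Wrapper feature selection runs greedy forward
(bottom-up) and backward (top-down) passes with a two-hidden-layer 3-7 base
net, scoring each candidate subset by mean F1 at the p = 0.5 cutoff over
stratified 3-fold cross-validation of cross-entropy-trained models — the
package's reading of scoring by "F1 cross-entropy"; a soft-F1 training loss
is a possible alternative reading but is not implemented. The architecture
screen scores a config grid by mean CV F1 (default 10-fold), breaking ties
toward fewer parameters; the default desk-scale grid uses widths
{3, 5, 10, 20} and depths 1–3, with larger grids reachable by config.

## Evaluation

Predictions use p ≥ 0.5 (ties positive). Confidence intervals are Wald
normal-approximation intervals with the exact 97.5 % quantile 1.959964 (the
rounded 1.96 is a flag), clipped to [0, 1]. Predictive values use the Bayes
identities with an externally supplied prevalence (default 0.83 %), because
the case-enriched test set's sample prevalence is not the population's; at
the sample prevalence the formulas reduce exactly to the confusion-matrix
PPV/NPV (property-tested). Detection at T0 restricts to records with a
usable visit within 0.25 y of T0. Horizon evaluation truncates CKD records
to visits ≥ h years before T0; records with no remaining visits leave the
denominator (a count-as-missed mode exists); no-CKD records are scored
untruncated, since their T0 is an administrative anchor without clinical
meaning. Stratified reports partition by whole age-year at T0, canine life
stage (adult [1.5, 6.5), mature [6.5, 9.75), senior [9.75, 13), geriatric
[13, ∞); boundaries belong to the older stage), or pre-T0 visit count.

## Pipeline, problem sizes and reproducibility

One global seed derives independent per-stage seeds by spawning a numpy
`SeedSequence`, so stages can be rerun in isolation. The manifest records
the config hash, stage seeds and the full record funnel
(simulated → labeled → eligible → train/test → augmented), reconciled so
records-in = records-out + records-rejected at every stage.

The default study replica uses 500 CKD + 500 no-CKD + 50 probable patients
with a reduced imputer (15 trees, ≤ 3 rounds, 2000-row fit subsample) — the
package's desk-scale choice; module defaults keep the full imputer (50
trees, ≤ 10 rounds). Generator calibration is checked at 5,000 patients per
group (group T0 means of creatinine/BUN/USG within 3 standard errors).

## Known limitations

* The trajectory model is linear in expectation with conditionally
  independent analytes; real renal decline is nonlinear and correlated.
* Specificity among old patients is genuinely poor — age is a feature and
  the healthy and CKD age distributions overlap — so stratum-level
  specificity in geriatric dogs can be near zero in small test strata. This
  mirrors the clinical trade-off the model makes by design.
* The Wald interval is inaccurate near rates of 0 or 1 at small n; it is
  retained for protocol fidelity rather than statistical optimality.
* PROBABLE_CKD records are identified but never scored; their clinical
  ambiguity is out of scope.
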