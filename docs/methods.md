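# Methods

## Estimation model

The estimator predicts a blood-gas target y (pH or PaCO₂) at time t from the
most recent prior blood gas and contemporaneous noninvasive measurements. One
*key predictor* z = pH[t−1] modulates every other predictor's effect through a
bank of M logistic sigmoids f_j(z) = σ(s·(z − c_j)):

    ŷ = b + Σ_{j=1..M} Σ_{i=0..K} w_ij · f_j(z) · x_i

* x_1..x_K are the non-key predictors of the feature table — PaCO₂[t−1],
  HCO₃⁻[t−1], PetCO₂[t], PetCO₂[t−1], and the deltas ΔFiO₂, ΔPEEP, ΔPIP,
  ΔMnAwP, ΔSpO₂, ΔTVin, ΔTVexp (current minus previous) — each standardized
  to training mean 0 / SD 1. A constant term x₀ ≡ 1 lets the key predictor
  act through Σ_j w_0j f_j(z).
* b is a global unpenalized intercept; all K·M interaction weights share one
  ridge penalty λ, solved in closed form from the normal equations.
* The model is fitted separately per target (pH, PaCO₂) on the natural target
  scale.

The bilinear form is chosen for transparency: the prediction decomposes
*exactly* into per-predictor contributions g(xᵢ) = Σ_j w_ij f_j(z) xᵢ (machine
precision; enforced by tests), each contribution is linear in xᵢ at fixed z,
and its key-conditional slope varies smoothly across the pH axis. The
per-sample importance of predictor i is the contribution shift relative to the
population, Iᵢ = g(xᵢ) − g(x̄ᵢ), evaluated with the key predictor held at the
sample's observed value; predictors are displayed ranked by |Iᵢ|. The
alternative convention — scoring non-key predictors with the key at its own
population mean — differs only by a multiplicative f-weighting and was not
adopted because holding z at the observed value answers the bedside question
"given this patient's previous pH, which measurements moved the estimate?".

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| M | grid {3, 5, 7} | number of sigmoid centers over previous pH |
| s | grid {5, 10, 20} per pH unit | shared sigmoid sharpness |
| centers c_j | equally spaced quantiles of training pH[t−1], clipped to [7.0, 7.6] | basis placement |
| λ | log grid 10⁻³ … 10³ | ridge penalty on interaction weights |

Selection minimizes the mean inner-CV 95th-percentile absolute pH error over
all (outer, inner) fold pairs of a 5×5 nested, patient-grouped, pH-stratified
cross-validation; ties keep the earliest grid point. The pure logistic form of
f_j (rather than a normalized partition of unity) was chosen because the
ridge-fitted weights absorb any fixed rescaling of the basis; nothing
downstream assumes Σ_j f_j = 1.

## Feature pipeline

Feature rows pair each observation with its most recent prior blood gas within
24 h (rows with an older or missing prior BG, or missing PetCO₂ at either
time, are dropped). A plausibility filter removes observations outside
generous physiologic bounds (pH 6.5–7.8, PaCO₂ 10–150 mmHg, PetCO₂ 0–150,
HCO₃⁻ 5–60 mmol/L, SpO₂ 0–100 %, FiO₂ 21–100 %, PEEP 0–25, PIP 0–60, MnAwP
0–45 cmH₂O, TV 0–25 mL/kg), logging every rejection; the bounds are
configurable. Derivation rows (never validation rows — enforced structurally
in the pipeline) are resampled toward pH-bin weights 0.17 / 0.54 / 0.29 over
< 7.30 / [7.30, 7.45) / ≥ 7.45: over-represented bins are subsampled without
replacement, under-represented bins keep all rows and duplicate with
replacement, with source indices recorded so the original distribution remains
recoverable. The pH bin edges 7.30 / 7.45 are used consistently everywhere
(stratification, resampling, per-range reporting, safe-range coverage).

## Uncertainty and abstention

The point estimate always comes from the final model trained on all
derivation rows. Uncertainty is the population variance (denominator = number
of models) of the predictions of the 5 outer-fold models — an ensemble
reading of bootstrap-style uncertainty; a true patient-resampling bootstrap
with configurable B is available as an option and behaves similarly at higher
cost. The displayed interval is point ± 1.96·√variance.

A sample is abstained on when its variance *strictly* exceeds a calibrated
threshold (so a degenerate ensemble with identical uncertainties abstains
nothing). Two calibration criteria:

* **rate** (default 0.25): threshold at the 75th percentile of calibration
  uncertainties, abstaining the top quarter;
* **error_bound**: the smallest abstention rate whose retained 95th-percentile
  |pH error| is ≤ 0.1 pH, subject to abstaining on at most half of the
  calibration samples; if unsatisfiable the calibration fails loudly,
  reporting the best achievable error.

The "at most half" cap is applied to samples rather than patients: at any
useful sample-abstention rate, most multi-sample patients have at least one
abstained sample, so a patient-level cap would be unsatisfiable in practice.
Calibration uses the unresampled derivation rows (natural pH distribution) and
the threshold is then frozen; the same row-level abstain decision is applied
to the paired PaCO₂ prediction, since abstention is a property of the sample,
not of the target.

## Synthetic cohort generator

No clinical dataset ships with the package, so a simulator generates cohorts
carrying exactly the structure the estimator exploits:

* **PaCO₂**: per-patient baseline plus a mean-reverting
  (Ornstein–Uhlenbeck-like) deviation. `paco2_ar_coeff` (default 0.75) is the
  autocorrelation over one *median* inter-sample gap and `paco2_noise_sd`
  (3 mmHg) the innovation SD over that gap; both scale continuously with the
  actual elapsed time, so estimation error grows with the age of the previous
  blood gas — the property the time-lag analysis measures.
* **Metabolic state**: HCO₃⁻ follows a random walk (`metabolic_drift_sd`,
  0.6 mmol/L per median gap, scaling with √time).
* **pH** is computed from (PaCO₂, HCO₃⁻) with Henderson–Hasselbalch
  (pK = 6.1, CO₂ solubility 0.03 mmol/L/mmHg — standard physiologic
  constants), so generated triples are exactly consistent.
* **PetCO₂** = PaCO₂·(1 − AVDSf) + noise with a patient-specific alveolar
  dead-space fraction drawn N(0.11, 0.07²) clipped to [0, 0.6].
* **Interventions**: with probability 0.25 per step the PIP changes by a few
  cmH₂O; the subsequent PaCO₂ shifts by a signed coefficient (−1.5 mmHg per
  cmH₂O: more pressure, more CO₂ clearance, lower PaCO₂).
* **Timing**: lognormal inter-sample gaps with median 4.7 h; patients average
  8 samples.
* **Case mix**: 12% of patients are seeded into acidotic/alkalotic baselines
  (35% of them acidotic), which together with within-patient dynamics puts
  roughly 12% / 69% / 18% of samples below / inside / above the 7.30–7.45
  band, the concentration typical of a mixed pediatric ICU. 10% of samples
  are flagged capillary; capillary samples are generated identically to
  arterial ones and matter only for subgroup evaluation.
* **SpO₂/FiO₂** are coupled through a bounded monotone map with noise — just
  enough for the ΔSpO₂/ΔFiO₂ predictors to carry signal, not an oxygenation
  model.

What the generator does **not** emulate: disease-specific trajectories,
missingness patterns, measurement artifacts, charting delays, oxygenation
indices, and real between-predictor correlation structure. Tests passing on
synthetic cohorts therefore demonstrate that the machinery is correct and that
the method behaves as designed under its own assumptions — not clinical-grade
accuracy on real patients.

Two derived benchmark cohorts support the test bench. The *heteroscedastic*
benchmark mixes default patients 50/50 with patients whose PaCO₂-innovation,
metabolic-drift and PetCO₂-noise SDs are tripled; it provides the
error/uncertainty correlation needed to demonstrate that uncertainty-ordered
abstention dominates random abstention. The *drifting* benchmark
(autocorrelation 0.5, drift 2.0 mmol/L, wider lognormal gaps with median 5 h)
populates every lag bin up to 24 h with a lag-degradation signal large enough
to exceed per-bin p95 sampling error at the bench's cohort sizes
(400 derivation / 500 validation patients).

## Evaluation conventions

* Quantiles use linear interpolation between order statistics (the p95 of a
  small bin is method-sensitive, so the method is fixed and documented).
* pH ranges: (−∞, 7.30), [7.30, 7.45), [7.45, ∞); PaCO₂ ranges labeled
  20–35 / 35–60 / 60–120 mmHg with unbounded outer edges so per-range counts
  partition the estimated samples.
* CLIA agreement (|error| ≤ 0.04 pH, ≤ 5 mmHg PaCO₂) and all error statistics
  are computed on non-abstained samples.
* Safe-range coverage: a prediction covers the truth's pH range when the
  closed interval point ± half-width intersects the truth's half-open bin.
* Bland–Altman limits are mean ± 1.96·SD (ddof = 1) of estimate − truth.
* Model comparison uses a two-sided Mann–Whitney U on absolute errors: exact
  null distribution for tie-free samples of ≤ 50, normal approximation with
  tie correction otherwise.
* Time-lag bins are [0–2, 2–4, 4–6, 6–8, 8–12, 12–24] h; empty bins are
  omitted and bins under 20 samples flagged low-n.
* The first-vs-previous analysis re-links the same cohort twice (most recent
  prior BG with the 24 h cap, vs the admission BG with no cap — every later
  sample must reuse it) and evaluates the same fitted model on both.

## Numerical and degenerate-input choices

Standardization scales of constant predictors fall back to 1 to avoid
division by zero. Basis centers from degenerate pH data fall back to an even
grid over [7.0, 7.6]; duplicate quantiles are nudged apart. A singular
normal-equations system at λ = 0 raises with instructions to use λ > 0.
Negative dead-space fractions (PetCO₂ > PaCO₂ under noise) are kept, with a
warning, because clipping would bias the carry-forward baseline's inversion;
AVDSf ≥ 1 makes that inversion undefined and the row is flagged not
estimated. Hyperparameter ties keep the first grid point. The master pipeline
seed fans out to per-stage child seeds via a seed sequence so stages can be
re-run independently and the whole run is bit-reproducible.

## Problem sizes

The default demonstration and the reproduction script use 500-patient
derivation and 200-patient validation cohorts (~2,800 / ~1,400 feature rows),
which give p95 estimates stable to a few thousandths of a pH unit while a full
run — simulation through selection, training, calibration and evaluation —
completes in well under a minute on one CPU. The bench's property checks use
150–500 patients per cohort, chosen as the smallest sizes at which the
measured quantities are stable across seeds.

## Known limitations

* The estimator requires at least one recent blood gas; patients without one
  are out of scope, and there is no predictor of *which* patients will
  generate high-uncertainty samples.
* Abstention is calibrated on pH only and shared with PaCO₂.
* The synthetic generator's simplicity means reported accuracies characterize
  the method under its assumptions, not expected clinical performance; the
  clinical accuracies reported for real ICU data are not reproducible here
  because such data are access-restricted.
* Selection from the wider candidate-predictor pool is exposed (ridge-based
  pruning over the same CV machinery) but the shipped default is the fixed
  final predictor list above.
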