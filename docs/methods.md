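# Methods

`mcisurv` re-implements, as a tested pipeline over synthetic cohorts, a
risk-stratification and survival-forecasting workflow for mild cognitive
impairment (MCI): CSF amyloid-quartile risk groups defined by regional
gray-matter atrophy centroids, discrete-time neural survival models that
predict the conditional probability of conversion to Alzheimer's disease
(AD) in three follow-up bins, censoring-aware evaluation, and voxel-level
attribution of the convolutional model. This note records the models, the
synthetic-data design, the numerical choices, and what the tests do and do
not establish.

## Discrete-time survival model

Follow-up is divided into three left-inclusive bins, [0, 24), [24, 48) and
[48, 108) months after the MCI visit. A model outputs a conditional hazard
h_j ∈ (0, 1) per bin — the probability of converting during bin j given
survival to its start. Survival to the end of bin j is Π_{i≤j}(1 − h_i);
the probability of converting in bin j is h_j·Π_{i<j}(1 − h_i).

Each outcome is encoded as per-bin indicators: an event in bin j
contributes ln h_j for bin j and ln(1 − h_i) for earlier bins; a censored
subject contributes ln(1 − h_j) for every bin whose midpoint the censoring
time reaches (half-interval credit, so a subject censored early in a bin
neither earns nor loses credit for it). Events at or beyond 108 months are
treated as censored at 108, because the prediction grid ends at the last
bin edge. The training objective is the negative of the summed
log-likelihood. Two properties anchor the implementation and are verified
directly: the per-bin optimum over constant hazards is the empirical
discrete hazard d_j/r_j, and the telescoping identity
S(j−1) − S(j) = h_j·Π_{i<j}(1 − h_i) holds for all hazard triples.
Hazards are clipped to [1e−7, 1 − 1e−7] before logs. Monthly survival
curves interpolate within bins by constant hazard (geometric decay); the
bin ends are interpolation-free.

## Networks

Both survival networks are implemented directly in NumPy with hand-written
backprop. They are small (≤ ~10^5 parameters), so this keeps training fast
on one CPU, makes every run exactly reproducible from a seed, and exposes
input gradients for the attribution analysis without extra machinery.
Gradients are verified against finite differences in the test-suite.

* **MLP** — input batch-normalization → affine(hidden, default 100) →
  dropout (default 0.2) → batch-normalization → leaky-ReLU → affine(3) →
  sigmoid. Input: 66 hemisphere-averaged, intracranial-volume-normalized
  regional gray-matter volumes, Z-scored to the discovery reference. The
  hidden width is a free choice (the architecture's description leaves it
  open); 100 is the default and configurable.
* **S-CNN** — two stages of [3×3×3 convolution (stride 1, no padding) →
  batch-normalization → leaky-ReLU → 2×2×2 max-pool], with 10 then 20
  filters, then flatten → dense(32) → dropout → leaky-ReLU → dense(3) →
  sigmoid; L2 weight decay 0.01, dropout 0.3, Kaiming-uniform
  initialization. For a 32³ input the flattened width is 20·6³ = 4,320.

Training is plain SGD on the survival loss with mean-normalized gradients
(step size independent of batch size). Sample weights are either uniform
or inverse-propensity (1/frequency of the subject's encoded outcome
pattern, normalized to mean 1). A checkpoint is kept per epoch: either the
lowest validation survival loss (MLP default) or the highest validation
concordance at 24 months (S-CNN default). Reference epochs/learning rates
follow the source configuration (S-CNN 2,000 epochs, lr 0.01, batch 10);
the desk-scale analyses in this repository train for far fewer epochs
(8–40), which the checkpoint rule makes safe — the problem sizes here are
deliberate choices to keep every analysis runnable on a laptop CPU.
At a learning rate of exactly zero the training loop runs in evaluation
mode, so dropout and normalization statistics are untouched and the
history is exactly constant — a null update.

Reference models: an elastic-net Cox model (coefficient path via
scikit-survival's coordinate descent; features Z-scored to the training
fold; penalty and L1 ratio chosen by mean validation concordance over the
three horizons; Breslow baseline cumulative hazard computed in-package and
tested against a brute-force evaluation), and a censored Weibull model
S(t|x) = exp(−(t/λ(x))^k(x)) with a log-linear link for the scale,
maximized by L-BFGS with analytic gradients for a fixed iteration budget
and no early stopping. The shape k is a single free parameter by default —
a covariate-dependent shape k(x) is available via a flag but is
ill-conditioned when the feature count (66) approaches the per-fold event
count, so the classical accelerated-failure-time form is the default —
and a mild ridge penalty (weight 1, intercepts exempt) on the covariate
coefficients keeps the link stable at desk-scale sample sizes.

## Synthetic cohorts

The generator emulates the statistical structure of the study cohorts, not
their images or measurements:

* **Groups.** Four latent risk groups H, IH, IL, L with default fractions
  (0.257, 0.194, 0.167, 0.381), the discovery cohort's printed group sizes
  normalized to 1. CSF amyloid-β is uniform within disjoint per-group
  ranges spanning the assay limits [200, 1700] pg/mL, with the H group at
  the lowest concentrations.
* **Atrophy.** Each group has a mean Z-shift per region, built from
  lobe-level severities: high-risk groups follow the AD gradient (mesial
  temporal worst — by definition the entorhinal area, parahippocampal
  gyrus, hippocampus, amygdala — then lateral temporal, parietal,
  spreading outward), while the low-risk group shows mild
  frontal/basal-ganglia-predominant, aging-like change. A fixed per-group,
  per-region multiplicative jitter (±50%, frozen seed) models idiosyncratic
  regional vulnerability and gives each group a distinctive rank pattern —
  necessary because the assignment statistic (Spearman correlation) is
  blind to profile magnitude and sees only rank order. Subject profiles add
  independent Gaussian noise (default SD 0.5 Z-units) and convert to volume
  fractions through fixed per-region reference means/SDs shipped in the
  region catalog (SD = 12% of the mean, a typical between-subject spread).
  The severity magnitudes were calibrated once so that centroid assignment
  at the reference noise level recovers ≥90% of group labels at n = 400,
  the regime the stratification analysis assumes; accuracy degrades
  monotonically as noise grows.
* **Region catalog.** 66 hemisphere-averaged gray-matter regions plus two
  ventricular regions, with Neuromorphometrics-style names and lobe
  assignments, shipped as editable CSV data. Only the mesial-temporal
  membership is anatomically canonical; other lobe assignments are the
  package's own catalog.
* **Outcomes.** Conversion follows the discrete model exactly: sequential
  Bernoulli draws over the three bins with the group's hazards, uniform
  placement within the chosen bin, administrative censoring at 108 months
  for survivors of all bins. Default hazards give ~42% lifetime conversion
  with the H group fastest. Independent censoring is uniform on (0, 108],
  applied to a calibrated fraction of subjects so the marginal censored
  fraction hits the target (default 0.72, the discovery cohort's rate);
  the calibration is closed-form from the hazard mixture. When the target
  is unreachable (events too early/frequent), the generator logs and uses
  the administrative floor.
* **Volumes.** Optional 3D images place the 66 regions as non-overlapping
  ellipsoids on a lattice inside a cubic grid (default 32³). Voxel
  intensity in region r is baseline·(1 + effect_scale·z_r) plus Gaussian
  noise; background is 0, and the region-id map is shared by all subjects.
  These are geometric stand-ins for registered, skull-stripped brains —
  they test the survival-CNN pipeline end to end but say nothing about
  real MRI appearance, scanner effects, or registration error.

Named scenario configurations (`mcisurv.scenarios`) freeze the study
conditions used by the analyses, tests and the acceptance script; the
strong-signal scenarios separate the group hazards more than the
cohort-emulating defaults, because under the default hazards even an
oracle ranking by the true generating hazards cannot exceed a concordance
of ≈0.69 — a ceiling of the emulated cohorts, not of any model.

## Stratification

Amyloid quartiles use linear-interpolation percentiles with
left-open/right-closed bins above H (the convention is the package's
choice; ties inside a profile use average ranks). Centroids are unweighted
within-group means of Z-scored profiles. Assignment maximizes Spearman
correlation against the four centroids; exact ties break toward the
higher-risk group (conservative for screening) and are flagged.

## Evaluation

* **Concordance.** Pairs (i, j) with an observed event for i and
  t_i < t_j; risk ties count ½. The risk score at horizon T is 1 − Ŝ(T).
  The implementation is checked for exact equality against brute-force
  enumeration.
* **IPCW Brier score.** BS(t) = n⁻¹ Σ [1{t_i ≤ t, event}·Ŝ_i(t)²/G(t_i⁻) +
  1{t_i > t}·(1 − Ŝ_i(t))²/G(t)], with G the Kaplan-Meier estimate of the
  censoring distribution from the training fold (flipped indicator; at
  tied times events precede censorings, so subjects with events at t leave
  the at-risk set before the censoring hazard at t forms; G(t⁻) is a left
  limit). Subjects that would need a zero weight are excluded and logged.
  The integrated Brier score is the trapezoidal integral over exactly the
  three bin ends, normalized by the 84-month range.
* **Truncation.** When test follow-up exceeds the training range,
  evaluation times are clipped to the training maximum and the boundary
  survival value comes from shape-preserving (PCHIP) interpolation of the
  monthly curve; monotonicity is preserved by construction.
* **Uncertainty.** Mean-curve bands by subject-level bootstrap (default
  10,000 replicates, percentile 2.5/97.5, chunked to bound memory);
  permutation nulls for the concordance of a given score vector.

Kaplan-Meier estimation (product-limit, Greenwood variance, log(−log)
confidence bands) is implemented in-package because the fixed-point
survival test needs the Greenwood variance on the log(−log) scale;
lifelines is the independent oracle in the tests. The fixed-point
chi-square statistic is evaluated at the KM step values; the cited
implementation interpolates the cumulative variance between event times,
so the two agree at event times and differ only by that interpolation.
Hazard ratios come from a univariate Cox partial likelihood with Breslow
ties (statsmodels), Wald 95% intervals; non-convergence (separation) is
reported, not raised. Benjamini-Hochberg adjustment is applied within each
family of pairwise tests.

## Attribution

Attributions are integrated gradients along the straight path from each of
six background volumes (a small training subset) to the input, averaged
over backgrounds. The networks are a sigmoid head over a piecewise-linear
body, so the path integral is computed segment-wise: the body's input
gradient is taken at each interval midpoint and the interval's
contribution is rescaled by the exact change of the head output across the
interval. Because each interval's voxel contributions then sum exactly to
that output change, the completeness identity — attributions for bin j sum
to f_j(x) − mean_b f_j(b) — holds by construction at any step count (up to
intervals with an exactly zero path-slope, which contribute nothing); the
step count (default 16, 8 in the desk-scale analyses) only controls how
finely attribution is resolved spatially. Aggregation follows the study
design: absolute values averaged over output bins (and folds), group-mean
difference maps Z-scored over in-mask voxels (background voxels excluded
from the mean/SD) and thresholded at |Z| ≥ 2.5 (2.0 available via the
threshold argument), and per-region mean absolute attribution with
pairwise Wilcoxon signed-rank tests, BH-adjusted within each risk group,
plus bootstrap intervals on group means. Identically zero difference maps
return an empty map rather than an error; a constant non-zero difference
map is degenerate and raises.

## Degenerate inputs and numerical choices

Quartiles require ≥4 non-missing amyloid values and non-degenerate cut
points; missing amyloid is excluded and flagged, never imputed.
Zero-variance Z-profiles are rejected (ranks undefined). The survival
difference test reports (not raises) when S(t) ∈ {0, 1}. The Weibull
optimizer clips log-parameters to avoid overflow and reports convergence
diagnostics. Fold splitting assigns shuffled k-ths as test and validation
(3:1:1 at k = 5) so test sets tile the cohort. All stage seeds derive
deterministically from a global seed and a stage tag (CRC-based, < 2³¹).

## What the tests show — and do not

Passing tests establish that the statistical machinery is correct (oracle
equality for concordance, hand-computed IPCW fixtures, likelihood
identities), that each stage recovers the structure its generator planted
(group labels, hazard ordering, Weibull parameters, mesial-temporal
importance), and that the pipeline is deterministic end to end. They do
not establish clinical performance: the synthetic cohorts have no
measurement error in amyloid, no site or scanner effects, independent
censoring by construction, and atrophy patterns exactly aligned with the
generating risk groups. Numbers obtained here characterize the method
under its own assumptions, not MCI prognosis in any real population.

## Known limitations

* The hemisphere-pairing and lobe map beyond the mesial temporal lobe is a
  package catalog, not a published atlas table.
* The S-CNN here is trained from scratch at desk scale; transfer learning
  from a large pretraining corpus is out of scope (a synthetic-pretraining
  hook would slot into `train_model` but is not implemented).
* Reversion from MCI to normal cognition is not modeled; non-converters
  are administratively censored.
* The NumPy networks run on CPU only; they are sized for the synthetic
  study, not for full-resolution MRI.

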