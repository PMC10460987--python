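# mcisurv

Risk-based stratification of mild cognitive impairment (MCI) and
discrete-time neural survival modeling of conversion to Alzheimer's
disease (AD), built as a fully synthetic, reproducible analysis pipeline.

Not every person with MCI develops AD, and identifying who is likely to
convert — and when — matters for trial enrollment and early intervention.
This package implements two linked ideas for that problem and exercises
them end to end on simulated cohorts that mimic the statistical structure
of real MCI studies (four amyloid-defined risk strata, graded regional
gray-matter atrophy, heavy right-censoring):

1. **CSF amyloid-quartile risk stratification.** Subjects are split by
   quartiles of CSF amyloid-β (lowest quartile = highest risk). Within
   each quartile the Z-scored regional gray-matter volumes are averaged
   into a centroid profile, and any subject is assigned the risk group
   whose centroid maximizes the Spearman correlation ρ with their own
   profile.
2. **Discrete-time neural survival models.** With follow-up split into
   left-inclusive bins [0,24), [24,48), [48,108) months, a network
   predicts per-bin conditional hazards h_j and is trained on the
   censoring-aware log-likelihood

       Loss_j = Σ_{i≤d_j} ln h_ji + Σ_{i=d_j+1}^{r_j} ln(1 − h_ji),
       Loss_S = Σ_j Loss_j,

   (r_j subjects in view in bin j, the first d_j of them converting), so
   that Pr(survival through bin j) = Π_{i≤j}(1 − h_i). Both a
   feature-based MLP and a 3D survival CNN (S-CNN) share this head, and
   are compared against elastic-net Cox and Weibull reference models with
   the concordance index and the IPCW integrated Brier score.

The audience is biostatisticians and ML-for-neuroimaging researchers who
want a tested, importable implementation of the full chain — simulation,
stratification, survival modeling, censoring-aware evaluation, and
voxelwise attribution — without access-restricted clinical data.

## Layout

- `src/mcisurv/` — the library: `simulate` (synthetic cohorts, 3D
  volumes, folds), `volumetrics` (TIV normalization, hemisphere
  averaging, ventricle exclusion, Z-scoring, lobes), `stratify`
  (quartiles, centroids, assignment), `classical` (Kaplan-Meier,
  fixed-point tests, hazard ratios, elastic-net Cox, BH), `discrete`
  (bins, encoding, survival loss, hazard-to-curve), `nets` (NumPy
  MLP/S-CNN with SGD), `weibull`, `evaluation` (concordance, IPCW
  Brier/IBS, PCHIP truncation, bootstrap bands), `attribution`
  (integrated gradients, Z-maps, region importance), `io`, `pipeline`,
  `scenarios` (named study conditions).
- `analysis/01…06_*.py` — numbered narrative drivers that run each stage
  and write tables under `results/`.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — model details, synthetic-data design, numerical
  choices, limitations.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 7 --n 1000
python analysis/02_stratify_risk_groups.py
```

prints

```
wrote 1000 subjects to results/cohort.csv
censored fraction: 0.722 (target 0.72)
group sizes: {'L': 379, 'H': 268, 'IH': 188, 'IL': 165}
assignment accuracy vs generating groups: 0.838
group
H     285
L     269
IL    240
IH    206
```

The cohort reproduces the intended censoring level and group mix, and the
centroid assignment recovers 83.8% of the latent risk groups at the
default noise level with unequal (cohort-realistic) group sizes — under
the equal-quartile conditions of the stratification scenario the same
procedure reaches 91–92% (see `tests/test_acceptance.py`). Continuing,

```bash
python analysis/04_fit_models.py --seed 11
```

prints the 5-fold model comparison on the strong-signal cohort
(concordance / integrated Brier score, mean over folds):

```
                ci_mean           ibs
                   mean    std   mean    std
model
Cox elastic net   0.750  0.036  0.137  0.023
MLP               0.739  0.060  0.141  0.033
Weibull           0.670  0.068  0.187  0.037
marginal KM       0.500  0.000  0.187  0.033
```

The discrete-time MLP and the elastic-net Cox model rank conversion risk
far above the uninformative marginal Kaplan-Meier predictor and carry a
~25% lower integrated Brier score; the Weibull reference discriminates
(CI 0.67) but its rigid parametric curves calibrate no better than the
marginal predictor under the piecewise-constant generating hazards.
`analysis/05_scnn_imaging.py` and `analysis/06_attribution.py` run the 3D
model on synthetic volumes and show that, when survival signal is
confined to the mesial temporal regions, the attribution analysis ranks
that lobe first in every risk group.

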