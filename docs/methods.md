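# Methods

## The problem

Clear cell renal cell carcinoma (ccRCC) is graded on the four-tier WHO/ISUP
nuclear scale, commonly dichotomized into low (1–2) vs high (3–4) grade; the
grade is prognostic for progression-free survival (PFS) and guides treatment.
Radiomics pipelines extract hundreds of quantitative features per CT contrast
phase, far more than the typical cohort size, so a feature-selection step is
unavoidable. This package implements a *network-centric* selector: instead of
scoring features against the label one at a time, it asks which features'
*dependency patterns with other features* rewire between the two grade
groups, and selects those.

## Maximum-entropy networks

For continuous features constrained to match first and second sample
moments, the maximum-entropy distribution is the multivariate Gaussian
ρ(x) ∝ exp(−½ xᵀMx). The interaction matrix M is the precision (inverse
covariance) matrix: `M = C⁻¹`. Where the covariance C mixes direct and
indirect associations, M keeps only conditional dependencies; the partial
correlation between features i and j given all the rest is

    R_ij = −M_ij / √(M_ii · M_jj).

Features are z-scored within each group before the covariance is taken —
radiomics features span wildly different scales, and the entropy argument is
scale-free only after standardization. A network is obtained by placing an
edge wherever |R_ij| ≥ τ (default τ = 0.1; the threshold is a package
convention, exposed as a parameter).

When p approaches or exceeds n, C is singular and cannot be inverted, so M
is estimated by L1-penalized Gaussian maximum likelihood (the
graphical-lasso objective `log det M − tr(CM) − λ‖M‖₁,off`), delegated to
scikit-learn's solver. The penalty λ may be fixed, or selected (`λ="auto"`)
on a 20-point log grid in [0.01, 1] by the extended BIC with γ = 0.5 — the
standard high-dimensional default. Requesting λ = 0 on an ill-conditioned
covariance (condition number above 10⁶) is refused with an error rather than
silently regularized. A solver run that hits the iteration cap but returns a
finite positive-definite precision is accepted with a warning; an unusable
result raises.

## Differential network and selection

One network is inferred per grade group (from that group's samples only).
Their *differential network* is the symmetric difference of the two edge
sets: an association present in both groups carries no grade information and
is dropped; an edge present in exactly one group survives, tagged with its
provenance (high-only / low-only) and weighted by |R_high − R_low|. The
symmetric-difference reading (rather than "high minus low" only) was chosen
so the degree histogram reflects dependency change in either direction.

Features are ranked by their differential node degree (unweighted edge
count — the weights are used only to break ties, then the feature position
breaks remaining ties so the ranking is total), and the top nodes with
degree ≥ 1 are selected, capped at 14 ("fewer than 15"). Selection runs once
per contrast phase (107 features each) and once jointly over all 428
features (`ALL`).

Inside cross-validation the selector is *re-fit in every training fold*, so
validation folds never influence selection; the reported final feature set
comes from a one-shot selection on the full training split. Both behaviors
are exposed (`selector=` vs `features=` in `cross_validate`).

## Grading model and evaluation

The grading model is an unpenalized logistic regression on the selected,
standardized features. Perfect separation (or optimizer non-convergence)
triggers a fallback to a small ridge penalty (strength 1e−4) with a warning.
Evaluation follows 5 repeats of stratified 5-fold cross-validation (seeds
0–4 by default) reporting AUC, precision, sensitivity and accuracy (0.5
probability threshold) on the internal-training and validation parts, plus a
held-out test split (defaults mirror a 175 → 125/50 stratified split).
AUC is the Mann–Whitney statistic (ties counted ½); paired model AUCs are
compared with the DeLong test (midrank implementation; identical scores
return p = 1 by convention). Control selectors — LassoCV, SVM-RFE, random
forest — run with library defaults through the same CV protocol.

## Survival analysis

The selected features of the winning phase feed a PFS analysis:

- **Optimal-cutpoint KM.** Each feature is dichotomized at the cut
  maximizing the standardized two-group log-rank statistic, subject to a
  minimum group proportion (default 0.1). The reported p-value is the naive
  log-rank p at the chosen cut and is **not corrected for the maximal
  selection** — a deliberate caveat matching the common `surv_cutpoint`
  workflow; under the null these p-values are anti-conservative.
- **Cox models** (lifelines, Efron tie handling): one univariate fit per
  feature; features with univariate p < 0.05 enter the multivariate model
  (the screening threshold is a parameter). Covariates are standardized by
  default (hazard ratios are then per-SD; raw-scale fits are available via
  `standardize=False`). Zero-variance covariates are reported as degenerate
  (coefficient 0, HR 1) rather than fit. Multivariate fits require at least
  5 more events than covariates.
- **Risk scores**: the Cox linear predictor, median-split into high/low
  risk, with the numeric data for the standard three-panel display.
- **C-index**: Harrell's concordance over usable pairs (lifelines), checked
  in the tests against explicit pair enumeration.
- **Calibration**: Hosmer–Lemeshow over 10 risk deciles (χ² with bins − 2
  df); at the 60-month horizon the predicted progression risk
  `1 − S₀(60)^exp(lp)` is compared with the observed 60-month status,
  restricted to samples whose 60-month outcome is observable (event, or
  followed past 60 months).
- **Nomogram (numeric only)**: each covariate's hazard contribution β·x over
  its observed range is rescaled so the most influential covariate spans
  0–100 points (reference value = the range end minimizing the hazard);
  total points map linearly back to the linear predictor and through the
  baseline survival to probabilities at 12, 36 and 60 months.

## Synthetic cohorts

The generator parameterizes each grade group directly by its precision
matrix, so the ground truth lives on exactly the object selection targets.
Defaults emulate the study shape: 175 samples (122 low / 53 high grade),
4 phases × 107 features, 10 driver features per phase, base conditional
dependency support with edge probability 0.05, 3 toggled (added/removed)
edges per driver in the high-grade precision, planted partial correlations
of magnitude 0.3–0.5, and Weibull(shape 1.2, scale 80 months) progression
times loading log-HR +0.7 / −0.7 on the first two drivers, with uniform
administrative censoring on 60–120 months.

Realizing sparse partial correlations of a prescribed magnitude under
positive definiteness is non-trivial: with ~3–6 edges per node, magnitudes
of 0.3–0.5 sit at (and partly beyond) the feasibility boundary. The
generator uses joint alternating projections between the positive-definite
cone (eigenvalue floor 0.02) and the set of unit-diagonal matrices with the
prescribed signed support and magnitude band, with an equality projection
keeping unperturbed edges identical across the two group matrices; a final
joint off-diagonal shrink guarantees positive definiteness when the sets do
not intersect. Realized magnitudes therefore sit at or slightly below the
nominal band floor — as close to it as positive definiteness allows (the
tests assert positive definiteness, unit diagonals and the 0.5 magnitude
ceiling exactly).

Two generator choices go beyond the minimal structure. First, the
high-grade group receives a small location shift (default 0.5 within-feature
SD) on the driver features: a purely covariance-coded grade difference is
invisible to a linear logistic classifier, whereas real graded cohorts
always carry some location signal; the shift does not affect network
inference because features are re-standardized within group. Second,
survival is linked to the features (not to the grade label directly), so the
survival analysis genuinely tests feature–prognosis recovery.

What the generator does **not** emulate: heavy-tailed and bounded feature
distributions, scanner batch effects (beyond an optional mean-shift batch
covariate used to exercise the PCA batch check), inter-phase correlation of
the same feature, and measurement noise from segmentation variability.
Passing tests therefore demonstrate correctness and statistical power under
the Gaussian graphical model the method assumes, not performance on real CT
radiomics.

## Numerical choices and problem sizes

- Graphical lasso: tol 1e−4, 200 iterations; EBIC γ = 0.5 on a 20-point
  grid in [0.01, 1].
- Unpenalized precision requires condition number < 10⁶.
- Degree ties broken by summed |ΔR|, then feature position — deterministic.
- Stratified folds are re-drawn with the next seed if a part lacks a class
  (error after 10 attempts).
- Power checks run at p = 50 features, 10 drivers, n = 200/group over 20
  seeds (driver recovery), and n = 500/group over 10 seeds for the
  zero-perturbation null; the EBIC penalty is intentionally conservative
  for p ≈ n, so recovery at n ≤ 75/group is asserted only as monotone in n.
  The end-to-end pipeline demonstration uses a single-phase 30-feature
  cohort with the study's 122:53 imbalance and 2×5-fold CV; these sizes keep
  every estimate stable while the full suite remains convenient to run.

## The feature-name registry

Only a subset of index → name pairs of the 107-feature schema is externally
anchored (e.g. X2 = Flatness, X11 = Sphericity, X107 = Strength). The
shipped registry orders the seven radiomics classes in fixed blocks — shape
1–14, first-order 15–32, GLCM 33–56, GLDM 57–70, GLRLM 71–86, GLSZM 87–102,
NGTDM 103–107 — alphabetically within each class using pyradiomics names.
Every anchored pair lands on the correct name and class under this layout;
the remaining assignments are a documented convention, not ground truth.

## Known limitations

- The edge threshold τ, the λ grid and the EBIC γ are conventions; the
  selection is moderately sensitive to them in the p ≈ n regime.
- Maximally-selected cutpoint p-values are selection-biased (see above).
- The nomogram assumes proportional hazards and uses the step baseline
  survival without smoothing.
- The `ALL`-phase network treats all 428 features jointly; with desk-scale
  cohorts this relies entirely on the penalized estimator.
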