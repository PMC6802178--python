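# Methods

This note records the models implemented in `ivfqol`, the numerical and
design choices made where the procedure was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Perimetric geometry

The 10-2 grid is generated as all points with odd integer coordinates
(degrees) satisfying x² + y² ≤ 82. This is the unique odd-lattice rule
with 2° spacing that yields the standard 68-point count; the printed
counts (68 points; 4 inner + 13 outer points per quadrant; 12 of the 54
24-2 points within 10°) anchor the layout. The 24-2 grid uses the
standard 52 symmetric points (|x| ∈ {3,9,15,21} up to the row limits)
plus two nasal-step points at |x| = 27, y = ±3 on the nasal side of the
tested eye.

Both eyes are expressed in visual-space coordinates (positive x to the
patient's right), so corresponding binocular locations share coordinates
and no retinal flip is applied. Subfield assignment for 10-2 crosses an
inner/outer split at 5° eccentricity (inclusive: ties go inner, though no
default point sits exactly at 5°) with the four quadrants; Euclidean
eccentricity is the default and Chebyshev is available, since the
boundary convention is a modelling choice rather than a physical fact.
The 24-2 field splits on the sign of y. No grid point lies on an axis, so
assignment is never ambiguous.

## Binocular integration

The best-location model takes, at each matched point, the maximum total
deviation of the two eyes; TD (not raw sensitivity) is integrated. The
two 24-2 nasal-step points have no fellow-eye counterpart; the integrated
field carries the single eye's value there, a documented choice (dropping
them would shrink the nasal hemifield sample). The binocular-summation
alternative linearises deviations as s = 10^(TD/10), combines
quadratically, (s₁² + s₂²)^½, and re-expresses in dB; two equal eyes thus
gain 10·log₁₀√2 ≈ 1.5 dB.

Two 10-2 IVF assessments around the questionnaire date are averaged
*after* integration (the average of IVF TD values, not of monocular
fields). A single available assessment is accepted with a warning rather
than rejected. Means are computed in double precision; rounding happens
only at report output.

## Rasch model

The questionnaire has 30 items in 7 tasks, answered as 0 (greatly
disabled), 1 (slightly disabled) or 2 (not disabled). The rating-scale
model is

P(X_ni = k) ∝ exp( k·(θ_n − δ_i) − Σ_{j≤k} τ_j ),  τ_0 ≡ 0,

with shared thresholds τ₁, τ₂; a partial-credit variant (item-specific
thresholds) is selectable. The published item-to-task allocation of the
questionnaire's appendix is not reproduced here; the default schema is a
synthetic allocation (4/4/5/5/4/3/5 items) that preserves the 30-item,
7-task structure and is explicitly plumbing, replaceable via YAML.

Estimation is joint (unconditional) maximum likelihood: alternating
damped Newton sweeps over persons, items and thresholds, with extreme
persons (raw score 0 or maximum) and constant items excluded from
estimation, the identifiability constraint mean(δ) = 0 (re-applied each
sweep, with θ shifted accordingly), convergence when the largest
parameter change falls below 1e-6 logits, and a hard cap of 200 sweeps
(a convergence error carries the last iterate). JML was chosen for
self-containment; it carries the usual finite-item bias, which at 30
items inflates difficulty spread by a few percent — visible in the
recovery RMSE but within the 0.2-logit tolerance the tests assert.
Thresholds are reported as estimated; monotone ordering is not forced.

Person scoring uses raw-score sufficiency: the RADPAI for a raw score r
on an item subset solves Σ E[X_i | θ] = r by Brent root-finding, with
extreme raw scores pulled in by 0.5 score units so every patient gets a
finite ability. Per-task RADPAI uses the task's items with their
difficulties from the joint fit (no re-centring), keeping task scores on
the common logit scale. Items whose observed column is constant in a
sample cannot be estimated; they are scored at average difficulty (0) so
raw-score ranges stay intact, with a logged warning.

## Random-forest permutation importance

Each ability score is regressed on the 13 explanatory variables by a
bagged ensemble of CART regression trees (default 1000 trees, 4 ≈ 13/3
candidate variables per split, minimum leaf 5, unpruned). Individual
trees come from scikit-learn; the bootstrap, out-of-bag (OOB)
bookkeeping, importance statistic and empirical null are implemented
here, so every index set is explicit and seeded.

The importance of variable v is the mean over trees of the increase in
OOB mean squared error when v is permuted among that tree's OOB cases —
the loss-based "decrease in accuracy" formulation.

Significance uses an empirical null: null draw r first decorrelates v
from the response by one global permutation of the column (the same
reassignment applied consistently across all trees, mirroring the role
the identity assignment plays in the observed statistic), then applies
the identical per-tree OOB permutation statistic to the decorrelated
copy. With R draws, p = (1 + #{null ≥ observed}) / (R + 1), never zero,
with resolution 1/(R+1); the default R is 2000. Under a global null with
exchangeable feature columns the observed statistic and the null draws
are exchangeable, and the measured type-I error at α = 0.05 over 500
simulated null datasets sits near nominal (the acceptance suite asserts
the [0.03, 0.07] band). A variant in which the baseline assignment is
drawn per tree rather than globally was evaluated and discarded: it
breaks the cross-tree correlation structure of the statistic and is
measurably anticonservative. A PIMP-style response-permutation null
(refit per replicate) is available by config for users who prefer a
model-level null at much higher cost.

Variables with p < α (default 0.05) are ranked by ascending p, ties
broken by descending observed importance, then name.

Marginal permutation importance is interpreted against correlated
proxies with care: when subfield mTDs are strongly inter-correlated (as
they are in advanced glaucoma and in the default generator), variables
correlated with a true driver also carry predictive information and can
be flagged. The recovery tests therefore assert that the *designated*
drivers are found and that an independent null variable (age) is not —
they do not assert sparsity of the flag set. Duplicating a feature
splits its importance between the copies; detection of the pair degrades
only within simulation noise (documented, not asserted strictly).

## Classical statistics

Spearman correlations use average ranks with the two-sided t
approximation (cohorts here are well above n = 10); the Bonferroni
family is variables × responses = 13 × 8 = 104, per-comparison threshold
0.05/104 ≈ 0.00048. Scheffé contrasts after one-way ANOVA use the
textbook statistic (x̄_i − x̄_j)² / (MSW(1/n_i + 1/n_j)) referred to
(k−1)·F_{k−1,N−k}. The better eye is the one with lower logMAR acuity,
ties broken by higher MD, then OD — the convention is not universal, so
it is centralised in `assign_better_eye`.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
tested; its defaults were fixed once at the scale of an advanced-glaucoma
cohort and are not tuned per test:

* n = 172 patients by default; age 62.5 ± 12.2 years.
* Per-eye global damage levels: better eye −17 ± 8.2 dB (capped at
  −2 dB), worse eye −26.3 ± 3 dB (capped at −20 dB, so the MD criterion
  is met); which anatomical eye is better is random.
* Spatial structure per eye: global level + hemifield offset (upper
  worse by 6 dB by default) + a shared N(0, 2 dB) random effect per
  subfield + independent N(0, 3 dB) point noise, truncated to the
  perimeter's [−35, 5] dB range. Two 10-2 assessments share the
  subfield effects (test–retest structure) and redraw point noise.
* Acuity: logMAR = −0.15 − 0.010 × (central 10-2 mTD of that eye)
  + N(0, 0.08), clipped to [−0.30, 0.30], tying acuity to central damage
  and keeping the cohort inside the 20/40 eligibility bound.
* Questionnaire: each task's latent ability is the standardised
  truth-map combination of the 13 feature columns plus N(0, 0.8) noise;
  responses are drawn from the rating-scale model with item difficulties
  evenly spaced in [−1.5, 1.5] and thresholds (−0.8, 0.8). The default
  truth map loads lower and lower-right central subfields, the lower
  24-2 hemifield and better-eye acuity on the tasks plausibly driven by
  them; age never enters, making it the built-in null variable. Effect
  sizes were chosen to give marginal Spearman correlations around
  0.4–0.5, the scale typical of this literature.

What the generator does **not** emulate: SITA threshold noise models and
their eccentricity-dependent variability, perimetric learning and
fatigue effects, longitudinal progression, floor effects of very
advanced loss, or the true (unpublished) item-task allocation. Passing
recovery tests therefore demonstrate that the pipeline's inference is
correct under its own assumptions at realistic effect sizes — not that
those assumptions capture every property of real perimetry.

## Problem sizes used in tests and the acceptance script

Parameter recovery uses n = 500 patients; null calibration uses 500
datasets of n = 200 with 199 null draws and 25-tree forests; end-to-end
recovery uses 20 cohorts of n = 300 with 200-tree forests and 199 null
draws (the acceptance script uses 10 cohorts and 200 calibration
datasets). Tree counts and null-draw counts in these studies are smaller
than the pipeline defaults (1000 trees, 2000 draws); they were sized so
the whole battery runs in minutes on a single core, and the calibration
and power conclusions are insensitive to them in the ranges tested.

## Known limitations

* JML item-parameter bias is uncorrected (no (L−1)/L shrinkage); with 30
  three-category items it is small but visible.
* Permutation importance is marginal, not conditional; correlated
  proxies of a true driver can be flagged (see above).
* The empirical null assumes exchangeable rows; strong feature
  correlation plus heteroscedastic noise could shift its level slightly.
* Eligibility filtering uses worst-case reliability indices per patient
  rather than per-test exclusion of individual fields.
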