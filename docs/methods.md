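# Methods

This note records the models, conventions and numerical choices behind
capdyn, and what the synthetic cohorts do and do not establish.

## Frame clustering

Frames are clustered after two standardizations. Per-subject, per-ROI
z-scoring (sample SD, ddof = 1) removes amplitude differences between
regions and subjects; it is refused on already-standardized input and on
zero-variance columns, and is idempotent to ~1e-10. Row standardization of
each frame is implied by the correlation distance itself: for frames x̃, ỹ
z-scored across ROIs, 1 − Pearson(x, y) = ‖x̃ − ỹ‖²/(2(R−1)). Lloyd
iterations therefore run in plain Euclidean geometry on row-standardized
frames. Centroids are cluster means of standardized frames, re-standardized
after each update; because all centroids then share the same norm, the
Euclidean arg-min over centroids is exactly the correlation-distance
arg-min, and the within-cluster objective is reported in correlation units.

Choices that matter:

* **Initialization** is greedy k-means++ (D² sampling with 2 + ln k
  candidates per step, keeping the potential-minimizing candidate), the
  default seeding of the widely used k-means implementations. Uniform
  random frame seeding (`init="random"`) is available but measurably less
  robust: at the default study scale it produced merge/split local optima
  in a few percent of best-of-5 runs.
* **Repetitions**: 5 independent initializations, keep the lowest total
  within-cluster distance; at most 500 iterations each.
* **Ties** in assignment go to the lower CAP index; **empty clusters** are
  re-seeded from the frame farthest from its centroid (logged).
* **Labels** are arbitrary; models are reported with CAPs sorted by pooled
  occupancy, and any cross-run, cross-k or cross-atlas comparison goes
  through Hungarian matching on spatial correlation (`match_caps`).

Cluster-number diagnostics compute the elbow curve, silhouette and Dunn in
correlation-distance geometry, and Calinski–Harabasz and Davies–Bouldin in
Euclidean geometry on standardized frames (their standard definitions).
The diagnostics are descriptive; k is a parameter (default 7).

## CAP maps and network attribution

A CAP's group map is a per-ROI one-sample Z statistic over subjects: each
subject contributes the mean of its standardized frames assigned to that
CAP; the across-subject mean is divided by SD/√n (ddof = 1). Subjects with
no frames in a CAP are excluded from that CAP's map; a CAP visited by fewer
than two subjects has an undefined (NaN, flagged) map rather than a silent
zero. Attribution uses |Z| > 1.96: method 1 reports each network's share of
total supra-threshold |Z| mass; method 2 reports supra-threshold positive
and negative mass separately per network.

## Dynamics metrics

From a subject's label sequence: dwell time is the mean duration of maximal
contiguous runs of a CAP (seconds, frames × TR); total dwell time is summed
occupancy; occurrence rate is the fraction of frames. Bookkeeping
identities (occurrences sum to 1, total dwell to T × TR, dwell × run count
= total dwell, transition counts to T − 1) hold exactly and are enforced by
tests. Transition probabilities are the maximum-likelihood row-normalized
counts without smoothing; a Laplace-ε option exists for sensitivity
analysis but defaults to 0. Unvisited states propagate as missing values,
never as zeros, and are excluded pairwise from group tests.

Trajectory entropy is computed per subject from that subject's transition
matrix, in bits (a nats option via `entropy_base`). For each target j the
vector H[:, j] solves (I − Q_j) H[:, j] = h with Q_j the transition matrix
with column j zeroed — the defining first-hitting recursion; any closed
form must agree with it, and tests verify both the first-return identity
H[j, j] = H(P)/μ_j to 1e-9 and agreement with an exact trajectory
enumeration (prefix aggregation) to 1e-3 bits. The solve refuses reducible
or substochastic matrices and systems with condition number above 1e12.
Subject-level entropies are computed on the visited-state sub-chain when it
is irreducible; otherwise the entries are missing. The stationary
distribution comes from a least-squares solve of μP = μ with the
normalization row appended.

## Group statistics

"t-test after controlling for covariates" is implemented as the group
coefficient of an OLS fit `value ~ group + covariates`, which is the
standard regression formulation; with no covariates it reduces exactly to
the pooled-variance two-sample t test. Sex and site are dummy-coded against
the alphabetically first level; rank-deficient designs are refused with the
offending columns listed; missing data are dropped listwise with a logged
count. Under 1000 null simulations at n = 60 the empirical type-I error is
≈0.05 (asserted within (0.035, 0.065)).

Symptom correlations are partial Pearson correlations: both variables are
residualized on [1, covariates] and the residuals correlated, with
p from t = r√((n−2−c)/(1−r²)).

BH-FDR is the step-up q_(i) = min_{j≥i}(p_(j)·m/j), capped at 1, applied
within metric families mirroring how such results are corrected per dynamic
property: per-CAP metrics within the K CAPs, path metrics (transition /
persistence, trajectory entropy) within the K² paths, separately per
contrast. Demographics helpers provide the Pearson chi-square (df = 1, no
continuity correction) and the Mann–Whitney U with the tie-corrected normal
approximation.

## Classification

Features are the dynamic metrics with raw p < α (default 0.05) from the
dwell, occurrence, persistence and trajectory-entropy families
(off-diagonal transitions excluded unless requested). Nested stratified CV
(5 outer × 5 inner folds) fits per-fold standardization on training data
only, grid-searches C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (log₂ steps of 2) by
inner-fold accuracy, and reports accuracy, AUC (decision-function scores),
sensitivity, specificity, F1, PPV and NPV per fold and averaged.
Permutation p values re-run the entire nested CV on permuted labels:
p = (1 + #{null ≥ observed})/(n_perm + 1), default n_perm = 1000.

Selecting features on the full cohort before cross-validating leaks the
selection step; this "as-paper" protocol is the default for comparability,
and a strict variant (selection inside each training fold) is available by
computing the stat table per fold. An inspection mode records per-fold
train indices and fitted scaler moments so the no-leakage property can be
audited; a single-point grid skips the inner loop.

## Synthetic cohorts

Each subject is a hidden-Markov process: a latent chain over K states emits
per frame a scaled spatial template plus i.i.d. Gaussian noise per ROI.
Defaults mirror the study conditions the pipeline targets: K = 7, R = 116
ROIs in six networks, T = 240 frames at TR = 2 s, and a planted dwell-time
effect as a raised control self-transition (0.80 vs 0.65) on one state,
with uniform off-diagonal mass. SNR is the per-ROI RMS template amplitude
over the emission SD (template amplitude = SNR · σ · √R for unit-norm
templates); the default SNR 2 gives frame–template correlations ≈0.9.

Templates concentrate signed weight on 1–2 networks (mean boosts over a
dense Gaussian background) and are then column-centered across states and
column-scaled to equal across-state variance before row normalization.
This mirrors what per-ROI temporal z-scoring does to real data — it
equalizes ROI variance and removes each ROI's occupancy-weighted mean — so
the generating templates live in the geometry the analysis estimates and
template recovery is well-posed; without this, the centering step alone
caps centroid–template correlation near 0.92 at k = 7 for purely geometric
reasons. The optional anti-correlated pair mixes the negated neighbor
template with an orthogonal residual, raising the mixing weight until the
post-transform correlation is ≤ −0.5 (at small k the attainable
anti-correlation saturates slightly past −0.5).

Covariates are drawn independently of group by default (age ~ N(33.5,
12.8²) clipped to [18, 70], sex 60% female, education ~ N(12.4, 3.2²),
six uniform sites, lognormal framewise displacement with median ≈0.14 mm),
so adjusted and unadjusted contrasts estimate the same effect; a
confounded mode shifts patient age and motion to exercise the adjustment.
Patient symptom scores are linear in the subject's true mean dwell time of
the effect state plus Gaussian noise, calibrated to a 21.7 ± 6.6
distribution, so partial-correlation recovery is testable.

What the generator does **not** emulate: hemodynamic convolution and
temporal autocorrelation beyond the Markov chain, site- or scanner-specific
covariance structure, motion artifacts correlated with the signal, and
spatially correlated noise. Passing tests therefore establish that the
pipeline's estimators and inference are correct under a Markov emission
model at realistic dimensions — not that any particular clinical contrast
in real data is reproducible.

## Problem sizes used in tests and the acceptance script

End-to-end checks run cohorts of 60 + 60 subjects at T = 240, R = 116,
k = 7, SNR 2 (50 seeds in the test suite, 20 in the acceptance script);
null calibrations use 1000 regression simulations at n = 60 and 100–200
null cohorts at n = 30/30 on true latent sequences; classifier checks use
n = 200 separable features and 199 label permutations with a reduced grid.
These sizes make the whole suite run in a few minutes while keeping every
assertion at the study's dimensionality.

## Known limitations

* Correlation distance is undefined for constant frames; such frames are
  rejected rather than imputed.
* Dwell times are skewed at T = 240; the adjusted t test is nevertheless
  well calibrated at n = 30–60 in simulation, but very small groups may
  warrant the Mann–Whitney path.
* The per-subject trajectory-entropy matrix requires the visited sub-chain
  to be irreducible; short scans with rarely visited states yield missing
  entries, which downstream tests drop pairwise.
* "As-paper" feature selection leaks information into the classifier
  estimate by construction; use the strict mode when an unbiased estimate
  matters.
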