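# capdyn

Co-activation pattern (CAP) dynamics for resting-state fMRI ROI time series:
transient brain states, Markov-chain dynamics metrics, covariate-adjusted
group statistics, and nested cross-validated SVM classification — with a
synthetic hidden-Markov cohort generator providing ground truth for every
stage.

## The problem

Static functional connectivity averages away how brain networks coalesce and
dissolve over a scan. CAP analysis instead treats every fMRI frame as a
point in ROI space and clusters frames into a small number of recurring
whole-brain configurations ("CAPs"). Each subject's scan then becomes a
label sequence over K states, and the interesting quantities are dynamic:
how long states persist, how often they occur, where the chain moves next,
and how predictable its routes are. Case–control studies (e.g. major
depressive disorder vs healthy controls) compare these dynamics between
groups, relate them to symptom severity, and ask whether they support
individual-level classification.

## The method

Given per-subject T×R matrices (default T = 240 frames at TR = 2 s, R = 116
ROIs in six networks: ATN, DMN, SMN, VN, SCN, CN):

1. **Standardize** each ROI time series to z-scores (zero mean, unit sample
   SD).
2. **Cluster** all pooled frames by k-means with distance
   d(x, y) = 1 − Pearson(x, y) (default k = 7, 5 initializations, ≤500
   Lloyd iterations). For row-standardized frames x̃, ỹ this distance equals
   ‖x̃ − ỹ‖² / (2(R−1)), so iterations run in Euclidean geometry with
   row-standardized centroids. Cluster-number diagnostics (elbow,
   silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn) are available over
   k ∈ [2, 20].
3. **Map** each CAP as a group Z statistic per ROI: subject-mean frames
   averaged across subjects and divided by the standard error; CAPs are
   attributed to networks by where supra-threshold |Z| > 1.96 mass
   concentrates.
4. **Quantify dynamics** per subject from the label sequence: mean dwell
   time (s), total dwell time (s), occurrence rate, the K×K transition
   matrix P̂ (diagonal = persistence), and the entropy of Markov
   trajectories H, where H[i, j] (bits) is the Shannon entropy of the random
   path from state i until it first reaches state j:

       H[i, j] = h_i + Σ_{m≠j} P[i, m] · H[m, j],   h_i = −Σ_m P[i, m] log₂ P[i, m]

   with the first-return identity H[j, j] = H(P)/μ_j (entropy rate over
   stationary mass).
5. **Test** group contrasts by the group coefficient in
   `value ~ group + age + sex + education + site + mean_fd` (two-tailed),
   correlate metrics with symptom scores by partial Pearson correlation
   under the same covariates, and control FDR by Benjamini–Hochberg within
   each metric family (per-CAP families of size K; path families of size
   K²).
6. **Classify** groups with an RBF-SVM on the metrics significant at raw
   p < 0.05, inside nested stratified CV (standardization and (C, γ) grid
   search fitted on training folds only), with permutation tests for
   significance.

## Worked example

```python
import numpy as np
from capdyn import (
    make_truth, simulate_cohort, zscore_series, pool_frames,
    kmeans_correlation, match_caps, dynamic_profile,
)
from capdyn.dynamics import profiles_to_long
from capdyn.group_stats import dynamics_stat_table

# 4-state cohort, 30 controls + 30 patients; controls get a raised
# self-transition (0.80 vs 0.65) on state 0 -> longer dwell time there
truth = make_truth(k=4, snr=2.0, effect_cap=0, effect_delta=0.15, seed=0)
manifest, series, latent = simulate_cohort(truth, n_control=30, n_patient=30, t=240, seed=0)

series = [zscore_series(ts) for ts in series]
pool, frame_map = pool_frames(series)
model = kmeans_correlation(pool, k=4, frame_map=frame_map, seed=0)

perm, r = match_caps(truth.templates, model.centroids)
print("template match r:", np.round(r, 3))

profiles = [dynamic_profile(sid, labels, k=4) for sid, labels in model.assignments.items()]
stats = dynamics_stat_table(profiles_to_long(profiles), manifest.table, ("HC", "MDD"))
dwell = stats[stats.metric == "dwell"]
print(dwell[["cap_from", "mean_a", "mean_b", "t", "p", "q"]].round(4).to_string(index=False))
```

Output:

```
template match r: [0.999 0.999 0.997 0.997]
 cap_from  mean_a  mean_b       t      p      q
        0  9.6282  5.7781 -8.6311 0.0000 0.0000
        1  5.7050  5.9986  1.3035 0.1985 0.3970
        2  5.6666  6.0091  0.8505 0.3992 0.5322
        3  5.5336  5.4870 -0.2670 0.7906 0.7906
```

The clustering recovers all four generating spatial templates (Hungarian-
matched correlation ≥ 0.997), and the covariate-adjusted dwell-time contrast
flags exactly the planted state: controls dwell ~9.6 s in CAP 0 versus
~5.8 s in patients (BH-FDR q ≪ 0.05 within the 4-CAP family), while the
three null states stay non-significant.

The same flow is available as a CLI:

```bash
capdyn run-all --config config.yaml --out run/ --seed 0
```

with subcommands `simulate`, `cluster`, `validity`, `dynamics`, `stats`,
`classify`, `run-all`. Every run directory carries the verbatim config and
its hash; re-running an unchanged config resumes after completed stages.

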