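"""Synthetic multi-subject cohorts with known CAP structure.

Each subject is a hidden-Markov emission process: a latent chain over K
states (with group-specific transition matrices) emits, per frame, a scaled
network-structured spatial template plus i.i.d. Gaussian noise per ROI. The
generator returns the latent sequences, so every downstream stage — frame
clustering, dynamic metrics, adjusted group tests, symptom correlations,
classification — can be validated against ground truth.

Study-shaped defaults: K = 7 states over R = 116 ROIs partitioned into six
networks, T = 240 frames at TR = 2 s, a cohort of 215 controls and 221
patients, and a planted dwell-time effect realized as a higher self-transition
probability for one state in controls (0.80 vs 0.65). Signal-to-noise ratio
is defined as the per-ROI root-mean-square template amplitude divided by the
emission noise SD. Symptom scores (HAMD-like, patients only) are linear in
the subject's true mean dwell time of the effect state plus Gaussian noise,
calibrated to a 21.7 +/- 6.6 score distribution.

Covariates (age, sex, education, site, head motion) are drawn independently
of group by default, so adjusted and unadjusted contrasts estimate the same
effect; a confounded mode shifts age and motion by group to exercise the
covariate adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import dwell_and_occurrence, stationary_distribution
from .io_model import (
    DEFAULT_NETWORKS,
    CohortManifest,
    NetworkAtlas,
    RoiTimeSeries,
    save_cohort,
)

# ROI counts per network for the default 116-region 6-network partition
# (sized after the anatomical parcellation: large cerebellar and default-mode
# blocks, smaller visual block).
DEFAULT_NETWORK_SIZES = {
    "ATN": 20,
    "DMN": 24,
    "SMN": 16,
    "VN": 14,
    "SCN": 16,
    "CN": 26,
}


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic cohort."""

    templates: np.ndarray  # K x R unit-norm spatial patterns
    p_control: np.ndarray  # K x K row-stochastic
    p_patient: np.ndarray
    emission_sigma: float
    snr: float
    effect_cap: int
    effect_delta: float
    tr_seconds: float
    seed: int
    hamd_slope: float = 4.0
    hamd_intercept: float = 21.71
    hamd_noise_sd: float = 5.0
    confounded: bool = False

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    @property
    def n_rois(self) -> int:
        return self.templates.shape[1]

    @property
    def amplitude(self) -> float:
        """Template scale so that per-ROI RMS signal = snr * emission_sigma."""
        return self.snr * self.emission_sigma * np.sqrt(self.n_rois)

    def to_json(self) -> dict:
        d = asdict(self)
        d["templates"] = self.templates.tolist()
        d["p_control"] = self.p_control.tolist()
        d["p_patient"] = self.p_patient.tolist()
        return d


def make_atlas(network_sizes: dict[str, int] | None = None) -> NetworkAtlas:
    """Deterministic atlas table with contiguous network blocks."""
    sizes = network_sizes or DEFAULT_NETWORK_SIZES
    rows = []
    idx = 0
    for net, size in sizes.items():
        for i in range(size):
            rows.append({"roi_index": idx, "roi_name": f"{net}_{i:03d}", "network": net})
            idx += 1
    return NetworkAtlas(pd.DataFrame(rows))


def make_templates(
    k: int,
    atlas: NetworkAtlas,
    anti_pair: bool = True,
    seed: int = 0,
    anti_strength: float = 0.5,
) -> np.ndarray:
    """K unit-norm spatial templates, each with signed weight concentrated
    on 1-2 networks.

    Templates are built in the geometry the analysis actually sees: because
    per-ROI temporal z-scoring equalizes variance across ROIs and removes
    each ROI's occupancy-weighted mean across states, the raw structured
    patterns (network mean boosts of alternating sign over a dense Gaussian
    background) are column-centered across states and column-scaled to equal
    across-state variance before row normalization. State means of
    standardized frames then converge to these templates, so template
    recovery is well-posed.

    With ``anti_pair``, the last template mixes the negated second-to-last
    with an orthogonal residual, with the mixing weight chosen so that the
    post-transform spatial correlation of the pair is <= -anti_strength
    (default -0.5) while every other pair stays |r| < 0.9.
    """
    r = atlas.n_rois
    if k > r:
        raise ValueError(f"k={k} exceeds R={r}")
    if anti_pair and k < 2:
        raise ValueError("anti_pair needs k >= 2")
    rng = np.random.default_rng(seed)
    networks = atlas.networks
    roi_net = atlas.roi_networks()

    supports: list[tuple[str, ...]] = []
    for i in range(k):
        if i % 2 == 0:
            supports.append((networks[i % len(networks)],))
        else:
            supports.append(
                (networks[i % len(networks)], networks[(i + 2) % len(networks)])
            )

    raw = np.zeros((k, r))
    for i, nets in enumerate(supports):
        sign = 1.0 if i % 2 == 0 else -1.0
        w = rng.normal(0.0, 0.5, size=r)
        for net in nets:
            w[roi_net == net] += sign * 2.0
        raw[i] = w

    noise = rng.normal(0.0, 1.0, size=r)

    def finalize(premix: float) -> np.ndarray:
        pat = raw.copy()
        if anti_pair and k >= 2:
            base = pat[k - 2] / np.linalg.norm(pat[k - 2])
            orth = noise - (noise @ base) * base
            orth /= np.linalg.norm(orth)
            pat[k - 1] = np.linalg.norm(pat[k - 2]) * (
                -premix * base + np.sqrt(1.0 - premix**2) * orth
            )
        t = pat - pat.mean(axis=0)
        t = t / t.std(axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    if not anti_pair:
        templates = finalize(0.0)
    else:
        # column centering attenuates the planted anti-correlation; raise the
        # premix until the post-transform pair correlation meets the target
        templates = None
        for premix in [*np.arange(anti_strength, 1.0, 0.05), 0.99, 0.999]:
            cand = finalize(premix)
            if np.corrcoef(cand[k - 2], cand[k - 1])[0, 1] <= -anti_strength:
                templates = cand
                break
        if templates is None:
            raise RuntimeError(
                f"could not realize anti-correlated pair at r <= -{anti_strength}"
            )

    corr = np.corrcoef(templates)
    off = corr[~np.eye(k, dtype=bool)]
    if np.abs(off).max() >= 0.9:
        raise RuntimeError("template pair too similar (|r| >= 0.9); change seed")
    return templates


def _transition_matrix(k: int, self_probs: np.ndarray) -> np.ndarray:
    p = np.empty((k, k))
    for i in range(k):
        off = (1.0 - self_probs[i]) / (k - 1)
        p[i] = off
        p[i, i] = self_probs[i]
    return p


def make_truth(
    k: int = 7,
    atlas: NetworkAtlas | None = None,
    base_self_prob: float = 0.65,
    effect_cap: int = 0,
    effect_delta: float = 0.15,
    snr: float = 2.0,
    emission_sigma: float = 1.0,
    tr_seconds: float = 2.0,
    anti_pair: bool = True,
    confounded: bool = False,
    seed: int = 0,
) -> SyntheticTruth:
    """Assemble generating truth: templates plus per-group Markov chains.

    Controls carry the raised self-transition (base + effect_delta) on
    ``effect_cap``; patients stay at the base, so patients have the shorter
    dwell time in that state. ``effect_delta=0`` yields a null cohort
    (identical dynamics in both groups).
    """
    if atlas is None:
        atlas = make_atlas()
    templates = make_templates(k, atlas, anti_pair=anti_pair, seed=seed)
    self_c = np.full(k, base_self_prob)
    self_c[effect_cap] = base_self_prob + effect_delta
    self_p = np.full(k, base_self_prob)
    if not (self_c.max() < 1.0 and self_c.min() > 0.0):
        raise ValueError("self-transition probabilities must lie in (0, 1)")
    return SyntheticTruth(
        templates=templates,
        p_control=_transition_matrix(k, self_c),
        p_patient=_transition_matrix(k, self_p),
        emission_sigma=emission_sigma,
        snr=snr,
        effect_cap=effect_cap,
        effect_delta=effect_delta,
        tr_seconds=tr_seconds,
        seed=seed,
        confounded=confounded,
    )


def simulate_chain(p: np.ndarray, t: int, rng: np.random.Generator) -> np.ndarray:
    """Length-t latent state sequence; initial state from the stationary
    distribution."""
    mu = stationary_distribution(p)
    k = p.shape[0]
    cum = np.cumsum(p, axis=1)
    seq = np.empty(t, dtype=int)
    seq[0] = rng.choice(k, p=mu)
    u = rng.random(t - 1)
    for i in range(1, t):
        seq[i] = np.searchsorted(cum[seq[i - 1]], u[i - 1])
    return seq


def simulate_subject(
    truth: SyntheticTruth,
    group: str,
    subject_id: str,
    t: int = 240,
    rng: np.random.Generator | None = None,
) -> tuple[RoiTimeSeries, np.ndarray]:
    """One subject's ROI series and its latent state sequence."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    if t < 2:
        raise ValueError("need T >= 2")
    p = truth.p_patient if group != "HC" else truth.p_control
    seq = simulate_chain(p, t, rng)
    signal = truth.amplitude * truth.templates[seq]
    noise = rng.normal(0.0, truth.emission_sigma, size=signal.shape)
    ts = RoiTimeSeries(
        subject_id=subject_id,
        data=signal + noise,
        tr_seconds=truth.tr_seconds,
        standardized=False,
    )
    return ts, seq


def simulate_cohort(
    truth: SyntheticTruth,
    n_control: int = 215,
    n_patient: int = 221,
    t: int = 240,
    seed: int | None = None,
    n_sites: int = 6,
    out_dir: str | Path | None = None,
) -> tuple[CohortManifest, list[RoiTimeSeries], dict[str, np.ndarray]]:
    """A full cohort: manifest with covariates + series + latent sequences.

    Age ~ N(33.5, 12.8) clipped to [18, 70]; sex female with probability 0.6;
    education ~ N(12.4, 3.2) clipped to [6, 22]; site uniform over
    ``n_sites``; mean framewise displacement lognormal (median about
    0.14 mm). HAMD is generated for patients only, linear in the subject's
    true mean dwell time (seconds) of the effect state.
    """
    if n_control < 2 or n_patient < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    series: list[RoiTimeSeries] = []
    latent: dict[str, np.ndarray] = {}
    groups = ["HC"] * n_control + ["MDD"] * n_patient
    for i, group in enumerate(groups):
        sid = f"sub-{i:04d}"
        ts, seq = simulate_subject(truth, group, sid, t, rng)
        series.append(ts)
        latent[sid] = seq
        age = float(np.clip(rng.normal(33.5, 12.8), 18, 70))
        fd = float(rng.lognormal(-2.0, 0.5))
        if truth.confounded and group == "MDD":
            age += 4.0
            fd *= 1.3
        if group == "MDD":
            dwell, _, _ = dwell_and_occurrence(seq, truth.k, truth.tr_seconds)
            d_eff = dwell[truth.effect_cap]
            if np.isnan(d_eff):
                d_eff = 0.0
            expected = truth.tr_seconds / (1.0 - truth.p_patient[truth.effect_cap, truth.effect_cap])
            hamd = (
                truth.hamd_intercept
                + truth.hamd_slope * (d_eff - expected)
                + rng.normal(0.0, truth.hamd_noise_sd)
            )
            hamd = float(max(hamd, 0.0))
        else:
            hamd = np.nan
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": age,
                "sex": "F" if rng.random() < 0.6 else "M",
                "education": float(np.clip(rng.normal(12.4, 3.2), 6, 22)),
                "site": f"site{rng.integers(n_sites)}",
                "mean_fd": fd,
                "hamd": hamd,
            }
        )
    manifest = CohortManifest(pd.DataFrame(rows))
    if out_dir is not None:
        out_dir = Path(out_dir)
        save_cohort(out_dir, manifest, series, make_atlas() if truth.n_rois == 116 else _atlas_for(truth))
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth.to_json(), fh)
        seq_dir = out_dir / "latent"
        seq_dir.mkdir(exist_ok=True)
        for sid, seq in latent.items():
            np.savetxt(seq_dir / f"{sid}.tsv", seq[None, :], fmt="%d", delimiter="\t")
    return manifest, series, latent


def _atlas_for(truth: SyntheticTruth) -> NetworkAtlas:
    """Even 6-network split for non-default ROI counts."""
    r = truth.n_rois
    base, extra = divmod(r, len(DEFAULT_NETWORKS))
    sizes = {
        net: base + (1 if i < extra else 0) for i, net in enumerate(DEFAULT_NETWORKS)
    }
    return make_atlas(sizes)
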