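"""Co-activation pattern (CAP) extraction by temporal k-means clustering.

Individual fMRI frames (rows of the standardized T x R matrices, pooled over
subjects) are clustered with the distance d(x, y) = 1 - Pearson(x, y). For
row-standardized frames x~, y~ (zero mean, unit sample SD across ROIs) this
distance equals ||x~ - y~||^2 / (2 (R - 1)), so Lloyd iterations are run in
Euclidean geometry on row-standardized frames; reported inertia is converted
back to correlation-distance units.

Group-level CAP maps are Z statistics over subjects: per CAP, each subject's
assigned frames are averaged, and the across-subject mean is divided by its
standard error. CAPs are attributed to networks by where the supra-threshold
|Z| mass (default |Z| > 1.96) concentrates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .io_model import NetworkAtlas, RoiTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class CapModel:
    """A fitted CAP clustering of pooled frames.

    centroids are cluster means of row-standardized frames, themselves
    row-standardized (K x R);
    assignments maps subject_id -> length-T integer label sequence;
    inertia is the total within-cluster correlation distance of the best
    initialization; zmaps (K x R group Z statistics) is filled in by
    :func:`compute_cap_zmaps`.
    """

    k: int
    centroids: np.ndarray
    assignments: dict[str, np.ndarray]
    seed: int
    inertia: float
    zmaps: np.ndarray | None = None
    objective_trace: list[float] = field(default_factory=list)

    @property
    def pooled_labels(self) -> np.ndarray:
        return np.concatenate(list(self.assignments.values()))


def row_standardize(frames: np.ndarray) -> np.ndarray:
    """Z-score each frame (row) across ROIs using the sample SD (ddof=1).

    A constant frame has no direction in correlation geometry and is refused.
    """
    frames = np.asarray(frames, dtype=float)
    sd = frames.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant frame(s) at pooled row(s) {bad.tolist()}")
    return (frames - frames.mean(axis=1, keepdims=True)) / sd[:, None]


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """d(x, y) = 1 - Pearson correlation between two frames."""
    return 1.0 - np.corrcoef(x, y)[0, 1]


def pool_frames(
    series: list[RoiTimeSeries],
) -> tuple[np.ndarray, dict[str, slice]]:
    """Stack standardized subject series into an N x R pooled frame matrix.

    Returns the pool (ordered by subject then time) and a map from subject_id
    to the slice of pooled rows holding that subject's frames, so per-subject
    label sequences can be recovered after clustering.
    """
    if not series:
        raise ValueError("empty cohort: no series to pool")
    r = series[0].n_rois
    frame_map: dict[str, slice] = {}
    blocks = []
    start = 0
    for ts in series:
        if not ts.standardized:
            raise ValueError(f"subject {ts.subject_id!r}: series not standardized")
        if ts.n_rois != r:
            raise ValueError(
                f"subject {ts.subject_id!r}: R={ts.n_rois} differs from {r}"
            )
        blocks.append(ts.data)
        frame_map[ts.subject_id] = slice(start, start + ts.n_frames)
        start += ts.n_frames
    return np.vstack(blocks), frame_map


def _sq_dists(xstd: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # ||x - c||^2 expanded; x norms constant per row so omitted for argmin,
    # but kept for the objective.
    d = (
        (xstd * xstd).sum(axis=1, keepdims=True)
        - 2.0 * xstd @ centroids.T
        + (centroids * centroids).sum(axis=1)
    )
    np.maximum(d, 0.0, out=d)
    return d


def _standardize_centroid(m: np.ndarray) -> np.ndarray:
    # cluster means of standardized frames already have zero row mean; the
    # rescaling to unit sample SD makes all centroid norms equal, so the
    # Euclidean argmin is exactly the correlation-distance argmin
    sd = m.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) centroid")
    return (m - m.mean()) / sd


def _init_centroids(
    xstd: np.ndarray, k: int, rng: np.random.Generator, init: str
) -> np.ndarray:
    n = xstd.shape[0]
    if init == "random":
        return xstd[rng.choice(n, size=k, replace=False)].copy()
    if init != "k-means++":
        raise ValueError(f"unknown init {init!r}")
    # greedy k-means++ seeding in the standardized-frame geometry: D^2
    # sampling with several candidates per step, keeping the candidate that
    # most reduces the potential
    n_candidates = 2 + int(np.log(k))
    idx = [int(rng.integers(n))]
    d2 = ((xstd - xstd[idx[0]]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        cand = rng.choice(n, size=n_candidates, p=d2 / d2.sum())
        best = None
        for ci in cand:
            nd = np.minimum(d2, ((xstd - xstd[int(ci)]) ** 2).sum(axis=1))
            if best is None or nd.sum() < best[0]:
                best = (nd.sum(), int(ci), nd)
        _, ci, d2 = best
        idx.append(ci)
    return xstd[np.array(idx)].copy()


def _lloyd(
    xstd: np.ndarray, k: int, max_iter: int, rng: np.random.Generator, init: str
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = xstd.shape[0]
    centroids = _init_centroids(xstd, k, rng, init)
    labels = np.full(n, -1, dtype=int)
    trace: list[float] = []
    for _ in range(max_iter):
        d = _sq_dists(xstd, centroids)
        new_labels = d.argmin(axis=1)  # ties -> lower CAP index
        obj = d[np.arange(n), new_labels].sum()
        trace.append(obj)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = labels == c
            if members.any():
                centroids[c] = _standardize_centroid(xstd[members].mean(axis=0))
            else:
                # re-seed an emptied cluster from the farthest frame
                far = d[np.arange(n), labels].argmax()
                centroids[c] = xstd[far]
                labels[far] = c
                logger.info("re-seeded empty cluster %d from frame %d", c, far)
    d = _sq_dists(xstd, centroids)
    labels = d.argmin(axis=1)
    inertia = d[np.arange(n), labels].sum()
    return labels, centroids, inertia, trace


def kmeans_correlation(
    pool: np.ndarray,
    k: int,
    frame_map: dict[str, slice] | None = None,
    n_init: int = 5,
    max_iter: int = 500,
    seed: int = 0,
    init: str = "k-means++",
    sort_by_occupancy: bool = True,
) -> CapModel:
    """K-means over frames with 1 - Pearson correlation distance.

    Runs ``n_init`` independent random initializations of at most
    ``max_iter`` Lloyd iterations each and keeps the partition with the
    lowest total within-cluster distance. Initialization defaults to
    k-means++ (D^2 sampling of seed frames) — the default seeding of the
    k-means implementations this workflow is usually run with — and is far
    less prone to bad local optima than ``init="random"`` (uniform frame
    selection), which remains available.
    CAP labels are relabelled by pooled occupancy (descending) unless
    ``sort_by_occupancy`` is disabled; label identity is otherwise arbitrary.
    """
    pool = np.asarray(pool, dtype=float)
    n, r = pool.shape
    if n <= k:
        raise ValueError(f"need more frames ({n}) than clusters ({k})")
    xstd = row_standardize(pool)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float, list[float]] | None = None
    for _ in range(n_init):
        labels, centroids, inertia, trace = _lloyd(xstd, k, max_iter, rng, init)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, trace)
    labels, centroids, inertia, trace = best

    if sort_by_occupancy:
        counts = np.bincount(labels, minlength=k)
        order = np.argsort(-counts, kind="stable")
        relabel = np.empty(k, dtype=int)
        relabel[order] = np.arange(k)
        labels = relabel[labels]
        centroids = centroids[order]

    if frame_map is None:
        assignments = {"pooled": labels}
    else:
        assignments = {sid: labels[sl].copy() for sid, sl in frame_map.items()}
    # inertia in correlation-distance units: d = ||x~-y~||^2 / (2(R-1))
    return CapModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        seed=seed,
        inertia=inertia / (2.0 * (r - 1)),
        objective_trace=[t / (2.0 * (r - 1)) for t in trace],
    )


def _dunn_index(dmat: np.ndarray, labels: np.ndarray) -> float:
    """min inter-cluster distance / max intra-cluster diameter."""
    ks = np.unique(labels)
    diam = 0.0
    for c in ks:
        idx = np.flatnonzero(labels == c)
        if idx.size > 1:
            diam = max(diam, dmat[np.ix_(idx, idx)].max())
    sep = np.inf
    for i, a in enumerate(ks):
        ia = np.flatnonzero(labels == a)
        for b in ks[i + 1 :]:
            ib = np.flatnonzero(labels == b)
            sep = min(sep, dmat[np.ix_(ia, ib)].min())
    if diam == 0.0:
        return np.inf
    return sep / diam


def compute_validity(
    pool: np.ndarray,
    k_range: tuple[int, int] = (2, 20),
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Cluster-number validity indices over a contiguous k range.

    Columns: within-cluster sum of correlation distances (elbow curve),
    silhouette and Dunn in correlation-distance geometry, Calinski-Harabasz
    and Davies-Bouldin in Euclidean geometry on the row-standardized frames.
    """
    pool = np.asarray(pool, dtype=float)
    n = pool.shape[0]
    lo, hi = k_range
    if lo < 2 or hi >= n:
        raise ValueError(f"k_range {k_range} outside [2, N-1] for N={n}")
    xstd = row_standardize(pool)
    dmat = squareform(pdist(xstd, metric="correlation"))
    rows = []
    for k in range(lo, hi + 1):
        model = kmeans_correlation(
            pool, k, n_init=n_init, max_iter=max_iter, seed=seed
        )
        labels = model.pooled_labels
        rows.append(
            {
                "k": k,
                "within_dist": model.inertia,
                "silhouette": silhouette_score(dmat, labels, metric="precomputed"),
                "calinski_harabasz": calinski_harabasz_score(xstd, labels),
                "davies_bouldin": davies_bouldin_score(xstd, labels),
                "dunn": _dunn_index(dmat, labels),
            }
        )
    return pd.DataFrame(rows)


def compute_cap_zmaps(
    series: list[RoiTimeSeries],
    assignments: dict[str, np.ndarray],
    k: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Group-level K x R Z-statistic CAP maps.

    For CAP c, each subject contributes the mean of its standardized frames
    assigned to c (subjects with no frame in c are excluded and flagged);
    Z_{c,r} = mean_s(v_{s,c,r}) / (SD_s(v_{s,c,r}, ddof=1) / sqrt(n_c)).
    Returns (zmaps, n_subjects_per_cap); CAPs visited by fewer than two
    subjects get an all-NaN row and a warning.
    """
    if k is None:
        k = int(max(a.max() for a in assignments.values())) + 1
    r = series[0].n_rois
    subject_means = {c: [] for c in range(k)}
    for ts in series:
        if not ts.standardized:
            raise ValueError(f"subject {ts.subject_id!r}: series not standardized")
        labels = assignments[ts.subject_id]
        for c in range(k):
            sel = labels == c
            if sel.any():
                subject_means[c].append(ts.data[sel].mean(axis=0))
    zmaps = np.full((k, r), np.nan)
    n_per_cap = np.zeros(k, dtype=int)
    for c in range(k):
        v = np.array(subject_means[c])
        n_per_cap[c] = len(v)
        if len(v) < 2:
            warnings.warn(
                f"CAP {c} visited by {len(v)} subject(s); Z map undefined",
                stacklevel=2,
            )
            continue
        se = v.std(axis=0, ddof=1) / np.sqrt(len(v))
        with np.errstate(divide="ignore", invalid="ignore"):
            zmaps[c] = np.where(se > 0, v.mean(axis=0) / se, np.nan)
    return zmaps, n_per_cap


def attribute_networks(
    zmaps: np.ndarray,
    atlas: NetworkAtlas,
    z_threshold: float = 1.96,
) -> pd.DataFrame:
    """Attribute each CAP to networks from its supra-threshold |Z| mass.

    Method 1 (``proportion``): per network, the share of summed |Z| over ROIs
    with |Z| > z_threshold relative to the summed supra-threshold |Z| over all
    ROIs (rows sum to 1 when any ROI is supra-threshold, all zero otherwise).
    Method 2 (``positive_mass`` / ``negative_mass``): per network, summed |Z|
    over supra-threshold ROIs split by activation sign (Z > thr vs Z < -thr).
    """
    zmaps = np.asarray(zmaps, dtype=float)
    networks = atlas.networks
    roi_net = atlas.roi_networks()
    rows = []
    for c, z in enumerate(zmaps):
        absz = np.abs(z)
        supra = absz > z_threshold
        total = absz[supra & np.isfinite(z)].sum()
        if total == 0:
            warnings.warn(f"CAP {c}: no supra-threshold ROI", stacklevel=2)
        for net in networks:
            in_net = roi_net == net
            sel = supra & in_net & np.isfinite(z)
            rows.append(
                {
                    "cap": c,
                    "network": net,
                    "proportion": absz[sel].sum() / total if total > 0 else 0.0,
                    "positive_mass": absz[sel & (z > z_threshold)].sum(),
                    "negative_mass": absz[sel & (z < -z_threshold)].sum(),
                    "z_threshold": z_threshold,
                }
            )
    return pd.DataFrame(rows)


def cap_similarity(zmaps: np.ndarray) -> np.ndarray:
    """K x K Pearson spatial-similarity matrix between CAP maps."""
    zmaps = np.asarray(zmaps, dtype=float)
    if zmaps.shape[0] < 2:
        raise ValueError("need at least two CAP maps")
    return np.corrcoef(zmaps)


def anticorrelated_pairs(
    sim: np.ndarray, threshold: float = -0.5
) -> list[tuple[int, int, float]]:
    """CAP pairs whose spatial correlation falls below ``threshold``."""
    pairs = []
    k = sim.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            if sim[i, j] < threshold:
                pairs.append((i, j, float(sim[i, j])))
    return pairs


def match_caps(
    reference: np.ndarray, other: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match CAP maps across runs/settings by spatial correlation (Hungarian).

    Returns (permutation, matched correlations) such that ``other[perm[i]]``
    corresponds to ``reference[i]``.
    """
    from scipy.optimize import linear_sum_assignment

    corr = 1.0 - cdist(
        np.asarray(reference, float), np.asarray(other, float), metric="correlation"
    )
    ri, ci = linear_sum_assignment(-corr)
    return ci, corr[ri, ci]
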