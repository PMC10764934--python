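"""Markov dynamics metrics of CAP label sequences.

A subject's CAP assignment sequence is treated as a realization of a
finite-state Markov chain over the K CAPs. Four families of metrics are
derived:

* dwell time — mean duration (seconds) of uninterrupted occupancy of a CAP
  (total dwell time, the summed occupancy, is emitted alongside);
* occurrence rate — fraction of frames assigned to each CAP;
* transition matrix — row-stochastic maximum-likelihood estimate of the
  frame-to-frame transition probabilities (diagonal = persistence);
* entropy of Markov trajectories — H[i, j], the Shannon entropy (bits) of the
  random path from state i until it first hits state j. Low H[i, j] means j
  is reached from i by predictable routes ("more accessible"). The matrix
  solves, for each target j, the linear recursion
  H[i, j] = h_i + sum_{m != j} P[i, m] H[m, j] with h_i the per-step entropy
  of row i, and satisfies the first-return identity H[j, j] = H(P) / mu_j
  where H(P) is the entropy rate and mu the stationary distribution.

Unvisited states propagate as missing values (NaN), never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class DynamicProfile:
    """Per-subject dynamic metrics derived from one label sequence."""

    subject_id: str
    dwell_time: np.ndarray  # mean run duration per CAP, seconds (NaN if unvisited)
    total_dwell_time: np.ndarray  # total occupancy per CAP, seconds
    occurrence_rate: np.ndarray  # frame fraction per CAP, sums to 1
    transition: np.ndarray  # K x K row-stochastic (NaN rows where undefined)
    counts: np.ndarray  # K x K transition counts
    trajectory_entropy: np.ndarray  # K x K bits (NaN where undefined)
    visited: np.ndarray  # length-K boolean


def _check_sequence(seq: np.ndarray, k: int) -> np.ndarray:
    seq = np.asarray(seq)
    if seq.ndim != 1 or seq.size < 2:
        raise ValueError("label sequence must be 1-D with T >= 2")
    if seq.min() < 0 or seq.max() >= k:
        bad = seq[(seq < 0) | (seq >= k)][0]
        raise ValueError(f"label {bad} outside 0..{k - 1}")
    return seq.astype(int)


def dwell_and_occurrence(
    seq: np.ndarray, k: int, tr_seconds: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean dwell time, total dwell time (seconds) and occurrence rate per CAP.

    Runs are maximal contiguous blocks of one label. An unvisited CAP gets
    NaN dwell times and occurrence 0.
    """
    seq = _check_sequence(seq, k)
    t = seq.size
    # run-length encode
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [t]))
    run_labels = seq[starts]
    run_lengths = ends - starts

    dwell = np.full(k, np.nan)
    total = np.zeros(k)
    occurrence = np.zeros(k)
    for c in range(k):
        lens = run_lengths[run_labels == c]
        if lens.size:
            dwell[c] = lens.mean() * tr_seconds
            total[c] = lens.sum() * tr_seconds
    counts = np.bincount(seq, minlength=k)
    occurrence = counts / t
    return dwell, total, occurrence


def estimate_transition_matrix(
    seq: np.ndarray, k: int, pseudocount: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Transition counts and row-normalized transition probabilities.

    counts[i, j] = #{t : seq_t = i, seq_{t+1} = j}. Rows without outgoing
    transitions are NaN (missing), never zero-filled. ``pseudocount`` adds a
    Laplace epsilon to every cell before normalization (default 0, i.e. the
    plain maximum-likelihood estimate); rows that are all-missing stay missing.
    """
    seq = _check_sequence(seq, k)
    counts = np.zeros((k, k))
    np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    smoothed = counts + pseudocount if pseudocount else counts
    row_sums = smoothed.sum(axis=1)
    trans = np.full((k, k), np.nan)
    visited_rows = counts.sum(axis=1) > 0
    rows = visited_rows if pseudocount == 0 else (row_sums > 0) & visited_rows
    trans[rows] = smoothed[rows] / row_sums[rows, None]
    return counts, trans


def _strong_components(p: np.ndarray) -> tuple[int, np.ndarray]:
    adj = csr_matrix((p > 0).astype(np.int8))
    return connected_components(adj, directed=True, connection="strong")


def _check_stochastic(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("transition matrix must be square")
    if not np.isfinite(p).all() or (p < 0).any():
        raise ValueError("transition matrix must be finite and non-negative")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must sum to 1 (substochastic input)")
    return p


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary distribution mu with mu P = mu, sum(mu) = 1, of an
    irreducible chain."""
    p = _check_stochastic(p)
    n_comp, comp = _strong_components(p)
    if n_comp > 1:
        groups = [np.flatnonzero(comp == c).tolist() for c in range(n_comp)]
        raise ValueError(f"reducible chain; strongly connected classes: {groups}")
    k = p.shape[0]
    # solve (P^T - I) mu = 0 with the normalization row appended
    a = np.vstack([p.T - np.eye(k), np.ones(k)])
    b = np.concatenate([np.zeros(k), [1.0]])
    mu, *_ = np.linalg.lstsq(a, b, rcond=None)
    mu = np.clip(mu, 0.0, None)
    return mu / mu.sum()


def entropy_rate(p: np.ndarray, base: float = 2.0) -> float:
    """Entropy rate H(P) = sum_i mu_i h_i of an irreducible chain."""
    p = _check_stochastic(p)
    mu = stationary_distribution(p)
    return float(mu @ _row_entropies(p, base))


def _row_entropies(p: np.ndarray, base: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(p > 0, np.log(p), 0.0)
    return -(p * lg).sum(axis=1) / np.log(base)


def trajectory_entropy(
    p: np.ndarray, base: float = 2.0, cond_limit: float = 1e12
) -> np.ndarray:
    """Entropy (bits by default) of the trajectory from i until first
    hitting j, for every ordered state pair; the diagonal is the
    first-return trajectory entropy.

    For each target j the vector H[:, j] solves (I - Q_j) H[:, j] = h where
    Q_j is P with column j zeroed and h the per-step row entropies.
    """
    p = _check_stochastic(p)
    n_comp, comp = _strong_components(p)
    if n_comp > 1:
        groups = [np.flatnonzero(comp == c).tolist() for c in range(n_comp)]
        raise ValueError(f"reducible chain; strongly connected classes: {groups}")
    k = p.shape[0]
    h = _row_entropies(p, base)
    out = np.empty((k, k))
    eye = np.eye(k)
    for j in range(k):
        q = p.copy()
        q[:, j] = 0.0
        a = eye - q
        if np.linalg.cond(a) > cond_limit:
            raise ValueError(f"ill-conditioned hitting system for target state {j}")
        out[:, j] = np.linalg.solve(a, h)
    return out


def dynamic_profile(
    subject_id: str,
    seq: np.ndarray,
    k: int,
    tr_seconds: float = 2.0,
    entropy_base: float = 2.0,
    pseudocount: float = 0.0,
) -> DynamicProfile:
    """All dynamic metrics for one subject's label sequence.

    Trajectory entropy is computed on the visited-state sub-chain when that
    sub-chain is irreducible; entries touching unvisited states (or the whole
    matrix, if the visited sub-chain is reducible) are missing.
    """
    seq = _check_sequence(seq, k)
    dwell, total, occ = dwell_and_occurrence(seq, k, tr_seconds)
    counts, trans = estimate_transition_matrix(seq, k, pseudocount)
    visited = np.bincount(seq, minlength=k) > 0

    ent = np.full((k, k), np.nan)
    vis_idx = np.flatnonzero(visited)
    if vis_idx.size >= 1:
        sub = trans[np.ix_(vis_idx, vis_idx)]
        if not np.isnan(sub).any() and np.allclose(sub.sum(axis=1), 1.0, atol=1e-10):
            n_comp, _ = _strong_components(sub)
            if n_comp == 1:
                ent[np.ix_(vis_idx, vis_idx)] = trajectory_entropy(sub, entropy_base)
    return DynamicProfile(
        subject_id=subject_id,
        dwell_time=dwell,
        total_dwell_time=total,
        occurrence_rate=occ,
        transition=trans,
        counts=counts,
        trajectory_entropy=ent,
        visited=visited,
    )


def profiles_to_long(profiles: list[DynamicProfile]) -> "pd.DataFrame":
    """Long-format table: subject_id, metric, cap_from, cap_to, value.

    metric is one of dwell, total_dwell, occurrence, transition, persistence,
    traj_entropy; cap_to is empty for the vector metrics.
    """
    import pandas as pd

    rows = []
    for pr in profiles:
        k = pr.occurrence_rate.size
        for c in range(k):
            rows.append((pr.subject_id, "dwell", c, None, pr.dwell_time[c]))
            rows.append((pr.subject_id, "total_dwell", c, None, pr.total_dwell_time[c]))
            rows.append((pr.subject_id, "occurrence", c, None, pr.occurrence_rate[c]))
        for i in range(k):
            for j in range(k):
                v = pr.transition[i, j]
                name = "persistence" if i == j else "transition"
                rows.append((pr.subject_id, name, i, j, v))
                rows.append((pr.subject_id, "traj_entropy", i, j, pr.trajectory_entropy[i, j]))
    return pd.DataFrame(
        rows, columns=["subject_id", "metric", "cap_from", "cap_to", "value"]
    )
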