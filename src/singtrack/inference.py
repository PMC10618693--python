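"""Permutation inference: shifted-pairing null and cluster-based test.

Two nonparametric procedures quantify evidence for envelope–EEG coupling:

- a *reversed circular-shift null* for predictive accuracy: the held-out EEG
  is time-reversed and circularly rotated against the unchanged model
  prediction, destroying true temporal alignment while preserving the
  autocorrelation structure; 400 shifts give a per-channel null accuracy
  whose average is the "randomized" accuracy of a subject.
- a *cluster-based permutation test* of the group TRF weights against zero:
  element-wise one-sample t statistics are thresholded, supra-threshold
  elements are grouped along lag adjacency and an electrode neighbour graph,
  cluster mass is the summed t, and the null is built from random sign flips
  of subjects. Clusters must span at least two adjacent electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .preprocess import montage_positions
from .trf import TRFResults, _pearson_columns

__all__ = [
    "NullDistribution",
    "ClusterResult",
    "shifted_null",
    "cluster_test",
    "electrode_adjacency",
]


@dataclass
class NullDistribution:
    """Per-channel predictive accuracies under the shifted pairing."""

    per_permutation_r: np.ndarray  # (n_permutations, n_channels)
    ch_names: Sequence[str]
    n_permutations: int
    seed: int
    dyad_id: str = "S00"
    condition: str = ""

    @property
    def mean_r(self) -> np.ndarray:
        return self.per_permutation_r.mean(axis=0)

    @property
    def mean_z(self) -> np.ndarray:
        return np.arctanh(np.clip(self.per_permutation_r, -0.999999, 0.999999)).mean(axis=0)

    def quantile(self, q: float) -> np.ndarray:
        return np.quantile(self.per_permutation_r, q, axis=0)


@dataclass
class Cluster:
    channels: list
    lag_ms_min: float
    lag_ms_max: float
    mass: float
    p_value: float
    sign: int


@dataclass
class ClusterResult:
    """Clusters of supra-threshold TRF weights with permutation p-values."""

    clusters: list
    n_randomizations: int
    alpha: float
    max_null_mass: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float | None = None) -> list:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value < a]


def shifted_null(
    results: TRFResults,
    n_permutations: int = 400,
    seed: int = 0,
    min_shift_s: float = 1.0,
    reverse: str = "once",
) -> NullDistribution:
    """Reversed circular-shift null accuracies on the held-out test split.

    The concatenated test EEG is time-reversed (a fixed transform, so
    reversing once or per permutation is equivalent; both spellings are
    accepted) and rotated by an independent uniform shift of at least
    ``min_shift_s`` seconds for each of ``n_permutations`` permutations;
    per-channel Pearson r against the unchanged prediction is recorded.
    """
    if reverse not in ("once", "per_permutation"):
        raise ValueError("reverse must be 'once' or 'per_permutation'")
    pred, obs = results.test_arrays()
    sfreq = results.encoder.dataset.sfreq
    n_ch, T = obs.shape
    min_shift = int(round(min_shift_s * sfreq))
    if T < 2 * min_shift:
        raise ValueError(
            f"test segment ({T / sfreq:.2f} s) too short for a {min_shift_s:.2f} s minimum shift"
        )
    rng = np.random.default_rng(seed)
    rev = obs[:, ::-1]
    shifts = rng.integers(min_shift, T - min_shift + 1, size=n_permutations)
    r = np.empty((n_permutations, n_ch))
    base = np.arange(T)
    for i, k in enumerate(shifts):
        shifted = rev[:, (base + k) % T]
        r[i] = _pearson_columns(pred.T, shifted.T)
    return NullDistribution(
        per_permutation_r=r,
        ch_names=results.ch_names,
        n_permutations=n_permutations,
        seed=seed,
        dyad_id=results.encoder.dyad_id,
        condition=results.encoder.dataset.condition,
    )


# ---------------------------------------------------------------------------
# electrode adjacency


def electrode_adjacency(
    ch_names: Sequence[str],
    positions: np.ndarray | None = None,
    target_degree: tuple[int, int] = (3, 6),
) -> np.ndarray:
    """Boolean neighbour matrix from template 10–20 positions.

    The neighbour-distance threshold is the smallest one that keeps every
    electrode at least ``target_degree[0]`` neighbours while the graph stays
    connected; with standard montages this lands the median degree in the
    3–6 range.
    """
    pos = positions if positions is not None else montage_positions(ch_names)
    n = len(ch_names)
    if pos.shape[0] != n:
        raise ValueError("one position per electrode is required")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    candidates = np.unique(d[np.isfinite(d)])
    lo, hi = 0, candidates.size - 1
    best = candidates[-1]
    while lo <= hi:  # smallest threshold meeting degree + connectivity
        mid = (lo + hi) // 2
        adj = d <= candidates[mid]
        deg_ok = adj.sum(axis=1).min() >= target_degree[0]
        conn_ok = connected_components(sparse.csr_matrix(adj), directed=False)[0] == 1
        if deg_ok and conn_ok:
            best = candidates[mid]
            hi = mid - 1
        else:
            lo = mid + 1
    adj = d <= best
    if connected_components(sparse.csr_matrix(adj), directed=False)[0] != 1:
        raise RuntimeError("electrode adjacency graph is disconnected")
    return adj


def _spatiotemporal_graph(adjacency: np.ndarray, n_lags: int) -> sparse.csr_matrix:
    """Sparse neighbour graph over (channel, lag) elements: adjacent lags on
    the same channel and the same lag on neighbouring channels."""
    n_ch = adjacency.shape[0]
    n = n_ch * n_lags
    rows, cols = [], []
    node = lambda c, l: c * n_lags + l  # noqa: E731
    lag_idx = np.arange(n_lags - 1)
    for c in range(n_ch):
        rows.append(node(c, lag_idx))
        cols.append(node(c, lag_idx + 1))
    ch_a, ch_b = np.nonzero(np.triu(adjacency, 1))
    all_lags = np.arange(n_lags)
    for a, b in zip(ch_a, ch_b):
        rows.append(node(a, all_lags))
        cols.append(node(b, all_lags))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    g = sparse.coo_matrix((np.ones(r.size, bool), (r, c)), shape=(n, n))
    return (g + g.T).tocsr()


def _cluster_masses(
    t_map: np.ndarray,
    t_crit: float,
    graph: sparse.csr_matrix,
    n_lags: int,
    min_electrodes: int,
) -> list[tuple[np.ndarray, float, int]]:
    """Clusters as (element indices, mass, sign); the ≥2-electrode rule applied."""
    out = []
    flat = t_map.ravel()
    for sign in (1, -1):
        mask = sign * flat > t_crit
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = graph[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for comp in range(n_comp):
            members = idx[labels == comp]
            channels = np.unique(members // n_lags)
            if channels.size < min_electrodes:
                continue
            out.append((members, float(flat[members].sum()), sign))
    return out


def cluster_test(
    weights: np.ndarray | Sequence[TRFResults],
    adjacency: np.ndarray | None = None,
    ch_names: Sequence[str] | None = None,
    lags_ms: np.ndarray | None = None,
    n_randomizations: int = 1000,
    alpha: float = 0.05,
    cluster_forming_alpha: float = 0.05,
    min_electrodes: int = 2,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test of TRF weights against zero.

    ``weights`` is a (subjects, channels, lags) stack or a list of fitted
    :class:`TRFResults`. Cluster mass is the sum of element t values; its
    null is the distribution of the maximal cluster mass over
    ``n_randomizations`` random sign flips of subjects, which controls the
    family-wise error at the cluster level.
    """
    if not isinstance(weights, np.ndarray):
        results = list(weights)
        ch_names = ch_names or results[0].ch_names
        lags_ms = results[0].lags_ms if lags_ms is None else lags_ms
        weights = np.stack([res.weights for res in results])
    weights = np.asarray(weights, dtype=float)
    n_subj, n_ch, n_lags = weights.shape
    if n_subj < 6:
        raise ValueError("cluster test needs at least 6 subjects")
    if ch_names is None:
        ch_names = [f"CH{i:02d}" for i in range(n_ch)]
    if lags_ms is None:
        lags_ms = np.arange(n_lags, dtype=float)
    if adjacency is None:
        adjacency = electrode_adjacency(ch_names)
    adjacency = np.asarray(adjacency, dtype=bool)
    if connected_components(sparse.csr_matrix(adjacency), directed=False)[0] != 1:
        raise ValueError("electrode adjacency graph must be connected")

    graph = _spatiotemporal_graph(adjacency, n_lags)
    df = n_subj - 1
    t_crit = float(t_dist.ppf(1.0 - cluster_forming_alpha / 2.0, df))
    flat = weights.reshape(n_subj, -1)

    def t_map(signs: np.ndarray) -> np.ndarray:
        x = flat * signs[:, None]
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n_subj))
        # zero-variance elements: nan -> 0, +-inf clamped to a finite mass
        return np.nan_to_num(t, nan=0.0, posinf=1e6, neginf=-1e6)

    observed = t_map(np.ones(n_subj))
    obs_clusters = _cluster_masses(observed, t_crit, graph, n_lags, min_electrodes)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_randomizations)
    for i in range(n_randomizations):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        masses = _cluster_masses(t_map(signs), t_crit, graph, n_lags, min_electrodes)
        if masses:
            null_max[i] = max(abs(m) for _, m, _ in masses)

    clusters = []
    for members, mass, sign in obs_clusters:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_randomizations)
        chans = sorted({ch_names[m // n_lags] for m in members})
        lag_vals = lags_ms[np.unique(members % n_lags)]
        clusters.append(
            Cluster(
                channels=chans,
                lag_ms_min=float(lag_vals.min()),
                lag_ms_max=float(lag_vals.max()),
                mass=mass,
                p_value=float(p),
                sign=sign,
            )
        )
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        clusters=clusters,
        n_randomizations=n_randomizations,
        alpha=alpha,
        max_null_mass=null_max,
    )
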