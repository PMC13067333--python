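"""Cluster-based permutation inference for node x frequency x time maps.

The multiple-comparison problem over channels (or voxels), frequencies and
time bins is handled nonparametrically: an element-wise statistic map is
thresholded at the two-sided parametric quantile for the cluster-forming
alpha, suprathreshold cells of equal sign are grouped into connected
clusters (neighboring channels / adjacent frequencies / adjacent bins), and
each cluster's mass (sum of the statistic over members) is compared against
a permutation null of the per-permutation maximum |mass|:

    p = (1 + #{null >= |mass_obs|}) / (n_perm + 1).

Using the maximum of |mass| over clusters of both signs as the null
statistic makes p exactly invariant to exchanging the two groups (which
negates every mass).  Permutation schemes follow the design: random sign
flips of within-subject differences (paired / one-sample), group-label
reshuffles (independent), and score permutation across subjects (Pearson
correlation).  When fewer distinct permutations exist than requested, the
scheme is enumerated exhaustively (with a warning) and p becomes
count / n_total over the complete group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import sparse, stats

from ._rng import substream

__all__ = ["ClusterResult", "Cluster", "stat_map", "form_clusters",
           "permutation_p", "combined_adjacency"]


# ----------------------------------------------------------- statistic maps

def _t_one_sample(d: np.ndarray):
    """One-sample t across axis 0; zero-variance cells -> 0, flagged."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    flagged = sd == 0
    t = np.zeros_like(m)
    np.divide(m, sd / np.sqrt(n), out=t, where=~flagged)
    return t, n - 1, flagged


def _t_independent(a: np.ndarray, b: np.ndarray):
    n1, n2 = a.shape[0], b.shape[0]
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    flagged = denom == 0
    t = np.zeros_like(sp2)
    np.divide(a.mean(axis=0) - b.mean(axis=0), denom, out=t, where=~flagged)
    return t, n1 + n2 - 2, flagged


def _pearson_r(data: np.ndarray, scores: np.ndarray):
    n = data.shape[0]
    dc = data - data.mean(axis=0)
    sc = scores - scores.mean()
    sx = np.sqrt((dc**2).sum(axis=0))
    sy = np.sqrt((sc**2).sum())
    denom = sx * sy
    flagged = denom == 0
    r = np.zeros(data.shape[1:])
    np.divide(np.tensordot(sc, dc, axes=(0, 0)), denom, out=r, where=~flagged)
    return r, n - 2, flagged


def stat_map(data_a: np.ndarray, data_b: np.ndarray | None = None,
             scores: np.ndarray | None = None, kind: str = "paired_t"):
    """Element-wise subject-level statistic map.

    data arrays are (n_subjects, ...cells...); the unit of observation is
    the participant.  Returns (map, df, flagged) where flagged marks
    zero-variance cells whose statistic was set to 0.
    """
    a = np.asarray(data_a, float)
    if kind == "one_sample_t":
        if a.shape[0] < 3:
            raise ValueError("need >= 3 subjects")
        return _t_one_sample(a)
    if kind == "paired_t":
        b = np.asarray(data_b, float)
        if a.shape != b.shape or a.shape[0] < 3:
            raise ValueError("paired design needs matching arrays, >= 3 subjects")
        return _t_one_sample(a - b)
    if kind == "independent_t":
        b = np.asarray(data_b, float)
        if a.shape[0] < 3 or b.shape[0] < 3:
            raise ValueError("need >= 3 subjects per group")
        return _t_independent(a, b)
    if kind == "pearson_r":
        if a.shape[0] < 4:
            raise ValueError("need >= 4 subjects for correlation")
        return _pearson_r(a, np.asarray(scores, float))
    raise ValueError(f"unknown kind {kind!r}")


def _threshold(kind: str, df: int, cluster_alpha: float) -> float:
    """Two-sided parametric cluster-forming threshold on the clustering scale.

    Correlations are clustered on their t-equivalent scale (see
    :func:`_r_to_t`), so the threshold is the t quantile for every kind.
    """
    return float(stats.t.ppf(1 - cluster_alpha / 2, df))


def _r_to_t(r: np.ndarray, df: int) -> np.ndarray:
    """Map Pearson r to its t statistic: monotone, so thresholding is
    unchanged, but cluster mass rewards strong correlations instead of
    saturating at |r| = 1."""
    rc = np.clip(r, -0.999999, 0.999999)
    return rc * np.sqrt(df / (1.0 - rc**2))


# ----------------------------------------------------------------- clusters

def combined_adjacency(node_adj: np.ndarray, n_freqs: int, n_bins: int,
                       freq_adjacent: bool = True,
                       time_adjacent: bool = True) -> sparse.csr_matrix:
    """Sparse adjacency over flattened (node, freq, bin) cells.

    Two cells are neighbors iff they differ along exactly one axis by one
    step: neighboring nodes at the same (freq, bin), or adjacent frequencies
    / adjacent bins at the same node.  Axis couplings are toggleable.
    """
    node_adj = sparse.csr_matrix(np.asarray(node_adj, bool))
    eye_f = sparse.identity(n_freqs, format="csr", dtype=bool)
    eye_t = sparse.identity(n_bins, format="csr", dtype=bool)
    chain_f = sparse.diags([True] * (n_freqs - 1), 1, shape=(n_freqs, n_freqs),
                           dtype=bool) if n_freqs > 1 else None
    chain_t = sparse.diags([True] * (n_bins - 1), 1, shape=(n_bins, n_bins),
                           dtype=bool) if n_bins > 1 else None
    eye_n = sparse.identity(node_adj.shape[0], format="csr", dtype=bool)
    A = sparse.kron(node_adj, sparse.kron(eye_f, eye_t))
    if freq_adjacent and chain_f is not None:
        A = A + sparse.kron(eye_n, sparse.kron(chain_f, eye_t))
    if time_adjacent and chain_t is not None:
        A = A + sparse.kron(eye_n, sparse.kron(eye_f, chain_t))
    A = A + A.T
    return sparse.csr_matrix(A, dtype=bool)


@dataclass(frozen=True)
class Cluster:
    members: np.ndarray  # flat cell indices into the map
    mass: float
    sign: int
    p: float = np.nan


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat: np.ndarray            # observed statistic map
    threshold: float
    df: int
    null_max_mass: np.ndarray   # per-permutation max |mass|
    n_permutations: int
    cluster_alpha: float
    exhaustive: bool = False
    seed: int | None = None
    permutation_log: np.ndarray | None = None  # permutation indices/signs

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]

    def to_json(self, path: str) -> None:
        """Serialize members, masses, p values, threshold and seed."""
        import json
        payload = {
            "clusters": [{"members": c.members.tolist(), "mass": c.mass,
                          "sign": c.sign, "p": c.p} for c in self.clusters],
            "threshold": self.threshold,
            "df": self.df,
            "n_permutations": self.n_permutations,
            "cluster_alpha": self.cluster_alpha,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
            "null_max_mass": self.null_max_mass.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _clusters_from_map(flat_stat: np.ndarray, threshold: float,
                       adj: sparse.csr_matrix, want_members: bool = True):
    """Connected same-sign suprathreshold components; returns list[(idx, mass)]."""
    out = []
    for sign in (1, -1):
        mask = (sign * flat_stat) > threshold
        k = int(mask.sum())
        if k == 0:
            continue
        if k == 1:
            idx = np.flatnonzero(mask)
            out.append((idx if want_members else None,
                        float(flat_stat[idx[0]]), sign))
            continue
        sel = np.flatnonzero(mask)
        sub = adj[sel][:, sel]
        n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
        for ci in range(n_comp):
            members = sel[labels == ci]
            out.append((members if want_members else None,
                        float(flat_stat[members].sum()), sign))
    return out


def form_clusters(stat: np.ndarray, threshold: float,
                  adj: sparse.csr_matrix) -> list[Cluster]:
    """Group suprathreshold same-sign cells into connected clusters."""
    flat = np.asarray(stat, float).ravel()
    if adj.shape[0] != flat.size:
        raise ValueError("adjacency does not cover all cells")
    return [Cluster(np.sort(m), mass, sign)
            for m, mass, sign in _clusters_from_map(flat, threshold, adj)]


# ------------------------------------------------------------- permutations

def _max_abs_mass(flat_stat, threshold, adj) -> float:
    cl = _clusters_from_map(flat_stat, threshold, adj, want_members=False)
    return max((abs(m) for _, m, _ in cl), default=0.0)


def _perm_signs(n_sub: int, n_perm: int, rng) -> tuple[np.ndarray, bool]:
    if 2**n_sub <= n_perm:
        signs = np.array(list(product([1.0, -1.0], repeat=n_sub)))
        return signs, True
    return rng.choice([1.0, -1.0], size=(n_perm, n_sub)), False


def permutation_p(data_a, data_b=None, scores=None, kind: str = "paired_t",
                  adj: sparse.csr_matrix | None = None, n_perm: int = 1000,
                  cluster_alpha: float = 0.05, seed: int = 0) -> ClusterResult:
    """Cluster-based permutation test; see module docstring for the recipe.

    ``adj`` is the combined cell adjacency from :func:`combined_adjacency`
    (or any sparse symmetric relation over the flattened map).
    """
    a = np.asarray(data_a, float)
    rng = substream(seed, "cluster-permutation")
    obs, df, _ = stat_map(data_a, data_b, scores, kind)
    threshold = _threshold(kind, df, cluster_alpha)
    # correlations cluster on the t-equivalent scale
    cluster_map = _r_to_t(obs, df) if kind == "pearson_r" else obs
    if adj is None:
        raise ValueError("adjacency is required")

    exhaustive = False
    log: np.ndarray | None = None
    if kind in ("paired_t", "one_sample_t"):
        d = a - np.asarray(data_b, float) if kind == "paired_t" else a
        dflat = d.reshape(d.shape[0], -1)
        n = d.shape[0]
        signs, exhaustive = _perm_signs(n, n_perm, rng)
        if exhaustive:
            warnings.warn(f"only {len(signs)} distinct sign flips; enumerating",
                          stacklevel=2)
        log = signs
        # sign flips leave per-cell sums of squares unchanged
        ssq = (dflat**2).sum(axis=0)
        null = np.empty(len(signs))
        for j, s in enumerate(signs):
            m = (s @ dflat) / n
            var = (ssq - n * m**2) / (n - 1)
            t = np.zeros_like(m)
            np.divide(m, np.sqrt(var / n), out=t, where=var > 0)
            null[j] = _max_abs_mass(t, threshold, adj)
    elif kind == "independent_t":
        b = np.asarray(data_b, float)
        pooled = np.concatenate([a, b], axis=0).reshape(len(a) + len(b), -1)
        n1, ntot = len(a), len(a) + len(b)
        from math import comb
        if comb(ntot, n1) <= n_perm:
            partitions = [np.array(c) for c in combinations(range(ntot), n1)]
            exhaustive = True
            warnings.warn(f"only {len(partitions)} distinct partitions; "
                          "enumerating", stacklevel=2)
        else:
            partitions = [rng.permutation(ntot)[:n1] for _ in range(n_perm)]
        log = np.array(partitions)
        null = np.empty(len(partitions))
        for j, ia in enumerate(partitions):
            mask = np.zeros(ntot, bool)
            mask[ia] = True
            t, _, _ = stat_map(pooled[mask], pooled[~mask], kind="independent_t")
            null[j] = _max_abs_mass(t, threshold, adj)
    elif kind == "pearson_r":
        sc = np.asarray(scores, float)
        n = len(sc)
        from math import factorial
        if factorial(n) <= n_perm:
            from itertools import permutations as iperm
            orders = [np.array(o) for o in iperm(range(n))]
            exhaustive = True
            warnings.warn(f"only {len(orders)} distinct score orders; "
                          "enumerating", stacklevel=2)
        else:
            orders = [rng.permutation(n) for _ in range(n_perm)]
        log = np.array(orders)
        flat_a = a.reshape(n, -1)
        null = np.empty(len(orders))
        for j, o in enumerate(orders):
            r, _, _ = stat_map(flat_a, scores=sc[o], kind="pearson_r")
            null[j] = _max_abs_mass(_r_to_t(r, df), threshold, adj)
    else:
        raise ValueError(f"unknown kind {kind!r}")

    clusters = form_clusters(cluster_map, threshold, adj)
    out = []
    for c in clusters:
        # relative slack: the vectorized null path and stat_map may differ at ~1e-11
        slack = 1e-9 * max(1.0, abs(c.mass))
        if exhaustive:
            p = float((null >= abs(c.mass) - slack).mean())
        else:
            p = float((1 + (null >= abs(c.mass) - slack).sum()) / (len(null) + 1))
        out.append(Cluster(c.members, c.mass, c.sign, p))
    res = ClusterResult(out, obs, threshold, df, null, len(null),
                        cluster_alpha, exhaustive, seed, log)
    return res
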