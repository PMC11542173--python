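"""Cluster-based permutation tests over electrode space.

Nonparametric familywise-error-controlling inference for scalar per-electrode
measures: a t map is thresholded at the two-tailed critical value for the
cluster-forming alpha, supra-threshold electrodes are grouped into connected,
same-signed clusters on a spatial adjacency graph, and each cluster's mass
(sum of member t values) is referred to a max-|mass| null distribution built
by permuting group labels (independent designs) or sign-flipping whole
subject difference vectors (paired designs).

Adjacency is a Delaunay triangulation of 2D-projected electrode positions
with implausibly long edges pruned. An exhaustive enumerator over the full
permutation space doubles as an exact-oracle for the Monte-Carlo procedure on
small designs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay, QhullError


class ClusterStatsError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyGraph:
    channel_labels: list[str]
    edges: set[frozenset]  # unordered label pairs
    coords: np.ndarray  # (n, 2)
    neighbors: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        index = {lab: i for i, lab in enumerate(self.channel_labels)}
        self.neighbors = {i: [] for i in range(len(self.channel_labels))}
        for e in self.edges:
            a, b = (index[x] for x in e)
            self.neighbors[a].append(b)
            self.neighbors[b].append(a)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


def _is_connected(n: int, neighbors: dict[int, list[int]]) -> bool:
    seen = {0}
    stack = [0]
    while stack:
        for j in neighbors[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n


def build_adjacency(channel_labels, coords2d, prune_factor: float = 1.5) -> AdjacencyGraph:
    """Delaunay adjacency over 2D electrode positions.

    Edges longer than ``prune_factor`` × the median Delaunay edge length are
    removed (they join electrodes across the head rather than neighbors).
    Channels left with fewer than two neighbors — typically sub-temporal rim
    electrodes whose ring edges are long — get their shortest pruned edges
    restored until they have two. Collinear layouts fall back to a
    nearest-neighbor chain. Raises if the resulting graph is disconnected.
    """
    labels = list(channel_labels)
    coords = np.asarray(coords2d, dtype=float)
    if coords.shape != (len(labels), 2):
        raise ValueError("coords2d must be (n_channels, 2)")
    if len(labels) < 3:
        raise ClusterStatsError("need at least 3 channels for an adjacency graph")

    def chain_edges() -> set[frozenset]:
        centered = coords - coords.mean(axis=0)
        axis = np.linalg.svd(centered, full_matrices=False)[2][0]
        order = np.argsort(centered @ axis)
        return {frozenset((labels[order[k]], labels[order[k + 1]]))
                for k in range(len(order) - 1)}

    try:
        tri = Delaunay(coords)
        pairs = set()
        for simplex in tri.simplices:
            for a, b in itertools.combinations(simplex, 2):
                pairs.add((min(a, b), max(a, b)))
        lengths = {p: np.linalg.norm(coords[p[0]] - coords[p[1]]) for p in pairs}
        median = np.median(list(lengths.values()))
        kept = {p for p, d in lengths.items() if d <= prune_factor * median}
        degree = {i: 0 for i in range(len(labels))}
        for a, b in kept:
            degree[a] += 1
            degree[b] += 1
        for i in range(len(labels)):
            if degree[i] >= 2:
                continue
            candidates = sorted((d, p) for p, d in lengths.items()
                                if i in p and p not in kept)
            for _, p in candidates:
                kept.add(p)
                degree[p[0]] += 1
                degree[p[1]] += 1
                if degree[i] >= 2:
                    break
        edges = {frozenset((labels[a], labels[b])) for a, b in kept}
    except QhullError:
        edges = chain_edges()

    graph = AdjacencyGraph(channel_labels=labels, edges=edges, coords=coords)
    if not _is_connected(graph.n_channels, graph.neighbors):
        raise ClusterStatsError(
            "adjacency graph disconnected after pruning; raise prune_factor")
    return graph


def expand_adjacency_over_bins(adjacency: AdjacencyGraph,
                               n_bins: int) -> AdjacencyGraph:
    """Channel × frequency-bin adjacency for spatio-spectral clustering.

    Nodes are "label@b"; two nodes are adjacent when they are spatial
    neighbors in the same bin, or the same channel in consecutive bins.
    Data matrices for the cluster tests are then (subjects, channels·bins),
    bin-major within channel. Optional mode; the default analyses cluster
    scalar per-electrode maps.
    """
    if n_bins < 1:
        raise ClusterStatsError("need at least 1 frequency bin")
    labels = [f"{lab}@{b}" for b in range(n_bins)
              for lab in adjacency.channel_labels]
    edges: set[frozenset] = set()
    for b in range(n_bins):
        for e in adjacency.edges:
            x, y = tuple(e)
            edges.add(frozenset((f"{x}@{b}", f"{y}@{b}")))
        if b + 1 < n_bins:
            for lab in adjacency.channel_labels:
                edges.add(frozenset((f"{lab}@{b}", f"{lab}@{b + 1}")))
    coords = np.vstack([
        adjacency.coords + np.array([0.0, 0.0])  # coords reused per bin
        for _ in range(n_bins)])
    return AdjacencyGraph(channel_labels=labels, edges=edges, coords=coords)


# ---------------------------------------------------------------------------
# t maps and effect sizes
# ---------------------------------------------------------------------------

def independent_t_map(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    """Pooled-variance two-sample t per channel; a, b are (subjects, channels)."""
    a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ClusterStatsError("need n >= 2 per group")
    df = n1 + n2 - 2
    var_p = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(var_p * (1.0 / n1 + 1.0 / n2))
    diff = a.mean(axis=0) - b.mean(axis=0)
    return _safe_t(diff, se), df


def paired_t_map(diffs: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t on per-subject differences; diffs is (subjects, channels)."""
    d = np.atleast_2d(np.asarray(diffs, float))
    n = d.shape[0]
    if n < 2:
        raise ClusterStatsError("need n >= 2 subjects")
    se = d.std(axis=0, ddof=1) / np.sqrt(n)
    return _safe_t(d.mean(axis=0), se), n - 1


def _safe_t(num: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / se
    zero_se = se == 0
    if np.any(zero_se):
        t = np.where(zero_se & (num == 0), 0.0, t)
        t = np.where(zero_se & (num != 0), np.sign(num) * np.inf, t)
        if np.any(zero_se & (num != 0)):
            warnings.warn("zero variance at some channels; t set to ±inf")
    return t


def electrode_t_map(kind: str, a: np.ndarray,
                    b: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    if kind == "independent":
        if b is None:
            raise ClusterStatsError("independent design needs two groups")
        return independent_t_map(a, b)
    if kind == "paired":
        return paired_t_map(a)
    raise ClusterStatsError(f"unknown design kind {kind!r}")


def cohens_d(kind: str, a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Per-channel Cohen's d: pooled-SD standardized mean difference
    (independent) or difference-score standardized mean (paired).

    Channels with zero SD yield NaN with a warning.
    """
    if kind == "independent":
        a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
        n1, n2 = a.shape[0], b.shape[0]
        var_p = ((n1 - 1) * a.var(axis=0, ddof=1)
                 + (n2 - 1) * b.var(axis=0, ddof=1)) / (n1 + n2 - 2)
        num = a.mean(axis=0) - b.mean(axis=0)
        denom = np.sqrt(var_p)
    elif kind == "paired":
        d = np.atleast_2d(np.asarray(a, float))
        num = d.mean(axis=0)
        denom = d.std(axis=0, ddof=1)
    else:
        raise ClusterStatsError(f"unknown design kind {kind!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / denom
    if np.any(denom == 0):
        warnings.warn("zero SD at some channels; Cohen's d undefined there")
        out = np.where(denom == 0, np.nan, out)
    return out


# ---------------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------------

def forming_threshold(df: int, cluster_alpha: float = 0.05) -> float:
    """Two-tailed t critical value used as the cluster-forming threshold."""
    return float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df))


def _components(t_map: np.ndarray, neighbors: dict[int, list[int]],
                threshold: float) -> list[tuple[list[int], float]]:
    supra = np.abs(t_map) > threshold
    sign = np.sign(t_map)
    visited = np.zeros(t_map.size, dtype=bool)
    out = []
    for start in np.flatnonzero(supra):
        if visited[start]:
            continue
        comp = [start]
        visited[start] = True
        stack = [start]
        s = sign[start]
        while stack:
            for j in neighbors[stack.pop()]:
                if supra[j] and not visited[j] and sign[j] == s:
                    visited[j] = True
                    comp.append(j)
                    stack.append(j)
        out.append((sorted(comp), float(np.sum(t_map[comp]))))
    return out


def form_clusters(t_map: np.ndarray, adjacency: AdjacencyGraph, df: int,
                  cluster_alpha: float = 0.05) -> list[tuple[list[int], float]]:
    """Partition supra-threshold channels into connected same-signed clusters.

    Returns (member channel indices, cluster mass) pairs; mass is the sum of
    member t values.
    """
    thr = forming_threshold(df, cluster_alpha)
    return _components(np.asarray(t_map, float), adjacency.neighbors, thr)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    channels: list[str]
    sign: int
    mass: float
    p_value: float
    t_max: float
    d_mean: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _null_max_masses(t_maps: np.ndarray, neighbors: dict[int, list[int]],
                     threshold: float) -> np.ndarray:
    out = np.zeros(t_maps.shape[0])
    for i, tm in enumerate(t_maps):
        comps = _components(tm, neighbors, threshold)
        if comps:
            out[i] = max(abs(m) for _, m in comps)
    return out


def _paired_perm_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for sign-flip permutations; signs is (n_perm, n_subjects)."""
    n = diffs.shape[0]
    mean = signs @ diffs / n
    sumsq = np.sum(diffs ** 2, axis=0)  # invariant under sign flips
    var = (sumsq - n * mean ** 2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)


def _independent_perm_t(z: np.ndarray, assign: np.ndarray, n1: int) -> np.ndarray:
    """t maps for label permutations; assign is (n_perm, N) boolean (group A)."""
    N = z.shape[0]
    n2 = N - n1
    df = N - 2
    tot = z.sum(axis=0)
    tot_sq = (z ** 2).sum(axis=0)
    a_sum = assign.astype(float) @ z
    a_sq = assign.astype(float) @ (z ** 2)
    mean_a = a_sum / n1
    mean_b = (tot - a_sum) / n2
    ss_a = a_sq - n1 * mean_a ** 2
    ss_b = (tot_sq - a_sq) - n2 * mean_b ** 2
    var_p = np.clip(ss_a + ss_b, 0.0, None) / df
    se = np.sqrt(var_p * (1.0 / n1 + 1.0 / n2))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    return np.where(se == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)


def _results_from_observed(observed, t_map, d, labels, null_max, denom, plus_one):
    results = []
    for members, mass in observed:
        # Tolerance so the identity relabeling, recomputed through the
        # vectorized permutation path, ties the observed mass despite float
        # roundoff.
        tol = 1e-9 * max(1.0, abs(mass))
        exceed = int(np.sum(null_max >= abs(mass) - tol))
        p = (exceed + (1 if plus_one else 0)) / denom
        results.append(ClusterResult(
            channels=[labels[i] for i in members],
            sign=int(np.sign(mass)),
            mass=mass,
            p_value=float(p),
            t_max=float(np.max(np.abs(t_map[members]))),
            d_mean=float(np.nanmean(d[members])),
        ))
    results.sort(key=lambda r: r.p_value)
    return results


def permutation_cluster_test(kind: str, a: np.ndarray, b: np.ndarray | None,
                             adjacency: AdjacencyGraph,
                             n_permutations: int = 10000,
                             cluster_alpha: float = 0.05,
                             rng: np.random.Generator | int | None = None,
                             ) -> list[ClusterResult]:
    """Monte-Carlo cluster test.

    ``kind`` is "independent" (a, b are group data, subjects × channels) or
    "paired" (a holds per-subject difference vectors). The null permutes
    whole subjects — group labels or difference-vector signs — never channels
    within a subject. Cluster p values use the (1 + exceedances) /
    (n_permutations + 1) convention, so p is never zero.
    """
    if n_permutations < 1:
        raise ClusterStatsError("need at least 1 permutation")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t_map, df = electrode_t_map(kind, a, b)
    thr = forming_threshold(df, cluster_alpha)
    observed = _components(t_map, adjacency.neighbors, thr)
    d = cohens_d(kind, a, b)
    labels = adjacency.channel_labels

    if kind == "paired":
        diffs = np.atleast_2d(np.asarray(a, float))
        n = diffs.shape[0]
        if n < 2:
            raise ClusterStatsError("need n >= 2 subjects")
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        perm_t = _paired_perm_t(diffs, signs)
    else:
        if b is None:
            raise ClusterStatsError("independent design needs two groups")
        z = np.vstack([np.atleast_2d(a), np.atleast_2d(b)]).astype(float)
        n1, N = np.atleast_2d(a).shape[0], z.shape[0]
        assign = np.zeros((n_permutations, N), dtype=bool)
        for i in range(n_permutations):
            assign[i, rng.permutation(N)[:n1]] = True
        perm_t = _independent_perm_t(z, assign, n1)

    null_max = _null_max_masses(perm_t, adjacency.neighbors, thr)
    return _results_from_observed(observed, t_map, d, labels, null_max,
                                  denom=n_permutations + 1, plus_one=True)


def exhaustive_cluster_test(kind: str, a: np.ndarray, b: np.ndarray | None,
                            adjacency: AdjacencyGraph,
                            cluster_alpha: float = 0.05,
                            max_enumeration: int = 2 ** 20,
                            ) -> list[ClusterResult]:
    """Exact test enumerating the full permutation space.

    Paired: all 2ⁿ sign patterns (identity included); independent: all
    C(N, n1) group assignments. p = (# null max-mass ≥ |observed mass|) /
    (# enumerated), which includes the identity relabeling, so p ≥ 1/#enum.
    """
    t_map, df = electrode_t_map(kind, a, b)
    thr = forming_threshold(df, cluster_alpha)
    observed = _components(t_map, adjacency.neighbors, thr)
    d = cohens_d(kind, a, b)
    labels = adjacency.channel_labels

    if kind == "paired":
        diffs = np.atleast_2d(np.asarray(a, float))
        n = diffs.shape[0]
        total = 2 ** n
        if total > max_enumeration:
            raise ClusterStatsError(
                f"2^{n} sign patterns exceed the enumeration limit; "
                "use permutation_cluster_test")
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
        perm_t = _paired_perm_t(diffs, signs)
    else:
        if b is None:
            raise ClusterStatsError("independent design needs two groups")
        z = np.vstack([np.atleast_2d(a), np.atleast_2d(b)]).astype(float)
        n1, N = np.atleast_2d(a).shape[0], z.shape[0]
        combos = list(itertools.combinations(range(N), n1))
        total = len(combos)
        if total > max_enumeration:
            raise ClusterStatsError(
                "group-assignment space exceeds the enumeration limit; "
                "use permutation_cluster_test")
        assign = np.zeros((total, N), dtype=bool)
        for i, combo in enumerate(combos):
            assign[i, list(combo)] = True
        perm_t = _independent_perm_t(z, assign, n1)

    null_max = _null_max_masses(perm_t, adjacency.neighbors, thr)
    return _results_from_observed(observed, t_map, d, labels, null_max,
                                  denom=total, plus_one=False)
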