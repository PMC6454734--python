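"""Clustering of disease deregulation profiles.

Two procedures: Partition Around Medoids (k-medoids, BUILD + SWAP) with
silhouette-based selection of the number of clusters, applied to continuous
combined-effect (mu_hat) profiles under correlation distance; and
agglomerative hierarchical clustering of discretized up/down/unchanged
gene-status matrices under several discrete metrics, used to ask which
diseases join a reference disease first.

All tie-breaks (equal-cost swaps, equidistant assignments, equal-variance
choices) resolve by lexicographic item id so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import squareform

CONTINUOUS_METRICS = {"correlation"}
DISCRETE_METRICS = {"hamming", "matching", "manhattan"}


def profile_distance_matrix(profiles: pd.DataFrame, metric: str = "correlation") -> pd.DataFrame:
    """Pairwise distances between columns of a profile matrix.

    ``profiles`` is genes x diseases.  Metrics: ``correlation``
    (1 - Pearson r over pairwise-complete genes, for continuous mu_hat
    profiles) or, for discrete {-1, 0, +1} status matrices, ``hamming``
    (mismatch fraction over all genes), ``matching`` (mismatch fraction
    over genes where at least one profile is nonzero) and ``manhattan``
    (sum of absolute status differences).
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 profiles")
    cols = list(profiles.columns)
    if metric == "correlation":
        d = 1.0 - profiles.corr(method="pearson")
    elif metric in DISCRETE_METRICS:
        x = profiles.to_numpy(dtype=float)
        n_items = len(cols)
        d = pd.DataFrame(0.0, index=cols, columns=cols)
        for i in range(n_items):
            for j in range(i + 1, n_items):
                a, b = x[:, i], x[:, j]
                if metric == "hamming":
                    val = float(np.mean(a != b))
                elif metric == "matching":
                    active = (a != 0) | (b != 0)
                    val = float(np.mean(a[active] != b[active])) if active.any() else 0.0
                else:  # manhattan
                    val = float(np.abs(a - b).sum())
                d.iloc[i, j] = d.iloc[j, i] = val
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d.values, 0.0)
    return d


@dataclass
class ClusterResult:
    """A k-medoids partition and its silhouette summary."""

    k: int
    medoids: list[str]
    assignment: dict[str, str]  # item -> medoid id
    total_cost: float
    avg_silhouette: float = float("nan")
    per_item_silhouette: dict[str, float] = field(default_factory=dict)


def _assign(d: pd.DataFrame, medoids: list[str]) -> tuple[dict[str, str], float]:
    """Nearest-medoid assignment; medoid ties break lexicographically."""
    meds = sorted(medoids)
    sub = d.loc[:, meds]
    assignment = {}
    cost = 0.0
    for item in d.index:
        if item in meds:  # a medoid always belongs to its own cluster
            assignment[item] = item
            continue
        row = sub.loc[item]
        best = row.idxmin()  # first (lexicographically smallest) minimizer
        assignment[item] = best
        cost += float(row[best])
    return assignment, cost


def _swap_descent(
    d: pd.DataFrame, items: list[str], medoids: list[str], max_iter: int
) -> tuple[list[str], float]:
    """Best-improvement SWAP passes until a local optimum (or max_iter)."""
    medoids = sorted(medoids)
    _, cost = _assign(d, medoids)
    for _ in range(max_iter):
        best_swap, best_cost = None, cost
        for out in list(medoids):
            for cand in items:
                if cand in medoids:
                    continue
                trial = [m for m in medoids if m != out] + [cand]
                _, c = _assign(d, trial)
                if c < best_cost - 1e-12:
                    best_swap, best_cost = (out, cand), c
        if best_swap is None:
            break
        out, cand = best_swap
        medoids = sorted([m for m in medoids if m != out] + [cand])
        assert best_cost < cost  # accepted swaps strictly decrease cost
        cost = best_cost
    return medoids, cost


def pam(
    distances: pd.DataFrame, k: int, max_iter: int = 100, n_starts: int = 8
) -> ClusterResult:
    """Partition Around Medoids: BUILD initialization plus SWAP descent.

    The SWAP neighborhood (one medoid exchanged at a time) can stall in a
    local optimum on unlucky instances, so the descent is additionally
    restarted from ``n_starts`` deterministic pseudo-random medoid sets and
    from the lexicographically first k items; the cheapest local optimum
    wins (ties by lexicographic medoid set).  Every accepted swap strictly
    decreases the total within-cluster distance to medoids.
    """
    items = sorted(distances.index)
    n = len(items)
    if not 2 <= k < n:
        raise ValueError("need 2 <= k < n items")
    d = distances.loc[items, items]

    # BUILD: start from the 1-medoid minimizer, then greedily add the
    # medoid giving the largest cost reduction (ties lexicographic).
    costs1 = {m: float(d.loc[:, m].sum()) for m in items}
    build = [min(items, key=lambda m: (costs1[m], m))]
    while len(build) < k:
        best_m, best_cost = None, None
        for cand in items:
            if cand in build:
                continue
            _, c = _assign(d, build + [cand])
            if best_cost is None or c < best_cost - 1e-12:
                best_m, best_cost = cand, c
        build.append(best_m)

    starts = [build, items[:k]]
    rng = np.random.default_rng(0)  # restarts are part of the algorithm, fixed
    for _ in range(n_starts):
        starts.append(list(rng.choice(items, size=k, replace=False)))

    best_meds, best_cost = None, None
    for s0 in starts:
        meds, cost = _swap_descent(d, items, s0, max_iter)
        key = (cost, tuple(meds))
        if best_cost is None or key < (best_cost, tuple(best_meds)):
            best_meds, best_cost = meds, cost
    assignment, cost = _assign(d, best_meds)
    return ClusterResult(k, sorted(best_meds), assignment, cost)


def silhouette(
    distances: pd.DataFrame, assignment: dict[str, str]
) -> tuple[dict[str, float], float]:
    """Silhouette widths s(i) = (b - a) / max(a, b); singletons get 0."""
    clusters: dict[str, list[str]] = {}
    for item, c in assignment.items():
        clusters.setdefault(c, []).append(item)
    if len(clusters) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    per_item: dict[str, float] = {}
    for item, own in assignment.items():
        mine = [x for x in clusters[own] if x != item]
        if not mine:
            per_item[item] = 0.0
            continue
        a = float(distances.loc[item, mine].mean())
        b = min(
            float(distances.loc[item, members].mean())
            for c, members in clusters.items()
            if c != own
        )
        per_item[item] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return per_item, float(np.mean(list(per_item.values())))


def select_k(
    distances: pd.DataFrame, k_range: range | list[int], max_iter: int = 100
) -> tuple[int, dict[int, ClusterResult]]:
    """Run PAM over a range of k and pick the best average silhouette.

    Returns the winning k (ties go to the smallest k) together with the
    full per-k table, so weak structure (uniformly low silhouettes) stays
    visible to the caller.
    """
    ks = sorted(set(k_range))
    n = distances.shape[0]
    if not ks or ks[0] < 2 or ks[-1] >= n:
        raise ValueError("k range must lie within [2, n-1]")
    results: dict[int, ClusterResult] = {}
    for k in ks:
        res = pam(distances, k, max_iter=max_iter)
        per_item, avg = silhouette(distances, res.assignment)
        res.per_item_silhouette = per_item
        res.avg_silhouette = avg
        results[k] = res
    best = max(ks, key=lambda k: (results[k].avg_silhouette, -k))
    return best, results


@dataclass
class HClustResult:
    """Agglomerative merge tree over profile columns."""

    labels: list[str]
    linkage: np.ndarray
    metric: str
    first_pair: tuple[str, str]  # the two columns merged first

    def newick(self) -> str:
        tree = to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return f"({walk(tree.left)},{walk(tree.right)});"

    def partners_of(self, column: str) -> list[str]:
        """Columns in the smallest non-trivial cluster containing ``column``.

        The readout used to ask which diseases join a reference disease
        first in the merge tree.
        """
        n = len(self.labels)
        members = {i: [i] for i in range(n)}
        idx = self.labels.index(column)
        current = {idx}
        for step, (a, b, _dist, _size) in enumerate(self.linkage):
            merged = members[int(a)] + members[int(b)]
            members[n + step] = merged
            if idx in merged and len(merged) > 1:
                return sorted(self.labels[i] for i in merged if i != idx)
        return []


def hclust_discrete(
    matrix: pd.DataFrame, metric: str = "hamming", linkage: str = "average"
) -> HClustResult:
    """Hierarchical clustering of a discrete gene-status matrix's columns."""
    bad = set(np.unique(matrix.to_numpy())) - {-1, 0, 1}
    if bad:
        raise ValueError(f"discrete matrix may only contain -1/0/+1, got {sorted(bad)}")
    d = profile_distance_matrix(matrix, metric)
    z = scipy_linkage(squareform(d.to_numpy(), checks=False), method=linkage)
    a, b = int(z[0, 0]), int(z[0, 1])
    labels = list(matrix.columns)
    return HClustResult(labels, z, metric, (labels[a], labels[b]))


def co_clustering_report(
    matrix: pd.DataFrame,
    reference: str,
    metrics: list[str] | None = None,
    linkage: str = "average",
) -> pd.DataFrame:
    """Which columns join ``reference`` first, under each discrete metric."""
    metrics = metrics or sorted(DISCRETE_METRICS)
    rows = []
    for m in metrics:
        res = hclust_discrete(matrix, metric=m, linkage=linkage)
        rows.append(
            {"metric": m, "partners": "|".join(res.partners_of(reference))}
        )
    return pd.DataFrame(rows)
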