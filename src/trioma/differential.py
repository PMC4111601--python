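"""Threshold differential calls and average-linkage hierarchical clustering.

A probe is differentially expressed (DE) when |SLR| exceeds the cut at one or
more non-baseline timepoints (strict inequality).  Clustering agglomerates
SLR profiles with average linkage on Euclidean distance; the agglomeration is
implemented here so ties break deterministically (among equal-distance
cluster pairs, merge the pair whose combined leaf set has the
lexicographically smallest (min leaf, max leaf) index pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data import SLRMatrix

__all__ = ["DifferentialCall", "call_differential", "Dendrogram",
           "hierarchical_cluster", "cut_tree"]


@dataclass(frozen=True)
class DifferentialCall:
    """Per-probe DE verdict with per-timepoint direction (up/down/flat)."""

    probe_id: str
    slr: tuple[float, ...]
    is_de: bool
    direction: tuple[str, ...]  # one entry per timepoint


def call_differential(slr: SLRMatrix, cut: float) -> list[DifferentialCall]:
    """Call DE for every probe: |SLR| > ``cut`` at >=1 non-baseline timepoint."""
    if cut <= 0:
        raise ValueError("cut must be > 0")
    baseline = slr.design.baseline
    nonbase = [s for s in slr.design.sample_ids if s != baseline]
    calls = []
    for probe_id, row in slr.data.iterrows():
        vals = row.to_numpy(dtype=float)
        de = bool((np.abs(row[nonbase].to_numpy(dtype=float)) > cut).any())
        direction = tuple(
            "up" if v > cut else ("down" if v < -cut else "flat") for v in vals
        )
        calls.append(DifferentialCall(str(probe_id), tuple(vals), de, direction))
    return calls


@dataclass
class Dendrogram:
    """Full agglomeration tree.

    ``merges[k] = (a, b, height, size)`` joins clusters ``a`` and ``b``
    (leaves are 0..n-1, internal nodes n, n+1, ... in merge order) at the
    average-linkage distance ``height`` into a cluster of ``size`` leaves.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible (n-1) x 4 linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def hierarchical_cluster(slr: SLRMatrix | np.ndarray, on: str = "probes",
                         labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA-style) agglomeration on Euclidean distances.

    ``on`` selects whether rows (probes) or columns (samples) of the SLR
    matrix are the clustered items.  A bare array clusters its rows.
    """
    if isinstance(slr, SLRMatrix):
        if on == "probes":
            X = slr.data.to_numpy(dtype=float)
            labels = slr.probe_ids
        elif on == "samples":
            X = slr.data.to_numpy(dtype=float).T
            labels = list(slr.data.columns)
        else:
            raise ValueError("on must be 'probes' or 'samples'")
    else:
        X = np.asarray(slr, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >=2 items to cluster")
    if not np.isfinite(X).all():
        raise ValueError("missing/non-finite values cannot be clustered")

    D = squareform(pdist(X, metric="euclidean"))
    active: dict[int, dict] = {
        i: {"size": 1, "min_leaf": i, "max_leaf": i} for i in range(n)
    }
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        # minimal distance, ties broken on the combined leaf-index span
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(active[kv[0][0]]["min_leaf"], active[kv[0][1]]["min_leaf"]),
                max(active[kv[0][0]]["max_leaf"], active[kv[0][1]]["max_leaf"]),
            ),
        )
        (a, b), h = best
        sa, sb = active[a]["size"], active[b]["size"]
        new = {
            "size": sa + sb,
            "min_leaf": min(active[a]["min_leaf"], active[b]["min_leaf"]),
            "max_leaf": max(active[a]["max_leaf"], active[b]["max_leaf"]),
        }
        merges.append((a, b, h, new["size"]))
        del active[a], active[b]
        # Lance-Williams update for average linkage
        new_dists = {}
        for k in active:
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            new_dists[(k, next_id)] = (sa * da + sb * db) / (sa + sb)
        dist = {
            pair: d for pair, d in dist.items() if a not in pair and b not in pair
        }
        dist.update(new_dists)
        active[next_id] = new
        next_id += 1
    return Dendrogram(labels=list(labels), merges=merges)


def cut_tree(tree: Dendrogram, n_clusters: int) -> dict[str, int]:
    """Cluster labels from cutting at the smallest height giving ``n_clusters``.

    With tied merge heights some cluster counts are unreachable; those raise
    a ValueError naming the achievable counts.
    """
    n = tree.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    heights = tree.heights
    k = n - n_clusters  # merges applied below the cut
    reachable = (
        k == 0 or k == n - 1 or heights[k] > heights[k - 1]
    )
    if not reachable:
        counts = sorted(
            {n} | {n - kk for kk in range(1, n)
                   if kk == n - 1 or heights[kk] > heights[kk - 1]}
        )
        raise ValueError(
            f"{n_clusters} clusters unreachable under tied heights; "
            f"achievable counts: {counts}"
        )
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx in range(k):
        a, b, _, _ = tree.merges[idx]
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, int] = {}
    out: dict[str, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        out[tree.labels[leaf]] = roots[r]
    return out
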