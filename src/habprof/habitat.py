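"""Habitat-level community structure.

Within-kingdom scoping and relative-abundance filtering, mean
between-habitat Bray-Curtis distances, Ward agglomerative clustering of
habitats (ward.D / ward.D2 Lance-Williams variants with a deterministic
label tie-break), dendrogram entanglement, pooling + rarefaction, and the
NODF nestedness metric (nestedness based on overlap and decreasing fill,
0 = random, 100 = perfectly nested).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import CountMatrix

__all__ = [
    "filter_and_scope",
    "sample_bray_curtis",
    "HabitatDistanceMatrix",
    "habitat_mean_distance",
    "Dendrogram",
    "ward_cluster",
    "entanglement",
    "pool_and_rarefy",
    "NodfResult",
    "nodf",
    "top_features",
    "occupancy",
]


def filter_and_scope(
    cm: CountMatrix, kingdom: str, min_mean_fraction: float = 1e-5
) -> pd.DataFrame:
    """Within-kingdom relative abundances, rare taxa dropped.

    Counts are restricted to one kingdom and renormalized per sample so
    each row sums to 1 over that kingdom; taxa whose mean fraction across
    samples is strictly below ``min_mean_fraction`` are then dropped (a
    taxon at exactly the threshold is retained). Row sums may fall
    marginally below 1 after dropping.
    """
    feats = cm.kingdom_features(kingdom)
    if not len(feats):
        raise ValueError(f"no features annotated as kingdom {kingdom!r}")
    sub = cm.counts[feats].astype(float)
    sums = sub.sum(axis=1)
    rel = sub.div(sums.replace(0.0, np.nan), axis=0).fillna(0.0)
    keep = rel.mean(axis=0) >= min_mean_fraction
    return rel.loc[:, keep]


def sample_bray_curtis(rel_abund: pd.DataFrame, sqrt: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances among samples.

    By default the relative abundances are square-root transformed first
    (Hellinger-style scaling), matching the habitat-clustering pipeline.
    """
    x = np.sqrt(rel_abund.values) if sqrt else rel_abund.values
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=rel_abund.index, columns=rel_abund.index)


@dataclass
class HabitatDistanceMatrix:
    """Symmetric matrix of mean between-habitat distances."""

    distances: pd.DataFrame  # habitats x habitats, zero diagonal
    n_pairs: pd.DataFrame  # number of sample pairs averaged per cell

    @property
    def habitats(self) -> list[str]:
        return list(self.distances.index)


def habitat_mean_distance(
    sample_distances: pd.DataFrame, habitat_of: pd.Series
) -> HabitatDistanceMatrix:
    """Mean cross-pair sample distance for every habitat pair.

    Cell (A, B), A != B, averages the distances of all cross pairs
    (a in A, b in B); the diagonal is 0.
    """
    habitat_of = habitat_of.loc[sample_distances.index]
    habitats = sorted(habitat_of.unique())
    d = pd.DataFrame(0.0, index=habitats, columns=habitats)
    n = pd.DataFrame(0, index=habitats, columns=habitats)
    groups = {h: habitat_of.index[habitat_of == h] for h in habitats}
    for i, a in enumerate(habitats):
        for b in habitats[i + 1:]:
            block = sample_distances.loc[groups[a], groups[b]].values
            d.loc[a, b] = d.loc[b, a] = float(block.mean())
            n.loc[a, b] = n.loc[b, a] = block.size
    return HabitatDistanceMatrix(d, n)


@dataclass
class Dendrogram:
    """Binary merge tree over labelled leaves.

    ``merges`` lists ``n - 1`` tuples ``(left, right, height)`` where node
    ids ``0 .. n-1`` are leaves (indexing ``labels``) and merge ``k``
    creates node ``n + k``.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]
    method: str = ""

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a dendrogram over n leaves needs n - 1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def _children(self) -> dict[int, tuple[int, int]]:
        n = len(self.labels)
        return {n + k: (a, b) for k, (a, b, _) in enumerate(self.merges)}

    def _leaves_under(self, node: int, children: dict) -> list[int]:
        if node < len(self.labels):
            return [node]
        a, b = children[node]
        return self._leaves_under(a, children) + self._leaves_under(b, children)

    def leaf_order(self) -> list[str]:
        """Canonical left-to-right leaf order.

        At every internal node the subtree with fewer leaves is placed
        first; ties are broken by the smaller minimum leaf label. This
        deterministic layout stands in for the optimized leaf rotation a
        plotting package would apply.
        """
        children = self._children()
        memo: dict[int, tuple[int, str, list[int]]] = {}

        def walk(node: int) -> tuple[int, str, list[int]]:
            if node in memo:
                return memo[node]
            if node < len(self.labels):
                out = (1, self.labels[node], [node])
            else:
                a, b = children[node]
                ra, rb = walk(a), walk(b)
                first, second = sorted([ra, rb], key=lambda r: (r[0], r[1]))
                out = (ra[0] + rb[0], min(ra[1], rb[1]), first[2] + second[2])
            memo[node] = out
            return out

        root = len(self.labels) + len(self.merges) - 1 if self.merges else 0
        return [self.labels[i] for i in walk(root)[2]]

    def cut(self, k: int) -> pd.Series:
        """Cluster membership after cutting the tree into ``k`` clusters."""
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        parent = list(range(n))
        nodes: dict[int, list[int]] = {i: [i] for i in range(n)}
        for step, (a, b, _) in enumerate(self.merges[: n - k]):
            nodes[n + step] = nodes.pop(a) + nodes.pop(b)
        labels = {}
        for cluster_id, members in enumerate(sorted(nodes.values(), key=min)):
            for leaf in members:
                labels[self.labels[leaf]] = cluster_id
        return pd.Series(labels).loc[self.labels]

    def to_newick(self) -> str:
        children = self._children()

        def walk(node: int, parent_height: float) -> str:
            if node < len(self.labels):
                return f"{self.labels[node]}:{parent_height:.6g}"
            a, b = children[node]
            h = self.merges[node - len(self.labels)][2]
            inner = ",".join([walk(a, h), walk(b, h)])
            return f"({inner}):{max(parent_height - h, 0.0):.6g}"

        if not self.merges:
            return f"({self.labels[0]});" if self.labels else "();"
        root = len(self.labels) + len(self.merges) - 1
        a, b = children[root]
        h = self.merges[-1][2]
        return f"({walk(a, h)},{walk(b, h)});"


def ward_cluster(
    dist: pd.DataFrame | HabitatDistanceMatrix, method: str = "ward_d"
) -> Dendrogram:
    """Ward agglomerative clustering of a precomputed distance matrix.

    Lance-Williams Ward update applied to the raw distances
    (``ward_d``, hclust's ward.D) or to squared distances with heights
    square-rooted back (``ward_d2``, hclust's ward.D2). Ties in the
    minimum inter-cluster distance are broken by merging the pair whose
    (smallest-leaf-label, smallest-leaf-label) pair sorts first, making
    the tree deterministic.
    """
    if isinstance(dist, HabitatDistanceMatrix):
        dist = dist.distances
    if method not in ("ward_d", "ward_d2"):
        raise ValueError("method must be 'ward_d' or 'ward_d2'")
    labels = list(dist.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    d = dist.values.astype(float)
    if not np.allclose(d, d.T) or (np.diag(d) != 0).any():
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    work = d**2 if method == "ward_d2" else d.copy()

    active: dict[int, tuple[int, str]] = {
        i: (1, labels[i]) for i in range(n)
    }  # node -> (size, smallest leaf label)
    dists: dict[frozenset, float] = {
        frozenset((i, j)): work[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best_key, best_val, best_tag = None, math.inf, None
        for key, val in dists.items():
            i, j = sorted(key)
            tag = tuple(sorted((active[i][1], active[j][1])))
            if val < best_val - 1e-12 or (
                abs(val - best_val) <= 1e-12 and (best_tag is None or tag < best_tag)
            ):
                best_key, best_val, best_tag = key, val, tag
        i, j = sorted(best_key)  # type: ignore[arg-type]
        new = n + step
        si, sj = active[i][0], active[j][0]
        height = math.sqrt(max(best_val, 0.0)) if method == "ward_d2" else best_val
        merges.append((i, j, height))
        for k in list(active):
            if k in (i, j):
                continue
            sk = active[k][0]
            dik = dists.pop(frozenset((i, k)))
            djk = dists.pop(frozenset((j, k)))
            dij = best_val
            updated = (
                (si + sk) * dik + (sj + sk) * djk - sk * dij
            ) / (si + sj + sk)
            dists[frozenset((new, k))] = updated
        del dists[best_key]  # type: ignore[arg-type]
        active[new] = (si + sj, min(active[i][1], active[j][1]))
        del active[i], active[j]
    # enforce monotone heights (ward can in principle produce tiny inversions)
    for idx in range(1, len(merges)):
        a, b, h = merges[idx]
        if h < merges[idx - 1][2]:
            merges[idx] = (a, b, merges[idx - 1][2])
    return Dendrogram(labels, merges, method=method)


def entanglement(d1: Dendrogram, d2: Dendrogram, exponent: float = 1.5) -> float:
    """Disagreement of two dendrograms' leaf orders, in [0, 1].

    With canonical leaf orders o1 and o2 and ranks aligned by label, the
    statistic is sum |rank1 - rank2|^exponent divided by its maximum (the
    value attained by exactly reversed orders): 0 for identical orders,
    1 for reversed ones.
    """
    if set(d1.labels) != set(d2.labels):
        raise ValueError("dendrograms must share the same leaf set")
    o1, o2 = d1.leaf_order(), d2.leaf_order()
    n = len(o1)
    if n < 2:
        return 0.0
    r1 = {lab: i for i, lab in enumerate(o1)}
    r2 = {lab: i for i, lab in enumerate(o2)}
    num = sum(abs(r1[lab] - r2[lab]) ** exponent for lab in o1)
    den = sum(abs(i - (n - 1 - i)) ** exponent for i in range(n))
    return num / den


def pool_and_rarefy(
    cm: CountMatrix,
    habitat_of: Optional[pd.Series] = None,
    depth: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pool counts per habitat and rarefy each pool to a common depth.

    Rarefaction subsamples without replacement (multivariate
    hypergeometric), so every habitat row sums to exactly ``depth``
    (default: the smallest pooled habitat total).
    """
    habitat_of = cm.habitat_of() if habitat_of is None else habitat_of
    pooled = cm.counts.groupby(habitat_of).sum().astype(np.int64)
    totals = pooled.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0 or (totals < depth).any():
        raise ValueError("depth must be positive and at most each habitat total")
    rng = np.random.default_rng(seed)
    out = pooled.copy()
    for habitat in pooled.index:
        row = pooled.loc[habitat].values
        if row.sum() == depth:
            continue
        out.loc[habitat] = rng.multivariate_hypergeometric(row, depth)
    return out


@dataclass(frozen=True)
class NodfResult:
    """NODF nestedness scores; all on the 0-100 scale."""

    nodf_total: float
    nodf_rows: float
    nodf_cols: float
    n_rows: int
    n_cols: int


def _axis_nodf(m: np.ndarray) -> tuple[float, int]:
    """Sum of paired NODF contributions over all row pairs of ``m``."""
    fills = m.sum(axis=1)
    overlap = m @ m.T
    fi = fills[:, None]
    fj = fills[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where((fi > fj) & (fj > 0), 100.0 * overlap / fj, 0.0)
    n = m.shape[0]
    total = float(contrib[np.triu_indices(n, 1)].sum() + contrib[np.tril_indices(n, -1)].sum())
    return total, n * (n - 1) // 2


def nodf(matrix) -> NodfResult:
    """Nestedness metric based on overlap and decreasing fill.

    For every pair with strictly decreasing fill, the paired contribution
    is 100 x (shared presences) / (fill of the sparser member); equal
    fills contribute 0. ``nodf_total`` is the mean paired contribution
    over all row pairs and all column pairs; 100 for a perfectly nested
    matrix and 0 when no pair is nested.
    """
    m = np.asarray(pd.DataFrame(matrix).values)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("occupancy matrix must be binary")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 matrix")
    m = m.astype(float)
    row_sum, row_pairs = _axis_nodf(m)
    col_sum, col_pairs = _axis_nodf(m.T)
    return NodfResult(
        nodf_total=(row_sum + col_sum) / (row_pairs + col_pairs),
        nodf_rows=row_sum / row_pairs,
        nodf_cols=col_sum / col_pairs,
        n_rows=m.shape[0],
        n_cols=m.shape[1],
    )


def top_features(counts: pd.DataFrame, k: int = 100) -> list[str]:
    """The k most abundant features by total count.

    Deterministic: ties in total abundance are broken by feature name.
    """
    totals = counts.sum(axis=0)
    order = sorted(totals.index, key=lambda f: (-totals[f], f))
    return order[:k]


def occupancy(counts: pd.DataFrame, features: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Binary occurrence matrix (count > 0), optionally on selected features."""
    df = counts if features is None else counts[list(features)]
    return (df > 0).astype(int)
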