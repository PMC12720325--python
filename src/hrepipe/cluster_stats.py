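"""Hierarchical clustering (R-style ward.D and ward.D2 on Euclidean
distances), dendrogram cutting, the between-minus-within cluster
separation statistic, and its Monte-Carlo / exhaustive permutation tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .core_io import ExpressionMatrix

__all__ = [
    "ClusterConfig",
    "Dendrogram",
    "ClusterAssignment",
    "ClusterPermutationResult",
    "hierarchical_cluster",
    "cut_dendrogram",
    "separation_statistic",
    "permutation_test",
    "exhaustive_permutation_test",
    "cluster_mean_profiles",
]


@dataclass(frozen=True)
class ClusterConfig:
    distance: str = "euclidean"
    linkage: str = "ward_d"  # "ward_d" (R ward.D) or "ward_d2" (classical Ward)
    first_cut_height: float = 50.0
    subdivide_k: int = 2
    standardize_rows: bool = False

    def __post_init__(self) -> None:
        if self.distance != "euclidean":
            raise ValueError("only euclidean distance is supported")
        if self.linkage not in ("ward_d", "ward_d2"):
            raise ValueError("linkage must be ward_d or ward_d2")
        if self.first_cut_height <= 0:
            raise ValueError("first_cut_height must be > 0")
        if self.subdivide_k < 2:
            raise ValueError("subdivide_k must be >= 2")


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-format linkage matrix plus item ids."""

    item_ids: list[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def merge_sequence(self) -> list[tuple[frozenset[int], frozenset[int], float]]:
        """Per merge: the two sets of leaf indices joined and the height."""
        n = len(self.item_ids)
        members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        out = []
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            sa, sb = members[int(a)], members[int(b)]
            if min(sb) < min(sa):
                sa, sb = sb, sa
            out.append((sa, sb, float(h)))
            members[n + step] = sa | sb
        return out


@dataclass
class ClusterAssignment:
    item_ids: list[str]
    labels: np.ndarray  # contiguous integers starting at 1
    level: str = "primary"

    def as_mapping(self) -> dict[str, int]:
        return dict(zip(self.item_ids, (int(x) for x in self.labels)))

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ClusterPermutationResult:
    observed_stat: float
    n_permutations: int
    n_at_least_as_extreme: int
    p_value: float
    mode: str  # "monte_carlo" or "exhaustive"
    seed: int | None = None


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values, list(matrix.gene_ids)
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(i) for i in matrix.index]
    arr = np.asarray(matrix, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def hierarchical_cluster(matrix, config: ClusterConfig = ClusterConfig()) -> Dendrogram:
    """Agglomerate rows by Euclidean distance with ward.D or ward.D2 linkage.

    ``ward_d`` applies the Lance-Williams Ward update to UNsquared
    distances (R hclust "ward.D"); ``ward_d2`` is classical Ward on
    squared distances. Implementation detail: scipy's Ward recurrence
    operates on squared input distances, so feeding it sqrt(d) and
    squaring the resulting heights reproduces ward.D on d exactly,
    including merge order.
    """
    values, ids = _as_matrix(matrix)
    if values.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; run drop_na_rows first")
    if config.standardize_rows:
        sd = values.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=1, keepdims=True)) / sd
    d = pdist(values, metric="euclidean")
    if config.linkage == "ward_d2":
        z = linkage(d, method="ward")
    else:
        z = linkage(np.sqrt(d), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    return Dendrogram(item_ids=ids, linkage_matrix=z, method=config.linkage)


def cut_dendrogram(
    dendrogram: Dendrogram,
    height: float | None = None,
    k: int | None = None,
    level: str = "primary",
) -> ClusterAssignment:
    """Cut the dendrogram either at a height or into exactly k clusters.

    Exactly one of ``height`` / ``k`` must be given. Height mode keeps
    merges with height <= the cut (components after removing merges above
    it). Labels are renumbered contiguously from 1 in order of first
    appearance.
    """
    if (height is None) == (k is None):
        raise ValueError("give exactly one of height or k")
    if height is not None:
        raw = fcluster(dendrogram.linkage_matrix, t=height, criterion="distance")
    else:
        raw = fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return ClusterAssignment(list(dendrogram.item_ids), labels, level=level)


def _check_distance_matrix(distance_matrix: np.ndarray) -> np.ndarray:
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have zero diagonal")
    return d


def _stat_from_sums(d: np.ndarray, labels: np.ndarray) -> float:
    """between-mean minus within-mean over unordered pairs."""
    n = d.shape[0]
    total_sum = d.sum() / 2.0
    total_pairs = n * (n - 1) // 2
    within_sum = 0.0
    within_pairs = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        m = idx.size
        if m > 1:
            within_sum += d[np.ix_(idx, idx)].sum() / 2.0
            within_pairs += m * (m - 1) // 2
    between_pairs = total_pairs - within_pairs
    if within_pairs == 0:
        raise ValueError("all clusters are singletons: no within-cluster pairs")
    if between_pairs == 0:
        raise ValueError("need >= 2 clusters")
    between_sum = total_sum - within_sum
    return between_sum / between_pairs - within_sum / within_pairs


def separation_statistic(distance_matrix: np.ndarray, labels: Sequence) -> float:
    """Mean between-cluster distance minus mean within-cluster distance.

    Means are over unordered item pairs; requires >= 2 clusters and at
    least one within-cluster pair.
    """
    d = _check_distance_matrix(distance_matrix)
    labels = np.asarray(labels)
    if labels.shape[0] != d.shape[0]:
        raise ValueError("labels length must match distance matrix")
    if np.unique(labels).size < 2:
        raise ValueError("need >= 2 clusters")
    return _stat_from_sums(d, labels)


def permutation_test(
    distance_matrix: np.ndarray,
    labels: Sequence,
    n_permutations: int = 999,
    seed: int | None = None,
    add_one: bool = False,
) -> ClusterPermutationResult:
    """Monte-Carlo significance of the separation statistic.

    Labels are uniformly reshuffled ``n_permutations`` times preserving
    group sizes; p is the fraction of permuted statistics >= the observed
    one. The literal rule can return p = 0; ``add_one`` switches to
    (count + 1) / (n + 1).
    """
    d = _check_distance_matrix(distance_matrix)
    labels = np.asarray(labels)
    observed = separation_statistic(d, labels)
    rng = np.random.default_rng(seed)
    count = 0
    work = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(work)
        if _stat_from_sums(d, work) >= observed:
            count += 1
    if add_one:
        p = (count + 1) / (n_permutations + 1)
    else:
        p = count / n_permutations
    return ClusterPermutationResult(
        observed_stat=observed,
        n_permutations=n_permutations,
        n_at_least_as_extreme=count,
        p_value=p,
        mode="monte_carlo",
        seed=seed,
    )


def _multiset_permutations(items: list) -> Iterator[tuple]:
    """All distinct orderings of a multiset, lexicographic."""
    items = sorted(items)
    n = len(items)
    while True:
        yield tuple(items)
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1 :] = reversed(items[i + 1 :])


def exhaustive_permutation_test(
    distance_matrix: np.ndarray,
    labels: Sequence,
    max_arrangements: int = 10**6,
) -> ClusterPermutationResult:
    """Exact null: enumerate every size-preserving label arrangement.

    p = (# arrangements with statistic >= observed) / total, with the
    observed arrangement included in the enumeration.
    """
    d = _check_distance_matrix(distance_matrix)
    labels = np.asarray(labels)
    observed = separation_statistic(d, labels)
    uniq, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    if total > max_arrangements:
        raise ValueError(
            f"{total} arrangements exceed the limit of {max_arrangements}"
        )
    count = 0
    n_seen = 0
    for arrangement in _multiset_permutations(list(labels)):
        n_seen += 1
        if _stat_from_sums(d, np.asarray(arrangement)) >= observed:
            count += 1
    assert n_seen == total
    return ClusterPermutationResult(
        observed_stat=observed,
        n_permutations=total,
        n_at_least_as_extreme=count,
        p_value=count / total,
        mode="exhaustive",
        seed=None,
    )


def cluster_mean_profiles(
    matrix: ExpressionMatrix, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Mean expression per cluster x (genotype, condition, timepoint).

    Rows are cluster labels; columns a MultiIndex over the sample groups.
    """
    cluster_of = assignment.as_mapping()
    df = matrix.to_dataframe()
    df = df.loc[[g for g in df.index if g in cluster_of]]
    clusters = [cluster_of[g] for g in df.index]
    cols = pd.MultiIndex.from_tuples(
        [
            (s.genotype.value, s.condition.value, s.timepoint_h)
            for s in matrix.samples
        ],
        names=["genotype", "condition", "timepoint_h"],
    )
    wide = pd.DataFrame(df.to_numpy(), index=clusters, columns=cols)
    profile = wide.groupby(level=0).mean()  # over genes within cluster
    profile = profile.T.groupby(level=[0, 1, 2]).mean().T  # over replicates
    profile.index.name = "cluster"
    return profile
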