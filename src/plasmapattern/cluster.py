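"""Hierarchical clustering, partition agreement, and discriminative patterns.

Clinical profiles are z-scored and clustered with Ward's method on
Euclidean distances; binary protein profiles are clustered with Ward on
Jaccard distances. Agreement between a clustering and the BMI-group
partition is scored with the Adjusted Rand Index (ARI). A cluster of
interest is characterised by its BMI distribution (Mann-Whitney U against
the complement) and by the proteins whose presence discriminates it
(two-sided Fisher exact tests with Benjamini-Hochberg adjustment).

The Ward implementation is a direct Lance-Williams agglomeration. Two
dialects are exposed: ``"D2"`` (default) applies the recurrence to squared
distances and reports heights on the distance scale — the classical
minimum-variance method when the input distances are Euclidean — while
``"D"`` applies the same recurrence to the raw distances, matching the
legacy unsquared variant found in some clustering environments. Ties are
broken toward the lowest cluster-index pair, so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact, kruskal, f_oneway, mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .io import CohortTable, PresenceMatrix


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with aligned ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape does not match id list")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise DataError("distances must be nonnegative")


@dataclass
class Dendrogram:
    """Agglomerative merge tree in linkage-table form.

    ``merges`` has one row per merge: (left id, right id, height, size),
    with original leaves numbered 0..n-1 and merge k creating node n+k —
    the same convention as scipy linkage matrices, so scipy's dendrogram
    utilities apply directly via :meth:`to_linkage`.
    """

    merges: np.ndarray
    leaf_ids: list[str]

    def to_linkage(self) -> np.ndarray:
        return np.asarray(self.merges, dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class Partition:
    """Flat cluster labels (1..k) aligned with ``ids``."""

    ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(self.labels):
            raise DataError("partition ids and labels differ in length")

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    def members(self, cluster_id: int) -> list[str]:
        return [i for i, lab in zip(self.ids, self.labels) if lab == cluster_id]

    @classmethod
    def from_groups(cls, cohort: CohortTable) -> "Partition":
        """Partition defined by the BMI group labels (external criterion)."""
        uniq: list[str] = []
        for g in cohort.groups:
            if g not in uniq:
                uniq.append(g)
        lab = {g: i + 1 for i, g in enumerate(uniq)}
        return cls(cohort.sample_ids, np.array([lab[g] for g in cohort.groups]))


@dataclass
class ScreenResult:
    """Group-difference screening outcome for one clinical parameter."""

    parameter: str
    group_medians: dict[str, float]
    statistic: float
    p_value: float
    selected: bool
    n_used: int


@dataclass
class PatternResult:
    """Discriminative protein pattern for one cluster.

    ``table`` has one row per tested protein: prevalence inside/outside the
    cluster, raw and BH-adjusted Fisher p-values; ``pattern`` lists the
    proteins passing the adjusted-alpha threshold ranked by absolute
    prevalence difference. BMI fields are populated when a cohort is given.
    """

    cluster_id: int
    table: pd.DataFrame
    pattern: list[str]
    bmi_mean_in: float | None = None
    bmi_mean_out: float | None = None
    bmi_p_value: float | None = None


def zscore_normalize(x: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Column z-scores (mean 0, sample SD 1, n-1 denominator).

    Constant columns are dropped with a warning; an all-constant matrix is
    an error. DataFrame input preserves index/column labels.
    """
    frame = isinstance(x, pd.DataFrame)
    arr = x.to_numpy(dtype=float) if frame else np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise DataError("expected a 2-D matrix")
    sd = arr.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise DataError("all columns are constant; nothing to normalize")
    if not keep.all():
        dropped = (
            [c for c, k in zip(x.columns, keep) if not k] if frame
            else list(np.flatnonzero(~keep))
        )
        warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
    arr = arr[:, keep]
    z = (arr - arr.mean(axis=0)) / arr.std(axis=0, ddof=1)
    if frame:
        return pd.DataFrame(z, index=x.index, columns=[c for c, k in zip(x.columns, keep) if k])
    return z


def screen_parameters(
    cohort: CohortTable,
    alpha: float = 0.05,
    method: str = "kruskal",
    max_missing_fraction: float = 0.5,
) -> list[ScreenResult]:
    """Screen clinical parameters for differences across the BMI groups.

    Kruskal-Wallis by default (``method="anova"`` for one-way ANOVA);
    missing values are excluded pairwise, and a parameter missing in more
    than half the samples is skipped with a warning. A parameter constant
    everywhere gets p = 1 by convention.
    """
    if method not in {"kruskal", "anova"}:
        raise DataError(f"unknown screening method {method!r}")
    groups = [g for g in dict.fromkeys(cohort.groups)]
    if len(groups) < 2:
        raise DataError("screening needs at least two groups")
    frame = cohort.clinical_frame()
    glabels = np.array(cohort.groups)
    results: list[ScreenResult] = []
    for name in cohort.parameter_names:
        col = frame[name].to_numpy(dtype=float)
        ok = np.isfinite(col)
        if ok.mean() < 1.0 - max_missing_fraction:
            warnings.warn(
                f"parameter {name!r} missing in more than "
                f"{max_missing_fraction:.0%} of samples; excluded", stacklevel=2
            )
            continue
        per_group = [col[ok & (glabels == g)] for g in groups]
        per_group = [v for v in per_group if len(v) >= 2]
        if len(per_group) < 2:
            warnings.warn(f"parameter {name!r}: fewer than two usable groups", stacklevel=2)
            continue
        pooled = np.concatenate(per_group)
        if np.allclose(pooled, pooled[0]):
            stat, p = 0.0, 1.0
        elif method == "kruskal":
            stat, p = kruskal(*per_group)
        else:
            stat, p = f_oneway(*per_group)
        medians = {
            g: float(np.nanmedian(col[ok & (glabels == g)]))
            for g in groups
            if (ok & (glabels == g)).sum() >= 2
        }
        results.append(
            ScreenResult(
                parameter=name,
                group_medians=medians,
                statistic=float(stat),
                p_value=float(p),
                selected=bool(p < alpha),
                n_used=int(ok.sum()),
            )
        )
    return results


def jaccard_distance(x: Sequence[int], y: Sequence[int]) -> float:
    """1 - |x AND y| / |x OR y| for binary vectors; 0 when both are all-zero."""
    xa = np.asarray(x, dtype=bool)
    ya = np.asarray(y, dtype=bool)
    if xa.shape != ya.shape:
        raise DataError(f"length mismatch: {xa.shape} vs {ya.shape}")
    union = np.logical_or(xa, ya).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(xa, ya).sum()
    return float(1.0 - inter / union)


def jaccard_distance_matrix(m: PresenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances between sample rows (vectorised)."""
    v = m.values.astype(np.int64)
    inter = v @ v.T
    counts = v.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(list(m.sample_ids), d)


def euclidean_distance_matrix(x: np.ndarray | pd.DataFrame, ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise Euclidean distances between rows of a numeric matrix."""
    if isinstance(x, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in x.index]
        x = x.to_numpy(dtype=float)
    if ids is None:
        ids = [str(i) for i in range(x.shape[0])]
    return DistanceMatrix(list(ids), squareform(pdist(np.asarray(x, dtype=float))))


def ward_linkage(d: DistanceMatrix, dialect: str = "D2") -> Dendrogram:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    Greedy agglomeration with the Lance-Williams Ward update

        d(k, i+j)^2 = [(n_i + n_k) d(i,k)^2 + (n_j + n_k) d(j,k)^2
                       - n_k d(i,j)^2] / (n_i + n_j + n_k)

    applied to squared distances (``dialect="D2"``; heights reported as the
    square root, i.e. on the input distance scale) or to raw distances
    (``dialect="D"``). Ties are broken toward the lowest (i, j) pair of
    cluster creation indices.
    """
    if dialect not in {"D2", "D"}:
        raise DataError(f"unknown Ward dialect {dialect!r}")
    n = len(d.ids)
    if n < 2:
        raise DataError("need at least two observations to cluster")
    # Work matrix indexed by node id 0..2n-2; W holds squared distances for
    # D2 and raw distances for D.
    total = 2 * n - 1
    W = np.full((total, total), np.inf)
    base = d.d ** 2 if dialect == "D2" else d.d.copy()
    W[:n, :n] = base
    np.fill_diagonal(W, np.inf)
    size = np.zeros(total, dtype=int)
    size[:n] = 1
    active = list(range(n))  # stays in ascending creation order
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        act = np.array(active)
        sub = W[np.ix_(act, act)]
        # row-major argmin over the upper triangle = lexicographically
        # smallest (i, j) among ties, i.e. the lowest-pair-index tie-break
        sub = np.where(np.tri(len(act), k=0, dtype=bool), np.inf, sub)
        flat = int(np.argmin(sub))
        ai, aj = divmod(flat, len(act))
        dist = float(sub[ai, aj])
        i, j = int(act[ai]), int(act[aj])
        new = n + step
        height = float(np.sqrt(dist)) if dialect == "D2" else float(dist)
        merges[step] = (i, j, height, size[i] + size[j])
        ni, nj = size[i], size[j]
        rest = act[(act != i) & (act != j)]
        if rest.size:
            nk = size[rest]
            upd = ((ni + nk) * W[i, rest] + (nj + nk) * W[j, rest] - nk * dist) / (
                ni + nj + nk
            )
            W[new, rest] = upd
            W[rest, new] = upd
        size[new] = ni + nj
        active.remove(i)
        active.remove(j)
        active.append(new)
    return Dendrogram(merges, list(d.ids))


def cut_tree(dend: Dendrogram, k: int) -> Partition:
    """Flat partition from the dendrogram by removing the k-1 highest merges.

    Labels 1..k are assigned in order of each cluster's first leaf.
    """
    n = len(dend.leaf_ids)
    if not 1 <= k <= n:
        raise DataError(f"k={k} out of range [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        i, j = int(dend.merges[step, 0]), int(dend.merges[step, 1])
        node = n + step
        parent[find(i)] = node
        parent[find(j)] = node
    roots = [find(i) for i in range(n)]
    labels = np.zeros(n, dtype=int)
    label_of: dict[int, int] = {}
    nxt = 1
    for i, r in enumerate(roots):
        if r not in label_of:
            label_of[r] = nxt
            nxt += 1
        labels[i] = label_of[r]
    return Partition(list(dend.leaf_ids), labels)


def adjusted_rand_index(p: Partition, q: Partition) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Computed from the contingency table: ARI = (index - expected) /
    (max - expected) with pair counts C(.,2); the degenerate 0/0 case
    (both partitions single-class or both all-singleton) is defined as 1.
    """
    if set(p.ids) != set(q.ids):
        raise DataError("partitions are over different id sets")
    order = {i: k for k, i in enumerate(p.ids)}
    q_labels = np.empty(len(q.ids), dtype=int)
    for i, lab in zip(q.ids, q.labels):
        q_labels[order[i]] = lab
    ct = pd.crosstab(pd.Series(p.labels), pd.Series(q_labels)).to_numpy()

    def comb2(x: np.ndarray) -> np.ndarray:
        x = x.astype(float)
        return x * (x - 1) / 2.0

    n = ct.sum()
    sum_ij = comb2(ct).sum()
    a = comb2(ct.sum(axis=1)).sum()
    b = comb2(ct.sum(axis=0)).sum()
    expected = a * b / comb2(np.array([n]))[0] if n >= 2 else 0.0
    max_index = 0.5 * (a + b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def compare_cluster_bmi(
    part: Partition,
    cohort: CohortTable,
    cluster_id: int,
    method: str = "mannwhitney",
) -> tuple[float, float, float]:
    """BMI of a cluster vs its complement: (mean_in, mean_out, p_value).

    Two-sided Mann-Whitney U by default (``method="welch"`` for a Welch
    t-test). The cluster must be nonempty and a strict subset.
    """
    bmi_of = {s.sample_id: s.bmi for s in cohort.samples}
    members = part.members(cluster_id)
    rest = [i for i in part.ids if i not in set(members)]
    if not members or not rest:
        raise DataError(f"cluster {cluster_id} is empty or covers all samples")
    x = np.array([bmi_of[i] for i in members])
    y = np.array([bmi_of[i] for i in rest])
    if method == "mannwhitney":
        _, p = mannwhitneyu(x, y, alternative="two-sided")
    elif method == "welch":
        _, p = ttest_ind(x, y, equal_var=False)
    else:
        raise DataError(f"unknown comparison method {method!r}")
    return float(x.mean()), float(y.mean()), float(p)


def extract_discriminative_pattern(
    m: PresenceMatrix,
    part: Partition,
    cluster_id: int,
    alpha: float = 0.05,
    cohort: CohortTable | None = None,
) -> PatternResult:
    """Proteins whose presence discriminates a cluster from its complement.

    Per protein: two-sided Fisher exact test on the 2x2 presence x
    membership table; Benjamini-Hochberg adjustment across proteins; the
    pattern keeps proteins with adjusted p <= alpha, ranked by absolute
    prevalence difference (ties by accession). When a cohort is supplied
    the cluster-vs-complement BMI comparison is attached.
    """
    in_cluster = np.array([lab == cluster_id for lab in part.labels])
    if m.sample_ids != part.ids:
        m = m.select_samples(part.ids)
    n_in = int(in_cluster.sum())
    n_out = int((~in_cluster).sum())
    if n_in == 0 or n_out == 0:
        raise DataError(f"cluster {cluster_id} is empty or covers all samples")
    rows = []
    for j, pid in enumerate(m.protein_ids):
        col = m.values[:, j].astype(bool)
        a = int((col & in_cluster).sum())
        b = int((col & ~in_cluster).sum())
        _, p = fisher_exact([[a, n_in - a], [b, n_out - b]], alternative="two-sided")
        rows.append((pid, a / n_in, b / n_out, p))
    table = pd.DataFrame(rows, columns=["protein", "prev_in", "prev_out", "p_value"])
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["prev_diff"] = table["prev_in"] - table["prev_out"]
    else:
        table["p_adjusted"] = []
        table["prev_diff"] = []
    hits = table[table["p_adjusted"] <= alpha].copy() if alpha > 0 else table.iloc[0:0]
    hits = hits.sort_values(
        by=["prev_diff", "protein"],
        key=lambda s: -s.abs() if s.name == "prev_diff" else s,
    )
    result = PatternResult(cluster_id=cluster_id, table=table, pattern=list(hits["protein"]))
    if cohort is not None:
        mean_in, mean_out, p = compare_cluster_bmi(part, cohort, cluster_id)
        result.bmi_mean_in, result.bmi_mean_out, result.bmi_p_value = mean_in, mean_out, p
    return result


def high_bmi_cluster(part: Partition, cohort: CohortTable) -> int:
    """Cluster id with the largest mean BMI."""
    bmi_of = {s.sample_id: s.bmi for s in cohort.samples}
    best, best_mean = None, -np.inf
    for cid in np.unique(part.labels):
        mean = float(np.mean([bmi_of[i] for i in part.members(int(cid))]))
        if mean > best_mean:
            best, best_mean = int(cid), mean
    return best


def pca_scores(x: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores and explained-variance fractions.

    The input should already be column-normalized; it is centred here and
    decomposed by SVD. Requesting more components than the matrix rank
    truncates with a warning. Component signs follow the convention that the
    largest-magnitude loading of each component is positive.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or min(x.shape) < 2:
        raise DataError("PCA needs a matrix with at least 2 rows and 2 columns")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max() * max(xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    # deterministic sign: largest |loading| positive
    for k in range(n_components):
        jmax = np.argmax(np.abs(vt[k]))
        if vt[k, jmax] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u[:, :n_components] * s[:n_components]
    var = s ** 2
    fractions = var[:n_components] / var.sum()
    return scores, fractions
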