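"""Machine-learning prioritization of network genes.

Given a per-gene table of topological indices, the workflow is:

1. clean (row removal / mean imputation of missing values),
2. z-score standardization,
3. K-means clustering with elbow selection of k (second difference of the
   within-cluster sum of squares, WCSS),
4. Isolation-Forest anomaly detection,
5. PCA projection to two components for inspection,
6. a direction-aware rank-aggregation composite score (mean of per-index
   fractional ranks; lower = more important),
7. the core-gene rule: Isolation-Forest outlier AND composite rank within
   a threshold.

K-means, the Isolation Forest and the PCA are implemented here directly so
that every stochastic choice flows from one explicit seed and results are
bit-reproducible across library versions.

The model interface follows the statsmodels convention: build a
:class:`CoreTargetModel` from a feature table (or a graph), call
:meth:`~CoreTargetModel.fit`, and read estimates, diagnostics and the
summary table off the returned :class:`CoreTargetResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph_io import GeneList, Graph
from .topology import centrality_table

__all__ = [
    "DESCENDING_INDICES",
    "ASCENDING_INDICES",
    "clean_features",
    "standardize",
    "kmeans",
    "elbow_select_k",
    "isolation_forest",
    "pca2",
    "composite_score",
    "select_core_genes",
    "KMeansFit",
    "ClusterResult",
    "OutlierResult",
    "PCAResult",
    "CompositeScores",
    "CoreTargetModel",
    "CoreTargetResults",
]

#: Indices where larger values indicate topological importance (ranked
#: descending: rank 1 = largest value).
DESCENDING_INDICES = (
    "MNC",
    "EPC",
    "Bottleneck",
    "BetweennessCentrality",
    "ClosenessCentrality",
    "Degree",
    "Radiality",
    "Stress",
    "NeighborhoodConnectivity",
    "NumberOfUndirectedEdges",
    "Betweenness",
)

#: Indices where smaller values indicate importance (ranked ascending).
#: Short path lengths, low topological coefficients and low clustering
#: coefficients are the hub-like signatures.
ASCENDING_INDICES = (
    "AverageShortestPathLength",
    "TopologicalCoefficient",
    "ClusteringCoefficient",
)


def _as_frame(X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Cleaning and standardization
# ---------------------------------------------------------------------------

def clean_features(
    raw: pd.DataFrame,
    feature_missing_max: float = 0.005,
    sample_missing_max: float = 0.005,
) -> pd.DataFrame:
    """Remove heavily missing rows, then mean-impute sparsely missing columns.

    Rows (genes) whose missing fraction is >= ``sample_missing_max`` are
    dropped first; columns whose remaining missing fraction is
    < ``feature_missing_max`` are imputed with the column mean.  Note that
    at the default thresholds any single missing value in a 14-column row
    (7.1%) already triggers row removal, so column imputation only engages
    at larger, laxer thresholds; the rule is applied literally as stated.
    """
    for name, val in (
        ("feature_missing_max", feature_missing_max),
        ("sample_missing_max", sample_missing_max),
    ):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {val}")
    df = _as_frame(raw).astype(float)
    row_frac = df.isna().mean(axis=1)
    df = df.loc[row_frac < sample_missing_max].copy()
    if df.empty:
        raise ValueError("all rows removed by the missingness filter")
    col_frac = df.isna().mean(axis=0)
    for col in df.columns[(col_frac > 0) & (col_frac < feature_missing_max)]:
        df[col] = df[col].fillna(df[col].mean())
    if df.isna().any().any():
        bad = list(df.columns[df.isna().any()])
        raise ValueError(
            f"columns {bad} still missing after cleaning; raise "
            f"feature_missing_max or drop them upstream"
        )
    return df


def standardize(m: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores with population SD; constant columns map to 0."""
    df = _as_frame(m).astype(float)
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    out = (df - mean).div(sd.where(sd > 0, 1.0), axis=1)
    out.loc[:, sd == 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# K-means with elbow selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMeansFit:
    """A single k-means solution."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    wcss: float
    n_iter: int


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++ seeding (several candidates per step, keep the one
    minimizing the potential)."""
    n = len(X)
    n_trials = 2 + int(math.log(k)) if k > 1 else 1
    centers = np.empty((k, X.shape[1]))
    first = rng.integers(n)
    centers[0] = X[first]
    closest = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = closest.sum()
        if total <= 0:  # all points coincide with chosen centers
            idx = rng.integers(n, size=1)
            centers[c] = X[idx[0]]
            continue
        cand_idx = rng.choice(n, size=n_trials, p=closest / total)
        best_pot, best = np.inf, cand_idx[0]
        for i in cand_idx:
            pot = np.minimum(closest, ((X - X[i]) ** 2).sum(axis=1)).sum()
            if pot < best_pot:
                best_pot, best = pot, i
        centers[c] = X[best]
        closest = np.minimum(closest, ((X - centers[c]) ** 2).sum(axis=1))
    return centers


def kmeans(
    X: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 42,
    max_iter: int = 300,
    tol: float = 1e-4,
    n_init: int = 1,
) -> KMeansFit:
    """Lloyd's algorithm with seeded greedy k-means++ initialization.

    Iteration stops when the squared Frobenius norm of the centroid shift
    drops below ``tol`` or after ``max_iter`` rounds.  A single seeded
    initialization by default; ``n_init`` > 1 keeps the lowest-WCSS run.
    """
    A = _as_frame(X).to_numpy(dtype=float)
    n = len(A)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best: KMeansFit | None = None
    for _ in range(max(1, n_init)):
        centers = _kmeanspp_init(A, k, rng)
        labels = np.zeros(n, dtype=np.int64)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            d2 = ((A[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = d2.argmin(axis=1)
            new_centers = centers.copy()
            for c in range(k):
                mask = labels == c
                if mask.any():
                    new_centers[c] = A[mask].mean(axis=0)
                else:  # re-seed an empty cluster on the worst-fit point
                    worst = d2[np.arange(n), labels].argmax()
                    new_centers[c] = A[worst]
            shift = float(((new_centers - centers) ** 2).sum())
            centers = new_centers
            if shift < tol:
                break
        d2 = ((A[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(n), labels].sum())
        fit = KMeansFit(k=k, labels=labels, centroids=centers, wcss=wcss, n_iter=n_iter)
        if best is None or fit.wcss < best.wcss:
            best = fit
    assert best is not None
    return best


@dataclass(frozen=True)
class ClusterResult:
    """Elbow-selected clustering: chosen k, labels, and the WCSS profile."""

    chosen_k: int
    labels: np.ndarray
    centroids: np.ndarray
    wcss: dict[int, float]
    weak_elbow: bool

    @property
    def second_differences(self) -> dict[int, float]:
        ks = sorted(self.wcss)
        return {
            k: self.wcss[k - 1] - 2 * self.wcss[k] + self.wcss[k + 1]
            for k in ks
            if k - 1 in self.wcss and k + 1 in self.wcss
        }


def elbow_select_k(
    X: pd.DataFrame | np.ndarray,
    k_range: Sequence[int] = range(1, 11),
    seed: int = 42,
    *,
    max_iter: int = 300,
    tol: float = 1e-4,
    n_init: int = 1,
) -> ClusterResult:
    """Fit k-means over ``k_range`` and pick k at the elbow of the WCSS curve.

    The elbow is the interior k maximizing the second difference
    WCSS(k-1) - 2 WCSS(k) + WCSS(k+1); ties resolve to the smallest k.
    When the maximal second difference is below 5% of the WCSS at the
    smallest k the curve has no pronounced kink and the result is flagged
    ``weak_elbow`` (and a warning is emitted).
    """
    A = _as_frame(X)
    n = len(A)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    usable = [k for k in ks if k <= n]
    if len(usable) < len(ks):
        warnings.warn(f"k_range truncated to k <= n = {n}", stacklevel=2)
    if len(usable) < 3:
        raise ValueError("need at least three k values to locate an elbow")
    fits = {k: kmeans(A, k, seed=seed, max_iter=max_iter, tol=tol, n_init=n_init) for k in usable}
    wcss = {k: fits[k].wcss for k in usable}
    interior = [k for k in usable if k - 1 in wcss and k + 1 in wcss]
    second = {k: wcss[k - 1] - 2 * wcss[k] + wcss[k + 1] for k in interior}
    best = max(second.values())
    chosen = min(k for k, v in second.items() if v == best)
    weak = best < 0.05 * wcss[usable[0]]
    if weak:
        warnings.warn(
            f"weak elbow: max second difference {best:.4g} is below 5% of "
            f"WCSS({usable[0]}) = {wcss[usable[0]]:.4g}",
            stacklevel=2,
        )
    fit = fits[chosen]
    return ClusterResult(
        chosen_k=chosen,
        labels=fit.labels,
        centroids=fit.centroids,
        wcss=wcss,
        weak_elbow=weak,
    )


# ---------------------------------------------------------------------------
# Isolation Forest
# ---------------------------------------------------------------------------

def _harmonic(n: int) -> float:
    if n < 1:
        return 0.0
    if n < 64:
        return float(np.sum(1.0 / np.arange(1, n + 1)))
    return math.log(n) + np.euler_gamma + 1.0 / (2 * n)


def _avg_path_correction(size: int) -> float:
    """c(m) = 2 H(m-1) - 2 (m-1)/m: mean unsuccessful-search depth of a BST."""
    if size <= 1:
        return 0.0
    return 2.0 * _harmonic(size - 1) - 2.0 * (size - 1) / size


class _IsoNode:
    __slots__ = ("feature", "split", "left", "right", "size")

    def __init__(self, feature=None, split=None, left=None, right=None, size=0):
        self.feature = feature
        self.split = split
        self.left = left
        self.right = right
        self.size = size


def _grow_iso_tree(
    X: np.ndarray, rows: np.ndarray, depth: int, limit: int, rng: np.random.Generator
) -> _IsoNode:
    if depth >= limit or len(rows) <= 1:
        return _IsoNode(size=len(rows))
    sub = X[rows]
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    splittable = np.flatnonzero(hi > lo)
    if len(splittable) == 0:  # all duplicate rows
        return _IsoNode(size=len(rows))
    f = int(rng.choice(splittable))
    s = float(rng.uniform(lo[f], hi[f]))
    left_mask = sub[:, f] < s
    if not left_mask.any() or left_mask.all():  # degenerate draw at the boundary
        return _IsoNode(size=len(rows))
    return _IsoNode(
        feature=f,
        split=s,
        left=_grow_iso_tree(X, rows[left_mask], depth + 1, limit, rng),
        right=_grow_iso_tree(X, rows[~left_mask], depth + 1, limit, rng),
    )


def _iso_path_lengths(tree: _IsoNode, X: np.ndarray) -> np.ndarray:
    out = np.zeros(len(X))
    stack: list[tuple[_IsoNode, np.ndarray, int]] = [(tree, np.arange(len(X)), 0)]
    while stack:
        node, rows, depth = stack.pop()
        if node.feature is None:
            out[rows] = depth + _avg_path_correction(node.size)
            continue
        mask = X[rows, node.feature] < node.split
        stack.append((node.left, rows[mask], depth + 1))
        stack.append((node.right, rows[~mask], depth + 1))
    return out


@dataclass(frozen=True)
class OutlierResult:
    """Isolation-Forest anomaly scores and flags, indexed like the input."""

    anomaly_score: pd.Series
    is_outlier: pd.Series
    threshold: float
    subsample_size: int

    @property
    def n_flagged(self) -> int:
        return int(self.is_outlier.sum())


def isolation_forest(
    X: pd.DataFrame | np.ndarray,
    n_trees: int = 100,
    subsample_fraction: float = 0.8,
    contamination: float = 0.10,
    seed: int = 42,
) -> OutlierResult:
    """Isolation-Forest anomaly detection with quantile-based flagging.

    ``n_trees`` trees are grown on seeded subsamples of
    ceil(``subsample_fraction`` * n) rows, with random axis-aligned splits
    drawn uniformly inside each node's observed feature range and a height
    limit of ceil(log2(subsample size)).  The anomaly score is
    s(x) = 2^(-E[h(x)] / c(m)) with c(m) the average unsuccessful-search
    path length of a binary search tree of m points; scores lie in (0, 1].
    The ceil(``contamination`` * n) highest-scoring rows are flagged, with
    every row tied at the cutoff score included.
    """
    df = _as_frame(X)
    A = df.to_numpy(dtype=float)
    n = len(A)
    if n < 2:
        raise ValueError("isolation forest needs at least two rows")
    if not 0.0 < contamination <= 0.5:
        raise ValueError(f"contamination must lie in (0, 0.5], got {contamination}")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError(
            f"subsample_fraction must lie in (0, 1], got {subsample_fraction}"
        )
    m = min(n, max(2, math.ceil(subsample_fraction * n)))
    limit = max(1, math.ceil(math.log2(m)))
    rng = np.random.default_rng(seed)
    depths = np.zeros(n)
    for _ in range(n_trees):
        rows = rng.choice(n, size=m, replace=False)
        tree = _grow_iso_tree(A, rows, 0, limit, rng)
        depths += _iso_path_lengths(tree, A)
    mean_depth = depths / n_trees
    scores = np.power(2.0, -mean_depth / _avg_path_correction(m))
    k = math.ceil(contamination * n)
    cutoff = float(np.sort(scores)[::-1][k - 1])
    flags = scores >= cutoff
    return OutlierResult(
        anomaly_score=pd.Series(scores, index=df.index, name="anomaly_score"),
        is_outlier=pd.Series(flags, index=df.index, name="is_outlier"),
        threshold=cutoff,
        subsample_size=m,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    coordinates: pd.DataFrame          # columns pc1, pc2
    components: np.ndarray             # (2, d) orthonormal rows
    explained_variance_ratio: np.ndarray


def pca2(X: pd.DataFrame | np.ndarray) -> PCAResult:
    """Project rows onto the first two principal components.

    Column-centered SVD; each component's sign is fixed so that its
    largest-magnitude loading is positive, making the projection
    deterministic.  With fewer than two informative directions the missing
    coordinates are zero.
    """
    df = _as_frame(X)
    A = df.to_numpy(dtype=float)
    A = A - A.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    n_comp = min(2, Vt.shape[0])
    comps = np.zeros((2, A.shape[1]))
    coords = np.zeros((len(A), 2))
    for c in range(n_comp):
        vec = Vt[c]
        j = int(np.abs(vec).argmax())
        sign = 1.0 if vec[j] >= 0 else -1.0
        comps[c] = sign * vec
        coords[:, c] = sign * U[:, c] * S[c]
    total = float((S**2).sum())
    evr = (S[:n_comp] ** 2 / total) if total > 0 else np.zeros(n_comp)
    evr = np.pad(evr, (0, 2 - n_comp))
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=df.index, columns=["pc1", "pc2"]),
        components=comps,
        explained_variance_ratio=evr,
    )


# ---------------------------------------------------------------------------
# Composite score and core-gene rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositeScores:
    """Per-index ranks, composite score (mean rank) and final rank."""

    ranks: pd.DataFrame
    score: pd.Series
    rank: pd.Series


def composite_score(
    table: pd.DataFrame,
    descending_indices: Sequence[str] = DESCENDING_INDICES,
    ascending_indices: Sequence[str] = ASCENDING_INDICES,
    *,
    rank_method: str = "average",
) -> CompositeScores:
    """Direction-aware rank aggregation across all indices.

    Descending indices rank their largest value 1; ascending indices rank
    their smallest value 1.  Ties receive fractional (mean-of-positions)
    ranks by default, which keeps the result order-independent and
    conserves the rank sum.  The composite score is the arithmetic mean of
    a gene's ranks across every index; genes are finally re-ranked by
    ascending composite score (lower = more important).
    """
    desc, asc = set(descending_indices), set(ascending_indices)
    cols = set(table.columns)
    if desc & asc:
        raise ValueError(f"direction sets overlap: {sorted(desc & asc)}")
    if desc | asc != cols:
        raise ValueError(
            "direction sets must partition the table columns; "
            f"missing={sorted(cols - desc - asc)}, extra={sorted((desc | asc) - cols)}"
        )
    ranks = pd.DataFrame(index=table.index)
    for col in table.columns:
        ranks[col] = table[col].rank(
            ascending=col in asc, method=rank_method
        )
    score = ranks.mean(axis=1)
    final = score.rank(method=rank_method)
    return CompositeScores(ranks=ranks, score=score.rename("composite_score"),
                           rank=final.rename("composite_rank"))


def select_core_genes(
    result: "CoreTargetResults | pd.DataFrame",
    rank_threshold: float = 20,
) -> GeneList:
    """Core genes: Isolation-Forest outliers with composite rank within the
    threshold, ordered by composite rank."""
    table = result.table if isinstance(result, CoreTargetResults) else result
    mask = table["is_outlier"].astype(bool) & (table["composite_rank"] <= rank_threshold)
    chosen = table.loc[mask].sort_values("composite_rank", kind="mergesort")
    return GeneList.from_iterable("core_genes", chosen.index)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

def _stage_seed(seed: int, stage: str) -> int:
    """Independent per-stage substream derived from one base seed."""
    import zlib

    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


class CoreTargetModel:
    """Core-target prioritization model over a per-gene feature table.

    Parameters
    ----------
    features : DataFrame
        Genes in rows, topological indices in columns (possibly with
        missing entries).
    descending_indices, ascending_indices : sequences of column names
        Direction map for the rank aggregation; defaults follow the
        14-index convention.
    Other keyword arguments expose every workflow hyperparameter with the
    reference defaults: K-means max_iter=300, tol=1e-4, k range 1-10;
    Isolation Forest with 100 trees, 0.8 subsampling, contamination 0.10;
    two PCA components; core-gene rank threshold 20.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        *,
        descending_indices: Sequence[str] | None = None,
        ascending_indices: Sequence[str] | None = None,
        feature_missing_max: float = 0.005,
        sample_missing_max: float = 0.005,
        k_range: Sequence[int] = range(1, 11),
        kmeans_max_iter: int = 300,
        kmeans_tol: float = 1e-4,
        kmeans_n_init: int = 1,
        if_n_trees: int = 100,
        if_subsample_fraction: float = 0.8,
        if_contamination: float = 0.10,
        rank_threshold: float = 20,
        rank_method: str = "average",
    ) -> None:
        self.features = _as_frame(features)
        if descending_indices is None and ascending_indices is None:
            cols = set(self.features.columns)
            descending_indices = tuple(c for c in DESCENDING_INDICES if c in cols)
            ascending_indices = tuple(c for c in ASCENDING_INDICES if c in cols)
        self.descending_indices = tuple(descending_indices or ())
        self.ascending_indices = tuple(ascending_indices or ())
        self.feature_missing_max = feature_missing_max
        self.sample_missing_max = sample_missing_max
        self.k_range = list(k_range)
        self.kmeans_max_iter = kmeans_max_iter
        self.kmeans_tol = kmeans_tol
        self.kmeans_n_init = kmeans_n_init
        self.if_n_trees = if_n_trees
        self.if_subsample_fraction = if_subsample_fraction
        self.if_contamination = if_contamination
        self.rank_threshold = rank_threshold
        self.rank_method = rank_method

    @classmethod
    def from_graph(
        cls,
        g: Graph,
        *,
        epc_retain_p: float = 0.5,
        epc_iterations: int = 1000,
        epc_seed: int = 42,
        genes: Iterable[str] | None = None,
        **kwargs,
    ) -> "CoreTargetModel":
        """Build the model from a network by computing the 14-index table.

        ``genes`` restricts the feature table to a subset (e.g. the hub
        intersection) while still computing topology on the full network.
        """
        table = centrality_table(
            g, epc_retain_p=epc_retain_p, epc_iterations=epc_iterations, seed=epc_seed
        )
        if genes is not None:
            wanted = [s for s in genes]
            table = table.loc[wanted]
        return cls(table, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CoreTargetModel":
        return cls(df, **kwargs)

    def fit(self, seed: int = 42) -> "CoreTargetResults":
        """Run the full workflow; all randomness flows from ``seed`` via
        per-stage substreams."""
        cleaned = clean_features(
            self.features, self.feature_missing_max, self.sample_missing_max
        )
        z = standardize(cleaned)
        cluster = elbow_select_k(
            z,
            k_range=self.k_range,
            seed=_stage_seed(seed, "kmeans"),
            max_iter=self.kmeans_max_iter,
            tol=self.kmeans_tol,
            n_init=self.kmeans_n_init,
        )
        outliers = isolation_forest(
            z,
            n_trees=self.if_n_trees,
            subsample_fraction=self.if_subsample_fraction,
            contamination=self.if_contamination,
            seed=_stage_seed(seed, "isolation_forest"),
        )
        projection = pca2(z)
        composite = composite_score(
            cleaned,
            self.descending_indices,
            self.ascending_indices,
            rank_method=self.rank_method,
        )
        return CoreTargetResults(
            model=self,
            seed=seed,
            cleaned=cleaned,
            standardized=z,
            cluster=cluster,
            outliers=outliers,
            projection=projection,
            composite=composite,
        )


class CoreTargetResults:
    """Fitted prioritization results.

    Attributes
    ----------
    table : DataFrame
        One row per gene: the 14 per-index ranks, composite score and
        rank, cluster label, anomaly score, outlier flag, core flag and
        the two principal-component coordinates.
    core_genes : GeneList
        Genes satisfying the core rule, ordered by composite rank.
    """

    def __init__(
        self,
        model: CoreTargetModel,
        seed: int,
        cleaned: pd.DataFrame,
        standardized: pd.DataFrame,
        cluster: ClusterResult,
        outliers: OutlierResult,
        projection: PCAResult,
        composite: CompositeScores,
    ) -> None:
        self.model = model
        self.seed = seed
        self.cleaned = cleaned
        self.standardized = standardized
        self.cluster = cluster
        self.outliers = outliers
        self.projection = projection
        self.composite = composite
        self.table = self._assemble()
        self.core_genes = select_core_genes(self, model.rank_threshold)
        self.table["is_core"] = self.table.index.isin(self.core_genes.as_set)

    def _assemble(self) -> pd.DataFrame:
        ranks = self.composite.ranks.add_prefix("rank_")
        out = ranks.copy()
        out["composite_score"] = self.composite.score
        out["composite_rank"] = self.composite.rank
        out["cluster"] = self.cluster.labels
        out["anomaly_score"] = self.outliers.anomaly_score
        out["is_outlier"] = self.outliers.is_outlier.astype(int)
        out["pc1"] = self.projection.coordinates["pc1"]
        out["pc2"] = self.projection.coordinates["pc2"]
        out.index.name = "gene"
        return out

    @property
    def chosen_k(self) -> int:
        return self.cluster.chosen_k

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.projection.explained_variance_ratio

    def top(self, n: int = 10) -> pd.DataFrame:
        """Top-n genes by composite score, in the two-column report layout."""
        ordered = self.table.sort_values("composite_rank", kind="mergesort")
        head = ordered.head(n)
        return pd.DataFrame(
            {"Gene": head.index, "Composite Score": head["composite_score"].round(2)}
        ).reset_index(drop=True)

    def summary(self, top_n: int = 10) -> str:
        lines = [
            "Core-target prioritization",
            "==========================",
            f"genes analysed:        {len(self.table)}",
            f"chosen k (elbow):      {self.chosen_k}"
            + ("  [weak elbow]" if self.cluster.weak_elbow else ""),
            f"outliers flagged:      {self.outliers.n_flagged} "
            f"(contamination {self.model.if_contamination})",
            f"PC1/PC2 variance:      "
            f"{self.explained_variance_ratio[0]:.1%} / "
            f"{self.explained_variance_ratio[1]:.1%}",
            "",
            f"Top {min(top_n, len(self.table))} by composite score "
            "(lower = more important)",
            "Gene\tComposite Score",
        ]
        for _, row in self.top(top_n).iterrows():
            lines.append(f"{row['Gene']}\t{row['Composite Score']:.2f}")
        lines.append("")
        if len(self.core_genes):
            lines.append("core genes: " + ", ".join(self.core_genes))
        else:
            lines.append("core genes: none selected")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        from .graph_io import write_table

        write_table(self.table, path)

    # -- plotting ------------------------------------------------------
    def plot_pca(self, ax=None):
        """Scatter of the two PC coordinates, colored by cluster, outliers
        circled."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        sc = ax.scatter(t["pc1"], t["pc2"], c=t["cluster"], cmap="viridis", s=30)
        flagged = t[t["is_outlier"] == 1]
        ax.scatter(
            flagged["pc1"], flagged["pc2"], facecolors="none", edgecolors="red",
            s=120, label="outlier",
        )
        ax.set_xlabel(f"PC1 ({self.explained_variance_ratio[0]:.1%})")
        ax.set_ylabel(f"PC2 ({self.explained_variance_ratio[1]:.1%})")
        ax.legend(*sc.legend_elements(), title="cluster", loc="best")
        return ax

    def plot_elbow(self, ax=None):
        """WCSS against k with the chosen elbow marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = sorted(self.cluster.wcss)
        ax.plot(ks, [self.cluster.wcss[k] for k in ks], "o-")
        ax.axvline(self.chosen_k, color="red", linestyle="--",
                   label=f"elbow k={self.chosen_k}")
        ax.set_xlabel("k")
        ax.set_ylabel("WCSS")
        ax.legend()
        return ax
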