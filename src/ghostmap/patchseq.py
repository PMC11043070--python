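"""Patch-seq count-matrix analysis: normalisation, Leiden clustering with
silhouette-based resolution selection, relative-expression summaries, QC and
diet-composition shift testing.

Counts are library-size normalised (counts per 10^4, log1p), embedded by PCA,
and clustered by the Leiden algorithm on an unweighted kNN-union graph over a
grid of resolution parameters; the resolution whose partition maximises the
mean silhouette (in PC space) is selected, ties going to the smallest
resolution.  Cluster labels are relabelled by decreasing size for
determinism.  Designed for the small-cohort regime of patch-seq (tens of
cells), so no highly-variable-gene selection is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .core import CountMatrix, InsufficientDataError, ValidationError


@dataclass
class ClusterParams:
    n_pcs: int = 20                   # capped at n_cells - 1 and n_genes
    knn_k: int = 10
    resolution_grid: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 21)])
    seed: int = 0
    min_silhouette: float = 0.0

    def __post_init__(self) -> None:
        grid = list(self.resolution_grid)
        if not grid or any(r <= 0 for r in grid) or any(
                b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError(
                "resolution_grid must be non-empty, positive, increasing")
        self.resolution_grid = grid


@dataclass
class ClusterResult:
    labels: np.ndarray                       # (n_cells,) int, 0-based, size-ordered
    n_clusters: int
    resolution_selected: float | None        # None when the degenerate rule fires
    silhouette_by_resolution: dict[float, float]
    embedding_dims: int
    pcs: np.ndarray | None = None            # (n_cells, embedding_dims)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

CP_TARGET = 1.0e4


def normalize_counts(matrix: CountMatrix) -> pd.DataFrame:
    """log(1 + counts-per-10^4) per cell; genes x cells DataFrame."""
    totals = matrix.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValidationError(
            f"cells with zero total count: {[matrix.cells[i] for i in zero[:5]]}")
    norm = np.log1p(matrix.counts / totals[None, :] * CP_TARGET)
    return pd.DataFrame(norm, index=matrix.genes, columns=matrix.cells)


# ---------------------------------------------------------------------------
# Leiden clustering with silhouette model selection
# ---------------------------------------------------------------------------

def _knn_union_graph(pcs: np.ndarray, k: int) -> igraph.Graph:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i, neigh in enumerate(idx):
        for j in neigh[1:]:            # drop self
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=len(pcs), edges=sorted(edges))
    return g


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Deterministic relabelling: cluster 0 is the largest, ties by first id."""
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


def cluster_cells(norm: pd.DataFrame, params: ClusterParams | None = None
                  ) -> ClusterResult:
    """PCA -> kNN-union graph -> Leiden over a resolution grid -> silhouette
    selection.

    Partitions with a single cluster are excluded from selection; if every
    resolution yields one cluster, or the best mean silhouette falls below
    ``min_silhouette``, the degenerate single-cluster result is returned.
    """
    params = params or ClusterParams()
    X = norm.to_numpy(float).T                      # cells x genes
    n_cells = X.shape[0]
    if n_cells < params.knn_k + 1:
        raise InsufficientDataError(
            f"{n_cells} cells < knn_k + 1 = {params.knn_k + 1}")
    n_pcs = min(params.n_pcs, n_cells - 1, X.shape[1])
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    graph = _knn_union_graph(pcs, params.knn_k)

    silhouettes: dict[float, float] = {}
    partitions: dict[float, np.ndarray] = {}
    for res in params.resolution_grid:
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res, seed=params.seed, n_iterations=-1)
        labels = np.asarray(part.membership)
        k = len(np.unique(labels))
        if k < 2 or k >= n_cells:
            continue
        silhouettes[res] = float(silhouette_score(pcs, labels))
        partitions[res] = labels

    if not silhouettes or max(silhouettes.values()) < params.min_silhouette:
        return ClusterResult(labels=np.zeros(n_cells, dtype=int), n_clusters=1,
                             resolution_selected=None,
                             silhouette_by_resolution=silhouettes,
                             embedding_dims=n_pcs, pcs=pcs)
    best = max(silhouettes.values())
    res_sel = min(r for r, s in silhouettes.items() if s == best)
    labels = _relabel_by_size(partitions[res_sel])
    return ClusterResult(labels=labels, n_clusters=len(np.unique(labels)),
                         resolution_selected=res_sel,
                         silhouette_by_resolution=silhouettes,
                         embedding_dims=n_pcs, pcs=pcs)


# ---------------------------------------------------------------------------
# Relative expression and marker panels
# ---------------------------------------------------------------------------

def relative_expression(norm: pd.DataFrame, labels: np.ndarray,
                        genes=None) -> pd.DataFrame:
    """Cluster x gene table of (mean in cluster - mean in all other cells),
    on the log-normalised scale."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValidationError("relative expression needs >= 2 clusters")
    sub = norm if genes is None else norm.loc[[g for g in genes
                                               if g in norm.index]]
    vals = sub.to_numpy(float)
    rows = {}
    for c in clusters:
        in_c = labels == c
        rows[c] = vals[:, in_c].mean(axis=1) - vals[:, ~in_c].mean(axis=1)
    return pd.DataFrame(rows, index=sub.index).T


def marker_panel_score(norm: pd.DataFrame, labels: np.ndarray,
                       panel: list[str]) -> dict:
    """Mean relative expression of a marker-gene panel per cluster.

    Returns per-cluster scores, the per-gene relative-expression table and
    which panel genes were absent from the matrix.
    """
    present = [g for g in panel if g in norm.index]
    missing = [g for g in panel if g not in norm.index]
    if not present:
        raise ValidationError("no panel gene present in the matrix")
    rel = relative_expression(norm, labels, genes=present)
    return {"scores": rel.mean(axis=1), "per_gene": rel,
            "genes_found": present, "genes_missing": missing}


# ---------------------------------------------------------------------------
# QC and composition shift
# ---------------------------------------------------------------------------

def cluster_qc(matrix: CountMatrix, labels: np.ndarray) -> dict:
    """Per-cluster totals and mito/ribo count fractions, with a one-way
    ANOVA across clusters for each metric."""
    labels = np.asarray(labels)
    totals = matrix.counts.sum(axis=0).astype(float)
    mito = matrix.gene_flags["is_mito"].to_numpy(bool)
    ribo = matrix.gene_flags["is_ribo"].to_numpy(bool)
    with np.errstate(invalid="ignore"):
        mito_frac = matrix.counts[mito].sum(axis=0) / totals
        ribo_frac = matrix.counts[ribo].sum(axis=0) / totals
    per_cell = pd.DataFrame({"cluster": labels, "total": totals,
                             "mito_frac": mito_frac, "ribo_frac": ribo_frac})
    table = per_cell.groupby("cluster").agg(
        n_cells=("total", "size"),
        total_mean=("total", "mean"), total_sd=("total", "std"),
        mito_frac_mean=("mito_frac", "mean"),
        ribo_frac_mean=("ribo_frac", "mean"))
    anova = {}
    groups = [g for _, g in per_cell.groupby("cluster")]
    for metric in ("total", "mito_frac", "ribo_frac"):
        vals = [g[metric].to_numpy(float) for g in groups]
        if len(vals) >= 2 and all(len(v) >= 2 for v in vals) and any(
                np.ptp(np.concatenate(vals)) > 0 for _ in (0,)):
            f, p = scipy.stats.f_oneway(*vals)
            anova[metric] = {"F": float(f), "p": float(p)}
        else:
            anova[metric] = {"F": np.nan, "p": np.nan}
    return {"table": table, "anova": anova}


def composition_shift(labels: np.ndarray, condition: np.ndarray) -> dict:
    """Cluster-composition change between conditions: per-condition cluster
    percentages and a Pearson chi-squared on the cluster x condition table."""
    labels = np.asarray(labels)
    condition = np.asarray(condition)
    conds = np.unique(condition)
    if len(conds) < 2:
        raise ValidationError("both conditions must be present")
    table = pd.crosstab(pd.Series(labels, name="cluster"),
                        pd.Series(condition, name="condition"))
    if (table.sum(axis=0) == 0).any():
        raise ValidationError("a condition has zero cells")
    pct = table / table.sum(axis=0) * 100.0
    chi2, p, df, _ = scipy.stats.chi2_contingency(table.to_numpy(),
                                                  correction=False)
    return {"counts": table, "percent_by_condition": pct,
            "chi2": float(chi2), "df": int(df), "p": float(p)}
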