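"""QC filtering, CLR normalization, PCA, SNN clustering, and annotation.

The clustering path mirrors the standard graph-based single-cell workflow:
CLR-normalized counts -> top variable genes -> per-gene z-score (clipped at
+-10) -> PCA -> shared-nearest-neighbor graph (Jaccard weights, pruned at
1/15) -> modularity communities over a resolution grid -> the candidate with
the best mean silhouette width in PC space wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "NormalizedMatrix",
    "ClusterAssignment",
    "qc_filter",
    "clr_normalize",
    "select_variable_genes",
    "embed_cells",
    "build_snn_graph",
    "jaccard_index",
    "cluster_cells",
    "choose_clustering",
    "annotate_clusters",
    "DEFAULT_RESOLUTIONS",
]

DEFAULT_RESOLUTIONS = tuple(np.round(np.arange(0.2, 2.01, 0.2), 2))
SNN_PRUNE = 1.0 / 15.0
ZSCORE_CLIP = 10.0


@dataclass
class QCThresholds:
    min_features: int = 200
    max_features: int = 2500
    max_mito_frac: float = 0.05
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not 0 < self.min_features < self.max_features:
            raise ValueError("need 0 < min_features < max_features")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must be in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_low_features: int
    removed_high_features: int
    removed_mito: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter(counts: CountMatrix, thresholds: QCThresholds | None = None):
    """Drop outlier cells.

    A cell is removed when its detected-feature count is strictly below
    ``min_features`` or strictly above ``max_features``, or when its
    mitochondrial count fraction strictly exceeds ``max_mito_frac``.
    Boundary cells (exactly 200 features, exactly 5% mito) are kept.
    """
    th = thresholds or QCThresholds()
    mat = counts.matrix.tocsc()
    detected = np.asarray((mat > 0).sum(axis=0)).ravel()
    totals = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    mito_mask = np.array(
        [str(g).startswith(th.mito_prefix) for g in counts.gene_ids]
    )
    mito_counts = (
        np.asarray(mat[mito_mask].sum(axis=0)).ravel().astype(float)
        if mito_mask.any()
        else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low = detected < th.min_features
    high = detected > th.max_features
    mito = mito_frac > th.max_mito_frac
    keep = ~(low | high | mito)
    report = QCReport(
        n_input=counts.n_cells,
        n_retained=int(keep.sum()),
        removed_low_features=int(low.sum()),
        removed_high_features=int(high.sum()),
        removed_mito=int(mito.sum()),
    )
    if not keep.any():
        raise ValueError(
            "QC removed every cell; review the thresholds "
            f"(min_features={th.min_features}, max_features={th.max_features}, "
            f"max_mito_frac={th.max_mito_frac})"
        )
    return counts.subset_cells(keep), report


@dataclass
class NormalizedMatrix:
    values: np.ndarray  # dense genes x cells, float
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    method: str = "clr"


def clr_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Centered log-ratio transform per cell: ln(1+x) minus the per-cell
    mean of ln(1+x) over genes. Every cell column has mean zero afterwards."""
    x = counts.matrix.toarray().astype(float)
    logx = np.log1p(x)
    y = logx - logx.mean(axis=0, keepdims=True)
    return NormalizedMatrix(y, counts.gene_ids, counts.cell_ids)


def select_variable_genes(norm: NormalizedMatrix, n_top: int = 2500) -> list:
    """Rank genes by standardized variance (variance over a running-median
    mean-variance trend); ties break by gene label. Returns top ``n_top``."""
    n_genes = norm.values.shape[0]
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds n_genes={n_genes}")
    means = norm.values.mean(axis=1)
    var = norm.values.var(axis=1, ddof=1) if norm.values.shape[1] > 1 else (
        np.zeros(n_genes)
    )
    if np.allclose(var, 0):
        raise ValueError("constant matrix: no variable genes to select")
    # robust trend: running median of variance along the mean axis
    order = np.argsort(means, kind="mergesort")
    window = max(min(n_genes // 10, 101), 5)
    trend_sorted = (
        pd.Series(var[order])
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    trend = np.empty(n_genes)
    trend[order] = trend_sorted
    trend = np.maximum(trend, 1e-12)
    std_var = var / trend
    order = sorted(range(n_genes), key=lambda i: (-std_var[i], str(norm.gene_ids[i])))
    return [norm.gene_ids[i] for i in order[:n_top]]


@dataclass
class Embedding:
    scores: np.ndarray  # cells x n_pcs
    components: np.ndarray  # n_pcs x genes, rows orthonormal
    explained_variance: np.ndarray
    cell_ids: np.ndarray


def embed_cells(norm: NormalizedMatrix, genes: list, n_pcs: int = 10) -> Embedding:
    """PCA on per-gene z-scored (clipped at +-10) values of selected genes."""
    idx = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = [idx[g] for g in genes if g in idx]
    x = norm.values[rows].T  # cells x genes
    n_cells, n_sel = x.shape
    if n_pcs > min(n_sel, n_cells):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_genes_selected={n_sel}, "
            f"n_cells={n_cells})"
        )
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = np.clip((x - mu) / sd, -ZSCORE_CLIP, ZSCORE_CLIP)
    z = z - z.mean(axis=0)  # clipping can shift the mean slightly
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    u = u * signs
    vt = vt * signs[:, None]
    scores = u[:, :n_pcs] * s[:n_pcs]
    explained = (s[:n_pcs] ** 2) / max(n_cells - 1, 1)
    return Embedding(scores, vt[:n_pcs], explained, norm.cell_ids)


def jaccard_index(a, b) -> float:
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def build_snn_graph(scores: np.ndarray, k: int = 20, prune: float = SNN_PRUNE):
    """Shared-nearest-neighbor graph: nodes are cells, edge weights are the
    Jaccard index of k-nearest-neighbor sets (each cell's set includes the
    cell itself); weights <= ``prune`` are dropped."""
    n_cells = scores.shape[0]
    if k >= n_cells:
        raise ValueError(f"k={k} must be below n_cells={n_cells}")
    nn = NearestNeighbors(n_neighbors=k).fit(scores)
    knn = nn.kneighbors(scores, return_distance=False)  # includes self (d=0)
    indicator = sp.csr_matrix(
        (
            np.ones(n_cells * k),
            (np.repeat(np.arange(n_cells), k), knn.ravel()),
        ),
        shape=(n_cells, n_cells),
    )
    inter = indicator @ indicator.T  # |A n B|
    inter = sp.coo_matrix(sp.triu(inter, k=1))
    jac = inter.data / (2.0 * k - inter.data)
    keep = jac > prune
    src, dst, w = inter.row[keep], inter.col[keep], jac[keep]
    g = ig.Graph(
        n=n_cells, edges=list(zip(src.tolist(), dst.tolist())), directed=False
    )
    g.es["weight"] = w.tolist()
    return g


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # contiguous cluster index per cell
    cell_ids: np.ndarray
    n_clusters: int
    resolution: float
    mean_silhouette: float = float("nan")

    def relabeled(self) -> np.ndarray:
        """Labels renumbered by first occurrence (order-invariant form)."""
        seen: dict = {}
        out = np.empty(len(self.labels), dtype=int)
        for i, lab in enumerate(self.labels):
            out[i] = seen.setdefault(lab, len(seen))
        return out


def cluster_cells(
    graph: ig.Graph,
    resolutions=DEFAULT_RESOLUTIONS,
    cell_ids=None,
    seed: int = 0,
) -> list:
    """Modularity community detection per resolution (Leiden, seeded)."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    cell_ids = (
        np.asarray(cell_ids, dtype=object)
        if cell_ids is not None
        else np.array([str(i) for i in range(graph.vcount())], dtype=object)
    )
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    out = []
    for r in resolutions:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=float(r),
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
        # contiguous indices from 0
        _, labels = np.unique(labels, return_inverse=True)
        out.append(
            ClusterAssignment(
                labels=labels,
                cell_ids=cell_ids,
                n_clusters=int(labels.max()) + 1,
                resolution=float(r),
            )
        )
    return out


def choose_clustering(candidates: list, scores: np.ndarray) -> ClusterAssignment:
    """Pick the candidate maximizing mean silhouette width in PC space.

    Silhouette ties (within 1e-12) resolve toward fewer clusters. Candidates
    with a single cluster cannot be scored; if none remain this errors."""
    scored = []
    for cand in candidates:
        if cand.n_clusters < 2 or cand.n_clusters >= len(cand.labels):
            continue
        sil = float(silhouette_score(scores, cand.labels, metric="euclidean"))
        cand.mean_silhouette = sil
        scored.append(cand)
    if not scored:
        raise ValueError("no candidate with >= 2 clusters to score")
    best = min(scored, key=lambda c: (-round(c.mean_silhouette, 12), c.n_clusters))
    if best.mean_silhouette < 0.3:
        warnings.warn(
            f"weak cluster structure: best mean silhouette "
            f"{best.mean_silhouette:.3f} < 0.3",
            stacklevel=2,
        )
    return best


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def annotate_clusters(
    assignment: ClusterAssignment,
    norm: NormalizedMatrix,
    markers: dict,
    q_thresh: float = 0.05,
    logfc_thresh: float = 0.25,
) -> dict:
    """Label clusters by marker-set enrichment of their upregulated genes.

    Per cluster: one-sided rank-sum test (cluster vs rest) per gene, BH q <
    ``q_thresh`` and mean-difference > ``logfc_thresh`` define the
    upregulated set; each marker set is then scored by the hypergeometric
    upper tail against the full gene universe, and the label with the
    smallest q wins (ties: larger overlap, then alphabetical). Clusters with
    no set at q < 0.05 get the label "unknown".

    ``markers``: cell type -> gene iterable (or (description, genes)).
    Returns cluster index -> dict(label, q, overlap).
    """
    if not markers:
        raise ValueError("marker collection is empty")
    universe = set(map(str, norm.gene_ids))
    clean: dict[str, frozenset] = {}
    for name, val in markers.items():
        genes = set(val[1]) if isinstance(val, tuple) else set(val)
        kept = frozenset(g for g in genes if g in universe)
        if len(kept) < len(genes):
            warnings.warn(
                f"marker set {name!r}: {len(genes) - len(kept)} genes absent "
                "from the matrix",
                stacklevel=2,
            )
        if kept:
            clean[name] = kept
    result = {}
    n_universe = len(universe)
    for c in range(assignment.n_clusters):
        in_c = assignment.labels == c
        if in_c.all() or not in_c.any():
            result[c] = {"label": "unknown", "q": 1.0, "overlap": 0}
            continue
        a, b = norm.values[:, in_c], norm.values[:, ~in_c]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = stats.mannwhitneyu(a, b, axis=1, alternative="greater")
        pvals = np.nan_to_num(stat.pvalue, nan=1.0)
        qvals = _bh_adjust(pvals)
        delta = a.mean(axis=1) - b.mean(axis=1)
        up = {
            str(norm.gene_ids[i])
            for i in np.flatnonzero((qvals < q_thresh) & (delta > logfc_thresh))
        }
        rows = []
        for name, genes in clean.items():
            k = len(up & genes)
            p = stats.hypergeom.sf(k - 1, n_universe, len(genes), len(up)) if up else 1.0
            rows.append((name, k, p))
        if rows:
            qs = _bh_adjust([r[2] for r in rows])
            scored = sorted(
                (
                    (q, -k, name)
                    for (name, k, _), q in zip(rows, qs)
                ),
            )
            q, negk, name = scored[0]
            if q < 0.05:
                result[c] = {"label": name, "q": float(q), "overlap": -negk}
                continue
        result[c] = {"label": "unknown", "q": 1.0, "overlap": 0}
    return result
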