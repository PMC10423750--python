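"""Embedding, Leiden clustering and AUC-gated subclustering.

The workflow: library-size log-normalization, highly-variable-gene
selection by standardized variance, per-gene scaling, PCA, a cosine kNN
graph, and Leiden community detection. Subclustering sweeps the Leiden
resolution upward and halts as soon as a cluster appears that has no gene
with a one-vs-rest AUC above the gate (default 0.60) — the point at which
further splits are no longer marker-supported. Near-duplicate clusters
are merged by cutting a Ward dendrogram of cluster mean-expression
profiles at a fraction of its maximum height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

import igraph as ig
import leidenalg

__all__ = [
    "EmbeddingConfig",
    "SubclusterConfig",
    "normalize_log",
    "select_hvg",
    "embed",
    "leiden",
    "cluster_max_aucs",
    "auc_gated_subcluster",
    "merge_similar_clusters",
    "signature_score",
    "screen_subclusters",
]


@dataclass
class EmbeddingConfig:
    n_hvg: int = 2000
    target_sum: float = 10_000.0
    n_pcs: int = 50
    neighbor_metric: str = "cosine"
    n_neighbors: int = 15
    scale_clip: float = 10.0
    seed: int = 0


@dataclass
class SubclusterConfig:
    auc_halt: float = 0.60
    resolution_start: float = 0.05
    resolution_step: float = 0.05
    resolution_max: float = 1.0
    merge_fraction: float = 0.25
    halt_return: str = "previous"  # or "current"
    seed: int = 0

    def __post_init__(self):
        if not 0.5 <= self.auc_halt <= 1.0:
            raise ValueError("auc_halt must be in [0.5, 1]")
        if not 0.0 < self.merge_fraction < 1.0:
            raise ValueError("merge_fraction must be in (0, 1)")


def normalize_log(counts, target_sum: float = 10_000.0):
    """Scale each nucleus to ``target_sum`` total counts, then log1p."""
    X = sp.csr_matrix(counts, dtype=float)
    tot = np.asarray(X.sum(axis=1)).ravel()
    if (tot <= 0).any():
        raise ValueError("zero-count nucleus cannot be normalized")
    out = sp.diags(target_sum / tot) @ X
    out.data = np.log1p(out.data)
    return out.tocsr()


def select_hvg(counts, n: int) -> np.ndarray:
    """Top-n highly variable genes by standardized variance.

    Per-gene variance of raw counts is compared against a quadratic
    mean-variance trend fitted in log10 space; genes are ranked by the
    ratio observed/expected variance. Constant genes are never selected.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    X = sp.csr_matrix(counts, dtype=float)
    n_obs, n_genes = X.shape
    if n > n_genes:
        raise ValueError("n exceeds the number of genes")
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    var *= n_obs / max(n_obs - 1, 1)
    # guard against floating residue making constant genes look variable
    usable = (mean > 0) & (var > 1e-10 * np.maximum(mean**2, 1e-30))
    score = np.full(n_genes, -np.inf)
    lm, lv = np.log10(mean[usable]), np.log10(var[usable])
    if usable.sum() >= 3:
        coef = np.polyfit(lm, lv, deg=2)
        expected = 10 ** np.polyval(coef, lm)
        score[usable] = var[usable] / expected
    else:
        score[usable] = var[usable]
    order = np.argsort(score)[::-1]
    return np.sort(order[:n])


def embed(log_matrix, config: EmbeddingConfig | None = None, batch_align=None):
    """Per-gene standardization then PCA; optional batch-alignment hook.

    ``batch_align`` is an optional callable ``(coords) -> coords`` applied
    to the principal-component coordinates (e.g. an external integration
    method); identity by default.
    """
    config = config or EmbeddingConfig()
    X = np.asarray(
        log_matrix.todense() if sp.issparse(log_matrix) else log_matrix, dtype=float
    )
    if config.n_pcs > min(X.shape):
        raise ValueError("n_pcs larger than the matrix allows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -config.scale_clip, config.scale_clip)
    coords = PCA(
        n_components=config.n_pcs, svd_solver="full", random_state=config.seed
    ).fit_transform(Z)
    if batch_align is not None:
        coords = batch_align(coords)
    return coords


def knn_graph(coords, metric: str = "cosine", n_neighbors: int = 15) -> ig.Graph:
    """Symmetrized (union) kNN graph with similarity edge weights."""
    n = coords.shape[0]
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be below the number of nuclei")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric=metric).fit(coords)
    dist, idx = nn.kneighbors(coords)
    edges, weights = {}, {}
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            key = (i, j) if i < j else (j, i)
            w = max(1.0 - d, 1e-9) if metric == "cosine" else 1.0 / (1.0 + d)
            weights[key] = max(weights.get(key, 0.0), w)
    edges = list(weights)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = [weights[e] for e in edges]
    return g


def leiden(
    coords,
    metric: str = "cosine",
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    graph: ig.Graph | None = None,
) -> np.ndarray:
    """Leiden community labels on the kNN graph of an embedding."""
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if graph is None:
        graph = knn_graph(coords, metric=metric, n_neighbors=n_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership)


def cluster_max_aucs(ranks: np.ndarray, labels: np.ndarray) -> dict:
    """Max one-vs-rest gene AUC per cluster from precomputed midranks.

    ``ranks`` is nuclei x genes, each column midranked over all nuclei;
    the Mann-Whitney identity AUC = (R1 - n1(n1+1)/2) / (n1 n2) then needs
    only per-cluster rank sums.
    """
    n = ranks.shape[0]
    out = {}
    for lab in np.unique(labels):
        mask = labels == lab
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 == 0 or n2 == 0:
            out[lab] = np.nan
            continue
        r1 = ranks[mask].sum(axis=0)
        auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
        out[lab] = float(auc.max())
    return out


def _emergent_failures(
    X: np.ndarray, prev_labels: np.ndarray, labels: np.ndarray, auc_halt: float
) -> list:
    """Newly emerged clusters with no within-parent marker above the gate.

    Each current cluster is assigned to the previous-resolution cluster it
    overlaps most (its parent). A cluster that shares its parent with
    siblings must show a gene separating it from those siblings (max
    one-vs-rest AUC within the parent's nuclei above ``auc_halt``);
    comparing against the full dataset instead would let a split inherit
    its parent's own markers and the gate would never close.
    """
    labs = np.unique(labels)
    parents = {}
    for lab in labs:
        mask = labels == lab
        vals, counts = np.unique(prev_labels[mask], return_counts=True)
        parents[lab] = vals[np.argmax(counts)]
    failing = []
    for parent in np.unique(list(parents.values())):
        children = [lab for lab in labs if parents[lab] == parent]
        if len(children) < 2:
            continue
        fam = np.isin(labels, children)
        ranks = rankdata(X[fam], axis=0, method="average")
        fam_labels = labels[fam]
        aucs = cluster_max_aucs(ranks, fam_labels)
        failing.extend(lab for lab, a in aucs.items() if a <= auc_halt)
    return failing


def auc_gated_subcluster(
    coords,
    log_expr,
    config: SubclusterConfig | None = None,
    metric: str = "cosine",
    n_neighbors: int = 15,
) -> np.ndarray:
    """Resolution sweep with the marker-AUC halt rule.

    Leiden is run at increasing resolutions. Whenever the partition gains
    clusters, each newly emerged cluster is checked for a marker gene
    separating it from its sibling clusters within the same parent; when
    some new cluster has no gene with AUC above ``auc_halt``, the sweep
    stops and (by default) the previous resolution's labels are returned.
    Single-cluster solutions are passed over without a check.
    """
    config = config or SubclusterConfig()
    X = np.asarray(log_expr.todense() if sp.issparse(log_expr) else log_expr, dtype=float)
    graph = knn_graph(coords, metric=metric, n_neighbors=n_neighbors)

    prev = None
    res = config.resolution_start
    labels = np.zeros(coords.shape[0], dtype=int)
    while res <= config.resolution_max + 1e-9:
        labels = leiden(coords, resolution=res, seed=config.seed, graph=graph)
        if len(np.unique(labels)) > 1:
            parent = prev if prev is not None else np.zeros(len(labels), dtype=int)
            failing = _emergent_failures(X, parent, labels, config.auc_halt)
            if failing:
                if config.halt_return == "previous" and prev is not None:
                    return prev
                if config.halt_return == "current":
                    out = labels.copy()
                    out[np.isin(labels, failing)] = -1
                    return out
                return labels
        prev = labels
        res += config.resolution_step
    return labels


def subcluster_pipeline(
    coords,
    log_expr,
    config: SubclusterConfig | None = None,
    metric: str = "cosine",
    n_neighbors: int = 15,
) -> np.ndarray:
    """AUC-gated resolution sweep followed by the Ward merge rule.

    The sweep can leave redundant splits (e.g. detection blobs of one
    rare transcript) whose mean profiles are nearly identical to their
    parent; merging clusters closer than ``merge_fraction`` times the
    maximum dendrogram height collapses them.
    """
    config = config or SubclusterConfig()
    labels = auc_gated_subcluster(
        coords, log_expr, config, metric=metric, n_neighbors=n_neighbors
    )
    X = np.asarray(log_expr.todense() if sp.issparse(log_expr) else log_expr, dtype=float)
    means = pd.DataFrame(X).groupby(labels).mean()
    mapping = merge_similar_clusters(means, config.merge_fraction)
    return mapping.loc[labels].to_numpy()


def merge_similar_clusters(
    cluster_means: pd.DataFrame,
    merge_fraction: float = 0.25,
    distance: str = "height",
) -> pd.Series:
    """Merge clusters by cutting a Ward dendrogram of mean profiles.

    The cut threshold is ``merge_fraction`` times the maximum inter-cluster
    distance — by default the dendrogram's maximum linkage height
    (``distance="height"``), alternatively the maximum pairwise centroid
    distance (``distance="centroid"``). Returns a mapping from input
    cluster label to merged label.
    """
    labels = cluster_means.index
    if len(labels) < 2:
        return pd.Series(np.zeros(len(labels), dtype=int), index=labels)
    Z = linkage(cluster_means.to_numpy(), method="ward", metric="euclidean")
    if distance == "height":
        max_d = Z[:, 2].max()
    elif distance == "centroid":
        max_d = pdist(cluster_means.to_numpy()).max()
    else:
        raise ValueError("distance must be 'height' or 'centroid'")
    merged = fcluster(Z, t=merge_fraction * max_d, criterion="distance") - 1
    return pd.Series(merged, index=labels)


def signature_score(
    log_matrix,
    gene_names,
    gene_set,
    n_bins: int = 25,
    n_control: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Gene-set signature score: mean set expression minus mean expression
    of expression-bin-matched control genes (scanpy's score_genes)."""
    import anndata as ad
    import scanpy as sc

    gene_names = pd.Index(gene_names)
    present = [g for g in dict.fromkeys(gene_set) if g in gene_names]
    if not present:
        raise ValueError("gene_set shares no genes with the matrix")
    adata = ad.AnnData(
        X=sp.csr_matrix(log_matrix, dtype=np.float32),
        var=pd.DataFrame(index=gene_names),
    )
    # with few genes, fine bins leave no controls in the set genes' bins
    n_bins = max(1, min(n_bins, len(gene_names) // 2))
    sc.tl.score_genes(
        adata,
        present,
        ctrl_size=n_control,
        n_bins=n_bins,
        random_state=seed,
        score_name="score",
    )
    return adata.obs["score"].to_numpy()


def screen_subclusters(
    sub_labels,
    own_type,
    type_scores: pd.DataFrame,
    mt_scores=None,
    mt_fence: float | None = None,
    fence_multiplier: float = 1.5,
) -> set:
    """Remove misclassified or low-quality subclusters by signature scores.

    A subcluster is removed when its median score for some foreign global
    type exceeds its median own-type score, or when its median
    mitochondrial score exceeds the fence (an absolute ``mt_fence``, or by
    default the upper Tukey fence over subcluster mitochondrial medians).
    ``own_type`` is either one global type for all subclusters or a
    mapping subcluster -> type.
    """
    sub_labels = pd.Series(np.asarray(sub_labels))
    subs = [s for s in pd.unique(sub_labels)]
    if not subs:
        return set()
    removed = set()
    med = type_scores.groupby(sub_labels.to_numpy()).median()
    for s in subs:
        t = own_type[s] if isinstance(own_type, dict) else own_type
        row = med.loc[s]
        foreign = row.drop(labels=[t])
        if len(foreign) and foreign.max() > row[t]:
            removed.add(s)
    if mt_scores is not None:
        mt_med = pd.Series(np.asarray(mt_scores)).groupby(sub_labels.to_numpy()).median()
        if mt_fence is None:
            if len(mt_med) >= 2:
                q1, q3 = np.quantile(mt_med, [0.25, 0.75])
                mt_fence = q3 + fence_multiplier * (q3 - q1)
            else:
                mt_fence = np.inf
        removed.update(mt_med.index[mt_med > mt_fence])
    return removed
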