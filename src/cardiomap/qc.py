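"""Per-nucleus QC metrics and the cluster-aware outlier-removal cascade.

Seven metrics are carried per nucleus: total UMI, detected genes,
mitochondrial fraction, exonic-read fraction, count entropy, a simulated
doublet score and the composite log(n_genes) x entropy. Removal happens in
stages: clusters whose median metrics are outlying are dropped wholesale,
then within each (sample, cluster) group nuclei outside Tukey fences
(Q1 - 1.5 IQR, Q3 + 1.5 IQR) on each metric are removed; groups too small
for stable quartiles fall back to fixed hard thresholds.

The entropy here is the plugin (maximum-likelihood) estimator in nats, and
the doublet score the fraction of simulated-doublet neighbors in a joint
PCA embedding — deliberately simple stand-ins for heavier published
estimators; their thresholds are parameters for exactly that reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "HardThresholds",
    "IQRRules",
    "plugin_entropy",
    "row_entropies",
    "doublet_score",
    "compute_qc",
    "quartiles",
    "iqr_filter",
    "flag_bad_clusters",
    "qc_cascade",
    "stage_summary",
]

#: metric -> fence direction, following the numbered outlier rule list:
#: two-sided where nuclei can fail low or high, upper-only otherwise.
IQR_DIRECTIONS = {
    "n_umi": "two-sided",
    "n_genes": "two-sided",
    "pct_mt": "upper",
    "entropy": "two-sided",
    "exon_prop": "upper",
    "doublet_score": "upper",
    "composite": "upper",
}


@dataclass
class HardThresholds:
    """Fixed per-metric bounds used when a (sample, cluster) group is too
    small for quartile fences. Defaults are the published values; note
    ``entropy_min`` presumes a particular estimator's scale and should be
    recalibrated when the estimator (or gene universe) changes."""

    n_umi_min: float = 150
    n_umi_max: float = 15000
    n_genes_min: float = 150
    n_genes_max: float = 6000
    pct_mt_max: float = 0.05
    entropy_min: float = 8.0
    exon_prop_max: float = 0.18
    doublet_max: float = 0.30
    composite_max: float = 75.0

    def __post_init__(self):
        if self.n_umi_min >= self.n_umi_max or self.n_genes_min >= self.n_genes_max:
            raise ValueError("min must be below max for paired bounds")

    def pass_mask(self, qc: pd.DataFrame) -> np.ndarray:
        ok = (
            (qc["n_umi"] >= self.n_umi_min)
            & (qc["n_umi"] <= self.n_umi_max)
            & (qc["n_genes"] >= self.n_genes_min)
            & (qc["n_genes"] <= self.n_genes_max)
            & (qc["pct_mt"] <= self.pct_mt_max)
            & (qc["entropy"] >= self.entropy_min)
            & (qc["exon_prop"] <= self.exon_prop_max)
            & (qc["doublet_score"] <= self.doublet_max)
            & (qc["composite"] <= self.composite_max)
        )
        return ok.to_numpy()


@dataclass
class IQRRules:
    """Tukey-fence settings for the per-(sample, cluster) outlier pass."""

    multiplier: float = 1.5
    min_group_size: int = 30
    directions: dict = field(default_factory=lambda: dict(IQR_DIRECTIONS))

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        unknown = set(self.directions) - set(IQR_DIRECTIONS)
        if unknown:
            raise ValueError(f"unknown metrics in rules: {sorted(unknown)}")


def plugin_entropy(count_vector) -> float:
    """Plugin (maximum-likelihood) entropy of a count vector, in nats."""
    c = np.asarray(count_vector, dtype=float)
    if c.sum() <= 0:
        raise ValueError("entropy undefined for an all-zero vector")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def row_entropies(counts: sp.spmatrix) -> np.ndarray:
    """Plugin entropy per row of a sparse count matrix (nats)."""
    X = sp.csr_matrix(counts, dtype=float)
    tot = np.asarray(X.sum(axis=1)).ravel()
    if (tot <= 0).any():
        raise ValueError("entropy undefined for all-zero nuclei")
    # sum c*log c per row, then H = log(tot) - (1/tot) * sum c log c
    clogc = X.copy()
    clogc.data = X.data * np.log(X.data)
    s = np.asarray(clogc.sum(axis=1)).ravel()
    return np.log(tot) - s / tot


def doublet_score(
    counts,
    k_neighbors: int | None = None,
    n_simulated: int | None = None,
    seed: int = 0,
    n_pcs: int = 30,
) -> np.ndarray:
    """Simulated-doublet k-nearest-neighbor score per nucleus.

    Artificial doublets are sums of random observed pairs; observed and
    simulated profiles are log-normalized and embedded in one PCA space,
    and each observed nucleus is scored by the fraction of its k nearest
    neighbors (excluding itself) that are simulated. By default k follows
    the usual kNN-classifier scaling, round(0.5 * sqrt(n)) expanded by the
    simulated:observed ratio, which keeps the score finely enough grained
    for downstream distribution-based fences.
    """
    X = sp.csr_matrix(counts, dtype=float)
    n = X.shape[0]
    if n_simulated is None:
        n_simulated = n
    if k_neighbors is None:
        k_neighbors = max(int(round(0.5 * np.sqrt(n) * (1.0 + n_simulated / n))), 1)
    if n_simulated < k_neighbors:
        raise ValueError("n_simulated must be at least k_neighbors")
    if n <= k_neighbors:
        raise ValueError("fewer nuclei than k_neighbors")
    rng = np.random.default_rng(seed)
    # Oversample candidate pairs and keep the most dissimilar parents:
    # near-duplicate parents give simulated profiles indistinguishable
    # from singlets, which only dilutes the score. Dissimilarity is
    # measured on log-normalized profiles in a coarse PCA space.
    n_cand = 3 * n_simulated
    i1 = rng.integers(0, n, size=n_cand)
    i2 = rng.integers(0, n, size=n_cand)
    tot_obs = np.asarray(X.sum(axis=1)).ravel()
    tot_obs[tot_obs == 0] = 1.0
    ln = sp.diags(1e4 / tot_obs) @ X
    ln.data = np.log1p(ln.data)
    obs_pc = PCA(n_components=min(10, min(X.shape) - 1),
                 svd_solver="randomized", random_state=seed).fit_transform(
        np.asarray(ln.todense()))
    gap = np.linalg.norm(obs_pc[i1] - obs_pc[i2], axis=1)
    keep = np.argsort(gap)[::-1][:n_simulated]
    i1, i2 = i1[keep], i2[keep]
    sim = X[i1] + X[i2]

    both = sp.vstack([X, sim]).tocsr()
    tot = np.asarray(both.sum(axis=1)).ravel()
    tot[tot == 0] = 1.0
    norm = sp.diags(1e4 / tot) @ both
    norm.data = np.log1p(norm.data)
    dense = np.asarray(norm.todense())
    dense -= dense.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, min(dense.shape) - 1)
    coords = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed).fit_transform(dense)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords[:n])
    idx = idx[:, 1:]  # drop self (an observed point is its own nearest neighbor)
    return (idx >= n).mean(axis=1)


def compute_qc(
    bundle,
    clusters,
    doublet_scores=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the per-nucleus QC table from a count bundle.

    ``clusters`` is a label per nucleus (a single global label is fine).
    ``doublet_scores`` may be precomputed; otherwise :func:`doublet_score`
    is run with defaults.
    """
    X = bundle.raw_counts
    if "mitochondrial" not in bundle.gene_meta:
        raise ValueError("gene_meta lacks mitochondrial flags")
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mt = bundle.gene_meta["mitochondrial"].to_numpy()
    mt_umi = np.asarray(X[:, mt].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        pct_mt = np.where(n_umi > 0, mt_umi / np.maximum(n_umi, 1), 0.0)
    entropy = row_entropies(X)
    if doublet_scores is None:
        doublet_scores = doublet_score(X, seed=seed)
    qc = pd.DataFrame(
        {
            "n_umi": n_umi,
            "n_genes": n_genes,
            "pct_mt": pct_mt,
            "exon_prop": bundle.nucleus_meta["exon_prop"].to_numpy(),
            "entropy": entropy,
            "doublet_score": np.asarray(doublet_scores),
            "cluster": np.asarray(clusters),
            "sample": bundle.nucleus_meta["sample"].to_numpy(),
        },
        index=bundle.barcodes,
    )
    qc["composite"] = np.log(np.maximum(qc["n_genes"], 1)) * qc["entropy"]
    qc["pass"] = True
    return qc


def quartiles(values) -> tuple:
    """(Q1, Q3) by linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return tuple(np.quantile(v, [0.25, 0.75]))


def _hard_bounds(hard: HardThresholds) -> dict:
    return {
        "n_umi": (hard.n_umi_min, hard.n_umi_max),
        "n_genes": (hard.n_genes_min, hard.n_genes_max),
        "pct_mt": (-np.inf, hard.pct_mt_max),
        "entropy": (hard.entropy_min, np.inf),
        "exon_prop": (-np.inf, hard.exon_prop_max),
        "doublet_score": (-np.inf, hard.doublet_max),
        "composite": (-np.inf, hard.composite_max),
    }


def iqr_filter(
    qc: pd.DataFrame,
    rules: IQRRules | None = None,
    hard: HardThresholds | None = None,
) -> pd.Series:
    """Per-(sample, cluster) Tukey-fence pass mask, hard-threshold fallback.

    Fences are computed once from the full group (single pass; the filter
    is not re-applied to its own survivors). Groups below
    ``min_group_size`` use the hard thresholds for every metric. A metric
    whose group IQR collapses to zero while values still differ (heavily
    quantized scores) also falls back to its hard bound — a zero-width
    fence would otherwise reject any nucleus off the modal value; a group
    constant on a metric keeps all its nuclei (they sit on the fence).
    """
    rules = rules or IQRRules()
    hard = hard or HardThresholds()
    bounds = _hard_bounds(hard)
    ok = np.ones(len(qc), dtype=bool)
    for _, g in qc.groupby(["sample", "cluster"], sort=False, observed=True):
        pos = qc.index.get_indexer(g.index)
        if len(g) < rules.min_group_size:
            ok[pos] &= hard.pass_mask(g)
            continue
        for metric, direction in rules.directions.items():
            vals = g[metric].to_numpy(dtype=float)
            q1, q3 = quartiles(vals)
            iqr = q3 - q1
            if iqr == 0 and (vals != vals[0]).any():
                lo, hi = bounds[metric]
            else:
                hi = q3 + rules.multiplier * iqr
                lo = q1 - rules.multiplier * iqr
            bad = vals > hi
            if direction == "two-sided":
                bad |= vals < lo
            ok[pos] &= ~bad
    return pd.Series(ok, index=qc.index, name="pass")


def _weighted_quartiles(values: np.ndarray, weights: np.ndarray) -> tuple:
    order = np.argsort(values)
    v, w = values[order], weights[order].astype(float)
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return tuple(np.interp([0.25, 0.75], cum, v))


def flag_bad_clusters(
    qc: pd.DataFrame,
    multiplier: float = 1.5,
    metrics=("pct_mt", "exon_prop", "doublet_score", "entropy"),
    weight_by_size: bool = True,
) -> set:
    """Flag whole clusters whose median QC metrics are outlying.

    A cluster is flagged when its median pct_mt, exon_prop or doublet_score
    exceeds the upper Tukey fence of the cluster-median distribution, or
    its median entropy falls below the lower fence. (The published rule is
    qualitative — "elevated levels" — so a median-of-medians fence stands
    in; the multiplier is configurable.) By default each cluster's median
    is weighted by cluster size when forming the fence, so that many small
    artifact clusters cannot drag the fence up to their own level;
    ``weight_by_size=False`` gives the unweighted variant.
    """
    med = qc.groupby("cluster", observed=True)[list(metrics)].median()
    sizes = qc.groupby("cluster", observed=True).size().to_numpy()
    if len(med) < 2:
        raise ValueError("need at least 2 clusters")
    flagged = set()
    for metric in metrics:
        vals = med[metric].to_numpy(dtype=float)
        if weight_by_size:
            q1, q3 = _weighted_quartiles(vals, sizes)
        else:
            q1, q3 = quartiles(vals)
        iqr = q3 - q1
        if metric == "entropy":
            bad = med.index[vals < q1 - multiplier * iqr]
        else:
            bad = med.index[vals > q3 + multiplier * iqr]
        flagged.update(bad)
    return flagged


def stage_summary(stages: list, n_initial: int) -> pd.DataFrame:
    """Bookkeeping of a staged removal cascade.

    ``stages`` is a list of (label, n_removed); returns cumulative counts
    with each stage's removal as a percentage of the initial total.
    """
    rows, remaining = [], n_initial
    for label, removed in stages:
        remaining -= removed
        rows.append((label, removed, 100.0 * removed / n_initial, remaining))
    return pd.DataFrame(
        rows, columns=["stage", "n_removed", "pct_of_initial", "n_remaining"]
    )


def qc_cascade(
    bundle,
    clusters,
    rules: IQRRules | None = None,
    hard: HardThresholds | None = None,
    doublet_scores=None,
    seed: int = 0,
):
    """Full cascade: cluster-level flagging then per-group outlier fences.

    Returns (qc_table_with_pass_column, stage_summary DataFrame).
    """
    qc = compute_qc(bundle, clusters, doublet_scores=doublet_scores, seed=seed)
    n0 = len(qc)
    flagged = flag_bad_clusters(qc)
    cluster_pass = ~qc["cluster"].isin(flagged)
    survivors = qc[cluster_pass]
    fence_pass = iqr_filter(survivors, rules=rules, hard=hard)
    qc["pass"] = cluster_pass & fence_pass.reindex(qc.index, fill_value=False)
    stages = [
        ("cluster_screen", int((~cluster_pass).sum())),
        ("iqr_fences", int((~fence_pass).sum())),
    ]
    return qc, stage_summary(stages, n0)
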