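"""Marker statistics and pseudobulk differential expression.

Nucleus counts are summed per (cell type, sample) and treated as bulk
RNA-seq so that the patient, not the nucleus, is the unit of replication.
Genes are prefiltered (prevalence, low counts, mitochondrial/ribosomal),
columns are normalized with median-of-ratios size factors, and per-gene
effects are estimated by ordinary least squares on log2-CPM with the
stated covariates (condition + age + sex, optionally a study indicator),
empirical-Bayes variance moderation across genes, and Benjamini-Hochberg
adjustment within each contrast. The engine does not reproduce any
particular bulk DE tool's numerics (no precision weights); what is
validated downstream is calibration (type-I error) and recovery of
planted effects, and ``moderated=False`` falls back to plain OLS.

Markers combine a rank-based one-vs-rest AUC with a pseudobulk
one-vs-rest contrast from a no-intercept cluster + individual model, and
are selected by tiered thresholds (AUC, adjusted p, logFC, fraction of
nuclei expressing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import special, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PseudobulkMatrix",
    "MarkerCriteria",
    "auc_one_vs_rest",
    "pct_expressed",
    "pseudobulk",
    "prefilter_genes",
    "size_factors",
    "fit_de",
    "concordance_filter",
    "fibrosis_association",
    "ovr_marker_de",
    "select_markers",
    "patient_pca",
    "bh_adjust",
]

MT_PREFIXES = ("MT-",)
RIBO_PREFIXES = ("RPS", "RPL")


@dataclass
class PseudobulkMatrix:
    """Genes x (cell_type, sample) summed counts plus column annotations."""

    counts: pd.DataFrame        # index: gene ids; columns: column ids
    col_meta: pd.DataFrame      # index: column ids; cell_type, sample, n_nuclei, condition, ...

    def __post_init__(self):
        if not self.counts.columns.equals(self.col_meta.index):
            raise ValueError("counts columns and col_meta index differ")

    def subset(self, cell_type: str) -> "PseudobulkMatrix":
        cols = self.col_meta.index[self.col_meta["cell_type"] == cell_type]
        return PseudobulkMatrix(self.counts[cols], self.col_meta.loc[cols])


@dataclass
class MarkerCriteria:
    auc_min: float = 0.60
    adj_p_max: float = 0.01
    logfc_min: float = 2.0
    pct_min: float = 0.25

    def __post_init__(self):
        if not 0.0 <= self.pct_min <= 1.0:
            raise ValueError("pct_min must be in [0, 1]")

    @classmethod
    def global_preset(cls) -> "MarkerCriteria":
        return cls(0.60, 0.01, 2.0, 0.25)

    @classmethod
    def subcluster_preset(cls) -> "MarkerCriteria":
        return cls(0.50, 0.01, 0.0, 0.15)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def auc_one_vs_rest(expr, in_cluster) -> np.ndarray:
    """Rank-based one-vs-rest AUC per gene (midrank tie handling).

    ``expr`` is nuclei x genes (or a single vector); the AUC is the
    Mann-Whitney U of the in-cluster group over U_max, i.e. the
    probability that an in-cluster nucleus expresses the gene more highly
    than an out-of-cluster one (ties counted half).
    """
    mask = np.asarray(in_cluster, dtype=bool)
    X = np.asarray(expr.todense() if sp.issparse(expr) else expr, dtype=float)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[:, None]
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(X, axis=0, method="average")
    r1 = ranks[mask].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    return float(auc[0]) if one_dim else auc


def pct_expressed(counts, mask=None) -> np.ndarray:
    """Fraction of (selected) nuclei with count > 0, per gene."""
    X = sp.csr_matrix(counts)
    if mask is not None:
        X = X[np.asarray(mask, dtype=bool)]
    if X.shape[0] == 0:
        raise ValueError("empty nucleus selection")
    return np.asarray((X > 0).mean(axis=0)).ravel()


def sample_table(nucleus_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample metadata (condition, age, sex, ...) from per-nucleus rows."""
    keep = [c for c in ("condition", "age", "sex", "study", "fibrosis_pct")
            if c in nucleus_meta.columns]
    return nucleus_meta.groupby("sample", observed=True)[keep].first()


def pseudobulk(
    counts,
    celltype_labels,
    sample_labels,
    min_nuclei: int = 25,
    gene_ids=None,
    sample_meta: pd.DataFrame | None = None,
) -> PseudobulkMatrix:
    """Sum counts per (cell type, sample); drop columns below ``min_nuclei``."""
    X = sp.csr_matrix(counts)
    ct = pd.Series(np.asarray(celltype_labels))
    sm = pd.Series(np.asarray(sample_labels))
    if len(ct) != X.shape[0] or len(sm) != X.shape[0]:
        raise ValueError("labels not aligned to nuclei")
    if gene_ids is None:
        gene_ids = pd.Index([f"G{i:05d}" for i in range(X.shape[1])])
    key = ct.astype(str) + "|" + sm.astype(str)
    codes, uniques = pd.factorize(key)
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(len(uniques), len(codes)),
    )
    sums = np.asarray((ind @ X).todense())
    n_nuc = np.bincount(codes, minlength=len(uniques))
    meta = pd.DataFrame(
        [u.split("|", 1) for u in uniques], columns=["cell_type", "sample"]
    )
    meta["n_nuclei"] = n_nuc
    meta.index = pd.Index(uniques, name="column")
    if sample_meta is not None:
        meta = meta.join(sample_meta, on="sample")
    keep = meta["n_nuclei"] >= min_nuclei
    if not keep.any():
        raise ValueError("no pseudobulk column meets min_nuclei")
    cdf = pd.DataFrame(sums.T, index=gene_ids, columns=meta.index)
    return PseudobulkMatrix(cdf.loc[:, keep], meta.loc[keep])


def prefilter_genes(
    counts,
    group_masks: dict,
    gene_meta: pd.DataFrame | None = None,
    gene_ids=None,
    pseudobulk_counts: pd.DataFrame | None = None,
    min_pct: float = 0.01,
    min_count: int = 10,
    min_samples: int | None = None,
) -> pd.Index:
    """Genes eligible for DE testing.

    Drops genes expressed in fewer than ``min_pct`` of nuclei in *every*
    group (a gene prevalent in either group alone is kept), genes failing
    the low-count rule on pseudobulk sums (at least ``min_count`` summed
    counts in at least ``min_samples`` columns — the smaller group size by
    default), and genes flagged mitochondrial or ribosomal by annotation
    or symbol prefix.
    """
    if not group_masks or any(not np.any(m) for m in group_masks.values()):
        raise ValueError("group masks must be non-empty")
    X = sp.csr_matrix(counts)
    if gene_ids is None:
        gene_ids = (
            gene_meta.index if gene_meta is not None
            else pd.Index([f"G{i:05d}" for i in range(X.shape[1])])
        )
    pcts = np.vstack([pct_expressed(X, m) for m in group_masks.values()])
    keep = (pcts >= min_pct).any(axis=0)

    if pseudobulk_counts is not None:
        if min_samples is None:
            min_samples = max(int(min(np.sum(m) for m in group_masks.values())), 1)
            min_samples = min(min_samples, pseudobulk_counts.shape[1])
        enough = (pseudobulk_counts.reindex(gene_ids).fillna(0) >= min_count).sum(axis=1)
        keep &= (enough >= min_samples).to_numpy()

    if gene_meta is not None:
        sym = gene_meta["symbol"].astype(str)
        mito = gene_meta.get("mitochondrial", pd.Series(False, index=gene_meta.index))
        ribo = gene_meta.get("ribosomal", pd.Series(False, index=gene_meta.index))
        bad = (
            mito.to_numpy()
            | ribo.to_numpy()
            | sym.str.startswith(MT_PREFIXES).to_numpy()
            | sym.str.startswith(RIBO_PREFIXES).to_numpy()
        )
        keep &= ~bad
    return pd.Index(gene_ids)[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes positive in all columns)."""
    M = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(M)
    ref = logs.mean(axis=1)  # log geometric mean across columns
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError("no gene is positive in all columns")
    ratios = logs[usable] - ref[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _log2_cpm(counts: pd.DataFrame, sf: pd.Series) -> np.ndarray:
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    cpm = norm / norm.sum(axis=0, keepdims=True) * 1e6
    return np.log2(cpm + 0.5)


def _design_matrix(meta: pd.DataFrame, condition_col: str, covariates) -> tuple:
    """Intercept + treatment-coded condition + covariates. Returns (X, names).

    Covariate columns that add no information on the available samples
    (constant, or collinear with columns already in the design) are
    dropped; intercept and condition columns are mandatory.
    """
    levels = list(pd.unique(meta[condition_col]))
    cols = [np.ones(len(meta))]
    names = ["Intercept"]
    for lev in levels[1:]:
        cols.append((meta[condition_col] == lev).to_numpy(float))
        names.append(f"{condition_col}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    for cov in covariates:
        v = meta[cov]
        cands = []
        if v.dtype.kind in "ifu":
            x = v.to_numpy(float)
            sd = x.std()
            if sd > 0:
                cands.append(((x - x.mean()) / sd, cov))
        else:
            for lev in list(pd.unique(v))[1:]:
                cands.append(((v == lev).to_numpy(float), f"{cov}[{lev}]"))
        for col, name in cands:
            trial = np.column_stack([X, col])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                X = trial
                names.append(name)
    return X, names, levels


def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple:
    """Empirical-Bayes shrinkage of per-gene variances toward a common
    prior (the moderated-statistics recipe: fit a scaled F prior to the
    observed variances by moments on the log scale, then posterior-average
    with prior df). Returns (posterior variances, prior df)."""
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        d0 = np.inf
        s0 = np.exp(e_mean)
        return np.full_like(s2, s0), d0
    d0 = 2.0 * _inv_trigamma(e_var)
    s0 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0


def _ols_contrast(
    Y: np.ndarray, X: np.ndarray, c: np.ndarray, moderated: bool = True
) -> tuple:
    """Vectorized per-gene OLS; effect and two-sided p for contrast c.

    Y is genes x samples, X samples x params. With ``moderated=True``
    residual variances are shrunk across genes before the t-test and the
    residual degrees of freedom gain the prior df.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    if n <= p:
        raise ValueError("not enough samples for the design")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T                      # p x n
    B = Y @ H.T                            # genes x p
    resid = Y - B @ X.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    if moderated and len(sigma2) >= 10:
        sigma2, d0 = _squeeze_var(sigma2, df)
        df_total = df + (d0 if np.isfinite(d0) else 1e6)
    else:
        df_total = df
    cvar = float(c @ XtX_inv @ c)
    eff = B @ c
    se = np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
    t = eff / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    return eff, pvals


def fit_de(
    pb: PseudobulkMatrix,
    contrast: tuple,
    condition_col: str = "condition",
    covariates: tuple = ("age", "sex"),
    min_samples_per_group: int = 3,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-cell-type pseudobulk DE for one pairwise contrast.

    Returns a tidy frame (gene, cell_type, contrast, logFC, p, adj_p);
    logFC is log2, positive when the first contrast level is higher. Cell
    types with fewer than ``min_samples_per_group`` samples in either
    contrasted group are skipped. BH adjustment is within cell type and
    contrast.
    """
    a, b = contrast
    out = []
    for ct in pd.unique(pb.col_meta["cell_type"]):
        sub = pb.subset(ct)
        meta = sub.col_meta
        n_a = int((meta[condition_col] == a).sum())
        n_b = int((meta[condition_col] == b).sum())
        if n_a < min_samples_per_group or n_b < min_samples_per_group:
            continue
        counts = sub.counts if genes is None else sub.counts.loc[
            sub.counts.index.intersection(genes)
        ]
        sf = size_factors(counts)
        Y = _log2_cpm(counts, sf)
        X, names, _ = _design_matrix(meta, condition_col, covariates)
        c = np.zeros(X.shape[1])
        for lev, sign in ((a, 1.0), (b, -1.0)):
            name = f"{condition_col}[{lev}]"
            if name in names:
                c[names.index(name)] = sign
        eff, pvals = _ols_contrast(Y, X, c)
        out.append(
            pd.DataFrame(
                {
                    "gene": counts.index,
                    "cell_type": ct,
                    "contrast": f"{a}_vs_{b}",
                    "logFC": eff,
                    "p": pvals,
                    "adj_p": bh_adjust(pvals),
                }
            )
        )
    if not out:
        raise ValueError("no cell type has enough samples in both groups")
    return pd.concat(out, ignore_index=True)


def concordance_filter(
    results_corrected: pd.DataFrame,
    results_raw: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes significant (adj_p < alpha) with the same sign in both runs.

    The two result frames must cover the same (gene, cell_type, contrast)
    universe; rows of the corrected-count results are returned.
    """
    keys = ["gene", "cell_type", "contrast"]
    a = results_corrected.set_index(keys)
    b = results_raw.set_index(keys)
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("mismatched gene universes between the two runs")
    b = b.loc[a.index]
    sig = (
        (a["adj_p"] < alpha)
        & (b["adj_p"] < alpha)
        & (np.sign(a["logFC"]) == np.sign(b["logFC"]))
    )
    return a[sig.to_numpy()].reset_index()


def fibrosis_association(
    pb_corrected: PseudobulkMatrix,
    pb_raw: PseudobulkMatrix,
    fibrosis_col: str = "fibrosis_pct",
    covariates: tuple = ("age", "sex"),
    p_max: float = 0.005,
) -> pd.DataFrame:
    """Genes whose pseudobulk expression tracks a continuous fibrosis
    covariate under both count versions (unadjusted p < ``p_max``, same
    sign). Exploratory by design: no multiplicity adjustment."""

    def one(pb: PseudobulkMatrix) -> pd.DataFrame:
        meta = pb.col_meta
        if len(meta) < 4:
            raise ValueError("need at least 4 samples")
        fib = meta[fibrosis_col].to_numpy(float)
        if np.std(fib) == 0:
            raise ValueError("constant fibrosis covariate")
        sf = size_factors(pb.counts)
        Y = _log2_cpm(pb.counts, sf)
        cols = [np.ones(len(meta)), (fib - fib.mean()) / fib.std()]
        names = ["Intercept", fibrosis_col]
        for cov in covariates:
            v = meta[cov]
            if v.dtype.kind in "ifu":
                x = v.to_numpy(float)
                sd = x.std()
                cols.append((x - x.mean()) / (sd if sd > 0 else 1.0))
            else:
                for lev in list(pd.unique(v))[1:]:
                    cols.append((v == lev).to_numpy(float))
            names.append(cov)
        X = np.column_stack(cols)
        c = np.zeros(X.shape[1])
        c[1] = 1.0
        eff, pvals = _ols_contrast(Y, X, c)
        return pd.DataFrame({"gene": pb.counts.index, "slope": eff, "p": pvals})

    ra = one(pb_corrected).set_index("gene")
    rb = one(pb_raw).set_index("gene")
    common = ra.index.intersection(rb.index)
    ra, rb = ra.loc[common], rb.loc[common]
    hit = (ra["p"] < p_max) & (rb["p"] < p_max) & (
        np.sign(ra["slope"]) == np.sign(rb["slope"])
    )
    out = ra[hit].copy()
    out["sign"] = np.sign(out["slope"]).astype(int)
    return out.reset_index()


def run_dual_de(
    bundle,
    celltype_labels,
    contrast: tuple = ("ICM", "NF"),
    keep_mask=None,
    min_nuclei: int = 25,
    alpha: float = 0.05,
    covariates: tuple = ("age", "sex"),
    condition_col: str = "condition",
) -> dict:
    """The dual-count DE workflow: pseudobulk both count versions, apply
    the gene prefilters per cell type (one shared universe, with the
    low-count rule evaluated on the corrected pseudobulk), fit the
    covariate model on each version, and intersect by the concordance
    filter.

    Returns {"corrected": DEResult, "raw": DEResult, "significant":
    concordance-filtered rows}.
    """
    nm = bundle.nucleus_meta
    ct = np.asarray(celltype_labels)
    keep = np.ones(len(ct), dtype=bool) if keep_mask is None else np.asarray(keep_mask)
    samples = nm["sample"].to_numpy()
    cond = nm[condition_col].to_numpy()
    smeta = sample_table(nm)
    pb_c = pseudobulk(bundle.corrected_counts[keep], ct[keep], samples[keep],
                      min_nuclei, gene_ids=bundle.gene_ids, sample_meta=smeta)
    pb_r = pseudobulk(bundle.raw_counts[keep], ct[keep], samples[keep],
                      min_nuclei, gene_ids=bundle.gene_ids, sample_meta=smeta)
    res = {"corrected": [], "raw": []}
    for ctk in pd.unique(pb_c.col_meta["cell_type"]):
        masks = {
            lev: keep & (ct == ctk) & (cond == lev) for lev in contrast
        }
        if any(not m.any() for m in masks.values()):
            continue
        sub_c, sub_r = pb_c.subset(ctk), pb_r.subset(ctk)
        genes = prefilter_genes(
            bundle.raw_counts, masks, gene_meta=bundle.gene_meta,
            gene_ids=bundle.gene_ids, pseudobulk_counts=sub_c.counts,
        )
        try:
            res["corrected"].append(
                fit_de(sub_c, contrast, condition_col, covariates, genes=genes)
            )
            res["raw"].append(
                fit_de(sub_r, contrast, condition_col, covariates, genes=genes)
            )
        except ValueError:
            continue
    if not res["corrected"]:
        raise ValueError("no cell type could be tested")
    rc = pd.concat(res["corrected"], ignore_index=True)
    rr = pd.concat(res["raw"], ignore_index=True)
    return {
        "corrected": rc,
        "raw": rr,
        "significant": concordance_filter(rc, rr, alpha),
    }


def ovr_marker_de(pb_by_cluster: PseudobulkMatrix) -> pd.DataFrame:
    """One-vs-rest pseudobulk marker model: ~0 + cluster + individual.

    Columns of ``pb_by_cluster`` are (cluster, sample) sums; for each
    cluster the contrast is that cluster's coefficient against the mean
    of all other cluster coefficients. The sample indicator absorbs the
    fact that each individual contributes nuclei to several clusters.
    """
    meta = pb_by_cluster.col_meta
    clusters = list(pd.unique(meta["cell_type"]))
    samples = list(pd.unique(meta["sample"]))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    sf = size_factors(pb_by_cluster.counts)
    Y = _log2_cpm(pb_by_cluster.counts, sf)
    cols = [
        (meta["cell_type"] == cl).to_numpy(float) for cl in clusters
    ] + [(meta["sample"] == s).to_numpy(float) for s in samples[1:]]
    X = np.column_stack(cols)
    out = []
    k = len(clusters)
    for i, cl in enumerate(clusters):
        c = np.zeros(X.shape[1])
        c[:k] = -1.0 / (k - 1)
        c[i] = 1.0
        eff, pvals = _ols_contrast(Y, X, c)
        out.append(
            pd.DataFrame(
                {
                    "gene": pb_by_cluster.counts.index,
                    "cluster": cl,
                    "logFC": eff,
                    "p": pvals,
                    "adj_p": bh_adjust(pvals),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def select_markers(
    auc: pd.DataFrame,
    de: pd.DataFrame,
    pct: pd.DataFrame,
    criteria: MarkerCriteria | None = None,
    coding: pd.Series | None = None,
) -> dict:
    """Markers per cluster meeting all four thresholds.

    ``auc`` and ``pct`` are genes x clusters tables; ``de`` is the
    :func:`ovr_marker_de` output. ``coding`` optionally restricts to
    protein-coding genes.
    """
    criteria = criteria or MarkerCriteria.global_preset()
    out = {}
    de_idx = de.set_index(["gene", "cluster"])
    for cl in auc.columns:
        genes = auc.index
        ok = (auc[cl] > criteria.auc_min) & (pct[cl] >= criteria.pct_min)
        if coding is not None:
            ok &= coding.reindex(genes).fillna(False).to_numpy()
        sel = []
        for g in genes[ok]:
            try:
                row = de_idx.loc[(g, cl)]
            except KeyError:
                continue
            if row["adj_p"] < criteria.adj_p_max and row["logFC"] > criteria.logfc_min:
                sel.append(g)
        out[cl] = sel
    return out


def patient_pca(
    counts: pd.DataFrame,
    min_total: int = 10,
    n_components: int = 10,
) -> pd.DataFrame:
    """PCA of per-sample summed expression after normalization and a
    log-based variance-stabilizing transform (log2(normalized + 1))."""
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    counts = counts[counts.sum(axis=1) >= min_total]
    sf = size_factors(counts)
    vst = np.log2(counts.to_numpy(float) / sf.to_numpy()[None, :] + 1.0)
    Z = vst.T - vst.T.mean(axis=0, keepdims=True)
    n_components = min(n_components, min(Z.shape))
    coords = PCA(n_components=n_components, svd_solver="full").fit_transform(Z)
    return pd.DataFrame(
        coords, index=counts.columns, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
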