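"""Downstream filter cascades and auxiliary statistics.

Given per-contrast differential-expression tables across several disease
groups and one control group, these routines extract genes consistently
shared by all diseases (with effect-size and prevalence floors, excluding
genes that differ between diseases), genes unique to one disease,
druggable-genome annotations with cell-type specificity, Fisher-exact
gene-set enrichment, in-situ probe-pair selectivity, RNA-vs-protein
concordance classes, and a reference-based log-ratio composition test.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .markers_de import bh_adjust

__all__ = [
    "multi_de_table",
    "assemble_multi_de",
    "shared_degs",
    "unique_disease_degs",
    "druggable_filter",
    "fisher_enrichment",
    "probe_pair_selectivity",
    "proteomics_concordance",
    "composition_test",
    "read_gmt",
    "read_druggable",
]


def assemble_multi_de(results: dict, significant: dict | None = None) -> pd.DataFrame:
    """Pivot per-contrast DE frames into one (gene, cell_type) table.

    ``results`` maps contrast name (e.g. ``"ICM_vs_NF"``) to a tidy DE
    frame with gene/cell_type/logFC/adj_p columns. ``significant``
    optionally maps contrast name to the set of (gene, cell_type) keys
    that passed the dual-count concordance filter; without it,
    significance defaults to adj_p < 0.05.
    """
    pieces = []
    for contrast, df in results.items():
        d = df.set_index(["gene", "cell_type"])[["logFC", "adj_p"]]
        d.columns = [f"logFC_{contrast}", f"adj_p_{contrast}"]
        if significant is not None:
            keys = significant[contrast]
            d[f"sig_{contrast}"] = d.index.isin(keys)
        else:
            d[f"sig_{contrast}"] = d[f"adj_p_{contrast}"] < 0.05
        pieces.append(d)
    return pd.concat(pieces, axis=1, join="inner")


def _contrast(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def multi_de_table(
    bundle,
    celltype_labels,
    diseases: list,
    control: str,
    keep_mask=None,
    min_nuclei: int = 25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Build the full multi-condition DE table for the filter cascades.

    Runs the dual-count pseudobulk DE for every disease-vs-control and
    disease-vs-disease pair (one covariate model per cell type with all
    condition levels; contrasts extracted pairwise; BH within each
    contrast), marks significance by the concordance filter, and attaches
    ``pct_max`` — each gene's maximum expressed fraction across condition
    groups within the cell type.
    """
    from . import markers_de as md

    nm = bundle.nucleus_meta
    ct = np.asarray(celltype_labels)
    keep = np.ones(len(ct), dtype=bool) if keep_mask is None else np.asarray(keep_mask)
    samples = nm["sample"].to_numpy()
    cond = nm["condition"].to_numpy()
    smeta = md.sample_table(nm)
    levels = [control] + list(diseases)
    pairs = [(d, control) for d in diseases] + [
        (a, b) for i, a in enumerate(diseases) for b in diseases[i + 1 :]
    ]
    pb_c = md.pseudobulk(bundle.corrected_counts[keep], ct[keep], samples[keep],
                         min_nuclei, gene_ids=bundle.gene_ids, sample_meta=smeta)
    pb_r = md.pseudobulk(bundle.raw_counts[keep], ct[keep], samples[keep],
                         min_nuclei, gene_ids=bundle.gene_ids, sample_meta=smeta)
    results, sigsets = {}, {}
    pct_rows = []
    for ctk in pd.unique(pb_c.col_meta["cell_type"]):
        masks = {lev: keep & (ct == ctk) & (cond == lev) for lev in levels}
        if any(not m.any() for m in masks.values()):
            continue
        sub_c, sub_r = pb_c.subset(ctk), pb_r.subset(ctk)
        genes = md.prefilter_genes(
            bundle.raw_counts, masks, gene_meta=bundle.gene_meta,
            gene_ids=bundle.gene_ids, pseudobulk_counts=sub_c.counts,
        )
        pcts = np.max(
            [md.pct_expressed(bundle.raw_counts, m) for m in masks.values()], axis=0
        )
        pct_rows.append(
            pd.DataFrame({"gene": bundle.gene_ids, "cell_type": ctk, "pct_max": pcts})
        )
        for a, b in pairs:
            try:
                rc = md.fit_de(sub_c, (a, b), genes=genes)
                rr = md.fit_de(sub_r, (a, b), genes=genes)
            except ValueError:
                continue
            key = _contrast(a, b)
            results.setdefault(key, []).append(rc)
            sig = md.concordance_filter(rc, rr, alpha)
            sigsets.setdefault(key, set()).update(
                zip(sig["gene"], sig["cell_type"])
            )
    if not results:
        raise ValueError("no contrast could be tested")
    results = {k: pd.concat(v, ignore_index=True) for k, v in results.items()}
    table = assemble_multi_de(results, sigsets)
    pct = pd.concat(pct_rows).set_index(["gene", "cell_type"])["pct_max"]
    table["pct_max"] = pct.reindex(table.index)
    return table


def shared_degs(
    table: pd.DataFrame,
    diseases: list,
    control: str,
    lfc_min: float = 1.0,
    pct_min: float = 0.05,
    pct_col: str = "pct_max",
) -> dict:
    """Genes consistently shared by every disease, split by direction.

    A gene (per cell type) qualifies when it is significant with the same
    sign in every disease-vs-control contrast, significant in no
    disease-vs-disease contrast, has |logFC| > ``lfc_min`` in all
    disease-vs-control contrasts, and is expressed in more than
    ``pct_min`` of nuclei in at least one group (``pct_col``; skipped when
    the column is absent). Returns {cell_type: {"up": set, "down": set}}.
    """
    vs_ctrl = [_contrast(d, control) for d in diseases]
    for c in vs_ctrl:
        if f"sig_{c}" not in table.columns:
            raise ValueError(f"missing contrast {c}")
    pairwise = [
        _contrast(a, b)
        for i, a in enumerate(diseases)
        for b in diseases[i + 1 :]
    ]
    pairwise = [c for c in pairwise if f"sig_{c}" in table.columns]
    missing = len(pairwise) < len(diseases) * (len(diseases) - 1) // 2
    if missing:
        raise ValueError("missing disease-vs-disease contrast")

    sig_all = np.logical_and.reduce([table[f"sig_{c}"].to_numpy() for c in vs_ctrl])
    lfc = np.column_stack([table[f"logFC_{c}"].to_numpy() for c in vs_ctrl])
    same_sign = (lfc > 0).all(axis=1) | (lfc < 0).all(axis=1)
    strong = (np.abs(lfc) > lfc_min).all(axis=1)
    no_pairwise = ~np.logical_or.reduce(
        [table[f"sig_{c}"].to_numpy() for c in pairwise]
    )
    keep = sig_all & same_sign & strong & no_pairwise
    if pct_col in table.columns:
        keep &= table[pct_col].to_numpy() > pct_min

    out = {}
    kept = table[keep]
    up_mask = (np.column_stack([kept[f"logFC_{c}"] for c in vs_ctrl]) > 0).all(axis=1)
    for ct in kept.index.get_level_values("cell_type").unique():
        sub = kept.index.get_level_values("cell_type") == ct
        genes = kept.index.get_level_values("gene")[sub]
        out[ct] = {
            "up": set(genes[up_mask[sub]]),
            "down": set(genes[~up_mask[sub]]),
        }
    return out


def unique_disease_degs(
    table: pd.DataFrame,
    focal: str,
    diseases: list,
    control: str,
) -> dict:
    """Genes changed in the focal disease and differing from at least one
    other disease: significant in focal-vs-control AND in focal-vs-other
    for some other disease. Returns {cell_type: set of genes}."""
    if focal not in diseases:
        raise ValueError(f"unknown disease: {focal!r}")
    others = [d for d in diseases if d != focal]

    def sig_col(a, b):
        for c in (_contrast(a, b), _contrast(b, a)):
            if f"sig_{c}" in table.columns:
                return table[f"sig_{c}"].to_numpy()
        raise ValueError(f"missing contrast between {a} and {b}")

    keep = sig_col(focal, control) & np.logical_or.reduce(
        [sig_col(focal, o) for o in others]
    )
    kept = table[keep]
    out = {}
    for ct in kept.index.get_level_values("cell_type").unique():
        sub = kept.index.get_level_values("cell_type") == ct
        out[ct] = set(kept.index.get_level_values("gene")[sub])
    return out


def druggable_filter(
    shared: dict,
    annotation: pd.Series,
    auc: pd.DataFrame | None = None,
    specificity_auc_min: float = 0.6,
) -> pd.DataFrame:
    """Intersect shared DEG sets with a tiered druggable-genome annotation.

    ``annotation`` maps gene symbol to tier label; unannotated genes are
    dropped. When a genes x cell_types AUC table is supplied, genes whose
    one-vs-rest AUC in the cell type exceeds ``specificity_auc_min`` are
    marked cell-type specific.
    """
    rows = []
    for ct, sets in shared.items():
        for direction in ("up", "down"):
            for g in sorted(sets.get(direction, ())):
                if g not in annotation.index:
                    continue
                specific = False
                if auc is not None and g in auc.index and ct in auc.columns:
                    specific = bool(auc.loc[g, ct] > specificity_auc_min)
                rows.append((g, ct, direction, annotation[g], specific))
    return pd.DataFrame(
        rows, columns=["gene", "cell_type", "direction", "tier", "cell_type_specific"]
    )


def fisher_enrichment(
    query,
    universe,
    collection: dict,
    min_size: int = 15,
    max_size: int = 500,
    mode: str = "unadjusted",
    p_max: float = 0.001,
    or_min: float = 2.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher-exact enrichment of a query set against a collection.

    Sets outside [min_size, max_size] (after restriction to the universe)
    are skipped. Two significance modes: ``"unadjusted"`` (p < p_max and
    odds ratio > or_min, no correction — enrichment over a term graph is
    not a family of independent tests) and ``"fdr"`` (BH FDR < fdr_max).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    N = len(universe)
    n = len(query)
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        K = len(members)
        if K < min_size or K > max_size:
            continue
        a = len(query & members)
        b = n - a
        c = K - a
        d = N - K - b
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        if a == 0:
            odds = 0.0
        elif b == 0 or c == 0:
            odds = np.inf
        else:
            odds = (a * d) / (b * c)
        rows.append((name, K, a, odds, p))
    out = pd.DataFrame(
        rows, columns=["set", "n_set", "n_overlap", "odds_ratio", "p"]
    )
    if len(out):
        out["adj_p"] = bh_adjust(out["p"])
        if mode == "unadjusted":
            out["significant"] = (out["p"] < p_max) & (out["odds_ratio"] > or_min)
        elif mode == "fdr":
            out["significant"] = out["adj_p"] < fdr_max
        else:
            raise ValueError("mode must be 'unadjusted' or 'fdr'")
    else:
        out["adj_p"] = []
        out["significant"] = []
    return out


def probe_pair_selectivity(
    counts,
    subtype_labels,
    target_subtype: str,
    pan_marker,
    gene_ids=None,
    auc_min: float = 0.6,
    lfc_min: float = 1.0,
    pct_target_min: float = 0.20,
    pct_other_max: float = 0.25,
) -> pd.DataFrame:
    """Rank candidate probe genes by double-positive selectivity.

    Candidates must separate the target subtype (one-vs-rest AUC on
    log-normalized expression > ``auc_min``, log2 mean fold-change >
    ``lfc_min``, expressed in > ``pct_target_min`` of target nuclei) and
    be expressed in no more than ``pct_other_max`` of any other
    population. Each candidate is then scored as the fraction of target
    nuclei positive for both the candidate and the pan marker, minus the
    maximum such double-positive rate in any other population.
    """
    from .markers_de import auc_one_vs_rest

    X = sp.csr_matrix(counts)
    labels = np.asarray(subtype_labels)
    if gene_ids is None:
        gene_ids = pd.Index([f"G{i:05d}" for i in range(X.shape[1])])
    gene_ids = pd.Index(gene_ids)
    if target_subtype not in labels:
        raise ValueError(f"target subtype absent: {target_subtype!r}")
    if pan_marker not in gene_ids:
        raise ValueError("pan marker gene not in matrix")
    mask = labels == target_subtype
    others = [l for l in pd.unique(labels) if l != target_subtype]

    tot = np.asarray(X.sum(axis=1)).ravel().astype(float)
    tot[tot == 0] = 1.0
    norm = sp.diags(1e4 / tot) @ X
    logn = norm.copy()
    logn.data = np.log1p(logn.data)
    auc = auc_one_vs_rest(logn, mask)
    mean_in = np.asarray(norm[mask].mean(axis=0)).ravel()
    mean_out = np.asarray(norm[~mask].mean(axis=0)).ravel()
    lfc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
    pct_in = np.asarray((X[mask] > 0).mean(axis=0)).ravel()
    pct_by_other = {
        o: np.asarray((X[labels == o] > 0).mean(axis=0)).ravel() for o in others
    }
    max_pct_other = np.max(np.vstack(list(pct_by_other.values())), axis=0)

    cand = (
        (auc > auc_min)
        & (lfc > lfc_min)
        & (pct_in > pct_target_min)
        & (max_pct_other <= pct_other_max)
    )
    pan_col = gene_ids.get_loc(pan_marker)
    pan_pos = np.asarray((X[:, pan_col] > 0).todense()).ravel()
    rows = []
    for gi in np.where(cand)[0]:
        gpos = np.asarray((X[:, gi] > 0).todense()).ravel()
        dp = gpos & pan_pos
        target_rate = dp[mask].mean()
        off = max(dp[labels == o].mean() for o in others) if others else 0.0
        rows.append((gene_ids[gi], auc[gi], lfc[gi], pct_in[gi], target_rate, off))
    out = pd.DataFrame(
        rows,
        columns=["gene", "auc", "logFC", "pct_target", "double_pos_target", "max_double_pos_other"],
    )
    out["selectivity"] = out["double_pos_target"] - out["max_double_pos_other"]
    return out.sort_values("selectivity", ascending=False).reset_index(drop=True)


def proteomics_concordance(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    rna_alpha: float = 0.05,
    protein_alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify genes by RNA/protein significance and sign agreement.

    ``rna`` rows are per (gene, cell_type) with logFC and adj_p; the
    protein table has one effect per gene (columns gene, logFC, p); on
    duplicate protein symbols the first row wins. Classes: concordant-up,
    concordant-down, discordant, rna-only, protein-only, neither.
    """
    prot = protein.drop_duplicates(subset="gene", keep="first").set_index("gene")
    rows = []
    for _, r in rna.iterrows():
        g = r["gene"]
        if g not in prot.index:
            continue
        p = prot.loc[g]
        rna_sig = r["adj_p"] < rna_alpha
        prot_sig = p["p"] < protein_alpha
        if rna_sig and prot_sig:
            if np.sign(r["logFC"]) == np.sign(p["logFC"]):
                cls = "concordant-up" if r["logFC"] > 0 else "concordant-down"
            else:
                cls = "discordant"
        elif rna_sig:
            cls = "rna-only"
        elif prot_sig:
            cls = "protein-only"
        else:
            cls = "neither"
        rows.append((g, r["cell_type"], r["logFC"], p["logFC"], cls))
    return pd.DataFrame(
        rows, columns=["gene", "cell_type", "rna_logFC", "protein_logFC", "class"]
    )


def composition_test(
    celltype_labels,
    sample_labels,
    condition_by_sample: pd.Series,
    reference_type: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Reference-based log-ratio test of cell-type composition.

    Per sample, each type's abundance is expressed as the log2 ratio of
    its nucleus count to the reference type's count (with a pseudocount);
    a two-sample t-test per type compares conditions, BH-adjusted across
    types. The reference type itself is never tested (its log-ratio is
    identically zero). A lightweight substitute for fully Bayesian
    compositional models, using the same reference-type convention.
    """
    ct = pd.Series(np.asarray(celltype_labels), name="cell_type")
    sm = pd.Series(np.asarray(sample_labels), name="sample")
    tab = pd.crosstab(sm, ct).astype(float)
    if reference_type not in tab.columns:
        raise ValueError(f"reference type absent: {reference_type!r}")
    if (tab[reference_type] == 0).any():
        warnings.warn(
            "reference type absent in some samples; pseudocount rescue applied",
            stacklevel=2,
        )
    conds = condition_by_sample.reindex(tab.index)
    levels = list(pd.unique(conds.dropna()))
    if len(levels) != 2:
        raise ValueError("composition test requires exactly two conditions")
    ref = tab[reference_type] + pseudocount
    rows = []
    for t in tab.columns:
        if t == reference_type:
            continue
        lr = np.log2((tab[t] + pseudocount) / ref)
        a = lr[conds == levels[0]]
        b = lr[conds == levels[1]]
        tstat, p = stats.ttest_ind(a, b)
        rows.append((t, float(a.mean() - b.mean()), float(tstat), float(p)))
    out = pd.DataFrame(rows, columns=["cell_type", "log2_ratio_diff", "t", "p"])
    out["adj_p"] = bh_adjust(out["p"]) if len(out) else []
    return out


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection (name, description, genes...)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:50]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_druggable(path) -> pd.Series:
    """Read a two-column (symbol, tier) druggable-genome annotation."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "tier"], comment="#")
    return df.drop_duplicates("gene").set_index("gene")["tier"]
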