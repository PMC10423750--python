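"""Per-gene, per-cell-type ambient-background contamination heuristic.

Ambient RNA biases droplet counts toward the dataset's most abundant
transcripts, so a gene that is (a) highly abundant overall and (b) not
specific to the cell type under test is likely to owe its apparent
expression there to background. The heuristic multiplies two components:

* ``bkg_prob`` — the gene's position on the ECDF of per-gene dataset
  UMI fractions (1.0 for the most abundant genes);
* ``nontarget_prob`` — one minus the mean of two prevalence-standardized
  positive predictive values for membership in the target cell type,
  dichotomizing counts at >0 (PPV0) and >1 (PPV1). At equal prevalence
  PPV = TPR / (TPR + FPR), the unique form in which prevalence cancels.

Genes with ``bkg_prob * nontarget_prob`` above a threshold (default 0.4)
are flagged as probable background and should be excluded from
enrichment inputs and marked in DE results rather than silently removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "dataset_fraction_ecdf",
    "standardized_ppv",
    "background_heuristic",
    "partitioned_heuristic",
]


def dataset_fraction_ecdf(counts, tie: str = "upper"):
    """Per-gene dataset UMI fraction and its ECDF value.

    ``bkg_prob`` for gene g is the fraction of genes whose dataset
    fraction is <= that of g (ties share the upper step); with
    ``tie="strict"`` strictly-less-than is used instead.
    """
    X = sp.csr_matrix(counts)
    tot = np.asarray(X.sum(axis=0)).ravel().astype(float)
    grand = tot.sum()
    if grand <= 0:
        raise ValueError("empty count matrix")
    frac = tot / grand
    G = len(frac)
    order = np.argsort(frac)
    sorted_f = frac[order]
    if tie == "upper":
        ecdf = np.searchsorted(sorted_f, frac, side="right") / G
    elif tie == "strict":
        ecdf = np.searchsorted(sorted_f, frac, side="left") / G
    else:
        raise ValueError("tie must be 'upper' or 'strict'")
    return frac, ecdf


def standardized_ppv(expr, in_celltype, positivity_threshold: float = 0.0) -> np.ndarray:
    """Prevalence-standardized PPV per gene at a positivity cut.

    TPR = P(expr > t | in type), FPR = P(expr > t | not in type);
    PPV at prevalence 1/2 = TPR / (TPR + FPR), defined as 0 when both
    rates are 0 (the gene is never positive).
    """
    mask = np.asarray(in_celltype, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both groups must be non-empty")
    X = sp.csr_matrix(expr)
    pos = X > positivity_threshold
    tpr = np.asarray(pos[mask].mean(axis=0)).ravel()
    fpr = np.asarray(pos[~mask].mean(axis=0)).ravel()
    denom = tpr + fpr
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(denom > 0, tpr / np.where(denom > 0, denom, 1.0), 0.0)
    return ppv


def background_heuristic(
    counts,
    celltype_labels,
    target_type,
    threshold: float = 0.4,
    gene_ids=None,
    ecdf_tie: str = "upper",
    in_mask=None,
) -> pd.DataFrame:
    """Full background-score table for one target cell type.

    ``in_mask`` overrides the classification target (used by
    :func:`partitioned_heuristic`); by default it is the set of nuclei
    labeled ``target_type``.
    """
    labels = np.asarray(celltype_labels)
    if in_mask is None:
        in_mask = labels == target_type
        if not in_mask.any():
            raise ValueError(f"unknown cell type: {target_type!r}")
    in_mask = np.asarray(in_mask, dtype=bool)
    X = sp.csr_matrix(counts)
    if gene_ids is None:
        gene_ids = pd.Index([f"G{i:05d}" for i in range(X.shape[1])])
    frac, bkg_prob = dataset_fraction_ecdf(X, tie=ecdf_tie)
    ppv0 = standardized_ppv(X, in_mask, 0.0)
    ppv1 = standardized_ppv(X, in_mask, 1.0)
    nontarget = 1.0 - (ppv0 + ppv1) / 2.0
    heuristic = bkg_prob * nontarget
    return pd.DataFrame(
        {
            "dataset_fraction": frac,
            "bkg_prob": bkg_prob,
            "ppv0": ppv0,
            "ppv1": ppv1,
            "nontarget_prob": nontarget,
            "heuristic": heuristic,
            "flagged": heuristic > threshold,
        },
        index=pd.Index(gene_ids, name="gene"),
    )


def partitioned_heuristic(
    counts,
    celltype_labels,
    lineage_types,
    target_subtype: str | None = None,
    threshold: float = 0.4,
    gene_ids=None,
    ecdf_tie: str = "upper",
) -> pd.DataFrame:
    """Background heuristic with a lineage partition as the classifier.

    For subtype-level testing within a lineage (e.g. endothelial
    subclusters), nuclei are split into in-lineage vs rest and the same
    calculation is run with that partition as the classification target.
    """
    labels = np.asarray(celltype_labels)
    lineage_types = set(lineage_types)
    if target_subtype is not None and target_subtype not in lineage_types:
        raise ValueError("target subtype must belong to the lineage partition")
    in_mask = np.isin(labels, sorted(lineage_types))
    if in_mask.all() or not in_mask.any():
        raise ValueError("partition must leave both sides non-empty")
    return background_heuristic(
        counts,
        labels,
        target_type=None,
        threshold=threshold,
        gene_ids=gene_ids,
        ecdf_tie=ecdf_tie,
        in_mask=in_mask,
    )
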