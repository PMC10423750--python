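"""Synthetic multi-sample, multi-condition snRNA-seq data with planted ground truth.

The generator emulates the statistical structure a nucleus-level QC /
clustering / pseudobulk-DE pipeline assumes: each cell type expresses a
sparse gene program with type-exclusive marker genes, every droplet's
counts are contaminated by an ambient pool shared across the sample,
a fraction of droplets are doublets (sums of two nuclei) or low-quality
nuclei (low-entropy, mitochondrially enriched programs), and condition
effects are planted as per-cell-type fold changes on chosen genes.

Two count matrices are produced per dataset: the raw counts and an
"ambient-corrected" version obtained by subtracting the expected ambient
component per gene and clipping at zero, standing in for the paired
corrected/uncorrected matrices real pipelines carry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SimulationConfig",
    "CountBundle",
    "SyntheticTruth",
    "generate_dataset",
    "write_bundle",
    "read_bundle",
]

DOUBLET_LABEL = "doublet"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults describe a desk-scale two-arm study (8 control vs 7 case
    samples, 250 nuclei each) with 10% planted low-quality nuclei, 5%
    doublets, a 10% mean ambient fraction and |log2FC| = 2 condition
    effects — the conditions the downstream recovery tests assume. The
    mild abundance gradient keeps every type above the pseudobulk
    inclusion floor in every sample, so all planted effects are testable.
    """

    n_genes: int = 2000
    n_cell_types: int = 5
    samples_per_condition: dict = field(
        default_factory=lambda: {"NF": 8, "ICM": 7}
    )
    control_condition: str = "NF"
    nuclei_per_sample: int = 250
    library_size_log_mean: float = 7.6  # ~2,000 UMI
    library_size_log_sd: float = 0.35
    ambient_fraction_mean: float = 0.10
    ambient_fraction_concentration: float = 50.0
    doublet_rate: float = 0.05
    lowq_rate: float = 0.10
    n_de_genes_per_celltype: int = 20
    de_log2fc: float = 2.0
    mt_gene_fraction: float = 0.0065  # 13 of 2,000 genes
    n_markers_per_type: int = 20
    n_ambient_genes: int = 30
    ambient_gene_mass: float = 0.15
    marker_mass: float = 0.10
    mt_mass: float = 0.02
    program_concentration: float = 0.3
    celltype_abundance: tuple | None = None  # None: mild gradient, all types testable
    composition_fold_change: dict = field(
        default_factory=lambda: {"type0": 0.55, "type1": 1.4}
    )  # per-type abundance factor in case samples (disease-linked composition shift)
    lowq_top_genes: int = 20
    lowq_mt_mass: float = 0.30
    exon_prop_clean: tuple = (8.0, 92.0)   # Beta(a, b): mean 0.08
    exon_prop_lowq: tuple = (30.0, 70.0)   # mean 0.30
    age_range: tuple = (40, 70)
    sample_libsize_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cell_types <= 0:
            raise ValueError("n_genes and n_cell_types must be positive")
        if self.nuclei_per_sample <= 0 or not self.samples_per_condition:
            raise ValueError("need at least one sample with at least one nucleus")
        for name, val in [
            ("ambient_fraction_mean", self.ambient_fraction_mean),
            ("doublet_rate", self.doublet_rate),
            ("lowq_rate", self.lowq_rate),
            ("mt_gene_fraction", self.mt_gene_fraction),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.doublet_rate + self.lowq_rate >= 1.0:
            raise ValueError("doublet_rate + lowq_rate must be < 1")
        if not np.isfinite(self.de_log2fc):
            raise ValueError("de_log2fc must be finite")
        if self.control_condition not in self.samples_per_condition:
            raise ValueError("control_condition missing from samples_per_condition")


@dataclass
class CountBundle:
    """Paired raw / ambient-corrected sparse count matrices with annotations.

    Both matrices are nucleus x gene CSR with identical shape and
    identifiers; ``nucleus_meta`` carries sample, condition, exon_prop,
    sex and age per nucleus, ``gene_meta`` the gene symbols and
    mitochondrial / ribosomal / protein-coding flags.
    """

    raw_counts: sp.csr_matrix
    corrected_counts: sp.csr_matrix
    nucleus_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self):
        if self.raw_counts.shape != self.corrected_counts.shape:
            raise ValueError("raw and corrected matrices differ in shape")
        if self.raw_counts.shape[0] != len(self.nucleus_meta):
            raise ValueError("nucleus_meta does not match matrix rows")
        if self.raw_counts.shape[1] != len(self.gene_meta):
            raise ValueError("gene_meta does not match matrix columns")

    @property
    def n_nuclei(self) -> int:
        return self.raw_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.raw_counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.nucleus_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index


@dataclass
class SyntheticTruth:
    """Planted ground truth: cell types, artifact flags and condition effects."""

    nucleus_celltype: pd.Series        # per nucleus; doublets labeled "doublet"
    is_doublet: pd.Series
    is_lowq: pd.Series
    ambient_fraction: pd.Series        # realized per-nucleus ambient fraction
    ambient_gene_ids: set
    marker_genes: dict                 # cell type -> list of exclusive marker gene ids
    de_gene_table: pd.DataFrame        # gene, cell_type, condition, log2fc
    programs: pd.DataFrame | None = None       # cell type x gene sampling probabilities
    composition_fold_change: dict | None = None

    def clean_singlets(self) -> pd.Series:
        return ~(self.is_doublet | self.is_lowq)


def _build_programs(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-cell-type gene programs plus the gene-role bookkeeping.

    Gene layout: [markers per type | ambient genes | MT genes | DE genes | rest].
    Marker genes carry mass only in their own type; ambient genes carry a
    large shared mass in every program so they dominate the ambient pool
    while being type-nonspecific.
    """
    G, T = cfg.n_genes, cfg.n_cell_types
    n_mt = max(int(round(cfg.mt_gene_fraction * G)), 1)
    n_marker_total = cfg.n_markers_per_type * T
    n_de_total = cfg.n_de_genes_per_celltype * T if cfg.de_log2fc != 0 else 0
    needed = n_marker_total + cfg.n_ambient_genes + n_mt + n_de_total
    if needed > G:
        raise ValueError("n_genes too small for the requested gene roles")

    marker_idx = np.arange(n_marker_total).reshape(T, cfg.n_markers_per_type)
    ambient_idx = np.arange(n_marker_total, n_marker_total + cfg.n_ambient_genes)
    mt_idx = np.arange(ambient_idx[-1] + 1 if cfg.n_ambient_genes else n_marker_total,
                       n_marker_total + cfg.n_ambient_genes + n_mt)
    de_start = n_marker_total + cfg.n_ambient_genes + n_mt
    de_idx = np.arange(de_start, de_start + n_de_total).reshape(
        T, -1) if n_de_total else np.zeros((T, 0), dtype=int)

    programs = rng.dirichlet(np.full(G, cfg.program_concentration), size=T)
    # zero out reserved genes, then assign their roles explicitly
    reserved = np.concatenate([marker_idx.ravel(), ambient_idx, mt_idx, de_idx.ravel()])
    programs[:, reserved] = 0.0
    for t in range(T):
        programs[t, marker_idx[t]] = cfg.marker_mass / cfg.n_markers_per_type
    if cfg.n_ambient_genes:
        # uneven but high abundance, shared identically across types
        w = rng.dirichlet(np.full(cfg.n_ambient_genes, 5.0))
        programs[:, ambient_idx] = cfg.ambient_gene_mass * w
    programs[:, mt_idx] = cfg.mt_mass / n_mt
    if n_de_total:
        base = rng.uniform(5e-4, 2e-3, size=n_de_total)  # ~1-4 counts per nucleus: testable but unremarkable
        programs[:, de_idx.ravel()] = base  # expressed in every type
    programs /= programs.sum(axis=1, keepdims=True)
    return programs, marker_idx, ambient_idx, mt_idx, de_idx


def generate_dataset(config: SimulationConfig):
    """Generate a (CountBundle, SyntheticTruth) pair. Deterministic given seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G, T = cfg.n_genes, cfg.n_cell_types

    programs, marker_idx, ambient_idx, mt_idx, de_idx = _build_programs(cfg, rng)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(G)], name="gene_id")
    symbols = np.array([f"GENE{i:05d}" for i in range(G)], dtype=object)
    symbols[mt_idx] = [f"MT-S{i}" for i in range(len(mt_idx))]
    gene_meta = pd.DataFrame(
        {
            "symbol": symbols,
            "mitochondrial": np.isin(np.arange(G), mt_idx),
            "ribosomal": False,
            "protein_coding": True,
        },
        index=gene_ids,
    )
    celltypes = [f"type{t}" for t in range(T)]
    if cfg.celltype_abundance is not None:
        abundance = np.asarray(cfg.celltype_abundance, dtype=float)
        if len(abundance) != T or (abundance <= 0).any():
            raise ValueError("celltype_abundance must be positive, one per type")
    else:
        abundance = np.linspace(2.0, 1.2, T)
    abundance = abundance / abundance.sum()
    case_abundance = abundance.copy()
    for t, cname in enumerate(celltypes):
        case_abundance[t] *= cfg.composition_fold_change.get(cname, 1.0)
    case_abundance = case_abundance / case_abundance.sum()

    # planted condition effects (same genes/effects for every case condition)
    case_conditions = [c for c in cfg.samples_per_condition if c != cfg.control_condition]
    de_rows = []
    fc_mult = np.ones((T, G))
    if cfg.de_log2fc != 0 and de_idx.size:
        for t in range(T):
            for j, g in enumerate(de_idx[t]):
                sign = 1.0 if j % 2 == 0 else -1.0
                lfc = sign * cfg.de_log2fc
                fc_mult[t, g] = 2.0 ** lfc
                for cond in case_conditions:
                    de_rows.append((gene_ids[g], celltypes[t], cond, lfc))
    de_gene_table = pd.DataFrame(
        de_rows, columns=["gene", "cell_type", "condition", "log2fc"]
    )

    # per-sample metadata
    samples, conditions = [], []
    for cond, n in cfg.samples_per_condition.items():
        for i in range(n):
            samples.append(f"{cond}_{i}")
            conditions.append(cond)
    n_samples = len(samples)
    sample_age = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n_samples)
    sample_sex = rng.choice(["M", "F"], size=n_samples)
    sample_libfactor = np.exp(rng.normal(0.0, cfg.sample_libsize_sd, size=n_samples))

    N = cfg.nuclei_per_sample
    total = N * n_samples
    raw = np.zeros((total, G), dtype=np.int64)
    corrected = np.zeros((total, G), dtype=np.int64)
    meta_rows = []
    ct_labels = np.empty(total, dtype=object)
    is_doublet = np.zeros(total, dtype=bool)
    is_lowq = np.zeros(total, dtype=bool)
    amb_frac = np.zeros(total)

    am, ac = cfg.ambient_fraction_mean, cfg.ambient_fraction_concentration
    for s in range(n_samples):
        cond = conditions[s]
        is_case = cond != cfg.control_condition
        progs_s = programs * fc_mult if is_case else programs
        progs_s = progs_s / progs_s.sum(axis=1, keepdims=True)
        ab = case_abundance if is_case else abundance
        ambient_pool = ab @ progs_s

        lo = s * N
        u = rng.random(N)
        dbl = u < cfg.doublet_rate
        lowq = (~dbl) & (u < cfg.doublet_rate + cfg.lowq_rate)

        types = rng.choice(T, size=N, p=ab)
        types2 = rng.choice(T, size=N, p=ab)  # doublet partners
        lib = np.maximum(
            np.round(
                rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd, N)
                * sample_libfactor[s]
            ),
            1,
        ).astype(np.int64)
        lib2 = np.maximum(
            np.round(
                rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd, N)
                * sample_libfactor[s]
            ),
            1,
        ).astype(np.int64)
        if am == 0:
            a = np.zeros(N)
        else:
            a = rng.beta(am * ac, (1 - am) * ac, size=N)

        # per-nucleus sampling distributions
        p = (1 - a)[:, None] * progs_s[types] + a[:, None] * ambient_pool
        counts = rng.multinomial(lib, p)
        expected_lib = lib.astype(float)

        # doublets: add a second, independently drawn singlet
        if dbl.any():
            idx = np.where(dbl)[0]
            p2 = (1 - a[idx])[:, None] * progs_s[types2[idx]] + a[idx][:, None] * ambient_pool
            counts[idx] += rng.multinomial(lib2[idx], p2)
            expected_lib[idx] += lib2[idx]

        # low-quality nuclei: low-entropy program + inflated MT mass
        if lowq.any():
            idx = np.where(lowq)[0]
            for i in idx:
                prog = progs_s[types[i]]
                top = np.argsort(prog)[::-1][: cfg.lowq_top_genes]
                conc = np.zeros(G)
                conc[top] = prog[top] / prog[top].sum()
                lp = (1 - cfg.lowq_mt_mass) * conc
                lp[mt_idx] += cfg.lowq_mt_mass / len(mt_idx)
                pi = (1 - a[i]) * lp + a[i] * ambient_pool
                counts[i] = rng.multinomial(lib[i], pi)

        # expectation-based ambient subtraction, clipped at zero
        expected_ambient = np.round(
            (a * expected_lib)[:, None] * ambient_pool[None, :]
        ).astype(np.int64)
        corr = np.maximum(counts - expected_ambient, 0)

        raw[lo : lo + N] = counts
        corrected[lo : lo + N] = corr
        amb_frac[lo : lo + N] = a
        is_doublet[lo : lo + N] = dbl
        is_lowq[lo : lo + N] = lowq
        lab = np.array([celltypes[t] for t in types], dtype=object)
        lab[dbl] = DOUBLET_LABEL
        ct_labels[lo : lo + N] = lab

        ex_cl = rng.beta(*cfg.exon_prop_clean, size=N)
        ex_lq = rng.beta(*cfg.exon_prop_lowq, size=N)
        exon = np.where(lowq, ex_lq, ex_cl)
        for i in range(N):
            meta_rows.append(
                (
                    f"{samples[s]}:BC{i:05d}",
                    samples[s],
                    cond,
                    exon[i],
                    sample_sex[s],
                    int(sample_age[s]),
                )
            )

    nucleus_meta = pd.DataFrame(
        meta_rows, columns=["barcode", "sample", "condition", "exon_prop", "sex", "age"]
    ).set_index("barcode")

    bundle = CountBundle(
        raw_counts=sp.csr_matrix(raw),
        corrected_counts=sp.csr_matrix(corrected),
        nucleus_meta=nucleus_meta,
        gene_meta=gene_meta,
    )
    truth = SyntheticTruth(
        nucleus_celltype=pd.Series(ct_labels, index=nucleus_meta.index, name="cell_type"),
        is_doublet=pd.Series(is_doublet, index=nucleus_meta.index, name="is_doublet"),
        is_lowq=pd.Series(is_lowq, index=nucleus_meta.index, name="is_lowq"),
        ambient_fraction=pd.Series(amb_frac, index=nucleus_meta.index, name="ambient_fraction"),
        ambient_gene_ids=set(gene_ids[ambient_idx]),
        marker_genes={celltypes[t]: list(gene_ids[marker_idx[t]]) for t in range(T)},
        de_gene_table=de_gene_table,
        programs=pd.DataFrame(programs, index=celltypes, columns=gene_ids),
        composition_fold_change=dict(cfg.composition_fold_change),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# I/O: 10x-style Matrix Market triplet + delimited annotation tables
# ---------------------------------------------------------------------------

def write_bundle(bundle: CountBundle, directory, truth: SyntheticTruth | None = None) -> None:
    """Write a bundle as raw.mtx/corrected.mtx + barcodes/features + meta TSVs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    # genes x nuclei, the 10x triplet orientation
    scipy.io.mmwrite(str(d / "raw.mtx"), bundle.raw_counts.T.tocoo(), field="integer")
    scipy.io.mmwrite(str(d / "corrected.mtx"), bundle.corrected_counts.T.tocoo(), field="integer")
    pd.Series(bundle.barcodes).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)
    feats = pd.DataFrame(
        {"gene_id": bundle.gene_ids, "symbol": bundle.gene_meta["symbol"].to_numpy()}
    )
    feats.to_csv(d / "features.tsv", sep="\t", index=False, header=False)
    bundle.nucleus_meta.to_csv(d / "nucleus_meta.tsv", sep="\t")
    bundle.gene_meta.to_csv(d / "gene_meta.tsv", sep="\t")
    if truth is not None:
        payload = {
            "nucleus_celltype": truth.nucleus_celltype.tolist(),
            "is_doublet": truth.is_doublet.astype(int).tolist(),
            "is_lowq": truth.is_lowq.astype(int).tolist(),
            "ambient_fraction": truth.ambient_fraction.tolist(),
            "ambient_gene_ids": sorted(truth.ambient_gene_ids),
            "marker_genes": truth.marker_genes,
            "de_gene_table": truth.de_gene_table.to_dict(orient="list"),
        }
        (d / "truth.json").write_text(json.dumps(payload))


def read_bundle(directory) -> CountBundle:
    """Read a bundle written by :func:`write_bundle` (lossless round trip)."""
    d = Path(directory)
    raw = sp.csr_matrix(scipy.io.mmread(str(d / "raw.mtx")).T)
    corrected = sp.csr_matrix(scipy.io.mmread(str(d / "corrected.mtx")).T)
    nucleus_meta = pd.read_csv(d / "nucleus_meta.tsv", sep="\t", index_col=0)
    gene_meta = pd.read_csv(d / "gene_meta.tsv", sep="\t", index_col=0)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    if raw.shape[0] != len(barcodes) or raw.shape[1] != len(features):
        raise ValueError("matrix dimensions do not match barcode/feature files")
    if not (nucleus_meta.index == barcodes.to_numpy()).all():
        raise ValueError("nucleus_meta order does not match barcodes.tsv")
    raw = raw.astype(np.int64)
    corrected = corrected.astype(np.int64)
    return CountBundle(raw, corrected, nucleus_meta, gene_meta)


def read_truth(directory) -> SyntheticTruth:
    d = Path(directory)
    payload = json.loads((d / "truth.json").read_text())
    meta = pd.read_csv(d / "nucleus_meta.tsv", sep="\t", index_col=0)
    idx = meta.index
    return SyntheticTruth(
        nucleus_celltype=pd.Series(payload["nucleus_celltype"], index=idx),
        is_doublet=pd.Series(payload["is_doublet"], index=idx).astype(bool),
        is_lowq=pd.Series(payload["is_lowq"], index=idx).astype(bool),
        ambient_fraction=pd.Series(payload["ambient_fraction"], index=idx),
        ambient_gene_ids=set(payload["ambient_gene_ids"]),
        marker_genes=payload["marker_genes"],
        de_gene_table=pd.DataFrame(payload["de_gene_table"]),
    )
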