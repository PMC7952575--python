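"""Image-morphology QTL mapping.

Within each tissue, image features that carry non-zero weight in a CCA
component are tested for association with SNPs that are known cis-eQTLs of
that component's non-zero-weight genes in the same tissue.  Features are
first normalized by projection onto the quantiles of the empirical
distribution pooled over all features; each (SNP, feature) pair is then
tested by univariate ordinary least squares of feature on allele dosage,
and discoveries are declared by Benjamini-Hochberg FDR (default 0.1).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeTable",
    "AssociationRecord",
    "quantile_normalize_features",
    "standardize_features",
    "build_test_set",
    "association_scan",
    "bh_fdr",
]


@dataclass
class GenotypeTable:
    """Dosage matrix (samples x SNPs); missing entries are NaN."""

    snp_ids: list
    sample_ids: list
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and not np.all(np.isin(vals, [0.0, 1.0, 2.0])):
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=list(df.index), sample_ids=list(df.columns),
                   dosages=df.to_numpy(dtype=float).T)

    @classmethod
    def from_vcf(cls, path) -> "GenotypeTable":
        from cyvcf2 import VCF
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        snp_ids, rows = [], []
        for variant in vcf:
            snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
            gts = variant.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            dos = np.where(gts == 0, 0.0,
                           np.where(gts == 1, 1.0,
                                    np.where(gts == 3, 2.0, np.nan)))
            rows.append(dos)
        return cls(snp_ids=snp_ids, sample_ids=samples,
                   dosages=np.array(rows, dtype=float).T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


@dataclass
class AssociationRecord:
    """One SNP-feature association test within a tissue."""

    snp_id: str
    feature_index: int
    tissue: str
    mediating_gene: str
    component: int
    beta: float
    se: float
    t_stat: float
    p: float
    q_fdr: float = np.nan
    n_used: int = 0
    degenerate: bool = False


def quantile_normalize_features(F: np.ndarray) -> np.ndarray:
    """Project each feature onto the quantiles of the pooled distribution.

    Every value is replaced by the quantile of the pooled distribution of
    all n*q values taken at that value's fractional rank within its own
    feature ((rank - 0.5)/n, average ranks for ties).  Constant features
    map to the pooled median, with a warning.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] < 3:
        raise ValueError("need an (n >= 3, q) feature matrix")
    n, q = F.shape
    pooled = np.sort(F.ravel())
    out = np.empty_like(F)
    n_constant = 0
    for j in range(q):
        col = F[:, j]
        if np.all(col == col[0]):
            n_constant += 1
            out[:, j] = np.quantile(pooled, 0.5)
            continue
        frac = (rankdata(col, method="average") - 0.5) / n
        out[:, j] = np.quantile(pooled, frac)
    if n_constant:
        warnings.warn(f"{n_constant} constant features mapped to the pooled median")
    return out


def standardize_features(F: np.ndarray) -> np.ndarray:
    """Alternative normalization: z-score each feature (mean 0, sd 1)."""
    F = np.asarray(F, dtype=float)
    sd = F.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (F - F.mean(axis=0)) / sd


def build_test_set(decomp, eqtl_table: pd.DataFrame, expr_raw: pd.DataFrame,
                   tissue_labels, min_samples: int = 20,
                   top_components: int = 100) -> pd.DataFrame:
    """Enumerate the (snp, feature, tissue, gene, component) tests.

    A pair is tested iff, for some component k <= top_components:
    the gene carries non-zero weight in component k, the SNP is a known
    cis-eQTL of that gene in that tissue, the feature carries non-zero
    weight in component k, the tissue has at least ``min_samples`` imaged
    samples, and the gene has non-zero expression in that tissue (median
    raw value > 0).  Duplicates are collapsed.
    """
    labels = pd.Series(tissue_labels)
    tissue_counts = labels.value_counts()
    ok_tissues = set(tissue_counts[tissue_counts >= min_samples].index)
    gene_index = {g: i for i, g in enumerate(decomp.gene_ids)}
    eq = eqtl_table[["snp_id", "gene_id", "tissue"]]
    rows = []
    K = min(top_components, decomp.n_components)
    for k in range(K):
        genes_k = {g for g in decomp.gene_ids
                   if decomp.U[gene_index[g], k] != 0}
        if not genes_k:
            continue
        feats_k = np.nonzero(decomp.V[:, k])[0]
        if feats_k.size == 0:
            continue
        sub = eq[eq["gene_id"].isin(genes_k) & eq["tissue"].isin(ok_tissues)]
        for snp, gene, tissue in sub.itertuples(index=False):
            if gene in expr_raw.index:
                in_tissue = labels.index[labels == tissue]
                cols = expr_raw.columns.intersection(in_tissue)
                if len(cols) == 0 or np.median(expr_raw.loc[gene, cols]) <= 0:
                    continue
            for f in feats_k:
                rows.append((snp, int(f), tissue, gene, k))
    if not rows:
        warnings.warn("no (snp, feature, tissue) pairs satisfy the filters")
        return pd.DataFrame(columns=["snp_id", "feature_index", "tissue",
                                     "gene_id", "component"])
    df = pd.DataFrame(rows, columns=["snp_id", "feature_index", "tissue",
                                     "gene_id", "component"])
    return df.drop_duplicates(ignore_index=True)


def _ols_single(x: np.ndarray, y: np.ndarray):
    """Univariate OLS of y on x with intercept; returns (beta, se, t, p, dgn)."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    beta = (xc @ yc) / sxx
    resid = yc - beta * xc
    dof = n - 2
    sigma2 = (resid @ resid) / dof
    if sigma2 <= 0:
        tiny = np.finfo(float).tiny
        return beta, 0.0, np.inf if beta != 0 else 0.0, tiny, True
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return beta, se, t, max(p, np.finfo(float).tiny), False


def association_scan(G: GenotypeTable, F: np.ndarray, pairs: pd.DataFrame,
                     tissue_labels, sample_ids=None, min_samples: int = 20,
                     fdr_threshold: float = 0.1,
                     fdr_per_tissue: bool = False) -> pd.DataFrame:
    """Univariate linear scan over the enumerated (SNP, feature) pairs.

    For each pair, ordinary least squares of the normalized feature on the
    allele dosage within the pair's tissue: effect beta per allele, its
    standard error, the T statistic and its two-sided p-value on n-2
    degrees of freedom.  Missing dosages are dropped pairwise; pairs with
    no genotype variance or fewer than ``min_samples`` complete cases are
    skipped.  q-values come from Benjamini-Hochberg, pooled over all tests
    (or within tissue with ``fdr_per_tissue``).
    """
    F = np.asarray(F, dtype=float)
    sample_ids = list(sample_ids) if sample_ids is not None else list(G.sample_ids)
    if F.shape[0] != len(sample_ids):
        raise ValueError("feature matrix rows do not match sample ids")
    labels = pd.Series(tissue_labels)
    g_pos = {s: i for i, s in enumerate(G.sample_ids)}
    f_pos = {s: i for i, s in enumerate(sample_ids)}
    snp_col = {s: j for j, s in enumerate(G.snp_ids)}
    # one regression per unique (snp, feature, tissue); a pair reachable
    # through several mediating genes or components is still one test
    unique = (pairs
              .groupby(["snp_id", "feature_index", "tissue"], sort=False)
              .agg(gene_id=("gene_id",
                            lambda g: ";".join(sorted(set(g)))),
                   component=("component", "min"))
              .reset_index())
    records = []
    for row in unique.itertuples(index=False):
        tissue_samples = [s for s in labels.index[labels == row.tissue]
                          if s in g_pos and s in f_pos]
        j = snp_col.get(row.snp_id)
        if j is None or not tissue_samples:
            continue
        x = np.array([G.dosages[g_pos[s], j] for s in tissue_samples])
        y = np.array([F[f_pos[s], row.feature_index] for s in tissue_samples])
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < min_samples:
            continue
        if np.all(x == x[0]):
            continue  # zero genotype variance in this tissue
        beta, se, t, p, degenerate = _ols_single(x, y)
        records.append(AssociationRecord(
            snp_id=row.snp_id, feature_index=int(row.feature_index),
            tissue=row.tissue, mediating_gene=row.gene_id,
            component=int(row.component), beta=float(beta), se=float(se),
            t_stat=float(t), p=float(p), n_used=int(len(x)),
            degenerate=degenerate))
    if not records:
        return pd.DataFrame(columns=[
            "snp_id", "feature_index", "tissue", "mediating_gene", "component",
            "beta", "se", "t_stat", "p", "q_fdr", "n_used", "degenerate",
            "discovery"])
    df = pd.DataFrame([r.__dict__ for r in records])
    if fdr_per_tissue:
        df["q_fdr"] = np.nan
        df["discovery"] = False
        for t in df["tissue"].unique():
            m = df["tissue"] == t
            q, disc = bh_fdr(df.loc[m, "p"].to_numpy(), fdr_threshold)
            df.loc[m, "q_fdr"] = q
            df.loc[m, "discovery"] = disc
    else:
        q, disc = bh_fdr(df["p"].to_numpy(), fdr_threshold)
        df["q_fdr"] = q
        df["discovery"] = disc
    return df.sort_values("q_fdr", kind="stable").reset_index(drop=True)


def bh_fdr(p_values: np.ndarray, threshold: float = 0.1):
    """Benjamini-Hochberg step-up q-values and the discovery mask q <= threshold."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= threshold
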