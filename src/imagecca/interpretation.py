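"""Component interpretation utilities.

Given a fitted decomposition these helpers rank the samples at the two
extremes of a component's canonical variate, summarise where a component's
genes are expressed across tissues, correlate components with sample
covariates (with a sign-flip convention anchored to a reference covariate),
and test a component's gene set for over-representation in user-supplied
gene sets by one-sided Fisher's exact tests (uncorrected, as reported).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentResult",
    "TissueSpecificityMatrix",
    "rank_extreme_samples",
    "tissue_specificity",
    "covariate_correlation",
    "enrichment_fisher",
    "encode_covariates",
]


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int
    overlap: int
    p_uncorrected: float


@dataclass
class TissueSpecificityMatrix:
    """Per-gene tissue expression profiles, each row an l1-normalized simplex."""

    tissues: list
    genes: list
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.tissues)


def rank_extreme_samples(scores, sample_ids=None, fraction: float = 0.1):
    """Sample IDs at the two extremes of a canonical variate.

    Returns ``(low_ids, high_ids)``: the bottom and top ceil(fraction * n)
    samples by score.  Ties are broken by sample ID so the split is
    deterministic.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    if isinstance(scores, pd.Series):
        sample_ids = list(scores.index)
        scores = scores.to_numpy()
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    k = int(np.ceil(fraction * n))
    if 2 * k > n:  # the two extreme sets would overlap
        warnings.warn(f"n={n} too small for disjoint {fraction:.0%} extremes")
        k = min(k, n)
    order = sorted(range(n), key=lambda i: (scores[i], str(sample_ids[i])))
    low = [sample_ids[i] for i in order[:k]]
    high_order = sorted(range(n), key=lambda i: (-scores[i], str(sample_ids[i])))
    high = [sample_ids[i] for i in high_order[:k]]
    return low, high


def tissue_specificity(expr_raw: pd.DataFrame, tissue_labels,
                       component_genes, extra_tissue: str | None = None
                       ) -> TissueSpecificityMatrix:
    """Tissue expression profile of a component's genes.

    For each gene, the mean raw expression per tissue is computed and the
    row is normalized by its l1 norm so the values across tissues sum to
    one.  ``extra_tissue`` optionally appends a tissue present in the
    labels but without images (kept for comparison).  All-zero genes are
    dropped with a warning.
    """
    labels = pd.Series(tissue_labels)
    if labels.index.inferred_type in ("integer", "range"):
        labels.index = list(expr_raw.columns)[:len(labels)]
    missing = [g for g in component_genes if g not in expr_raw.index]
    if missing:
        raise KeyError(f"component genes absent from expression matrix: {missing[:5]}")
    unlabeled = [s for s in expr_raw.columns if s not in labels.index]
    if unlabeled:
        raise ValueError(f"samples without tissue labels: {unlabeled[:5]}")
    tissues = [t for t in pd.unique(labels) if t is not None]
    if extra_tissue is not None and extra_tissue not in tissues:
        tissues.append(extra_tissue)
    sub = expr_raw.loc[list(component_genes)]
    means = np.column_stack([
        sub[labels.index[labels == t].intersection(sub.columns)].mean(axis=1)
        if (labels == t).any() else np.zeros(len(sub))
        for t in tissues
    ])
    tissues = [t for j, t in enumerate(tissues) if not np.all(np.isnan(means[:, j]))]
    means = means[:, [j for j in range(means.shape[1])
                      if not np.all(np.isnan(means[:, j]))]]
    row_sums = np.nansum(means, axis=1)
    keep = row_sums > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} genes with zero expression "
                      "across all tissues")
    values = means[keep] / row_sums[keep, None]
    genes = [g for g, k in zip(component_genes, keep) if k]
    return TissueSpecificityMatrix(tissues=tissues, genes=genes, values=values)


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric-code a covariate table: categoricals become integer levels in
    order of first appearance; numerics pass through."""
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            levels = {v: i for i, v in enumerate(pd.unique(s.dropna()))}
            out[col] = s.map(levels).astype(float)
    return pd.DataFrame(out, index=covariates.index)


def covariate_correlation(decomp, covariates: pd.DataFrame,
                          reference_covariate: str,
                          use_image_scores: bool = True) -> pd.DataFrame:
    """Pearson correlation of each component's canonical variate with each
    covariate, sign-flipped so the correlation with the reference covariate
    is non-negative (the whole component row is negated together).

    Missing covariate entries are pairwise-deleted.  Returns a K x C
    DataFrame.
    """
    scores = decomp.image_scores if use_image_scores else decomp.gene_scores
    cov = encode_covariates(covariates)
    if reference_covariate not in cov.columns:
        raise KeyError(f"reference covariate {reference_covariate!r} not found")
    if decomp.sample_ids and list(cov.index) != list(decomp.sample_ids):
        cov = cov.reindex(decomp.sample_ids)
    K = scores.shape[1]
    R = np.full((K, cov.shape[1]), np.nan)
    for j, col in enumerate(cov.columns):
        y = cov[col].to_numpy()
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.std(y[ok]) == 0:
            continue
        yc = y[ok] - y[ok].mean()
        for k in range(K):
            x = scores[ok, k]
            sx = x.std()
            if sx == 0:
                continue
            R[k, j] = float((x - x.mean()) @ yc / (len(yc) * sx * y[ok].std()))
    ref_j = list(cov.columns).index(reference_covariate)
    ref_col = R[:, ref_j]
    if np.all(~np.isfinite(ref_col)):
        warnings.warn(f"reference covariate {reference_covariate!r} is constant "
                      "or missing; no sign flip applied")
    else:
        flip = np.where(np.nan_to_num(ref_col) < 0, -1.0, 1.0)
        R = R * flip[:, None]
    return pd.DataFrame(R, columns=cov.columns,
                        index=[f"component_{k + 1}" for k in range(K)])


def enrichment_fisher(query_genes, universe, term_sets: dict
                      ) -> list[EnrichmentResult]:
    """One-sided (over-representation) Fisher's exact test per gene set.

    ``term_sets`` maps term id -> iterable of gene ids (e.g. a parsed GMT
    file); terms are intersected with the universe first.  p-values are the
    hypergeometric upper tail P(X >= overlap) and are *not* corrected for
    multiple testing.  Results are sorted by p.
    """
    query = set(query_genes)
    uni = set(universe)
    if not uni or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    N, n_query = len(uni), len(query)
    results = []
    for term, genes in term_sets.items():
        t = set(genes) & uni
        if not t:
            continue
        overlap = len(t & query)
        p = float(hypergeom.sf(overlap - 1, N, len(t), n_query))
        results.append(EnrichmentResult(term_id=term, term_size=len(t),
                                        overlap=overlap,
                                        p_uncorrected=min(p, 1.0)))
    results.sort(key=lambda r: (r.p_uncorrected, r.term_id))
    return results
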