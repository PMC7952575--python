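"""Paired feature-matrix construction.

Image side: window codes are averaged per sample (bag of features) and the
resulting n x q matrix is PCA-whitened so the image features entering CCA
are decorrelated with unit variance.  Expression side: a genes x samples
abundance matrix (TPM/RPKM) is log-transformed and per-gene standardized.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EmbeddingMatrix",
    "ExpressionMatrix",
    "WhiteningBasis",
    "average_embeddings",
    "pca_whiten",
    "preprocess_expression",
]


@dataclass
class WhiteningBasis:
    """Stored PCA-whitening transform: x -> (x - mean) @ rotation / scales."""

    mean: np.ndarray       # (q,)
    rotation: np.ndarray   # (q, r) principal axes, columns
    scales: np.ndarray     # (r,) per-axis standard deviations

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.rotation / self.scales

    def to_json(self) -> str:
        return json.dumps({
            "mean": self.mean.tolist(),
            "rotation": self.rotation.tolist(),
            "scales": self.scales.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "WhiteningBasis":
        d = json.loads(text)
        return cls(np.array(d["mean"]), np.array(d["rotation"]), np.array(d["scales"]))


@dataclass
class EmbeddingMatrix:
    """Per-sample averaged image representations (n samples x q features)."""

    sample_ids: list
    values: np.ndarray
    whitened: bool = False
    basis: WhiteningBasis | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match value rows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Preprocessed expression: n samples x p genes, each gene standardized."""

    sample_ids: list
    gene_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValueError("id lists do not match matrix shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def average_embeddings(window_codes: np.ndarray) -> np.ndarray:
    """Average the m window codes of one sample into a single q-vector.

    y_j = (1/m) * sum_l x_{j,l}; the mean is taken in sorted order per
    dimension so the result is bitwise invariant to window order.
    """
    codes = np.asarray(window_codes, dtype=float)
    if codes.ndim != 2 or codes.shape[0] < 1:
        raise ValueError("expected a non-empty (m, q) code matrix")
    return np.sort(codes, axis=0).mean(axis=0)


def pca_whiten(E: EmbeddingMatrix, eps: float = 1e-8) -> EmbeddingMatrix:
    """PCA-whiten an embedding matrix.

    Centers, rotates to principal axes and rescales each retained axis to
    unit variance; axes with eigenvalue <= eps are dropped, so the output
    has rank min(n-1, q) columns at most and its sample covariance is the
    identity on the retained axes.  The fitted basis can transform new
    samples consistently.
    """
    X = E.values
    n, q = X.shape
    if n < 2:
        raise ValueError("whitening requires at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    keep = eigvals > eps
    r = int(keep.sum())
    rotation = Vt[:r].T
    scales = np.sqrt(eigvals[:r])
    basis = WhiteningBasis(mean=mean, rotation=rotation, scales=scales)
    white = U[:, :r] * np.sqrt(n - 1)
    return EmbeddingMatrix(sample_ids=list(E.sample_ids), values=white,
                           whitened=True, basis=basis)


def preprocess_expression(raw: pd.DataFrame, pseudocount: float = 1.0,
                          log_base: float = 2.0,
                          sample_ids=None) -> ExpressionMatrix:
    """Prepare a genes x samples abundance matrix for CCA.

    Applies log(x + pseudocount) (base 2 by default), drops zero-variance
    genes, and standardizes each gene to mean 0 / sd 1 (sample sd).  If
    ``sample_ids`` is given, samples are restricted to (and ordered by)
    that list intersected with the matrix columns.
    """
    if not isinstance(raw, pd.DataFrame):
        raise TypeError("raw expression must be a genes x samples DataFrame")
    if (raw.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    if sample_ids is not None:
        cols = [s for s in sample_ids if s in raw.columns]
        if not cols:
            raise ValueError("no overlap between requested samples and matrix columns")
        raw = raw[cols]
    logged = np.log(raw.to_numpy(dtype=float) + pseudocount) / np.log(log_base)
    sd = logged.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} zero-variance genes")
    logged = logged[keep]
    sd = sd[keep]
    z = (logged - logged.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        sample_ids=list(raw.columns),
        gene_ids=list(np.asarray(raw.index)[keep]),
        values=z.T,
    )
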