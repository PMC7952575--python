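"""Sparse canonical correlation analysis by penalized matrix decomposition.

Components are extracted one at a time as rank-1 factors (u, v, d) of the
cross-product matrix C = X'Z/(n-1) under unit-l2 / bounded-l1 constraints
on u and v, then C is deflated by d*u*v' and the next component is fitted
conditionally on the previous ones.  The within-view covariances are
treated as identity (diagonal-covariance CCA), so the penalized singular
vectors play the role of sparse canonical weight vectors.

Sparsity is parameterised by fractions lambda in (0, 1]: the l1 budget for
a weight vector of dimension d is c = lambda * sqrt(d), so lambda = 1 is
the unpenalised (dense) limit and small lambda forces few non-zero weights.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds

__all__ = [
    "CCAConfig",
    "CCADecomposition",
    "soft_threshold",
    "l1_bounded_unit_vector",
    "pmd_rank1",
    "fit_sparse_cca",
    "compute_pve",
    "tune_hyperparameters",
    "permutation_validation",
]


@dataclass
class CCAConfig:
    """Settings for the sparse CCA fit.

    lambda_images / lambda_genes are the fractional l1 penalties for the
    image-feature and gene weight vectors; K is the number of components.
    """

    K: int = 100
    lambda_images: float = 0.15
    lambda_genes: float = 0.05
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self):
        for lam, name in ((self.lambda_images, "lambda_images"),
                          (self.lambda_genes, "lambda_genes")):
            if not 0 < lam <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {lam}")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class CCADecomposition:
    """K sparse components linking genes (U) to image features (V)."""

    U: np.ndarray                 # (p, K) sparse gene weights
    V: np.ndarray                 # (q, K) sparse image-feature weights
    d: np.ndarray                 # (K,) non-negative singular values
    gene_scores: np.ndarray       # X @ U, (n, K)
    image_scores: np.ndarray      # Z @ V, (n, K)
    pve: np.ndarray               # (K,) proportion of variance explained
    config: CCAConfig
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    converged: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.d)

    def nnz(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(self.n_components),
            "nnz_genes": (self.U != 0).sum(axis=0),
            "nnz_features": (self.V != 0).sum(axis=0),
        })


def soft_threshold(x: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise sign(x) * max(|x| - delta, 0)."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def _delta_bisect(abs_a: np.ndarray, c: float, lo: float, hi: float,
                  tol: float = 1e-13) -> float:
    """Bisection fallback for the l1-bound threshold on [lo, hi]."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        s = np.maximum(abs_a - mid, 0.0)
        l2 = np.sqrt(s @ s)
        if l2 == 0 or s.sum() > c * l2:
            lo = mid
        else:
            hi = mid
    return hi


def _delta_for_l1_bound(abs_a: np.ndarray, c: float) -> float:
    """Smallest delta >= 0 with ||S(a,delta)||_1 / ||S(a,delta)||_2 <= c.

    The ratio f(delta) is continuous and decreasing in delta, piecewise
    smooth between the sorted |a| values.  The crossing segment is located
    with cumulative sums, then f(delta) = c is solved in closed form there
    (f^2 = c^2 is quadratic in delta); an interval bisection backs up the
    rare ill-conditioned segment.
    """
    u = np.sort(abs_a)  # ascending breakpoints
    d = len(u)
    # suffix sums: survivors at delta just below u[i] are the entries u[i:]
    cum1 = np.cumsum(u[::-1])[::-1]   # cum1[i] = sum of u[i:]
    cum2 = np.cumsum((u * u)[::-1])[::-1]
    k = (d - np.arange(d)).astype(float)
    # f just below u[i]: (sum - k u[i]) / sqrt(sum of squares shifted); only
    # meaningful where u[i] starts a new value block (ties collapse segments)
    num = cum1 - k * u
    den = cum2 - 2 * u * cum1 + k * u * u
    # relative guard: den is a difference of like-sized terms, so float
    # cancellation in a tied block leaves noise ~eps * cum2, not exact zero
    degenerate = den <= 1e-10 * np.maximum(cum2, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_at = np.where(degenerate, np.sqrt(k),
                        num / np.sqrt(np.maximum(den, 1e-300)))
    valid = np.empty(d, dtype=bool)
    valid[0] = True
    valid[1:] = u[1:] > u[:-1]
    f_at = np.where(valid, f_at, np.inf)
    below = np.nonzero(f_at <= c)[0]
    if below.size == 0:
        # the top |a| values are tied and the ratio plateaus at sqrt(k) > c:
        # no threshold attains the bound
        return None
    i = int(below[0])
    lo = u[i - 1] if i > 0 else 0.0
    hi = u[i]
    s1, s2, kk = cum1[i], cum2[i], float(k[i])
    A = kk * (kk - c * c)
    B = -2.0 * s1 * (kk - c * c)
    C = s1 * s1 - c * c * s2
    if abs(A) < 1e-12 * max(1.0, s1 * s1):
        return _delta_bisect(abs_a, c, lo, hi)
    disc = B * B - 4 * A * C
    if disc < 0:
        return _delta_bisect(abs_a, c, lo, hi)
    r = np.sqrt(disc)
    for delta in ((-B - r) / (2 * A), (-B + r) / (2 * A)):
        if lo - 1e-12 <= delta <= hi + 1e-12:
            return float(min(max(delta, lo), hi))
    return _delta_bisect(abs_a, c, lo, hi)


def l1_bounded_unit_vector(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-l2 soft-thresholded version of ``a`` with l1 norm at most ``c``.

    Returns S(a, delta)/||S(a, delta)||_2 where delta >= 0 is the smallest
    threshold bringing the l1 norm of the normalised vector under ``c``
    (solved in closed form per sorted segment); delta = 0 when the plain
    normalisation already satisfies the bound.  c must lie in
    [1, sqrt(len(a))].
    """
    a = np.asarray(a, dtype=float)
    if not np.any(a):
        raise ValueError("cannot normalise an all-zero vector")
    if not 1 <= c <= np.sqrt(len(a)) + 1e-12:
        raise ValueError(f"c={c} outside [1, sqrt(d)={np.sqrt(len(a)):.4f}]")
    abs_a = np.abs(a)
    norm = np.sqrt(abs_a @ abs_a)
    if abs_a.sum() <= c * norm:
        return a / norm
    if c <= 1.0:  # tight bound: single non-zero at the first max-|a| entry
        out = np.zeros_like(a)
        j = int(np.argmax(abs_a))
        out[j] = np.sign(a[j])
        return out
    delta = _delta_for_l1_bound(abs_a, c)
    if delta is None:
        # tied maxima make the bound unattainable by thresholding; the
        # constrained maximiser of <a, x> spreads uniformly over the
        # floor(c^2) largest |a| (stable order breaks ties)
        k = max(1, int(np.floor(c * c)))
        idx = np.argsort(-abs_a, kind="stable")[:k]
        out = np.zeros_like(a)
        out[idx] = np.sign(a[idx]) / np.sqrt(k)
        return out
    s = soft_threshold(a, delta)
    return s / np.linalg.norm(s)


def _leading_right_singular_vector(C: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p, q = C.shape
    if min(p, q) <= 2:
        _, _, Vt = np.linalg.svd(C, full_matrices=False)
        v = Vt[0]
    else:
        v0 = rng.standard_normal(min(p, q))
        try:
            _, _, Vt = svds(C, k=1, v0=v0)
            v = Vt[0]
        except Exception:  # rare non-convergence: dense fallback
            _, _, Vt = np.linalg.svd(C, full_matrices=False)
            v = Vt[0]
    # deterministic sign: largest-|entry| coordinate positive, lowest index first
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v


def pmd_rank1(C: np.ndarray, c1: float, c2: float, tol: float = 1e-6,
              max_iter: int = 1000, init: np.ndarray | None = None,
              seed: int = 0, objective_trace: list | None = None):
    """Rank-1 penalized matrix decomposition of C (p x q).

    Alternates u <- l1_bounded_unit_vector(C v, c1) and
    v <- l1_bounded_unit_vector(C' u, c2) until the largest change in v is
    below ``tol``.  Returns ``(u, v, d, converged)`` with
    d = u' C v >= 0 (u is flipped if needed).  If ``objective_trace`` is a
    list, the objective u' C v is appended after every alternating update.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("cross-product matrix contains non-finite values")
    rng = np.random.default_rng(seed)
    v = _leading_right_singular_vector(C, rng) if init is None else np.asarray(init, float)
    u = np.zeros(C.shape[0])
    converged = False
    for _ in range(max_iter):
        Cv = C @ v
        if not np.any(Cv):  # v orthogonal to C's row space (C may be ~0)
            break
        u = l1_bounded_unit_vector(Cv, c1)
        v_new = l1_bounded_unit_vector(C.T @ u, c2)
        if objective_trace is not None:
            objective_trace.append(abs(float(u @ C @ v_new)))
        if np.max(np.abs(v_new - v)) < tol:
            v = v_new
            converged = True
            break
        v = v_new
    d = float(u @ C @ v)
    if d < 0:
        u, d = -u, -d
    return u, v, d, converged


def fit_sparse_cca(X, Z, config: CCAConfig,
                   gene_ids=None, sample_ids=None) -> CCADecomposition:
    """Fit K sparse CCA components between expression X (n x p) and image
    features Z (n x q); rows must be the same samples in the same order.

    Accepts plain arrays or the ExpressionMatrix / EmbeddingMatrix
    containers; columns are assumed standardized.
    """
    X, gene_ids, sample_ids_x = _coerce_view(X, gene_ids, sample_ids, "gene_ids")
    Z, _, sample_ids_z = _coerce_view(Z, None, sample_ids, None)
    if sample_ids_x and sample_ids_z and sample_ids_x != sample_ids_z:
        extra = sorted(set(sample_ids_x) ^ set(sample_ids_z))
        raise ValueError(f"sample mismatch between views; differing ids: {extra[:10]}")
    if X.shape[0] != Z.shape[0]:
        raise ValueError(f"views have {X.shape[0]} vs {Z.shape[0]} samples")
    n, p = X.shape
    q = Z.shape[1]
    K = config.K
    if K > min(p, q):
        warnings.warn(f"K={K} exceeds min(p, q)={min(p, q)}; truncating")
        K = min(p, q)
    c_genes = max(1.0, config.lambda_genes * np.sqrt(p))
    c_images = max(1.0, config.lambda_images * np.sqrt(q))
    C = X.T @ Z / (n - 1)
    U = np.zeros((p, K))
    V = np.zeros((q, K))
    d = np.zeros(K)
    conv = np.zeros(K, dtype=bool)
    rng = np.random.default_rng(config.seed)
    for k in range(K):
        u, v, dk, ck = _pmd_rank1_multistart(C, c_genes, c_images, config, rng)
        # reporting sign convention: strongest image-feature weight positive
        j = int(np.argmax(np.abs(v))) if np.any(v) else 0
        if v[j] < 0:
            u, v = -u, -v
        U[:, k], V[:, k], d[k], conv[k] = u, v, dk, ck
        C = C - dk * np.outer(u, v)
    decomp = CCADecomposition(
        U=U, V=V, d=d,
        gene_scores=X @ U, image_scores=Z @ V,
        pve=compute_pve(d), config=config,
        gene_ids=list(gene_ids) if gene_ids else [],
        sample_ids=list(sample_ids_x or sample_ids_z or []),
        converged=conv,
    )
    return decomp


def _pmd_rank1_multistart(C, c1, c2, config: CCAConfig,
                          rng: np.random.Generator, n_coord_inits: int = 3):
    """Deterministic multi-start for one rank-1 extraction.

    The alternating updates solve a non-convex problem; the global SVD
    direction of a noisy cross-product matrix can miss a sparse block that
    scores higher under the l1 bounds.  Besides the leading right singular
    vector, coordinate inits at the columns of C with the largest l2 norm
    are tried, and the fit with the largest d is kept (ties go to the
    earliest candidate, so the result is reproducible).
    """
    candidates = [_leading_right_singular_vector(C, rng)]
    norms = np.linalg.norm(C, axis=0)
    for j in np.argsort(-norms, kind="stable")[:n_coord_inits]:
        if norms[j] > 0:
            e = np.zeros(C.shape[1])
            e[j] = 1.0
            candidates.append(e)
    best = None
    for init in candidates:
        fit = pmd_rank1(C, c1, c2, tol=config.tol,
                        max_iter=config.max_iter, init=init)
        if best is None or fit[2] > best[2] + 1e-12:
            best = fit
    return best


def _coerce_view(M, ids, sample_ids, _name):
    """Return (array, column_ids, sample_ids) from array / DataFrame / container."""
    col_ids = list(ids) if ids is not None else None
    samp = list(sample_ids) if sample_ids is not None else None
    if hasattr(M, "values") and hasattr(M, "sample_ids"):  # our containers
        samp = samp or list(M.sample_ids)
        col_ids = col_ids or list(getattr(M, "gene_ids", []) or [])
        M = M.values
    elif isinstance(M, pd.DataFrame):
        samp = samp or list(M.index)
        col_ids = col_ids or list(M.columns)
        M = M.to_numpy()
    return np.asarray(M, dtype=float), col_ids, samp


def compute_pve(d: np.ndarray) -> np.ndarray:
    """Proportion of variance explained per component: d_k^2 / sum d_j^2."""
    d = np.asarray(getattr(d, "d", d), dtype=float)
    total = np.sum(d ** 2)
    if total == 0:
        raise ValueError("all singular values are zero")
    return d ** 2 / total


def tune_hyperparameters(X, Z, lambda_grid, holdout_fraction: float = 0.25,
                         seed: int = 0, K: int = 10) -> pd.DataFrame:
    """Grid search over (lambda_images, lambda_genes) by held-out
    cross-view reconstruction correlation.

    For each grid cell the model is fitted on a training split; each view of
    the held-out samples is then reconstructed by the least-squares linear
    map from the *other* view's canonical scores, and the flattened Pearson
    correlation between reconstruction and truth is reported
    (corr_X: genes reconstructed from image scores; corr_Z: image features
    reconstructed from gene scores).
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    Z = np.asarray(getattr(Z, "values", Z), dtype=float)
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n = X.shape[0]
    n_test = int(round(holdout_fraction * n))
    if n_test < 5 or n - n_test < 5:
        raise ValueError(f"degenerate holdout: {n_test} test of {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test, train = perm[:n_test], perm[n_test:]
    rows = []
    for lam_img, lam_gene in grid:
        cfg = CCAConfig(K=min(K, min(X.shape[1], Z.shape[1])),
                        lambda_images=lam_img, lambda_genes=lam_gene, seed=seed)
        fit = fit_sparse_cca(X[train], Z[train], cfg)
        rows.append({
            "lambda_images": lam_img,
            "lambda_genes": lam_gene,
            "corr_X": _heldout_corr(X[train], Z[train] @ fit.V,
                                    X[test], Z[test] @ fit.V),
            "corr_Z": _heldout_corr(Z[train], X[train] @ fit.U,
                                    Z[test], X[test] @ fit.U),
        })
    return pd.DataFrame(rows)


def _heldout_corr(target_train, scores_train, target_test, scores_test):
    """Pearson correlation between a view and its reconstruction from the
    other view's canonical scores (least squares fitted on training rows)."""
    B, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(len(scores_train)), scores_train]),
        target_train, rcond=None)
    recon = np.column_stack([np.ones(len(scores_test)), scores_test]) @ B
    a, b = recon.ravel(), target_test.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def permutation_validation(X, Z, config: CCAConfig, n_perms: int = 50,
                           k_top: int = 10, seed: int = 0):
    """Permutation test of cross-view structure.

    The statistic is the sum of the top ``k_top`` singular values of the
    sparse fit; the null is built by refitting after permuting the sample
    rows of X.  Returns ``(observed, null_distribution, empirical_p)`` with
    p = (1 + #{null >= observed}) / (1 + n_perms).
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    Z = np.asarray(getattr(Z, "values", Z), dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to permute")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    cfg = CCAConfig(K=min(k_top, min(X.shape[1], Z.shape[1])),
                    lambda_images=config.lambda_images,
                    lambda_genes=config.lambda_genes,
                    tol=config.tol, max_iter=config.max_iter, seed=config.seed)
    observed = float(fit_sparse_cca(X, Z, cfg).d[:k_top].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perms)
    for i in range(n_perms):
        Xp = X[rng.permutation(X.shape[0])]
        null[i] = fit_sparse_cca(Xp, Z, cfg).d[:k_top].sum()
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perms)
    return observed, null, float(p)
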