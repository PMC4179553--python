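"""Surrogate variable analysis on a training database.

The model is X = B·S + Γ·G + U: an m×n expression matrix decomposed into a
known outcome design S (p1×n), an unknown low-rank dependence structure G
(p2×n) capturing batch and other unmeasured confounders, and independent
noise U. SVA estimates G by alternating two steps:

1. empirical-Bayes feature weights: the probability pi_w that each feature
   is confounder-associated but *not* outcome-associated, from moderated
   F-test p-values converted through one minus the local FDR;
2. a singular value decomposition of the row-weighted matrix diag(pi_w)·X;
   the leading right singular vectors are the new surrogate estimate.

After a fixed number of rounds, B̂ and Γ̂ are obtained by per-feature least
squares on the stacked design [S; Ĝ], and the training set is cleaned by
subtracting Γ̂·Ĝ.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from ._ebayes import local_fdr
from ._exceptions import ContractError
from .containers import (
    DesignMatrix,
    ExpressionMatrix,
    FeatureWeights,
    SurrogateFit,
)

__all__ = [
    "build_design",
    "fit_feature_regressions",
    "estimate_num_sv",
    "eb_probability_weights",
    "weighted_svd",
    "irwsva_fit",
    "clean_training",
]

#: relative condition threshold beyond which a stacked design [S; G] is
#: treated as confounded (G numerically collinear with S)
_CONFOUND_TOL = 1e-8


def _values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def build_design(labels) -> DesignMatrix:
    """Reference-coded design matrix from a categorical label vector.

    Row 0 is the intercept; row k (k ≥ 1) indicates membership in the k-th
    class in sorted order (the lexicographically first class is the
    reference).
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if n < 2:
        raise ContractError("degenerate design: need at least 2 samples")
    classes = np.array(sorted(set(labels)), dtype=object)
    if classes.size < 2:
        raise ContractError("degenerate design: single class")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ContractError(f"insufficient replication: class {c!r} has < 2 samples")
    S = np.ones((classes.size, n))
    for k, c in enumerate(classes[1:], start=1):
        S[k] = (labels == c).astype(np.float64)
    return DesignMatrix(S=S, labels=labels, classes=classes)


def fit_feature_regressions(X, D) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature ordinary least squares of every row of X on the rows of D.

    Returns (coefficients, residuals) with coefficients m × rows(D) and
    residuals = X − coef·D. D must have full row rank.
    """
    Xv = _values(X)
    D = np.asarray(D, dtype=np.float64)
    if D.ndim == 1:
        D = D[None, :]
    if D.shape[1] != Xv.shape[1]:
        raise ContractError("design columns do not match sample count")
    if np.linalg.matrix_rank(D) < D.shape[0]:
        raise ContractError("singular design")
    gram = D @ D.T
    coef = np.linalg.solve(gram, D @ Xv.T).T
    resid = Xv - coef @ D
    return coef, resid


def weighted_svd(X, w) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of diag(w)·X with a deterministic sign convention.

    Singular values descend; in every left singular vector the
    largest-magnitude entry is made positive (ties resolved to the lowest
    index), with the matching right singular vector flipped accordingly, so
    repeated runs are bit-identical.
    """
    Xv = _values(X)
    w = np.asarray(w, dtype=np.float64)
    if not np.all(np.isfinite(Xv)) or not np.all(np.isfinite(w)):
        raise ContractError("invalid matrix: non-finite input")
    if w.ndim != 1 or w.size != Xv.shape[0]:
        raise ContractError("invalid matrix: weight length must equal feature count")
    if np.any(w < 0):
        raise ContractError("invalid matrix: negative weight")
    return _signed_svd(w[:, None] * Xv)


def _signed_svd(WX: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, d, Vt = scipy.linalg.svd(WX, full_matrices=False, lapack_driver="gesdd")
    # sign convention: dominant entry of each left singular vector positive
    peaks = np.argmax(np.abs(U), axis=0)
    flip = U[peaks, np.arange(U.shape[1])] < 0
    U[:, flip] *= -1.0
    Vt[flip] *= -1.0
    return U, d, Vt.T


def estimate_num_sv(X, S: DesignMatrix, n_perm: int = 20, alpha: float = 0.05,
                    seed: int = 0) -> int:
    """Permutation (parallel-analysis) estimate of the number of surrogates.

    Residualizes X on S, measures the proportion of variance carried by each
    right singular vector of the residual matrix, and compares against a null
    built by permuting each feature's residuals independently and
    re-residualizing. Counts leading components whose observed share exceeds
    the (1−alpha) null quantile, stopping at the first non-significant one.
    """
    if n_perm < 1:
        raise ContractError("invalid parameter: n_perm must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ContractError("invalid parameter: alpha must be in (0, 1)")
    Xv = _values(X)
    Smat = S.S if isinstance(S, DesignMatrix) else np.asarray(S, dtype=np.float64)
    _, resid = fit_feature_regressions(Xv, Smat)
    n = Xv.shape[1]
    p1 = Smat.shape[0] if Smat.ndim == 2 else 1
    n_comp = min(Xv.shape[0], n) - p1
    if n_comp < 1:
        return 0

    def _var_share(R):
        d = scipy.linalg.svdvals(R)
        total = np.sum(d ** 2)
        if total <= 0:
            return np.zeros(min(len(d), n_comp))
        return (d ** 2 / total)[:n_comp]

    observed = _var_share(resid)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.size))
    for b in range(n_perm):
        permuted = rng.permuted(resid, axis=1)
        _, perm_resid = fit_feature_regressions(permuted, Smat)
        null[b] = _var_share(perm_resid)
    thresholds = np.quantile(null, 1.0 - alpha, axis=0)
    count = 0
    for k in range(observed.size):
        if observed[k] > thresholds[k]:
            count += 1
        else:
            break
    return count


def _f_test_pvalues(Xv: np.ndarray, full: np.ndarray, reduced: np.ndarray,
                    ok: np.ndarray) -> np.ndarray:
    """Ordinary per-feature F-test p-values of *full* against nested *reduced*."""
    import scipy.stats

    n = Xv.shape[1]
    df_full = n - full.shape[0]
    df_diff = full.shape[0] - reduced.shape[0]
    if df_full < 1:
        raise ContractError("confounded design: no residual degrees of freedom")
    _, r_full = fit_feature_regressions(Xv, full)
    _, r_red = fit_feature_regressions(Xv, reduced)
    rss1 = np.sum(r_full ** 2, axis=1)
    rss0 = np.sum(r_red ** 2, axis=1)
    p = np.ones(Xv.shape[0])
    pos = ok & (rss1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0[pos] - rss1[pos]) / df_diff) / (rss1[pos] / df_full)
    p[pos] = scipy.stats.f.sf(np.maximum(f, 0.0), df_diff, df_full)
    # perfect fit under the full model: overwhelming evidence of association
    p[ok & (rss1 <= 0) & (rss0 > 0)] = 0.0
    return p


def eb_probability_weights(X, S: DesignMatrix, G_hat: np.ndarray) -> FeatureWeights:
    """Per-feature probabilities of surrogate- and outcome-association.

    pi_gamma comes from F-tests of the surrogate rows ([S; G] vs S) and pi_b
    from F-tests of the outcome rows ([S; G] vs [intercept; G]), each
    converted to a posterior probability as 1 − localFDR. Zero-variance
    features get all-zero weights and are excluded from density estimation.
    """
    Xv = _values(X)
    Smat = S.S if isinstance(S, DesignMatrix) else np.asarray(S, dtype=np.float64)
    G_hat = np.asarray(G_hat, dtype=np.float64)
    if G_hat.ndim == 1:
        G_hat = G_hat[None, :]
    if G_hat.shape[0] < 1:
        raise ContractError("invalid parameter: need at least one surrogate row")
    stacked = np.vstack([Smat, G_hat])
    sv = scipy.linalg.svdvals(stacked)
    if sv[-1] <= _CONFOUND_TOL * sv[0]:
        raise ContractError("confounded design: surrogate collinear with outcome design")

    m = Xv.shape[0]
    ok = Xv.var(axis=1) > 0
    p_gamma = _f_test_pvalues(Xv, stacked, Smat, ok)
    reduced_b = np.vstack([np.ones((1, Xv.shape[1])), G_hat])
    p_b = _f_test_pvalues(Xv, stacked, reduced_b, ok)

    pi_gamma = np.zeros(m)
    pi_b = np.zeros(m)
    if ok.any():
        pi_gamma[ok] = np.clip(1.0 - local_fdr(p_gamma[ok]), 0.0, 1.0)
        pi_b[ok] = np.clip(1.0 - local_fdr(p_b[ok]), 0.0, 1.0)
    pi_w = (1.0 - pi_b) * pi_gamma
    return FeatureWeights(pi_gamma=pi_gamma, pi_b=pi_b, pi_w=pi_w)


def irwsva_fit(X: ExpressionMatrix, S: DesignMatrix, n_sv: int,
               n_iter: int = 5) -> SurrogateFit:
    """Iteratively re-weighted SVA fit with a fixed iteration budget.

    Initializes the surrogates from the unweighted SVD of the residuals of X
    on S, then alternates the weight and weighted-SVD steps ``n_iter`` times.
    The final surrogates are the leading right singular vectors of
    diag(pi_w)·X; coefficients come from least squares on [S; Ĝ].
    """
    Xv = _values(X)
    m, n = Xv.shape
    p1 = S.p1
    if not (1 <= n_sv <= min(m, n) - p1):
        raise ContractError(f"invalid n_sv: must be in [1, {min(m, n) - p1}]")
    if n_iter < 1:
        raise ContractError("invalid parameter: n_iter must be >= 1")

    _, resid = fit_feature_regressions(Xv, S.S)
    _, _, V0 = _signed_svd(resid)
    G = V0[:, :n_sv].T

    weights = None
    U = d = V = None
    for _ in range(n_iter):
        weights = eb_probability_weights(Xv, S, G)
        U, d, V = weighted_svd(Xv, weights.pi_w)
        G = V[:, :n_sv].T

    stacked = np.vstack([S.S, G])
    coef, noise = fit_feature_regressions(Xv, stacked)
    B_hat = coef[:, :p1]
    Gamma_hat = coef[:, p1:]
    return SurrogateFit(
        n_sv=n_sv, G_hat=G, Gamma_hat=Gamma_hat, B_hat=B_hat,
        weights=weights, svd_U=U, svd_D=d, svd_V=V, noise=noise,
        n_iter=n_iter,
    )


def clean_training(X: ExpressionMatrix, fit: SurrogateFit) -> ExpressionMatrix:
    """Remove the estimated confounder signal: X_clean = X − Γ̂·Ĝ."""
    if isinstance(X, ExpressionMatrix):
        vals, fids, sids = X.values, X.feature_ids, X.sample_ids
    else:
        vals = np.asarray(X, dtype=np.float64)
        fids = [f"feature{i}" for i in range(vals.shape[0])]
        sids = [f"sample{j}" for j in range(vals.shape[1])]
    if vals.shape[0] != fit.m or vals.shape[1] != fit.n:
        raise ContractError("fit/data mismatch")
    return ExpressionMatrix(vals - fit.Gamma_hat @ fit.G_hat, fids, sids)
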