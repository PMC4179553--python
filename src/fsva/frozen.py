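"""Frozen correction of new samples.

Once a surrogate-variable model has been fit on a training database, new
samples arriving one at a time can be batch-corrected without knowing their
batch or outcome, by borrowing the training-set quantities:

* **exact mode** appends the single new sample to the retained training
  matrix, recomputes the weighted SVD with the *frozen* training feature
  weights, and reads the new sample's surrogate values off the augmented
  right singular vectors;
* **fast mode** skips the decomposition entirely: the operator
  P = D⁻¹·Uᵀ·W projects any column onto the training right singular
  vectors, so P·x estimates the surrogate values of a new sample x in one
  matrix-vector product.

Either way the corrected sample is x − Γ̂·ĝ with the frozen training
coefficients Γ̂.
"""

from __future__ import annotations

import numpy as np

from ._exceptions import ContractError
from .containers import (
    ExpressionMatrix,
    FrozenModel,
    ProjectionOperator,
    SurrogateFit,
)
from .sva import _signed_svd

__all__ = [
    "build_projection",
    "build_frozen_model",
    "fsva_fast",
    "fsva_exact_one",
    "fsva_exact",
    "align_surrogates",
]

DEFAULT_SV_TOL = 1e-10


def build_projection(fit: SurrogateFit, sv_tol: float = DEFAULT_SV_TOL) -> ProjectionOperator:
    """Assemble P = diag(D)⁻¹ · Uᵀ · diag(w) over the usable components.

    Components with singular value ≤ sv_tol·D₁ are dropped (their inverse is
    numerically meaningless). Requires at least n_sv usable components.
    """
    d = fit.svd_D
    if d.size == 0 or d[0] <= 0:
        raise ContractError("rank too low: no nonzero singular values")
    keep = int(np.sum(d > sv_tol * d[0]))
    if keep < fit.n_sv:
        raise ContractError("rank too low: fewer usable components than surrogates")
    P = (fit.svd_U[:, :keep].T * fit.weights.pi_w[None, :]) / d[:keep, None]
    # canonical memory layout so saved/reloaded models reproduce corrections
    # bit-for-bit (BLAS summation order depends on strides)
    return ProjectionOperator(P=np.ascontiguousarray(P), n_sv=fit.n_sv)


def build_frozen_model(X_train: ExpressionMatrix, fit: SurrogateFit,
                       keep_train: bool = True,
                       sv_tol: float = DEFAULT_SV_TOL) -> FrozenModel:
    """Bundle a fit with its projection operator (and optionally the data).

    Fast-only models (``keep_train=False``) drop the training matrix and
    support only :func:`fsva_fast`.
    """
    if X_train.m != fit.m or X_train.n != fit.n:
        raise ContractError("fit/data mismatch")
    proj = build_projection(fit, sv_tol=sv_tol)
    return FrozenModel(
        fit=fit, projection=proj,
        X_train=X_train if keep_train else None,
        feature_ids=X_train.feature_ids,
    )


def _aligned_values(model: FrozenModel, X_new: ExpressionMatrix) -> ExpressionMatrix:
    try:
        return X_new.reorder_features(model.feature_ids)
    except ContractError:
        raise ContractError("feature space mismatch") from None


def fsva_fast(model: FrozenModel, X_new: ExpressionMatrix) -> ExpressionMatrix:
    """Fast frozen correction: project, then subtract Γ̂·Ĝ_new.

    Columns are corrected independently — the result for any sample does not
    depend on which other samples share the matrix.
    """
    Xn = _aligned_values(model, X_new)
    P = model.projection.P[: model.fit.n_sv]
    # columns corrected one at a time so each sample's result is bit-identical
    # no matter which other samples share the matrix
    cleaned = np.empty_like(Xn.values)
    for j in range(Xn.n):
        x = np.ascontiguousarray(Xn.values[:, j])
        cleaned[:, j] = x - model.fit.Gamma_hat @ (P @ x)
    return ExpressionMatrix(cleaned, Xn.feature_ids, Xn.sample_ids)


def align_surrogates(G_aug_train: np.ndarray, G_train: np.ndarray) -> np.ndarray:
    """Least-squares scalar (sign + scale) mapping augmented onto training SVs.

    For each component k returns c_k minimizing ‖c·G_aug_train[k] −
    G_train[k]‖; applying c_k to the full augmented surrogate rows makes the
    frozen Γ̂ applicable despite the sign/scale indeterminacy of the augmented
    decomposition.
    """
    G_aug_train = np.asarray(G_aug_train, dtype=np.float64)
    G_train = np.asarray(G_train, dtype=np.float64)
    if G_aug_train.shape != G_train.shape:
        raise ContractError("surrogate matrices differ in shape")
    denom = np.sum(G_aug_train ** 2, axis=1)
    if np.any(denom <= 0):
        raise ContractError("degenerate component: zero-variance augmented surrogate")
    return np.sum(G_aug_train * G_train, axis=1) / denom


def fsva_exact_one(model: FrozenModel, x_new: np.ndarray) -> np.ndarray:
    """Exact frozen correction of one sample via the augmented weighted SVD.

    Appends the sample to the training matrix, decomposes diag(w)·[X | x]
    with the frozen weights, aligns the augmented surrogates to the training
    surrogates on the training columns, and subtracts Γ̂ times the new
    sample's aligned surrogate values.
    """
    if model.X_train is None:
        raise ContractError("exact mode unavailable: model has no training matrix")
    x = np.asarray(x_new, dtype=np.float64).ravel()
    if x.size != model.fit.m:
        raise ContractError("feature space mismatch")
    if not np.all(np.isfinite(x)):
        raise ContractError("invalid sample: non-finite value")
    fit = model.fit
    n = fit.n
    w = fit.weights.pi_w
    WX_aug = np.empty((fit.m, n + 1))
    WX_aug[:, :n] = w[:, None] * model.X_train.values
    WX_aug[:, n] = w * x
    _, _, V = _signed_svd(WX_aug)
    G_aug = V[:, : fit.n_sv].T
    c = align_surrogates(G_aug[:, :n], fit.G_hat)
    g_new = c * G_aug[:, n]
    return x - fit.Gamma_hat @ g_new


def fsva_exact(model: FrozenModel, X_new: ExpressionMatrix) -> ExpressionMatrix:
    """Exact frozen correction of a sample set, one column at a time.

    Samples are never appended jointly: appending several new samples at once
    would let the decomposition latch onto similarities *among* the new
    samples rather than between each new sample and the database.
    """
    Xn = _aligned_values(model, X_new)
    cleaned = np.empty_like(Xn.values)
    for j in range(Xn.n):
        cleaned[:, j] = fsva_exact_one(model, Xn.values[:, j])
    return ExpressionMatrix(cleaned, Xn.feature_ids, Xn.sample_ids)
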