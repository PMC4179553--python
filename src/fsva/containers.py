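"""Core data containers.

The orientation convention throughout the package is *features in rows,
samples in columns*: an expression matrix is m features by n samples, a
design matrix has one row per covariate and one column per sample, and the
surrogate-variable matrix G has one row per latent factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ContractError

__all__ = [
    "ExpressionMatrix",
    "DesignMatrix",
    "FeatureWeights",
    "SurrogateFit",
    "ProjectionOperator",
    "FrozenModel",
]


def _as_id_array(ids, what: str, expected: int) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1 or arr.size != expected:
        raise ContractError(f"{what}: expected {expected} identifiers, got shape {arr.shape}")
    arr = np.array([str(x) for x in arr], dtype=object)
    if len(set(arr)) != arr.size:
        raise ContractError(f"duplicate identifier in {what}")
    return arr


@dataclass(frozen=True)
class ExpressionMatrix:
    """An m-feature by n-sample real-valued expression matrix.

    Values may be in any expression unit (log intensities, normalized counts);
    the methods in this package are unit-agnostic. Non-finite entries are
    rejected at construction.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ContractError(f"expression values must be 2-D, got ndim={vals.ndim}")
        m, n = vals.shape
        if m < 1 or n < 1:
            raise ContractError("empty matrix")
        if not np.all(np.isfinite(vals)):
            raise ContractError("non-finite value in expression matrix")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "feature_ids", _as_id_array(self.feature_ids, "feature_ids", m))
        object.__setattr__(self, "sample_ids", _as_id_array(self.sample_ids, "sample_ids", n))

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(self.values[:, idx], self.feature_ids, self.sample_ids[idx])

    def reorder_features(self, feature_ids) -> "ExpressionMatrix":
        """Return a copy with rows reordered to match *feature_ids*.

        Raises ContractError if the feature sets differ.
        """
        want = _as_id_array(feature_ids, "feature_ids", len(feature_ids))
        if set(want) != set(self.feature_ids):
            raise ContractError("feature space mismatch")
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        order = np.array([pos[f] for f in want])
        return ExpressionMatrix(self.values[order], want, self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=np.float64), df.index.to_numpy(), df.columns.to_numpy())


@dataclass(frozen=True)
class DesignMatrix:
    """Outcome model matrix: intercept row plus K−1 class-indicator rows.

    ``S`` is p1 × n with an all-ones first row; ``labels`` holds the original
    class label of each sample and ``classes`` the sorted distinct labels
    (reference class first).
    """

    S: np.ndarray
    labels: np.ndarray
    classes: np.ndarray = field(default=None)

    def __post_init__(self):
        S = np.asarray(self.S, dtype=np.float64)
        if S.ndim == 1:
            S = S[None, :]
        if not np.all(np.isfinite(S)):
            raise ContractError("non-finite value in design matrix")
        object.__setattr__(self, "S", S)
        labels = np.asarray(self.labels, dtype=object)
        if labels.size != S.shape[1]:
            raise ContractError("labels length does not match design columns")
        object.__setattr__(self, "labels", labels)
        if self.classes is None:
            object.__setattr__(self, "classes", np.array(sorted(set(labels)), dtype=object))

    @property
    def p1(self) -> int:
        return self.S.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]


@dataclass(frozen=True)
class FeatureWeights:
    """Per-feature empirical-Bayes probability weights.

    pi_gamma_i estimates Pr(feature i associated with the surrogate
    variables), pi_b_i estimates Pr(associated with the outcome | associated
    with the surrogates), and pi_w = (1 − pi_b)·pi_gamma is the probability of
    being confounder-driven but not outcome-driven — the SVD row weight.
    """

    pi_gamma: np.ndarray
    pi_b: np.ndarray
    pi_w: np.ndarray

    def __post_init__(self):
        for name in ("pi_gamma", "pi_b", "pi_w"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.ndim != 1:
                raise ContractError(f"{name} must be 1-D")
            if not np.all(np.isfinite(v)) or v.min() < 0 or v.max() > 1:
                raise ContractError(f"{name} outside [0, 1]")
            object.__setattr__(self, name, v)
        if not (self.pi_gamma.size == self.pi_b.size == self.pi_w.size):
            raise ContractError("weight vectors differ in length")
        if not np.allclose(self.pi_w, (1.0 - self.pi_b) * self.pi_gamma, atol=1e-12):
            raise ContractError("pi_w must equal (1 - pi_b) * pi_gamma")


@dataclass(frozen=True)
class SurrogateFit:
    """A fitted surrogate-variable model on a training database.

    Holds the estimated surrogate variables ``G_hat`` (rows are right singular
    vectors of the weighted matrix W·X), the least-squares coefficients
    ``B_hat`` (outcome design) and ``Gamma_hat`` (surrogates), the final
    feature weights, and the frozen SVD factors of W·X used later to correct
    new samples. ``noise`` is the exact residual X − B̂S − Γ̂Ĝ (None on models
    reloaded from disk without a retained training matrix).
    """

    n_sv: int
    G_hat: np.ndarray          # (n_sv, n)
    Gamma_hat: np.ndarray      # (m, n_sv)
    B_hat: np.ndarray          # (m, p1)
    weights: FeatureWeights
    svd_U: np.ndarray          # (m, r)
    svd_D: np.ndarray          # (r,)
    svd_V: np.ndarray          # (n, r)
    noise: np.ndarray | None   # (m, n)
    n_iter: int | None = None
    seed: int | None = None

    @property
    def m(self) -> int:
        return self.Gamma_hat.shape[0]

    @property
    def n(self) -> int:
        return self.G_hat.shape[1]


@dataclass(frozen=True)
class ProjectionOperator:
    """Maps a sample column x to its right-singular-vector coordinates.

    P = diag(D)^{-1} · Uᵀ · diag(w), restricted to components whose singular
    value exceeds tolerance; by the SVD identity Vᵀ = D⁻¹UᵀWX, P·X_train
    reproduces the training right singular vectors. The first ``n_sv`` rows
    are the surrogate-variable projectors.
    """

    P: np.ndarray              # (r_kept, m)
    n_sv: int


@dataclass(frozen=True)
class FrozenModel:
    """Everything needed to batch-correct new samples one at a time.

    ``X_train`` may be None for fast-only models (the exact mode requires the
    retained training matrix for the augmented decomposition).
    """

    fit: SurrogateFit
    projection: ProjectionOperator
    X_train: ExpressionMatrix | None
    feature_ids: np.ndarray

    def __post_init__(self):
        fids = _as_id_array(self.feature_ids, "feature_ids", len(self.feature_ids))
        object.__setattr__(self, "feature_ids", fids)
        if fids.size != self.fit.m:
            raise ContractError("fit/data mismatch: feature count")
        if self.X_train is not None and self.X_train.m != self.fit.m:
            raise ContractError("fit/data mismatch: training matrix")
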