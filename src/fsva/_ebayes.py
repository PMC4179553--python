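"""Empirical-Bayes machinery: pi0 estimation and local false discovery rates.

Given a vector of p-values from a mixture of null (uniform) and alternative
features, the local FDR at p is pi0 * f0(p) / f(p) with f0 ≡ 1; one minus
the local FDR estimates the posterior probability that the feature is
non-null. pi0 is estimated by the smoother method: the natural estimates
pi0(λ) = #{p > λ} / (m(1−λ)) on a grid λ = 0, 0.05, ..., 0.90 are smoothed
with a cubic least-squares fit and extrapolated to λ → 1. The marginal
density f is a Gaussian kernel density estimate on logit-transformed
p-values mapped back through the Jacobian 1/(p(1−p)).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["estimate_pi0", "local_fdr"]

_P_EPS = 1e-15
_LAMBDA_GRID = np.arange(0.0, 0.901, 0.05)


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Smoother estimate of the null proportion pi0, clipped to (0, 1]."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return 1.0
    pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    # cubic least-squares fit in lambda, evaluated at the limit lambda -> 1
    coeffs = np.polynomial.polynomial.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(1.0, coeffs))
    return float(np.clip(pi0, 1e-8, 1.0))


def local_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Local false discovery rate for each p-value, in [0, 1].

    Monotone non-decreasing in p (enforced by a running maximum over the
    sorted p-values). Degenerate inputs (too few values, or no spread for the
    kernel density) fall back to the constant pi0, i.e. an uninformative
    posterior.
    """
    p = np.clip(np.asarray(pvalues, dtype=np.float64), _P_EPS, 1.0 - _P_EPS)
    pi0 = estimate_pi0(p)
    if p.size < 8 or np.ptp(p) < 1e-12:
        return np.full(p.size, pi0)
    x = np.log(p / (1.0 - p))
    try:
        kde = gaussian_kde(x)
        fx = kde(x)
    except np.linalg.LinAlgError:
        return np.full(p.size, pi0)
    # density of p via the logit Jacobian
    fp = fx / (p * (1.0 - p))
    lfdr = np.clip(pi0 / np.maximum(fp, 1e-300), 0.0, 1.0)
    order = np.argsort(p, kind="stable")
    lfdr[order] = np.maximum.accumulate(lfdr[order])
    return lfdr
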