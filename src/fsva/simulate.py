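"""Synthetic two-batch, two-outcome expression data with tunable confounding.

Data follow X = B·outcomeᵀ + Γ·batchᵀ + U: a binary outcome affects a
fraction of features with Gaussian coefficients B, a single binary batch
factor affects another (overlapping) fraction with Gaussian coefficients Γ,
and U is iid Gaussian noise. Both label vectors are balanced; the Pearson
(phi) correlation between batch and outcome in the database is a tunable
confounding level ρ, while new samples are always generated uncorrelated so
every batch×outcome combination fills 25% of them.

Three stock scenarios mimic a subtle outcome under a strong batch effect:

========  ====  =======  ====  ==========  ============  =========
scenario  sd_B  sd_Γ     sd_U  frac_batch  frac_outcome  frac_both
========  ====  =======  ====  ==========  ============  =========
1         1     3        2     0.50        0.50          0.40
2         1     4        3     0.50        0.50          0.40
3         1     4        3     0.80        0.80          0.50
========  ====  =======  ====  ==========  ============  =========
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ContractError
from .containers import ExpressionMatrix

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "SCENARIOS",
    "sample_confounded_labels",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Coefficient scales and affected-feature fractions for one scenario."""

    sd_B: float
    sd_Gamma: float
    sd_U: float
    frac_batch: float
    frac_outcome: float
    frac_both: float

    def __post_init__(self):
        if min(self.sd_B, self.sd_Gamma, self.sd_U) <= 0:
            raise ContractError("invalid scenario: standard deviations must be positive")
        fracs = (self.frac_batch, self.frac_outcome, self.frac_both)
        if any(f < 0 or f > 1 for f in fracs):
            raise ContractError("invalid scenario: fractions must lie in [0, 1]")
        if self.frac_both > min(self.frac_batch, self.frac_outcome):
            raise ContractError("invalid scenario: frac_both exceeds a marginal fraction")


SCENARIOS: dict[int, SimulationScenario] = {
    1: SimulationScenario(1.0, 3.0, 2.0, 0.50, 0.50, 0.40),
    2: SimulationScenario(1.0, 4.0, 3.0, 0.50, 0.50, 0.40),
    3: SimulationScenario(1.0, 4.0, 3.0, 0.80, 0.80, 0.50),
}


@dataclass(frozen=True)
class SimulatedDataset:
    """A database plus new-sample set with full generative ground truth."""

    X_db: ExpressionMatrix
    X_new: ExpressionMatrix
    outcome_db: np.ndarray
    batch_db: np.ndarray
    outcome_new: np.ndarray
    batch_new: np.ndarray
    mask_batch: np.ndarray
    mask_outcome: np.ndarray
    true_B: np.ndarray
    true_Gamma: np.ndarray
    noise_db: np.ndarray
    noise_new: np.ndarray
    rho_target: float
    rho_realized: float
    scenario: SimulationScenario
    seed: int


def sample_confounded_labels(n: int, rho: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Balanced binary outcome/batch vectors with target phi-correlation rho.

    Both margins are exactly n/2. With a = round(n(1+rho)/4) samples in the
    (outcome=1, batch=1) cell the realized phi coefficient is 4a/n − 1, the
    grid value closest to rho. Sample order is shuffled by the seed.
    """
    if n % 4 != 0:
        raise ContractError("invalid n: must be divisible by 4")
    if not (0.0 <= rho <= 1.0):
        raise ContractError("invalid parameter: rho must be in [0, 1]")
    a = int(round(n * (1.0 + rho) / 4.0))
    a = min(max(a, n // 4), n // 2)
    off = n // 2 - a
    outcome = np.concatenate([np.ones(a), np.ones(off), np.zeros(off), np.zeros(a)])
    batch = np.concatenate([np.ones(a), np.zeros(off), np.ones(off), np.zeros(a)])
    order = np.random.default_rng(seed).permutation(n)
    return outcome[order].astype(np.int64), batch[order].astype(np.int64)


def realized_phi(n: int, rho: float) -> float:
    """The phi correlation actually achieved by the rounded cell counts."""
    a = min(max(int(round(n * (1.0 + rho) / 4.0)), n // 4), n // 2)
    return 4.0 * a / n - 1.0


def simulate_dataset(scenario: SimulationScenario | int, rho: float,
                     n_db: int = 100, n_new: int = 100, m: int = 10000,
                     seed: int = 0) -> SimulatedDataset:
    """Generate one database + new-sample pair under a scenario.

    Feature masks are assigned by a seeded permutation: the first
    ⌊frac_both·m⌋ permuted features load on both batch and outcome, the next
    block on batch only, the next on outcome only, and the remainder on
    neither. If the three fractions are jointly infeasible (union above
    100%, as in stock scenario 3), the batch margin and the overlap are
    honored exactly and the outcome-only block is truncated to the remaining
    features. Coefficients are mask-gated Gaussians; the intercept is zero
    (it is absorbed by the design's intercept row and affects nothing).
    """
    if isinstance(scenario, int):
        scenario = SCENARIOS[scenario]
    if m < 10:
        raise ContractError("invalid parameter: m must be >= 10")
    rng = np.random.default_rng(seed)

    perm = rng.permutation(m)
    n_both = int(np.floor(scenario.frac_both * m))
    n_batch = int(np.floor(scenario.frac_batch * m))
    n_outcome = int(np.floor(scenario.frac_outcome * m))
    mask_batch = np.zeros(m, dtype=np.int64)
    mask_outcome = np.zeros(m, dtype=np.int64)
    mask_batch[perm[:n_batch]] = 1
    mask_outcome[perm[:n_both]] = 1
    mask_outcome[perm[n_batch:n_batch + (n_outcome - n_both)]] = 1

    true_B = rng.normal(0.0, scenario.sd_B, m) * mask_outcome
    true_Gamma = rng.normal(0.0, scenario.sd_Gamma, m) * mask_batch

    seed_db = int(rng.integers(2 ** 31))
    seed_new = int(rng.integers(2 ** 31))
    outcome_db, batch_db = sample_confounded_labels(n_db, rho, seed_db)
    outcome_new, batch_new = sample_confounded_labels(n_new, 0.0, seed_new)

    noise_db = rng.normal(0.0, scenario.sd_U, (m, n_db))
    noise_new = rng.normal(0.0, scenario.sd_U, (m, n_new))
    X_db = true_B[:, None] * outcome_db + true_Gamma[:, None] * batch_db + noise_db
    X_new = true_B[:, None] * outcome_new + true_Gamma[:, None] * batch_new + noise_new

    width = len(str(m))
    feature_ids = np.array([f"gene{i:0{width}d}" for i in range(m)], dtype=object)
    db_ids = np.array([f"db{j:04d}" for j in range(n_db)], dtype=object)
    new_ids = np.array([f"new{j:04d}" for j in range(n_new)], dtype=object)

    return SimulatedDataset(
        X_db=ExpressionMatrix(X_db, feature_ids, db_ids),
        X_new=ExpressionMatrix(X_new, feature_ids, new_ids),
        outcome_db=outcome_db, batch_db=batch_db,
        outcome_new=outcome_new, batch_new=batch_new,
        mask_batch=mask_batch, mask_outcome=mask_outcome,
        true_B=true_B, true_Gamma=true_Gamma,
        noise_db=noise_db, noise_new=noise_new,
        rho_target=float(rho), rho_realized=realized_phi(n_db, rho),
        scenario=scenario, seed=seed,
    )
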