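"""Nearest-shrunken-centroid classification and the four-method benchmark.

The classifier standardizes each class centroid's offset from the overall
centroid by its standard error, soft-thresholds the offsets toward zero
(dropping uninformative features), and assigns new samples to the class with
the smallest standardized squared distance to the shrunken centroid, minus
twice the log prior. The shrinkage threshold is chosen by stratified
cross-validation over a grid, preferring the sparsest model on ties.

The benchmark reproduces a four-arm comparison on simulated confounded data:
no correction, surrogate-variable correction of the database only, and
frozen correction of the new samples in exact or fast mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._exceptions import ContractError, FsvaError
from .containers import ExpressionMatrix
from .frozen import build_frozen_model, fsva_exact, fsva_fast
from .simulate import SimulationScenario, SCENARIOS, simulate_dataset
from .sva import build_design, clean_training, irwsva_fit

__all__ = [
    "CentroidModel",
    "nsc_train",
    "nsc_predict",
    "split_study",
    "run_benchmark",
    "BENCHMARK_METHODS",
]

BENCHMARK_METHODS = ("none", "sva_db_only", "fsva_exact", "fsva_fast")


@dataclass(frozen=True)
class CentroidModel:
    classes: np.ndarray
    overall_centroid: np.ndarray           # (m,)
    shrunken_class_centroids: np.ndarray   # (m, K)
    pooled_sd: np.ndarray                  # (m,)
    s0: float
    shrinkage_threshold: float
    class_priors: np.ndarray               # (K,)
    feature_ids: np.ndarray


def _centroid_stats(Xv: np.ndarray, y: np.ndarray, classes: np.ndarray):
    """Overall/class centroids, pooled within-class sd, and standardized offsets."""
    m, n = Xv.shape
    K = classes.size
    centroids = np.empty((m, K))
    counts = np.empty(K)
    wss = np.zeros(m)
    for k, c in enumerate(classes):
        cols = Xv[:, y == c]
        counts[k] = cols.shape[1]
        centroids[:, k] = cols.mean(axis=1)
        wss += np.sum((cols - centroids[:, k][:, None]) ** 2, axis=1)
    overall = Xv.mean(axis=1)
    s = np.sqrt(wss / max(n - K, 1))
    s0 = float(np.median(s))
    mk = np.sqrt(np.maximum(1.0 / counts - 1.0 / n, 0.0))
    denom = (s + s0)[:, None] * mk[None, :]
    d = np.where(denom > 0, (centroids - overall[:, None]) / np.where(denom > 0, denom, 1.0), 0.0)
    return overall, centroids, counts, s, s0, mk, d


def _soft_threshold(d: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)


def _shrunken_centroids(overall, s, s0, mk, d, thr):
    return overall[:, None] + mk[None, :] * (s + s0)[:, None] * _soft_threshold(d, thr)


def _discriminant_predict(Xv, classes, shrunk, s, s0, priors):
    """Class of minimum standardized squared distance minus 2·log prior.

    Ties go to the lexicographically first class (np.argmin keeps the first
    minimum and ``classes`` is sorted).
    """
    scale = (s + s0)[:, None]
    scores = np.empty((classes.size, Xv.shape[1]))
    for k in range(classes.size):
        diff = (Xv - shrunk[:, k][:, None]) / scale
        scores[k] = np.sum(diff * diff, axis=0) - 2.0 * np.log(priors[k])
    return classes[np.argmin(scores, axis=0)]


def nsc_train(X: ExpressionMatrix, y, threshold_grid=None, cv_folds: int = 5,
              seed: int = 0) -> CentroidModel:
    """Train a nearest-shrunken-centroid classifier with a CV-chosen threshold.

    The default grid is 30 evenly spaced thresholds on [0, max|d|), excluding
    the fully-shrunk endpoint (a degenerate prior-only classifier). Ties in
    cross-validated accuracy resolve to the largest threshold (sparsest
    model).
    """
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=np.float64)
    fids = X.feature_ids if isinstance(X, ExpressionMatrix) else np.array(
        [f"feature{i}" for i in range(Xv.shape[0])], dtype=object)
    y = np.asarray(y, dtype=object)
    classes = np.array(sorted(set(y)), dtype=object)
    if classes.size < 2:
        raise ContractError("insufficient samples: need at least 2 classes")
    counts = np.array([np.sum(y == c) for c in classes])
    if counts.min() < cv_folds:
        raise ContractError("insufficient samples: a class is smaller than the fold count")

    overall, _, counts_f, s, s0, mk, d = _centroid_stats(Xv, y, classes)
    if threshold_grid is None:
        threshold_grid = np.linspace(0.0, float(np.abs(d).max()), num=30, endpoint=False)
    threshold_grid = np.asarray(threshold_grid, dtype=np.float64)

    y_codes = np.searchsorted(classes, y)  # classes sorted, so codes valid
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    correct = np.zeros(threshold_grid.size)
    for train_idx, val_idx in skf.split(Xv.T, y_codes):
        yt = y[train_idx]
        ov, _, cnt, st, st0, mkt, dt = _centroid_stats(Xv[:, train_idx], yt, classes)
        priors = cnt / cnt.sum()
        for t, thr in enumerate(threshold_grid):
            shrunk = _shrunken_centroids(ov, st, st0, mkt, dt, thr)
            pred = _discriminant_predict(Xv[:, val_idx], classes, shrunk, st, st0, priors)
            correct[t] += np.sum(pred == y[val_idx])
    best = int(np.flatnonzero(correct == correct.max()).max())
    thr = float(threshold_grid[best])

    shrunk = _shrunken_centroids(overall, s, s0, mk, d, thr)
    return CentroidModel(
        classes=classes, overall_centroid=overall, shrunken_class_centroids=shrunk,
        pooled_sd=s, s0=s0, shrinkage_threshold=thr,
        class_priors=counts_f / counts_f.sum(), feature_ids=fids,
    )


def nsc_predict(model: CentroidModel, X_new: ExpressionMatrix) -> np.ndarray:
    """Predict class labels for new samples (features aligned by ID)."""
    if isinstance(X_new, ExpressionMatrix):
        try:
            X_new = X_new.reorder_features(model.feature_ids)
        except ContractError:
            raise ContractError("feature space mismatch") from None
        Xv = X_new.values
    else:
        Xv = np.asarray(X_new, dtype=np.float64)
        if Xv.shape[0] != model.feature_ids.size:
            raise ContractError("feature space mismatch")
    return _discriminant_predict(Xv, model.classes, model.shrunken_class_centroids,
                                 model.pooled_sd, model.s0, model.class_priors)


def split_study(X: ExpressionMatrix, y, seed: int = 0):
    """Seeded stratified half-split of a study into database and new-sample sets.

    Returns ((X_db, y_db), (X_new, y_new)); halves are disjoint, exhaustive,
    and preserve class proportions within one sample per class.
    """
    y = np.asarray(y, dtype=object)
    if X.n < 4:
        raise ContractError("cannot stratify: need at least 4 samples")
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if counts.min() < 2:
        raise ContractError("cannot stratify: a class has < 2 samples")
    idx = np.arange(X.n)
    db_idx, new_idx = train_test_split(idx, test_size=0.5, stratify=y.astype(str),
                                       random_state=seed)
    db_idx, new_idx = np.sort(db_idx), np.sort(new_idx)
    return (X.subset_samples(db_idx), y[db_idx]), (X.subset_samples(new_idx), y[new_idx])


def run_benchmark(scenario_ids, rhos, reps: int, n_db: int = 100, n_new: int = 100,
                  m: int = 1000, seed: int = 0, n_sv: int = 1,
                  n_iter: int = 5) -> pd.DataFrame:
    """Four-method prediction benchmark on simulated confounded data.

    For every (scenario, rho, replicate): simulate a database + new samples,
    fit the surrogate model on the database, clean it, train the classifier
    on the cleaned database, and score accuracy on the new samples under the
    four arms (no correction; cleaned-database model on raw new samples;
    exact frozen correction; fast frozen correction). All four arms see the
    identical simulated data within a replicate. A replicate whose surrogate
    fit fails (confounded design) is recorded with ``fit_failed=True`` rather
    than dropped.
    """
    if reps < 1:
        raise ContractError("invalid parameter: reps must be >= 1")
    scenario_ids = sorted(scenario_ids)
    rhos = list(rhos)
    cells = list(product(scenario_ids, rhos, range(reps)))
    children = np.random.SeedSequence(seed).spawn(len(cells))
    rows = []
    for (sc_id, rho, rep), child in zip(cells, children):
        state = child.generate_state(2)
        data_seed = int(state[0] % (2 ** 31))
        cls_seed = int(state[1] % (2 ** 31))
        scenario = SCENARIOS[sc_id] if isinstance(sc_id, int) else sc_id
        ds = simulate_dataset(scenario, rho, n_db=n_db, n_new=n_new, m=m, seed=data_seed)
        y_db = ds.outcome_db.astype(str)
        y_new = ds.outcome_new.astype(str)

        model_raw = nsc_train(ds.X_db, y_db, seed=cls_seed)
        acc = {"none": float(np.mean(nsc_predict(model_raw, ds.X_new) == y_new))}
        fit_failed = False
        try:
            S = build_design(y_db)
            fit = irwsva_fit(ds.X_db, S, n_sv=n_sv, n_iter=n_iter)
            X_clean = clean_training(ds.X_db, fit)
            frozen = build_frozen_model(ds.X_db, fit)
            model_clean = nsc_train(X_clean, y_db, seed=cls_seed)
            acc["sva_db_only"] = float(np.mean(nsc_predict(model_clean, ds.X_new) == y_new))
            acc["fsva_exact"] = float(
                np.mean(nsc_predict(model_clean, fsva_exact(frozen, ds.X_new)) == y_new))
            acc["fsva_fast"] = float(
                np.mean(nsc_predict(model_clean, fsva_fast(frozen, ds.X_new)) == y_new))
        except FsvaError:
            fit_failed = True
            for method in ("sva_db_only", "fsva_exact", "fsva_fast"):
                acc[method] = np.nan
        for method in BENCHMARK_METHODS:
            rows.append({
                "scenario": sc_id, "rho": rho, "rep": rep, "method": method,
                "accuracy": acc[method],
                "fit_failed": fit_failed and method != "none",
                "seed": data_seed,
            })
    return pd.DataFrame(rows)
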