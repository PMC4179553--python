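"""File formats and model persistence.

Expression matrices travel as tab-delimited text: first column feature IDs,
header row sample IDs, numeric body; values are written with enough digits
(%.17g) to round-trip float64 exactly. Phenotype tables are tab-delimited
with columns ``sample_id``, ``outcome`` and optional ``batch`` (batch is
used only by evaluation code, never by the fitting path).

A frozen model persists as a directory of component matrices plus a
key = value metadata file. The residual (noise) matrix is not stored — no
correction step consumes it — so models reloaded from disk carry
``noise=None``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from ._exceptions import ContractError
from .containers import (
    ExpressionMatrix,
    FeatureWeights,
    FrozenModel,
    SurrogateFit,
)
from .frozen import build_projection

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = "1"
_FLOAT_FMT = "%.17g"


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-delimited feature-by-sample matrix, validating strictly."""
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - normalize any parse failure
        raise ContractError(f"parse error: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ContractError("empty matrix")
    if raw.index.duplicated().any() or raw.columns.duplicated().any():
        raise ContractError("duplicate identifier")
    values = np.empty(raw.shape)
    body = raw.to_numpy()
    for i in range(raw.shape[0]):
        try:
            values[i] = np.asarray(body[i], dtype=np.float64)
        except (TypeError, ValueError):
            # +2: one for the header row, one for 1-based numbering
            raise ContractError(f"parse error at line {i + 2}: non-numeric cell") from None
    if not np.all(np.isfinite(values)):
        raise ContractError("non-finite value in expression matrix")
    return ExpressionMatrix(values, raw.index.to_numpy(), raw.columns.to_numpy())


def write_expression(X: ExpressionMatrix, path) -> None:
    X.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="feature_id")


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "outcome" not in df.columns:
        raise ContractError("parse error: phenotype table needs sample_id and outcome columns")
    if df["sample_id"].duplicated().any():
        raise ContractError("duplicate identifier in phenotype table")
    return df


def write_phenotype(sample_ids, outcome, path, batch=None) -> None:
    cols = {"sample_id": sample_ids, "outcome": outcome}
    if batch is not None:
        cols["batch"] = batch
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _write_matrix(path, arr):
    np.savetxt(path, np.atleast_2d(np.asarray(arr, dtype=np.float64)),
               fmt=_FLOAT_FMT, delimiter="\t")


def _read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", ndmin=2))


_REQUIRED_FILES = ("metadata.txt", "ids.tsv", "G_hat.tsv", "Gamma_hat.tsv",
                   "B_hat.tsv", "weights.tsv", "svd_U.tsv", "svd_D.tsv", "svd_V.tsv")


def save_model(model: FrozenModel, dirpath, include_train: bool = True) -> None:
    """Serialize a frozen model to a directory of tab-delimited files."""
    os.makedirs(dirpath, exist_ok=True)
    fit = model.fit
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_sv": fit.n_sv,
        "n_iter": fit.n_iter if fit.n_iter is not None else "",
        "seed": fit.seed if fit.seed is not None else "",
        "m": fit.m,
        "n": fit.n,
    }
    with open(os.path.join(dirpath, "metadata.txt"), "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k} = {v}\n")
    sample_ids = model.X_train.sample_ids if model.X_train is not None else \
        np.array([f"sample{j}" for j in range(fit.n)], dtype=object)
    pd.DataFrame({"feature_id": model.feature_ids}).to_csv(
        os.path.join(dirpath, "ids.tsv"), sep="\t", index=False)
    pd.DataFrame({"sample_id": sample_ids}).to_csv(
        os.path.join(dirpath, "sample_ids.tsv"), sep="\t", index=False)
    _write_matrix(os.path.join(dirpath, "G_hat.tsv"), fit.G_hat)
    _write_matrix(os.path.join(dirpath, "Gamma_hat.tsv"), fit.Gamma_hat)
    _write_matrix(os.path.join(dirpath, "B_hat.tsv"), fit.B_hat)
    weights = pd.DataFrame({
        "pi_gamma": fit.weights.pi_gamma,
        "pi_b": fit.weights.pi_b,
        "pi_w": fit.weights.pi_w,
    })
    weights.to_csv(os.path.join(dirpath, "weights.tsv"), sep="\t", index=False,
                   float_format=_FLOAT_FMT)
    _write_matrix(os.path.join(dirpath, "svd_U.tsv"), fit.svd_U)
    _write_matrix(os.path.join(dirpath, "svd_D.tsv"), fit.svd_D)
    _write_matrix(os.path.join(dirpath, "svd_V.tsv"), fit.svd_V)
    if include_train and model.X_train is not None:
        write_expression(model.X_train, os.path.join(dirpath, "X_train.tsv"))


def load_model(dirpath) -> FrozenModel:
    """Load a frozen model saved by :func:`save_model`.

    Missing component files or a format-version mismatch raise
    "incompatible model". Models saved without the training matrix support
    fast mode only.
    """
    for fname in _REQUIRED_FILES:
        if not os.path.exists(os.path.join(dirpath, fname)):
            raise ContractError(f"incompatible model: missing {fname}")
    meta = {}
    with open(os.path.join(dirpath, "metadata.txt")) as fh:
        for line in fh:
            if "=" in line:
                k, _, v = line.partition("=")
                meta[k.strip()] = v.strip()
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ContractError("incompatible model: format version mismatch")
    n_sv = int(meta["n_sv"])
    feature_ids = pd.read_csv(os.path.join(dirpath, "ids.tsv"), sep="\t",
                              dtype=str)["feature_id"].to_numpy()
    wdf = pd.read_csv(os.path.join(dirpath, "weights.tsv"), sep="\t",
                      float_precision="round_trip")
    weights = FeatureWeights(pi_gamma=wdf["pi_gamma"].to_numpy(),
                             pi_b=wdf["pi_b"].to_numpy(),
                             pi_w=wdf["pi_w"].to_numpy())
    fit = SurrogateFit(
        n_sv=n_sv,
        G_hat=_read_matrix(os.path.join(dirpath, "G_hat.tsv")),
        Gamma_hat=_read_matrix(os.path.join(dirpath, "Gamma_hat.tsv")),
        B_hat=_read_matrix(os.path.join(dirpath, "B_hat.tsv")),
        weights=weights,
        svd_U=_read_matrix(os.path.join(dirpath, "svd_U.tsv")),
        svd_D=_read_matrix(os.path.join(dirpath, "svd_D.tsv")).ravel(),
        svd_V=_read_matrix(os.path.join(dirpath, "svd_V.tsv")),
        noise=None,
        n_iter=int(meta["n_iter"]) if meta.get("n_iter") else None,
        seed=int(meta["seed"]) if meta.get("seed") else None,
    )
    train_path = os.path.join(dirpath, "X_train.tsv")
    X_train = read_expression(train_path) if os.path.exists(train_path) else None
    projection = build_projection(fit)
    return FrozenModel(fit=fit, projection=projection, X_train=X_train,
                       feature_ids=feature_ids)
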