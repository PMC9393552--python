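"""Cross-validation harness for the biomass prediction models.

Three schemes validate a chosen model (typically M4, FM ~ LV x LV_Den):

* ``repeated_kfold`` — k-fold CV repeated R times (default 10 x 10),
* ``loocv`` — leave-one-out (deterministic, no seed sensitivity),
* ``random_split`` — repeated random train/test splits (default 80/20 x 100).

Metrics are computed on out-of-fold predictions only. Per replicate, R^2 is
the pooled out-of-fold 1 - SSE/SST (a per-fold-averaged R^2 is also
reported); aggregates are means over replicates. Fold assignment is fully
reproducible from the scheme seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, LeaveOneOut, ShuffleSplit

from .models import FitResult, ModelSpec, fit_ols

__all__ = ["CVScheme", "CVResult", "cross_validate", "press_loocv"]


class SchemeError(ValueError):
    """Invalid scheme parameters or folds too small to fit the model."""


@dataclass(frozen=True)
class CVScheme:
    kind: str = "repeated_kfold"  # repeated_kfold | loocv | random_split
    k: int = 10
    repeats: int = 10
    train_fraction: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("repeated_kfold", "loocv", "random_split"):
            raise SchemeError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "repeated_kfold" and self.k < 2:
            raise SchemeError("k must be >= 2 for k-fold")
        if not 0.0 < self.train_fraction < 1.0:
            raise SchemeError("train_fraction must lie in (0, 1)")
        if self.kind != "loocv" and self.seed is None:
            raise SchemeError(f"seed is mandatory for the stochastic scheme {self.kind!r}")


@dataclass
class CVResult:
    scheme: CVScheme
    per_replicate: pd.DataFrame  # columns: replicate, rmse, r_squared, mae, r2_fold_mean
    rmse: float  # g, mean over replicates
    r_squared: float
    mae: float  # g
    fold_assignments: list[np.ndarray]  # test-index arrays per replicate, concatenated folds


def _replicate_splits(scheme: CVScheme, n: int):
    """Yield (replicate_id, list of (train_idx, test_idx)) pairs."""
    if scheme.kind == "loocv":
        yield 0, list(LeaveOneOut().split(np.arange(n)))
        return
    rng = np.random.SeedSequence(scheme.seed)
    child_seeds = rng.generate_state(scheme.repeats)
    for rep, s in enumerate(child_seeds):
        if scheme.kind == "repeated_kfold":
            splitter = KFold(n_splits=scheme.k, shuffle=True, random_state=int(s % 2**31))
        else:
            splitter = ShuffleSplit(n_splits=1, train_size=scheme.train_fraction,
                                    random_state=int(s % 2**31))
        yield rep, list(splitter.split(np.arange(n)))


def cross_validate(spec: ModelSpec, data: pd.DataFrame, scheme: CVScheme) -> CVResult:
    """Cross-validate one model spec; all metrics from held-out predictions.

    Raises :class:`SchemeError` when any training fold is too small to fit
    the model (n_train <= p), suggesting a smaller k.
    """
    data = data.reset_index(drop=True)
    n = len(data)
    y = data[spec.response].to_numpy(dtype=float)
    rep_rows = []
    assignments = []
    for rep, splits in _replicate_splits(scheme, n):
        preds = np.full(n, np.nan)
        fold_r2 = []
        test_order = []
        for train_idx, test_idx in splits:
            if len(train_idx) <= spec.p:
                raise SchemeError(
                    f"training fold of size {len(train_idx)} cannot fit p={spec.p} "
                    f"parameters; use a smaller k"
                )
            fit = fit_ols(spec, data.iloc[train_idx])
            preds[test_idx] = fit.predict(data.iloc[test_idx])
            test_order.append(np.asarray(test_idx))
            yt = y[test_idx]
            sst_f = float(np.sum((yt - yt.mean()) ** 2))
            if sst_f > 0:
                fold_r2.append(1.0 - float(np.sum((yt - preds[test_idx]) ** 2)) / sst_f)
        held = ~np.isnan(preds)
        resid = y[held] - preds[held]
        sse = float(resid @ resid)
        sst = float(np.sum((y[held] - y[held].mean()) ** 2))
        rep_rows.append({
            "replicate": rep,
            "rmse": math.sqrt(sse / held.sum()),
            "r_squared": 1.0 - sse / sst if sst > 0 else float("nan"),
            "mae": float(np.mean(np.abs(resid))),
            "r2_fold_mean": float(np.mean(fold_r2)) if fold_r2 else float("nan"),
        })
        assignments.append(np.concatenate(test_order))
    per_rep = pd.DataFrame(rep_rows)
    return CVResult(
        scheme=scheme,
        per_replicate=per_rep,
        rmse=float(per_rep["rmse"].mean()),
        r_squared=float(per_rep["r_squared"].mean()),
        mae=float(per_rep["mae"].mean()),
        fold_assignments=assignments,
    )


def press_loocv(spec: ModelSpec, data: pd.DataFrame) -> tuple[float, float]:
    """Closed-form LOOCV (RMSE, MAE) via the PRESS / hat-matrix identity.

    For OLS, the leave-one-out residual is e_i / (1 - h_ii) with h the hat
    matrix of the single full-data fit; no refitting is performed. Serves as
    an independent oracle for :func:`cross_validate` with the loocv scheme.
    """
    fit = fit_ols(spec, data)
    X = spec.design_matrix(data)
    # h_ii = x_i (X'X)^-1 x_i'
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    loo_resid = fit.residuals / (1.0 - h)
    rmse = float(np.sqrt(np.mean(loo_resid**2)))
    mae = float(np.mean(np.abs(loo_resid)))
    return rmse, mae
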