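"""Accuracy scoring and the strategy-comparison / learning-curve harnesses.

Estimates are scored against reference LAI with the coefficient of
determination and root-mean-square error,

    R²   = 1 − Σ(yᵢ − yᵢ′)² / Σ(yᵢ − ȳ)²        (can be negative)
    RMSE = sqrt( Σ(yᵢ − yᵢ′)² / n )              (m²/m²)

where yᵢ are measured and yᵢ′ predicted values.  R² is one minus the
residual/total sum-of-squares ratio, not a squared correlation.

:func:`compare_strategies` runs every requested feature strategy through
its inversion engine (LUT or GPR) against a validation plot set and tables
R²/RMSE per strategy; :func:`training_size_sweep` traces the GPR learning
curve over training-set sizes with replicates.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import Strategy, enumerate_strategies, feature_matrix
from .gpr_inversion import make_training_set, predict_gpr, train_gpr
from .lut_inversion import build_lut, invert_lut
from .rtm_forward import DistributionSpec, ViewGeometry, default_distribution_spec

__all__ = ["EvaluationResult", "score", "compare_strategies", "training_size_sweep"]


@dataclass
class EvaluationResult:
    """Per-strategy accuracy against reference LAI."""

    strategy: Strategy
    r_squared: float
    rmse: float
    n: int
    runtime: float = float("nan")


def score(measured, predicted) -> tuple[float, float]:
    """(R², RMSE) of predictions against measurements.

    Pairs with a non-finite member are dropped; a constant measured vector
    leaves R² undefined (NaN) while RMSE is still returned.
    """
    y = np.asarray(measured, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    if y.shape != yp.shape:
        raise ValueError("measured and predicted must have equal length")
    keep = np.isfinite(y) & np.isfinite(yp)
    y, yp = y[keep], yp[keep]
    if y.size < 2:
        raise ValueError("need at least 2 valid pairs")
    ss_res = float(np.sum((y - yp) ** 2))
    rmse = math.sqrt(ss_res / y.size)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant measured vector: R² undefined", stacklevel=2)
        return math.nan, rmse
    return 1.0 - ss_res / ss_tot, rmse


def _invert_plots_lut(band_refl: np.ndarray, strategy: Strategy, lut, q: float) -> np.ndarray:
    feats = feature_matrix(band_refl, strategy)
    out = np.empty(feats.shape[0])
    for i, row in enumerate(feats):
        if not np.all(np.isfinite(row)):
            out[i] = np.nan
            continue
        sol = invert_lut(row, lut, q=q)
        out[i] = sol.lai_estimate if sol.valid else np.nan
    return out


def compare_strategies(
    validation: pd.DataFrame,
    strategies: list[Strategy] | None = None,
    spec: DistributionSpec | None = None,
    geom: ViewGeometry = ViewGeometry(),
    backend="toy",
    lut_size: int = 10_000,
    gpr_size: int = 3000,
    noise_sigma: float = 0.01,
    q: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every strategy on a validation plot table.

    ``validation`` needs columns ``B1..B4`` (reflectance) and ``true_lai``
    (or ``measured_lai``).  All strategies of one method share a single
    forward-simulated database (same seed ⇒ paired comparison); LUT
    strategies reduce a ``lut_size`` table, GPR strategies train on
    ``gpr_size`` samples.  Returns a DataFrame
    ``strategy, method, r2, rmse, n, runtime_s`` sorted by RMSE; a strategy
    that fails is recorded with NaN scores and the run continues.
    """
    if len(validation) < 2:
        raise ValueError("validation set needs at least 2 plots")
    strategies = enumerate_strategies() if strategies is None else strategies
    spec = default_distribution_spec() if spec is None else spec
    lai_col = "true_lai" if "true_lai" in validation else "measured_lai"
    band_refl = validation[["B1", "B2", "B3", "B4"]].to_numpy(dtype=float)
    measured = validation[lai_col].to_numpy(dtype=float)

    rows = []
    for strat in strategies:
        t0 = time.perf_counter()
        try:
            if strat.method == "LUT":
                lut = build_lut(spec, strat, n_entries=lut_size, geom=geom,
                                backend=backend, seed=seed, noise_sigma=noise_sigma)
                predicted = _invert_plots_lut(band_refl, strat, lut, q)
            else:
                train = make_training_set(spec, strat, n=gpr_size, geom=geom,
                                          backend=backend, noise_sigma=noise_sigma,
                                          seed=seed)
                model = train_gpr(train, seed=seed)
                feats = feature_matrix(band_refl, strat)
                predicted, _ = predict_gpr(model, feats)
            r2, rmse = score(measured, predicted)
            n_valid = int(np.sum(np.isfinite(predicted) & np.isfinite(measured)))
        except Exception as exc:  # noqa: BLE001 - per-strategy failures must not stop the run
            warnings.warn(f"strategy {strat.name}/{strat.method} failed: {exc}", stacklevel=2)
            r2, rmse, n_valid = math.nan, math.nan, 0
        rows.append({"strategy": strat.name, "method": strat.method,
                     "r2": r2, "rmse": rmse, "n": n_valid,
                     "runtime_s": time.perf_counter() - t0})
    columns = ["strategy", "method", "r2", "rmse", "n", "runtime_s"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns).sort_values(
        "rmse", kind="stable").reset_index(drop=True)


def training_size_sweep(
    sizes=(500, 1000, 2000, 3000, 5000),
    replicates: int = 3,
    seed: int = 0,
    strategy: Strategy | str = "MSAVI",
    spec: DistributionSpec | None = None,
    geom: ViewGeometry = ViewGeometry(),
    backend="toy",
    noise_sigma: float = 0.01,
    n_validation: int = 500,
) -> pd.DataFrame:
    """GPR accuracy as a function of training-set size.

    For each size, ``replicates`` independent training sets are simulated
    and scored on one fixed simulated validation set; the table reports
    mean ± std RMSE per size.  Accuracy typically plateaus by a few
    thousand samples.
    """
    if not len(sizes):
        raise ValueError("sizes must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec = default_distribution_spec() if spec is None else spec
    rng = np.random.default_rng(seed)
    val_seed = int(rng.integers(2**31))
    val = make_training_set(spec, strategy, n=n_validation, geom=geom, backend=backend,
                            noise_sigma=noise_sigma, seed=val_seed)
    rows = []
    for size in sizes:
        if size < 2:
            warnings.warn(f"training size {size} < 2 skipped", stacklevel=2)
            continue
        rmses = []
        for _ in range(replicates):
            s = int(rng.integers(2**31))
            train = make_training_set(spec, strategy, n=size, geom=geom, backend=backend,
                                      noise_sigma=noise_sigma, seed=s)
            model = train_gpr(train, seed=s)
            predicted, _ = predict_gpr(model, val.features)
            _, rmse = score(val.lai_targets, predicted)
            rmses.append(rmse)
        rows.append({"train_size": int(size),
                     "rmse_mean": float(np.mean(rmses)),
                     "rmse_std": float(np.std(rmses, ddof=0)),
                     "replicates": replicates})
    return pd.DataFrame(rows)
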