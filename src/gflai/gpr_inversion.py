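"""Hybrid inversion: Gaussian-process regression trained on simulated data.

A forward-simulated set of (features → LAI) pairs replaces field training
data, so the regressor inherits the radiative-transfer model's generality
while predicting at empirical-model speed.  The covariance is a squared-
exponential (RBF) kernel with a single shared length-scale — one
hyperparameter to tune — plus a white-noise term; the signal variance is
folded into the kernel scale.  Hyperparameters maximise the log marginal
likelihood with multiple restarts.

Numerical choices: features are standardised (training mean/std) before
kernel evaluation; when the training set is large the marginal-likelihood
optimisation runs on a seeded subsample (default 1000 points) and the exact
GP is then conditioned on the full set with the optimised hyperparameters —
the O(n³) Cholesky is paid once instead of once per optimiser step.
Predictions are clipped to the physical LAI support [0, 7] m²/m²; the raw
posterior mean is retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .features import Strategy, feature_matrix, strategy_from_name
from .rtm_forward import (
    DistributionSpec,
    ViewGeometry,
    add_noise,
    default_distribution_spec,
    sample_parameter_array,
    simulate_bands,
    PARAM_NAMES,
)

__all__ = ["TrainingSet", "GPRModel", "make_training_set", "train_gpr",
           "predict_gpr", "save_gpr", "load_gpr", "DEFAULT_TRAINING_SIZE",
           "LAI_SUPPORT"]

#: Training-set size at which the learning curve plateaus.
DEFAULT_TRAINING_SIZE = 3000

#: Physical support of LAI (m²/m²) used to clip predictions.
LAI_SUPPORT = (0.0, 7.0)

_LAI_COL = PARAM_NAMES.index("lai")


@dataclass
class TrainingSet:
    """Simulated (features, LAI) pairs for one strategy."""

    features: np.ndarray       # (n, n_features)
    lai_targets: np.ndarray    # (n,)
    strategy: Strategy
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.lai_targets = np.asarray(self.lai_targets, dtype=float)
        if self.features.shape[0] != self.lai_targets.shape[0]:
            raise ValueError("features and targets row counts differ")

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass
class GPRModel:
    """Fitted GP with its feature-standardisation constants and provenance."""

    regressor: GaussianProcessRegressor
    feature_mean: np.ndarray
    feature_std: np.ndarray
    strategy: Strategy
    metadata: dict = field(default_factory=dict)

    @property
    def length_scale(self) -> float:
        return float(self.regressor.kernel_.k1.k2.length_scale)

    @property
    def noise_variance(self) -> float:
        return float(self.regressor.kernel_.k2.noise_level)

    @property
    def signal_variance(self) -> float:
        return float(self.regressor.kernel_.k1.k1.constant_value)


def make_training_set(
    spec: DistributionSpec | None = None,
    strategy: Strategy | str = "MSAVI",
    n: int = DEFAULT_TRAINING_SIZE,
    geom: ViewGeometry = ViewGeometry(),
    backend="toy",
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> TrainingSet:
    """Simulate a training set through the same generation path as the LUT
    (sample priors → forward model → bands → noise → features); targets are
    the sampled LAI values."""
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if isinstance(strategy, str):
        strategy = strategy_from_name(strategy, method="GPR")
    spec = default_distribution_spec() if spec is None else spec
    rng = np.random.default_rng(seed)
    params = sample_parameter_array(spec, n, rng)
    bands = simulate_bands(params, geom, backend)
    if noise_sigma > 0:
        bands = add_noise(bands, noise_sigma, rng)
    feats = feature_matrix(bands, strategy)
    keep = np.all(np.isfinite(feats), axis=1)
    meta = {"seed": seed, "noise_sigma": noise_sigma,
            "geometry": (geom.tts, geom.tto, geom.psi),
            "backend": backend if isinstance(backend, str) else "toy-custom",
            "n_dropped_invalid": int((~keep).sum())}
    return TrainingSet(feats[keep], params[keep, _LAI_COL], strategy, meta)


def train_gpr(
    train: TrainingSet,
    seed: int = 0,
    n_restarts: int = 1,
    hyperfit_max_n: int = 800,
) -> GPRModel:
    """Fit the squared-exponential GP by maximising the marginal likelihood.

    ``hyperfit_max_n`` caps the number of points used during hyperparameter
    optimisation (a seeded subsample); the returned model is always
    conditioned on the full training set.  Deterministic given the seed and
    training set.
    """
    X, y = train.features, train.lai_targets
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite values")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    degenerate = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if degenerate.any():
        import warnings
        warnings.warn("constant feature column(s) in training set; "
                      "standardisation skipped for those columns", stacklevel=2)
        std = np.where(degenerate, 1.0, std)
    Z = (X - mean) / std

    # white-noise floor and jitter keep the Cholesky positive definite even
    # on noise-free simulated data
    kernel = (ConstantKernel(1.0, (1e-3, 1e4))
              * RBF(length_scale=1.0, length_scale_bounds=(1e-3, 1e3))
              + WhiteKernel(noise_level=1e-5, noise_level_bounds=(1e-8, 1.0)))
    jitter = 1e-8

    rng = np.random.default_rng(seed)
    if Z.shape[0] > hyperfit_max_n:
        idx = rng.choice(Z.shape[0], hyperfit_max_n, replace=False)
        sub = GaussianProcessRegressor(
            kernel=kernel, n_restarts_optimizer=n_restarts, alpha=jitter,
            normalize_y=True, random_state=int(rng.integers(2**31)),
        ).fit(Z[idx], y[idx])
        fitted_kernel = sub.kernel_
        gpr = GaussianProcessRegressor(kernel=fitted_kernel, optimizer=None,
                                       alpha=jitter, normalize_y=True).fit(Z, y)
    else:
        gpr = GaussianProcessRegressor(
            kernel=kernel, n_restarts_optimizer=n_restarts, alpha=jitter,
            normalize_y=True, random_state=int(rng.integers(2**31)),
        ).fit(Z, y)

    meta = dict(train.metadata)
    meta.update(train_seed=seed, n_train=train.n,
                length_scale=float(gpr.kernel_.k1.k2.length_scale),
                noise_level=float(gpr.kernel_.k2.noise_level))
    return GPRModel(gpr, mean, std, train.strategy, meta)


def predict_gpr(
    model: GPRModel,
    observed: np.ndarray,
    return_raw: bool = False,
):
    """Posterior mean and std of LAI for one observation or an (n, m) batch.

    The mean is clipped to the physical support [0, 7] m²/m²; rows with any
    non-finite feature (e.g. a masked index) come back NaN.  Batch
    prediction equals the concatenation of single predictions.
    """
    obs = np.asarray(observed, dtype=float)
    single = obs.ndim == 1
    obs2 = np.atleast_2d(obs)
    if obs2.shape[1] != model.strategy.n_features:
        raise ValueError("observation width does not match the model's strategy")
    valid = np.all(np.isfinite(obs2), axis=1)
    mean = np.full(obs2.shape[0], np.nan)
    sd = np.full(obs2.shape[0], np.nan)
    if valid.any():
        Z = (obs2[valid] - model.feature_mean) / model.feature_std
        m, s = model.regressor.predict(Z, return_std=True)
        mean[valid] = m
        sd[valid] = s
    clipped = np.clip(mean, *LAI_SUPPORT)
    out = (mean, sd) if return_raw else (clipped, sd)
    if single:
        return float(out[0][0]), float(out[1][0])
    return out


# ---------------------------------------------------------------------------
# Serialization: arrays + kernel hyperparameters; reload refits the exact GP
# with fixed hyperparameters (a single deterministic Cholesky).
# ---------------------------------------------------------------------------

def save_gpr(model: GPRModel, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path, X=model.regressor.X_train_,
                        y_raw=model.regressor.y_train_ * model.regressor._y_train_std
                        + model.regressor._y_train_mean,
                        feature_mean=model.feature_mean, feature_std=model.feature_std)
    meta = {
        "strategy": model.strategy.name, "method": model.strategy.method,
        "signal_variance": model.signal_variance,
        "length_scale": model.length_scale,
        "noise_variance": model.noise_variance,
        "metadata": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in model.metadata.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_gpr(path: str | Path) -> GPRModel:
    path = Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    kernel = (ConstantKernel(meta["signal_variance"]) * RBF(meta["length_scale"])
              + WhiteKernel(meta["noise_variance"]))
    gpr = GaussianProcessRegressor(kernel=kernel, optimizer=None, alpha=1e-8,
                                   normalize_y=True)
    gpr.fit(arrays["X"], arrays["y_raw"])
    strategy = strategy_from_name(meta["strategy"], method=meta.get("method", "GPR"))
    return GPRModel(gpr, arrays["feature_mean"], arrays["feature_std"],
                    strategy, meta.get("metadata", {}))
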