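"""Look-up-table inversion of LAI with a relative-RMSE cost.

The LUT is a large multi-solution database: parameter vectors drawn from
the prior distributions, forward-modelled to band reflectance, and reduced
to the strategy's features.  An observation is inverted by computing the
relative root-mean-square error (RRMSE) between its features and every LUT
entry,

    band features:  sqrt( (1/m) Σ_i ((R_obs,i − R_sim,i) / R_obs,i)² )
    single index:   |(VI_obs − VI_sim) / VI_obs|

sorting costs ascending and averaging the LAI of the best fraction q
(default 10% of the table) — multi-solution averaging that regularises the
ill-posed inversion.  Observed features smaller than an epsilon guard make
the relative error undefined: such band components are excluded (m reduced)
and an all-excluded observation yields an invalid solution rather than an
exception.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureVector, Strategy, feature_matrix, strategy_from_name
from .rtm_forward import (
    DistributionSpec,
    ViewGeometry,
    add_noise,
    default_distribution_spec,
    sample_parameter_array,
    simulate_bands,
    PARAM_NAMES,
)

__all__ = ["LookUpTable", "LUTSolution", "build_lut", "rrmse", "invert_lut",
           "save_lut", "load_lut", "DEFAULT_LUT_SIZE", "EPSILON"]

#: Database size that balances inversion accuracy against compute.
DEFAULT_LUT_SIZE = 100_000

#: Observed-feature magnitude below which a relative error is undefined.
EPSILON = 1e-6

_LAI_COL = PARAM_NAMES.index("lai")


@dataclass
class LookUpTable:
    """Paired (features, parameters) database for one strategy."""

    features: np.ndarray          # (n_entries, n_features)
    params: np.ndarray            # (n_entries, 10), PARAM_NAMES column order
    strategy: Strategy
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.features.shape[0] != self.params.shape[0]:
            raise ValueError("features and params row counts differ")
        if self.features.shape[1] != self.strategy.n_features:
            raise ValueError("feature width does not match strategy")

    @property
    def n_entries(self) -> int:
        return self.features.shape[0]

    @property
    def lai(self) -> np.ndarray:
        return self.params[:, _LAI_COL]


@dataclass
class LUTSolution:
    """Result of inverting one observation: the mean LAI of the retained
    best-cost entries, with provenance for inspection."""

    lai_estimate: float
    n_retained: int
    rrmse_min: float
    retained_indices: np.ndarray
    mean_params: np.ndarray | None = None
    valid: bool = True

    @classmethod
    def invalid(cls) -> "LUTSolution":
        return cls(math.nan, 0, math.nan, np.empty(0, dtype=int), None, valid=False)


def build_lut(
    spec: DistributionSpec | None = None,
    strategy: Strategy | str = "B1B2B3B4",
    n_entries: int = DEFAULT_LUT_SIZE,
    geom: ViewGeometry = ViewGeometry(),
    backend="toy",
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> LookUpTable:
    """Sample ``n_entries`` parameter vectors, forward-model them to band
    reflectance, optionally add Gaussian noise, and reduce to the strategy's
    features.  Deterministic per seed."""
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    if isinstance(strategy, str):
        strategy = strategy_from_name(strategy)
    spec = default_distribution_spec() if spec is None else spec
    rng = np.random.default_rng(seed)
    params = sample_parameter_array(spec, n_entries, rng)
    bands = simulate_bands(params, geom, backend)
    if noise_sigma > 0:
        bands = add_noise(bands, noise_sigma, rng)
    feats = feature_matrix(bands, strategy)
    meta = {"seed": seed, "geometry": (geom.tts, geom.tto, geom.psi),
            "noise_sigma": noise_sigma,
            "backend": backend if isinstance(backend, str) else "toy-custom"}
    return LookUpTable(feats, params, strategy, meta)


def rrmse(observed: FeatureVector | np.ndarray, candidates: np.ndarray,
          epsilon: float = EPSILON) -> np.ndarray:
    """RRMSE cost between one observation and one or many candidate feature
    rows.

    Returns an array of costs, one per candidate row; ``NaN`` where the cost
    is undefined (every observed component below ``epsilon``).  For
    multi-band observations, near-zero components are dropped and the band
    count m reduced accordingly.
    """
    obs = observed.values if isinstance(observed, FeatureVector) else np.atleast_1d(np.asarray(observed, dtype=float))
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    if cand.shape[1] != obs.shape[0]:
        raise ValueError(f"observed length {obs.shape[0]} != candidate length {cand.shape[1]}")
    usable = np.isfinite(obs) & (np.abs(obs) >= epsilon)
    if not usable.any():
        return np.full(cand.shape[0], np.nan)
    rel = (obs[usable] - cand[:, usable]) / obs[usable]
    if obs.shape[0] == 1:
        return np.abs(rel[:, 0])
    return np.sqrt(np.mean(rel**2, axis=1))


def invert_lut(
    observed: FeatureVector | np.ndarray,
    lut: LookUpTable,
    q: float = 0.10,
) -> LUTSolution:
    """Invert one observation against the table.

    Retains the ``ceil(q * n_entries)`` entries of smallest cost (stable
    sort, ties broken by entry index) and returns the arithmetic mean of
    their LAI values.  ``q = 0.10`` is the default threshold fraction.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("threshold fraction q must be in (0, 1]")
    if lut.n_entries == 0:
        raise ValueError("empty look-up table")
    costs = rrmse(observed, lut.features)
    finite = np.isfinite(costs)
    if not finite.any():
        return LUTSolution.invalid()
    k = math.ceil(q * lut.n_entries)
    order = np.argsort(costs, kind="stable")  # NaNs sort last
    order = order[: min(k, int(finite.sum()))]
    retained_lai = lut.lai[order]
    return LUTSolution(
        lai_estimate=float(retained_lai.mean()),
        n_retained=int(order.size),
        rrmse_min=float(costs[order[0]]),
        retained_indices=order,
        mean_params=lut.params[order].mean(axis=0),
    )


# ---------------------------------------------------------------------------
# Serialization: numeric arrays in .npz + JSON metadata sidecar
# ---------------------------------------------------------------------------

def save_lut(lut: LookUpTable, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path, features=lut.features, params=lut.params)
    meta = {
        "strategy": lut.strategy.name,
        "method": lut.strategy.method,
        "metadata": {k: v if not isinstance(v, tuple) else list(v)
                     for k, v in lut.metadata.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_lut(path: str | Path) -> LookUpTable:
    path = Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    strategy = strategy_from_name(meta["strategy"], method=meta.get("method", "LUT"))
    return LookUpTable(arrays["features"], arrays["params"], strategy, meta.get("metadata", {}))
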