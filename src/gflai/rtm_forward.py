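"""Forward canopy reflectance simulation for a four-band blue/green/red/NIR sensor.

This module owns the generative side of the retrieval problem:

* truncated-Gaussian sampling of leaf/canopy/soil parameters
  (:func:`sample_parameters`) over the ranges used to build inversion
  databases for broadband sensors;
* a pluggable forward model (:func:`forward_model`) mapping a parameter
  vector and view geometry to a top-of-canopy reflectance spectrum — either
  PROSAIL5B (PROSPECT-5 + 4SAIL, if the ``prosail`` library is installed) or
  a built-in analytic two-stream *toy* canopy model that is closed-form,
  strictly monotone in LAI, and therefore invertible — the reference model
  for every parameter-recovery test downstream;
* spectral resampling of the hyperspectral output to broad sensor bands
  (:func:`resample_to_bands`) with a boxcar response by default;
* additive Gaussian reflectance noise (:func:`add_noise`).

All stochastic functions take an explicit seed and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CanopyParams",
    "ViewGeometry",
    "BandDefinition",
    "GF1_BANDS",
    "Spectrum",
    "SpectralSample",
    "ParamDistribution",
    "DistributionSpec",
    "default_distribution_spec",
    "lai_only_spec",
    "sample_parameters",
    "sample_parameter_array",
    "forward_model",
    "simulate_bands",
    "resample_to_bands",
    "add_noise",
    "ToyCanopyModel",
    "BackendUnavailableError",
    "PARAM_NAMES",
]

PARAM_NAMES = ("N", "cab", "car", "cbrown", "cw", "cm", "lai", "alia", "hspot", "psoil")


class BackendUnavailableError(RuntimeError):
    """Raised when a forward-model backend's dependency is not installed."""


@dataclass(frozen=True)
class CanopyParams:
    """One leaf + canopy + soil parameter vector of the radiative transfer model.

    Units: ``cab``/``car`` in µg·cm⁻², ``cw`` in cm, ``cm`` in g·cm⁻²,
    ``lai`` in m²/m², ``alia`` in degrees; ``N`` (leaf structure),
    ``cbrown``, ``hspot`` and ``psoil`` are unitless.
    """

    N: float = 1.5
    cab: float = 50.0
    car: float = 10.0
    cbrown: float = 0.2
    cw: float = 0.02
    cm: float = 0.01
    lai: float = 3.5
    alia: float = 60.0
    hspot: float = 0.45
    psoil: float = 0.5

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "CanopyParams":
        return cls(**{name: float(v) for name, v in zip(PARAM_NAMES, values, strict=True)})


@dataclass(frozen=True)
class ViewGeometry:
    """Sun/sensor angles in degrees: solar zenith ``tts``, view zenith ``tto``,
    relative azimuth ``psi``.  One fixed triple per database build."""

    tts: float = 30.0
    tto: float = 0.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        if not (25.0 <= self.tts <= 70.0):
            raise ValueError(f"tts={self.tts} outside [25, 70] degrees")
        if not (0.0 <= self.tto <= 80.0):
            raise ValueError(f"tto={self.tto} outside [0, 80] degrees")
        if not (-120.0 <= self.psi <= 120.0):
            raise ValueError(f"psi={self.psi} outside [-120, 120] degrees")


@dataclass(frozen=True)
class BandDefinition:
    """A broad sensor band as a wavelength interval in nm."""

    name: str
    wavelength_lo: float
    wavelength_hi: float

    def __post_init__(self) -> None:
        if not self.wavelength_lo < self.wavelength_hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


#: The four wide-field-camera bands: blue, green, red, near-infrared.
GF1_BANDS = (
    BandDefinition("B1", 450.0, 520.0),
    BandDefinition("B2", 520.0, 590.0),
    BandDefinition("B3", 630.0, 690.0),
    BandDefinition("B4", 770.0, 890.0),
)


@dataclass
class Spectrum:
    """Directional-hemispherical canopy reflectance on a nm wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must have equal length")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("non-finite reflectance in spectrum")


@dataclass
class SpectralSample:
    """Reflectance in the sensor bands (B1..B4 order) for one observation.

    ``source`` tags provenance (``"simulated"`` or ``"observed"``).  Simulated
    samples must lie in [0, 1]; observed values outside that range mark the
    sample invalid rather than raising, so raster pixels can be masked.
    """

    band_reflectance: np.ndarray
    source: str = "simulated"

    def __post_init__(self) -> None:
        self.band_reflectance = np.asarray(self.band_reflectance, dtype=float)
        if self.source == "simulated" and self.is_valid is False:
            raise ValueError("simulated reflectance outside [0, 1]")

    @property
    def is_valid(self) -> bool:
        r = self.band_reflectance
        return bool(np.all(np.isfinite(r)) and np.all(r >= 0.0) and np.all(r <= 1.0))


# ---------------------------------------------------------------------------
# Parameter distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDistribution:
    """Marginal law for one model parameter: truncated Gaussian by default."""

    min: float
    max: float
    mean: float
    std: float
    law: str = "truncated-gaussian"

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"min={self.min} > max={self.max}")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"mean={self.mean} outside [{self.min}, {self.max}]")
        if self.std < 0:
            raise ValueError(f"negative std {self.std}")
        if self.law not in ("truncated-gaussian", "uniform", "fixed"):
            raise ValueError(f"unknown law {self.law!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.law == "fixed" or self.std == 0.0 and self.law == "truncated-gaussian":
            return np.full(n, self.mean)
        if self.law == "uniform":
            return rng.uniform(self.min, self.max, size=n)
        a = (self.min - self.mean) / self.std
        b = (self.max - self.mean) / self.std
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.std, size=n, random_state=rng)


DistributionSpec = Mapping[str, ParamDistribution]


def default_distribution_spec() -> dict[str, ParamDistribution]:
    """The standard sampling ranges for broadband LUT/training-set generation.

    All leaf/canopy/soil parameters follow truncated Gaussians over their
    plausible physical ranges (LAI 0–7 m²/m² with mean 3.5 and std 2.5,
    chlorophyll 0–90 µg·cm⁻² with mean 50 and std 40, etc.) so the database
    spans many vegetation types and states — the multi-species setting.
    """
    g = ParamDistribution
    return {
        "N": g(1.0, 2.5, 1.5, 1.0),
        "cab": g(0.0, 90.0, 50.0, 40.0),
        "car": g(0.0, 20.0, 10.0, 7.0),
        "cbrown": g(0.0, 1.5, 0.2, 0.8),
        "cw": g(0.0, 0.05, 0.02, 0.025),
        "cm": g(0.0, 0.02, 0.01, 0.01),
        "lai": g(0.0, 7.0, 3.5, 2.5),
        "alia": g(30.0, 80.0, 60.0, 20.0),
        "hspot": g(0.0, 1.0, 0.45, 0.6),
        "psoil": g(0.0, 1.0, 0.5, 0.5),
    }


def lai_only_spec() -> dict[str, ParamDistribution]:
    """A restricted prior where only LAI varies and every other parameter is
    fixed at its default mean.

    Under this prior the feature → LAI relation of the toy model is a
    deterministic monotone function, so noise-free inversion must recover
    LAI essentially exactly — the configuration for parameter-recovery and
    identifiability checks.  The full :func:`default_distribution_spec`
    deliberately breaks this determinism (leaf chemistry, structure and
    soil confound the signal) and is the realistic study condition.
    """
    out = {}
    for name, d in default_distribution_spec().items():
        if name == "lai":
            out[name] = d
        else:
            out[name] = ParamDistribution(d.min, d.max, d.mean, 0.0, law="fixed")
    return out


def spec_from_dict(raw: Mapping[str, Mapping[str, float]]) -> dict[str, ParamDistribution]:
    """Build a distribution spec from plain dicts (e.g. parsed JSON config)."""
    out = dict(default_distribution_spec())
    for name, row in raw.items():
        if name not in out:
            raise KeyError(f"unknown parameter {name!r}")
        out[name] = ParamDistribution(
            min=row["min"], max=row["max"],
            mean=row.get("mean", 0.5 * (row["min"] + row["max"])),
            std=row.get("std", 0.0), law=row.get("law", "truncated-gaussian"),
        )
    return out


def sample_parameter_array(
    spec: DistributionSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` parameter vectors; returns an ``(n, 10)`` array in
    ``PARAM_NAMES`` column order.  Vectorized companion of
    :func:`sample_parameters`."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols = []
    for name in PARAM_NAMES:
        if name not in spec:
            raise KeyError(f"distribution spec missing parameter {name!r}")
        cols.append(spec[name].sample(n, rng))
    return np.column_stack(cols) if n else np.empty((0, len(PARAM_NAMES)))


def sample_parameters(
    spec: DistributionSpec, n: int, seed: int | np.random.Generator
) -> list[CanopyParams]:
    """Draw ``n`` :class:`CanopyParams` from the per-parameter truncated laws."""
    arr = sample_parameter_array(spec, n, seed)
    return [CanopyParams.from_array(row) for row in arr]


# ---------------------------------------------------------------------------
# Toy canopy model
# ---------------------------------------------------------------------------

def _as_spectrum_fn(value) -> Callable[[np.ndarray], np.ndarray]:
    if callable(value):
        return value
    const = float(value)
    return lambda wl: np.full_like(wl, const, dtype=float)


def _default_soil_shape(wl: np.ndarray) -> np.ndarray:
    # dry-soil-like: brightens with wavelength
    return 0.12 + 0.30 * (wl - 400.0) / 2100.0


def _red_edge(wl: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - 710.0) / 20.0))


def _visible_shape(wl: np.ndarray) -> np.ndarray:
    # green-peak visible reflectance shape, normalised to ~1 at 550 nm
    return 0.35 + 0.65 * np.exp(-((wl - 550.0) ** 2) / (2.0 * 35.0**2))


class ToyCanopyModel:
    """Analytic two-stream canopy: exponential mixing of a soil background and
    an infinite-canopy (dense vegetation) spectrum,

        R(λ) = R_soil(λ) · exp(−k·LAI) + R_∞(λ) · (1 − exp(−k·LAI)),

    with extinction k = cos(ALIA) ∈ (0, 1] for leaf inclinations in
    (0°, 90°).  The model is strictly monotone in LAI wherever soil and
    dense-canopy reflectance differ, which makes LAI identifiable and gives
    every inversion test an exact ground truth.

    By default the endmember spectra respond to the leaf/soil parameters so
    that cross-sample heterogeneity confounds retrieval realistically:
    visible R_∞ decreases with chlorophyll, the NIR plateau grows with leaf
    structure N and drops with brown pigment, and the soil line is scaled by
    the brightness factor psoil.  Constant overrides (``soil_spectrum``,
    ``leaf_spectrum``, ``extinction``) turn it into the fixed closed form
    used by hand-calculated oracles.
    """

    wavelength_lo = 400.0
    wavelength_hi = 1000.0

    def __init__(
        self,
        soil_spectrum=None,
        leaf_spectrum=None,
        extinction: float | None = None,
        grid_step: float = 1.0,
    ) -> None:
        self.wavelengths = np.arange(self.wavelength_lo, self.wavelength_hi + grid_step, grid_step)
        self._soil_override = None if soil_spectrum is None else _as_spectrum_fn(soil_spectrum)
        self._leaf_override = None if leaf_spectrum is None else _as_spectrum_fn(leaf_spectrum)
        self._k_override = extinction
        if extinction is not None and not (0.0 < extinction <= 1.5):
            raise ValueError("extinction must be in (0, 1.5]")

    # -- per-parameter endmember scalars (vectorized over sample axis) -------

    @staticmethod
    def _nir_plateau(N, cbrown, cw):
        return np.clip(0.32 + 0.12 * (np.asarray(N) - 1.0) / 1.5
                       - 0.08 * np.asarray(cbrown) / 1.5
                       - 0.04 * np.asarray(cw) / 0.05, 0.10, 0.60)

    @staticmethod
    def _vis_amplitude(cab, car):
        return 0.02 + 0.16 * np.exp(-np.asarray(cab) / 45.0) + 0.01 * np.asarray(car) / 20.0

    @staticmethod
    def _soil_scale(psoil):
        return 0.3 + 0.7 * np.asarray(psoil)

    def extinction_of(self, alia) -> np.ndarray:
        if self._k_override is not None:
            return np.broadcast_to(self._k_override, np.shape(alia)) if np.ndim(alia) else np.float64(self._k_override)
        return np.cos(np.deg2rad(np.asarray(alia, dtype=float)))

    def endmembers(self, wl: np.ndarray, p: CanopyParams) -> tuple[np.ndarray, np.ndarray]:
        """(soil, infinite-canopy) reflectance spectra for one parameter set."""
        if self._soil_override is not None:
            soil = self._soil_override(wl)
        else:
            soil = self._soil_scale(p.psoil) * _default_soil_shape(wl)
        if self._leaf_override is not None:
            leaf = self._leaf_override(wl)
        else:
            s = _red_edge(wl)
            leaf = self._nir_plateau(p.N, p.cbrown, p.cw) * s \
                + self._vis_amplitude(p.cab, p.car) * _visible_shape(wl) * (1.0 - s)
        return soil, leaf

    def spectrum(self, p: CanopyParams, geom: ViewGeometry) -> Spectrum:
        wl = self.wavelengths
        soil, leaf = self.endmembers(wl, p)
        k = float(self.extinction_of(p.alia))
        att = np.exp(-k * p.lai)
        return Spectrum(wl, soil * att + leaf * (1.0 - att))

    def bands(self, params: np.ndarray, geom: ViewGeometry,
              bands: Sequence[BandDefinition] = GF1_BANDS) -> np.ndarray:
        """Band reflectance for an ``(n, 10)`` parameter array without forming
        the full (n, n_wavelengths) matrix: the model is linear in three fixed
        wavelength shapes, so band means of the shapes are precomputed once."""
        params = np.atleast_2d(np.asarray(params, dtype=float))
        wl = self.wavelengths
        masks = []
        for b in bands:
            m = (wl >= b.wavelength_lo) & (wl <= b.wavelength_hi)
            if not m.any():
                raise ValueError(f"band {b.name} outside model wavelength grid")
            masks.append(m)

        col = {name: params[:, i] for i, name in enumerate(PARAM_NAMES)}
        k = self.extinction_of(col["alia"])
        att = np.exp(-k * col["lai"])[:, None]  # (n, 1)

        if self._soil_override is not None:
            soil_b = np.array([self._soil_override(wl)[m].mean() for m in masks])
            soil = np.broadcast_to(soil_b, (params.shape[0], len(bands)))
        else:
            shape_b = np.array([_default_soil_shape(wl)[m].mean() for m in masks])
            soil = self._soil_scale(col["psoil"])[:, None] * shape_b

        if self._leaf_override is not None:
            leaf_b = np.array([self._leaf_override(wl)[m].mean() for m in masks])
            leaf = np.broadcast_to(leaf_b, (params.shape[0], len(bands)))
        else:
            s = _red_edge(wl)
            nir_b = np.array([s[m].mean() for m in masks])
            vis_b = np.array([(_visible_shape(wl) * (1.0 - s))[m].mean() for m in masks])
            leaf = (self._nir_plateau(col["N"], col["cbrown"], col["cw"])[:, None] * nir_b
                    + self._vis_amplitude(col["cab"], col["car"])[:, None] * vis_b)
        return soil * att + leaf * (1.0 - att)


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

_TOY = ToyCanopyModel()


def _prosail_spectrum(p: CanopyParams, geom: ViewGeometry) -> Spectrum:
    try:
        import prosail  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise BackendUnavailableError(
            "the 'prosail' backend requires the prosail package "
            "(pip install prosail); the 'toy' backend is always available"
        ) from exc
    refl = prosail.run_prosail(
        n=p.N, cab=p.cab, car=p.car, cbrown=p.cbrown, cw=p.cw, cm=p.cm,
        lai=p.lai, lidfa=p.alia, hspot=p.hspot, psoil=p.psoil, rsoil=1.0,
        tts=geom.tts, tto=geom.tto, psi=geom.psi, typelidf=2,
    )
    return Spectrum(np.arange(400.0, 2501.0), refl)


def forward_model(
    params: CanopyParams,
    geom: ViewGeometry = ViewGeometry(),
    backend: str | ToyCanopyModel = "toy",
) -> Spectrum:
    """Simulate top-of-canopy reflectance for one parameter vector.

    ``backend`` is ``"toy"`` (built-in analytic model), ``"prosail"``
    (PROSAIL5B, requires the optional dependency), or a
    :class:`ToyCanopyModel` instance for configured oracles.  Deterministic.
    """
    model = _resolve_backend(backend)
    if model is None:
        return _prosail_spectrum(params, geom)
    return model.spectrum(params, geom)


def _resolve_backend(backend) -> ToyCanopyModel | None:
    if isinstance(backend, ToyCanopyModel):
        return backend
    if backend == "toy":
        return _TOY
    if backend == "prosail":
        return None
    raise ValueError(f"unknown backend {backend!r}; expected 'toy' or 'prosail'")


def simulate_bands(
    params: np.ndarray,
    geom: ViewGeometry = ViewGeometry(),
    backend: str | ToyCanopyModel = "toy",
    bands: Sequence[BandDefinition] = GF1_BANDS,
) -> np.ndarray:
    """Forward-model an ``(n, 10)`` parameter array straight to band
    reflectance ``(n, n_bands)``.  Agrees with the per-sample
    forward_model → resample_to_bands path to floating-point accuracy."""
    model = _resolve_backend(backend)
    if model is not None:
        return model.bands(params, geom, bands)
    params = np.atleast_2d(np.asarray(params, dtype=float))
    out = np.empty((params.shape[0], len(bands)))
    for i, row in enumerate(params):
        spec = _prosail_spectrum(CanopyParams.from_array(row), geom)
        out[i] = resample_to_bands(spec, bands).band_reflectance
    return out


# ---------------------------------------------------------------------------
# Band resampling and noise
# ---------------------------------------------------------------------------

def resample_to_bands(
    spectrum: Spectrum,
    bands: Sequence[BandDefinition] = GF1_BANDS,
    response: Mapping[str, np.ndarray] | None = None,
) -> SpectralSample:
    """Integrate a spectrum to broad-band reflectance.

    Default response is a boxcar: the unweighted mean of the spectrum over
    [wavelength_lo, wavelength_hi] inclusive.  ``response`` may supply
    per-band weights on the spectrum's wavelength grid (e.g. measured sensor
    response curves), used as a weighted mean instead.
    """
    wl = spectrum.wavelengths
    values = np.empty(len(bands))
    for j, b in enumerate(bands):
        if response is not None and b.name in response:
            w = np.asarray(response[b.name], dtype=float)
            if w.shape != wl.shape:
                raise ValueError(f"response weights for {b.name} do not match the grid")
            if w.sum() <= 0:
                raise ValueError(f"response weights for {b.name} sum to zero")
            values[j] = float(np.sum(w * spectrum.reflectance) / np.sum(w))
            continue
        mask = (wl >= b.wavelength_lo) & (wl <= b.wavelength_hi)
        if b.wavelength_lo < wl.min() or b.wavelength_hi > wl.max() or not mask.any():
            raise ValueError(
                f"band {b.name} [{b.wavelength_lo}, {b.wavelength_hi}] nm is not "
                f"covered by the spectrum grid [{wl.min()}, {wl.max()}] nm"
            )
        values[j] = float(spectrum.reflectance[mask].mean())
    return SpectralSample(values, source="simulated")


def add_noise(
    sample: SpectralSample | np.ndarray,
    sigma: float,
    seed: int | np.random.Generator,
) -> SpectralSample | np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise (std ``sigma``, absolute
    reflectance units) to each band; the result is clipped to [0, 1].
    Accepts a single sample or an (n, n_bands) array."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(sample, SpectralSample):
        noisy = sample.band_reflectance + rng.normal(0.0, sigma, sample.band_reflectance.shape) \
            if sigma > 0 else sample.band_reflectance.copy()
        return SpectralSample(np.clip(noisy, 0.0, 1.0), source=sample.source)
    arr = np.asarray(sample, dtype=float)
    if sigma == 0:
        return arr.copy()
    return np.clip(arr + rng.normal(0.0, sigma, arr.shape), 0.0, 1.0)
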