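"""Synthetic study inputs with known truth.

Real validation campaigns for LAI retrieval — a few dozen field plots
measured with a plant canopy analyzer plus one four-band satellite scene —
are rarely redistributable, so this module generates statistically
analogous stand-ins:

* :func:`simulate_field_campaign` — a plot table (default 29 plots, the
  size of a typical arid-basin campaign) where each plot gets a full
  canopy/leaf/soil parameter draw.  Because *all* parameters vary between
  plots, leaf chemistry and structure confound the reflectance–LAI relation
  exactly as species mixtures do in the field; that heterogeneity, not
  sensor noise, is what caps achievable retrieval accuracy.
* :func:`simulate_scene` — a small georeferenced four-band raster with a
  hidden true-LAI surface (gradient, patches or random-smooth patterns,
  default range 0–4 m²/m² as in sparse arid vegetation), plus a nodata
  border strip to exercise masking.

Both are reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .rtm_forward import (
    DistributionSpec,
    PARAM_NAMES,
    ViewGeometry,
    add_noise,
    default_distribution_spec,
    sample_parameter_array,
    simulate_bands,
)

__all__ = ["SyntheticScene", "simulate_field_campaign", "simulate_scene",
           "SPECIES_LABELS", "DEFAULT_NODATA"]

#: Cosmetic species labels for campaign plots (mixed desert-riparian flora);
#: no species-specific physics is attached to them.
SPECIES_LABELS = ("Hami melon", "Tamarix chinensis", "reed", "weed",
                  "flower wood", "bitter bean")

DEFAULT_NODATA = -9999.0

_LAI_COL = PARAM_NAMES.index("lai")

# campaign bounding box (degrees): lower reaches of an inland river basin
_LON_RANGE = (100.0, 101.5)
_LAT_RANGE = (41.0, 42.3)


@dataclass
class SyntheticScene:
    """Four-band reflectance grid with affine georeferencing and hidden truth.

    ``transform`` is a GDAL-style geotransform
    ``(x0, dx, 0, y0, 0, -dy)``: the coordinates of the upper-left corner
    and the pixel size.  ``true_lai`` is NaN on masked cells; ``mask`` is
    True where the pixel is valid.
    """

    bands: np.ndarray           # (4, rows, cols) reflectance
    true_lai: np.ndarray        # (rows, cols)
    mask: np.ndarray            # (rows, cols) bool, True = valid
    transform: tuple[float, float, float, float, float, float]
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        self.true_lai = np.asarray(self.true_lai, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.bands.ndim != 3 or self.bands.shape[0] != 4:
            raise ValueError("bands must have shape (4, rows, cols)")
        if self.bands.shape[1:] != self.true_lai.shape or self.true_lai.shape != self.mask.shape:
            raise ValueError("band/truth/mask grid dimensions differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.true_lai.shape

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        x0, dx, _, y0, _, ndy = self.transform
        return x0 + (col + 0.5) * dx, y0 + (row + 0.5) * ndy


def simulate_field_campaign(
    n_plots: int = 29,
    spec: DistributionSpec | None = None,
    geom: ViewGeometry = ViewGeometry(),
    backend="toy",
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a plot-level validation campaign.

    Returns a DataFrame with columns ``plot_id, lon, lat, true_lai,
    B1..B4, species`` where band reflectance is the forward model of the
    plot's full (hidden) parameter draw plus Gaussian noise.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    spec = default_distribution_spec() if spec is None else spec
    rng = np.random.default_rng(seed)
    params = sample_parameter_array(spec, n_plots, rng)
    bands = simulate_bands(params, geom, backend)
    if noise_sigma > 0:
        bands = add_noise(bands, noise_sigma, rng)
    lon = rng.uniform(*_LON_RANGE, n_plots)
    lat = rng.uniform(*_LAT_RANGE, n_plots)
    species = rng.choice(SPECIES_LABELS, n_plots)
    df = pd.DataFrame({
        "plot_id": [f"P{i + 1:03d}" for i in range(n_plots)],
        "lon": lon, "lat": lat,
        "true_lai": params[:, _LAI_COL],
        "B1": bands[:, 0], "B2": bands[:, 1], "B3": bands[:, 2], "B4": bands[:, 3],
        "species": species,
    })
    for j, name in enumerate(PARAM_NAMES):
        if name != "lai":
            df[f"param_{name}"] = params[:, j]
    return df


def _lai_pattern(pattern: str, rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-interval spatial field for the named pattern."""
    if pattern == "gradient":
        return np.tile(np.linspace(0.0, 1.0, cols), (rows, 1))
    if pattern == "patches":
        block = max(1, min(rows, cols) // 8)
        br, bc = -(-rows // block), -(-cols // block)
        levels = rng.uniform(0.0, 1.0, (br, bc))
        return np.kron(levels, np.ones((block, block)))[:rows, :cols]
    if pattern == "random-smooth":
        noise = rng.normal(size=(rows, cols))
        smooth = ndimage.gaussian_filter(noise, sigma=max(rows, cols) / 16.0, mode="reflect")
        lo, hi = smooth.min(), smooth.max()
        return (smooth - lo) / (hi - lo) if hi > lo else np.full((rows, cols), 0.5)
    raise ValueError(f"unknown LAI pattern {pattern!r}; "
                     "expected gradient, patches or random-smooth")


def simulate_scene(
    rows: int = 64,
    cols: int = 64,
    lai_field: str = "gradient",
    lai_range: tuple[float, float] = (0.0, 4.0),
    spec: DistributionSpec | None = None,
    geom: ViewGeometry = ViewGeometry(),
    backend="toy",
    noise_sigma: float = 0.01,
    seed: int = 0,
    border: int = 2,
    pixel_size_deg: float = 16.0 / 111_000.0,
) -> SyntheticScene:
    """Generate a georeferenced four-band scene over a hidden LAI surface.

    Non-LAI parameters are resampled per pixel (spatially uncorrelated
    heterogeneity); the named ``lai_field`` pattern is scaled into
    ``lai_range``.  A ``border``-pixel nodata strip runs along the top edge
    so downstream masking is always exercised.  The default pixel size is a
    16 m ground sample expressed in degrees.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    spec = default_distribution_spec() if spec is None else spec
    rng = np.random.default_rng(seed)
    unit = _lai_pattern(lai_field, rows, cols, rng)
    lo, hi = lai_range
    truth = lo + (hi - lo) * unit

    params = sample_parameter_array(spec, rows * cols, rng)
    params[:, _LAI_COL] = truth.ravel()
    bands_flat = simulate_bands(params, geom, backend)
    if noise_sigma > 0:
        bands_flat = add_noise(bands_flat, noise_sigma, rng)
    bands = bands_flat.T.reshape(4, rows, cols)

    mask = np.ones((rows, cols), dtype=bool)
    if border > 0 and rows > border:
        mask[:border, :] = False
    truth = np.where(mask, truth, np.nan)
    bands = np.where(mask[None, :, :], bands, np.nan)

    transform = (_LON_RANGE[0], pixel_size_deg, 0.0, _LAT_RANGE[1], 0.0, -pixel_size_deg)
    meta = {"lai_field": lai_field, "lai_range": list(lai_range), "seed": seed,
            "noise_sigma": noise_sigma,
            "backend": backend if isinstance(backend, str) else "toy-custom"}
    return SyntheticScene(bands, truth, mask, transform, metadata=meta)
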