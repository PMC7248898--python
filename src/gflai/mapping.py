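"""Per-pixel LAI mapping over four-band reflectance rasters.

Scenes are stored as plain multiband float TIFFs (band order B1..B4, plus
an optional truth band) with a JSON sidecar carrying the geotransform, CRS
and nodata value.  Inversion runs every valid pixel through *the same
scalar code path* as plot-level inversion — the map of a scene is, by
construction, the per-pixel map of its samples — and masks pixels whose
features are invalid (nodata input, out-of-range reflectance, undefined
vegetation index).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .features import Strategy, extract_features
from .gpr_inversion import GPRModel, predict_gpr
from .lut_inversion import LookUpTable, invert_lut
from .synthetic_data import DEFAULT_NODATA, SyntheticScene

__all__ = ["LAIMap", "write_scene", "read_scene", "invert_scene",
           "match_plots_to_pixels", "write_map", "read_map"]


@dataclass
class LAIMap:
    """Georeferenced LAI grid (m²/m²) with validity mask and provenance."""

    lai: np.ndarray             # (rows, cols), NaN on masked cells
    mask: np.ndarray            # bool, True = valid
    transform: tuple[float, float, float, float, float, float]
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lai = np.asarray(self.lai, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.lai.shape != self.mask.shape:
            raise ValueError("lai and mask dimensions differ")


# ---------------------------------------------------------------------------
# Scene I/O: multiband float TIFF + JSON georeferencing sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_scene(scene: SyntheticScene, path: str | Path, include_truth: bool = True) -> None:
    """Write a scene as a (4 or 5)-band float32 TIFF; band 5 is the hidden
    true-LAI surface when ``include_truth``.  Nodata cells carry the scene's
    nodata value in every band."""
    path = Path(path)
    stack = [np.where(scene.mask, scene.bands[i], scene.nodata) for i in range(4)]
    if include_truth:
        stack.append(np.where(scene.mask, scene.true_lai, scene.nodata))
    tifffile.imwrite(path, np.stack(stack).astype(np.float32))
    meta = {"transform": list(scene.transform), "crs": scene.crs,
            "nodata": scene.nodata, "has_truth_band": include_truth,
            "metadata": scene.metadata}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_scene(path: str | Path, scale_factor: float = 1.0) -> SyntheticScene:
    """Read a scene raster back into memory.

    ``scale_factor`` divides integer-scaled reflectance (e.g. 10000 for
    reflectance stored as 0–10000 integers).  Pixels equal to nodata, or
    with reflectance outside [0, 1] after scaling, are masked.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    has_truth = bool(meta.get("has_truth_band", data.shape[0] == 5))
    expected = 5 if has_truth else 4
    if data.shape[0] != expected:
        raise ValueError(
            f"expected a {expected}-band raster (B1..B4"
            + (", truth)" if has_truth else ")") + f", got {data.shape[0]} bands")
    nodata = float(meta.get("nodata", DEFAULT_NODATA))
    bands = data[:4]
    nodata_mask = np.any(bands == nodata, axis=0)
    bands = bands / scale_factor
    in_range = np.all((bands >= 0.0) & (bands <= 1.0), axis=0)
    mask = ~nodata_mask & in_range
    bands = np.where(mask[None], bands, np.nan)
    if has_truth:
        truth = np.where(mask & (data[4] != nodata), data[4], np.nan)
    else:
        truth = np.full(mask.shape, np.nan)
    transform = tuple(meta.get("transform", (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)))
    return SyntheticScene(bands, truth, mask, transform,
                          crs=meta.get("crs", "EPSG:4326"), nodata=nodata,
                          metadata=meta.get("metadata", {}))


def write_map(lai_map: LAIMap, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.where(lai_map.mask, lai_map.lai,
                                    lai_map.nodata).astype(np.float32))
    meta = {"transform": list(lai_map.transform), "crs": lai_map.crs,
            "nodata": lai_map.nodata, "provenance": lai_map.provenance}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_map(path: str | Path) -> LAIMap:
    path = Path(path)
    lai = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    mask = lai != meta["nodata"]
    return LAIMap(np.where(mask, lai, np.nan), mask, tuple(meta["transform"]),
                  crs=meta["crs"], nodata=meta["nodata"],
                  provenance=meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# Per-pixel inversion
# ---------------------------------------------------------------------------

def _scene_checksum(scene: SyntheticScene) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.nan_to_num(scene.bands)).tobytes())
    return h.hexdigest()[:16]


def invert_scene(
    scene: SyntheticScene,
    strategy: Strategy,
    artifact: LookUpTable | GPRModel,
    q: float = 0.10,
) -> LAIMap:
    """Invert every valid pixel of a scene to LAI.

    ``artifact`` is a built :class:`LookUpTable` or trained
    :class:`GPRModel`; its strategy must match ``strategy``.  Each pixel is
    inverted through the scalar plot-level path, so the map is independent
    of traversal order and identical to a per-pixel loop by construction.
    """
    if artifact.strategy.name != strategy.name:
        raise ValueError(
            f"artifact was built for strategy {artifact.strategy.name}, "
            f"requested {strategy.name}")
    engine = "LUT" if isinstance(artifact, LookUpTable) else "GPR"
    rows, cols = scene.shape
    lai = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            if not scene.mask[i, j]:
                continue
            pixel = scene.bands[:, i, j]
            if not np.all(np.isfinite(pixel)):
                continue
            feats = extract_features(pixel, strategy)
            if not feats.is_valid:
                continue
            if engine == "LUT":
                sol = invert_lut(feats, artifact, q=q)
                if sol.valid:
                    lai[i, j] = sol.lai_estimate
            else:
                est, _ = predict_gpr(artifact, feats.values)
                lai[i, j] = est
    mask = np.isfinite(lai)
    prov = {"strategy": strategy.name, "engine": engine,
            "input_checksum": _scene_checksum(scene)}
    if engine == "LUT":
        prov["q"] = q
    return LAIMap(lai, mask, scene.transform, crs=scene.crs,
                  nodata=scene.nodata, provenance=prov)


def match_plots_to_pixels(
    plots: pd.DataFrame,
    raster: SyntheticScene | LAIMap,
) -> pd.DataFrame:
    """Assign each plot (columns ``lon``/``lat``) to the nearest pixel
    center of a raster; plots outside the footprint are dropped with a
    warning.  Returns the surviving plots with added ``row``/``col``
    columns (many plots may share one pixel)."""
    x0, dx, _, y0, _, ndy = raster.transform
    grid = raster.lai if isinstance(raster, LAIMap) else raster.true_lai
    rows, cols = grid.shape
    col_idx = np.floor((plots["lon"].to_numpy(dtype=float) - x0) / dx).astype(int)
    row_idx = np.floor((plots["lat"].to_numpy(dtype=float) - y0) / ndy).astype(int)
    inside = (col_idx >= 0) & (col_idx < cols) & (row_idx >= 0) & (row_idx < rows)
    n_dropped = int((~inside).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} plot(s) outside the raster footprint dropped",
                      stacklevel=2)
    out = plots.loc[inside].copy()
    out["row"] = row_idx[inside]
    out["col"] = col_idx[inside]
    out.attrs["n_dropped"] = n_dropped
    return out
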