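"""Retrieval features: the 15 band combinations and 10 vegetation indices.

A *strategy* is one feature definition paired with an inversion method
(LUT or GPR): either a non-empty subset of the four sensor bands
(B1 blue, B2 green, B3 red, B4 near-infrared), or a single published
vegetation index.  The ten indices span simple differences (DVI), the
normalized-difference family (NDVI, GNDVI), ratio (GRVI), triangular
(TVI, MTVI2) and soil-adjusted / nonlinear forms (MSAVI, MNLI, EVI2,
MCARI-type).

Indices with a discriminant (MSAVI, MCARI, MTVI2) or a denominator can be
undefined for extreme inputs; those evaluate to NaN rather than raising, so
per-pixel raster processing can mask them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .rtm_forward import SpectralSample

__all__ = [
    "Strategy",
    "FeatureVector",
    "VI_NAMES",
    "BAND_SUBSETS",
    "compute_vi",
    "extract_features",
    "enumerate_strategies",
    "strategy_from_name",
]

#: The 15 band combinations, in canonical enumeration order: the four
#: singletons, the six pairs, the four triples, then the full set.
BAND_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("B1",), ("B2",), ("B3",), ("B4",),
    ("B1", "B2"), ("B1", "B3"), ("B1", "B4"),
    ("B2", "B3"), ("B2", "B4"), ("B3", "B4"),
    ("B1", "B2", "B3"), ("B1", "B2", "B4"),
    ("B1", "B3", "B4"), ("B2", "B3", "B4"),
    ("B1", "B2", "B3", "B4"),
)

_BAND_INDEX = {"B1": 0, "B2": 1, "B3": 2, "B4": 3}


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(num, dtype=float) / den
    return np.where(np.abs(den) < 1e-12, np.nan, out)


def _safe_sqrt(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(x < 0, np.nan, np.sqrt(np.maximum(x, 0.0)))


def _tri_denominator(b3, b4, literal: bool):
    # shared discriminant of the MCARI2/MTVI2 family; the canonical
    # published form uses sqrt(red); the as-printed variant uses red itself
    red_term = b3 if literal else _safe_sqrt(b3)
    return _safe_sqrt((2 * b4 + 1) ** 2 - (6 * b4 - 5 * red_term) - 0.5)


def _ndvi(b1, b2, b3, b4, literal=False):
    return _safe_div(b4 - b3, b4 + b3)


def _dvi(b1, b2, b3, b4, literal=False):
    return np.asarray(b4, dtype=float) - np.asarray(b3, dtype=float)


def _tvi(b1, b2, b3, b4, literal=False):
    return 0.5 * (120.0 * (b4 - b2) - 200.0 * (b3 - b2))


def _evi2(b1, b2, b3, b4, literal=False):
    return _safe_div(2.5 * (b4 - b3), b4 + 2.4 * b3 + 1.0)


def _gndvi(b1, b2, b3, b4, literal=False):
    return _safe_div(b4 - b2, b4 + b2)


def _grvi(b1, b2, b3, b4, literal=False):
    return _safe_div(b4, b2) - 1.0


def _mcari(b1, b2, b3, b4, literal=False):
    return _safe_div(1.5 * (2.5 * (b4 - b3) - 1.3 * (b4 - b2)),
                     _tri_denominator(b3, b4, literal))


def _mnli(b1, b2, b3, b4, literal=False):
    b4sq = np.asarray(b4, dtype=float) ** 2
    return _safe_div(1.5 * (b4sq - b3), b4sq + b3 + 0.5)


def _msavi(b1, b2, b3, b4, literal=False):
    return 0.5 * ((2 * b4 + 1) - _safe_sqrt((2 * b4 + 1) ** 2 - 8.0 * (b4 - b3)))


def _mtvi2(b1, b2, b3, b4, literal=False):
    return _safe_div(1.5 * (1.2 * (b4 - b2) - 2.5 * (b3 - b2)),
                     _tri_denominator(b3, b4, literal))


_VI_FUNCS = {
    "NDVI": _ndvi, "DVI": _dvi, "TVI": _tvi, "EVI2": _evi2, "GNDVI": _gndvi,
    "GRVI": _grvi, "MCARI": _mcari, "MNLI": _mnli, "MSAVI": _msavi, "MTVI2": _mtvi2,
}

#: The ten vegetation indices in canonical enumeration order.
VI_NAMES: tuple[str, ...] = tuple(_VI_FUNCS)


@dataclass(frozen=True)
class Strategy:
    """One feature definition + inversion method.

    Exactly one of ``bands`` / ``vi_name`` is set.  ``method`` is "LUT" or
    "GPR"; it selects the inversion engine in the comparison harness but
    does not change the feature values.
    """

    method: str = "LUT"
    bands: tuple[str, ...] | None = None
    vi_name: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("LUT", "GPR"):
            raise ValueError(f"method must be LUT or GPR, got {self.method!r}")
        if (self.bands is None) == (self.vi_name is None):
            raise ValueError("exactly one of bands / vi_name must be given")
        if self.bands is not None:
            if tuple(self.bands) not in BAND_SUBSETS:
                raise ValueError(f"bands {self.bands!r} is not one of the 15 legal subsets")
        elif self.vi_name not in _VI_FUNCS:
            raise ValueError(f"unknown vegetation index {self.vi_name!r}")

    @property
    def feature_kind(self) -> str:
        return "band-subset" if self.bands is not None else "vegetation-index"

    @property
    def n_features(self) -> int:
        return len(self.bands) if self.bands is not None else 1

    @property
    def name(self) -> str:
        return "".join(self.bands) if self.bands is not None else self.vi_name  # type: ignore[return-value]


@dataclass
class FeatureVector:
    """Feature values for one observation under one strategy; NaN marks an
    undefined (maskable) feature."""

    values: np.ndarray
    strategy: Strategy

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.shape[-1] != self.strategy.n_features:
            raise ValueError("feature length does not match strategy")

    @property
    def is_valid(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


def compute_vi(sample, vi_name: str, variant: str = "canonical"):
    """Evaluate a vegetation index for a sample or an (..., 4) band array.

    The default formulas are the canonical published forms; ``variant=
    "literal"`` switches MCARI/MTVI2 to the as-printed discriminant (red
    band instead of its square root).  Undefined values (zero denominator,
    negative discriminant) come back as NaN.
    """
    if vi_name not in _VI_FUNCS:
        raise ValueError(f"unknown vegetation index {vi_name!r}")
    if variant not in ("canonical", "literal"):
        raise ValueError(f"variant must be 'canonical' or 'literal', got {variant!r}")
    arr = sample.band_reflectance if isinstance(sample, SpectralSample) else np.asarray(sample, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError("expected 4 band values (B1..B4)")
    b1, b2, b3, b4 = (arr[..., i] for i in range(4))
    out = _VI_FUNCS[vi_name](b1, b2, b3, b4, literal=(variant == "literal"))
    return float(out) if np.ndim(out) == 0 else out


def extract_features(sample, strategy: Strategy, variant: str = "canonical") -> FeatureVector:
    """Apply a strategy's feature definition to one spectral sample."""
    arr = sample.band_reflectance if isinstance(sample, SpectralSample) else np.asarray(sample, dtype=float)
    if strategy.bands is not None:
        idx = [_BAND_INDEX[b] for b in strategy.bands]
        return FeatureVector(arr[..., idx], strategy)
    return FeatureVector(np.atleast_1d(compute_vi(arr, strategy.vi_name, variant)), strategy)


def feature_matrix(band_reflectance: np.ndarray, strategy: Strategy,
                   variant: str = "canonical") -> np.ndarray:
    """Vectorized feature extraction for an (n, 4) reflectance matrix,
    returning (n, n_features)."""
    arr = np.asarray(band_reflectance, dtype=float)
    if strategy.bands is not None:
        return arr[:, [_BAND_INDEX[b] for b in strategy.bands]]
    return np.asarray(compute_vi(arr, strategy.vi_name, variant)).reshape(-1, 1)


def enumerate_strategies(methods: Iterable[str] = ("LUT", "GPR")) -> list[Strategy]:
    """All 25 feature strategies (15 band subsets + 10 indices) for each
    requested method, band subsets first."""
    out: list[Strategy] = []
    for method in methods:
        out.extend(Strategy(method=method, bands=subset) for subset in BAND_SUBSETS)
        out.extend(Strategy(method=method, vi_name=vi) for vi in VI_NAMES)
    return out


def strategy_from_name(name: str, method: str = "LUT") -> Strategy:
    """Parse a strategy label like ``"B2B4"`` or ``"MSAVI"``."""
    if name in _VI_FUNCS:
        return Strategy(method=method, vi_name=name)
    bands = tuple(name[i:i + 2] for i in range(0, len(name), 2))
    return Strategy(method=method, bands=bands)
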