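"""Spectral indices (BSI, NBR, FZ, IFZ) and annual best-pixel composites.

The integrated forest z-score (IFZ) measures how far a pixel's spectrum sits
from a local reference population of undisturbed forest:

    FZ_i = (b_i - mean_i) / SD_i          (per band)
    IFZ  = sqrt( (1/NB) * sum_i FZ_i^2 )  (root-mean-square over NB bands)

Low IFZ means forest-like.  By default the RED, SWIR1 and SWIR2 bands are
used, the bands in which closed-canopy forest is darkest and most stable.

BSI here is the standard four-band bare soil index
((SWIR1+RED)-(NIR+BLUE)) / ((SWIR1+RED)+(NIR+BLUE)): positive over bare
ground, negative over vegetation, so its 0-crossing marks stand
establishment for the moving-average detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BAND_INDEX, CalibrationError, PixelTimeSeries

DEFAULT_IFZ_BANDS = ("red", "swir1", "swir2")

#: Default target fraction-of-year for the annual composite (mid growing
#: season, matching the generator's seasonal peak).
DEFAULT_TARGET_DOY_FRACTION = 0.55


@dataclass
class ForestReference:
    """Per-band forest statistics (mean, SD) used by FZ/IFZ.

    ``mean`` and ``sd`` are aligned with ``bands_used``; SD must be strictly
    positive for every band used.
    """

    mean: np.ndarray
    sd: np.ndarray
    n_samples: int = 0
    bands_used: tuple = DEFAULT_IFZ_BANDS

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        nb = len(self.bands_used)
        if self.mean.shape != (nb,) or self.sd.shape != (nb,):
            raise CalibrationError(
                "mean/sd must have one entry per band in bands_used"
            )
        if not np.all(np.isfinite(self.mean)) or not np.all(np.isfinite(self.sd)):
            raise CalibrationError("reference statistics must be finite")
        if np.any(self.sd <= 0):
            raise CalibrationError("reference SD must be strictly positive")

    @property
    def nb(self) -> int:
        return len(self.bands_used)

    def band_indices(self) -> np.ndarray:
        return np.array([BAND_INDEX[b] for b in self.bands_used])


def _nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Normalized difference (a-b)/(a+b); NaN where the denominator is 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    return out


def bsi(v: np.ndarray) -> np.ndarray:
    """Bare soil index of band vectors ``v`` (shape (..., 6)); in [-1, 1].

    Zero denominators yield NaN (undefined-value flag); such observations
    are dropped downstream.
    """
    v = np.asarray(v, dtype=float)
    swir1, red = v[..., BAND_INDEX["swir1"]], v[..., BAND_INDEX["red"]]
    nir, blue = v[..., BAND_INDEX["nir"]], v[..., BAND_INDEX["blue"]]
    return _nd(swir1 + red, nir + blue)


def nbr(v: np.ndarray) -> np.ndarray:
    """Normalized burn ratio (NIR-SWIR2)/(NIR+SWIR2); in [-1, 1]."""
    v = np.asarray(v, dtype=float)
    return _nd(v[..., BAND_INDEX["nir"]], v[..., BAND_INDEX["swir2"]])


def fz(v: np.ndarray, ref: ForestReference) -> np.ndarray:
    """Per-band forest z-scores of ``v`` against ``ref``; shape (..., NB)."""
    v = np.asarray(v, dtype=float)
    b = v[..., ref.band_indices()]
    return (b - ref.mean) / ref.sd


def ifz(v: np.ndarray, ref: ForestReference) -> np.ndarray:
    """Integrated forest z-score: RMS of the per-band z-scores."""
    z = fz(v, ref)
    return np.sqrt(np.mean(z * z, axis=-1))


def composite_score(
    times: np.ndarray, target_doy_fraction: float = DEFAULT_TARGET_DOY_FRACTION
) -> np.ndarray:
    """Best-available-pixel score: proximity to the target day of year.

    Scores are in (0, 1]; 1 means exactly at the target fraction.  Distance
    is circular within the year.
    """
    frac = np.asarray(times, dtype=float) % 1.0
    d = np.abs(frac - target_doy_fraction)
    d = np.minimum(d, 1.0 - d)
    return 1.0 - d


def annual_composite(
    ts: PixelTimeSeries,
    year: int,
    target_doy_fraction: float = DEFAULT_TARGET_DOY_FRACTION,
) -> np.ndarray | None:
    """Best clear observation of ``year`` (single-criterion BAP); None if
    the year has no clear observation."""
    in_year = (ts.times >= year) & (ts.times < year + 1) & ts.clear
    if not np.any(in_year):
        return None
    idx = np.flatnonzero(in_year)
    scores = composite_score(ts.times[idx], target_doy_fraction)
    return ts.reflectance[idx[int(np.argmax(scores))]]


def annual_composites(
    ts: PixelTimeSeries,
    years: np.ndarray,
    target_doy_fraction: float = DEFAULT_TARGET_DOY_FRACTION,
) -> np.ndarray:
    """Stack of annual composites for ``years``; missing years are NaN rows."""
    years = np.asarray(years, dtype=int)
    out = np.full((years.size, ts.reflectance.shape[1]), np.nan)
    for i, y in enumerate(years):
        comp = annual_composite(ts, int(y), target_doy_fraction)
        if comp is not None:
            out[i] = comp
    return out
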