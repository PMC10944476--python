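"""Shared domain types for the secondary-forest-age pipeline.

Every detector consumes a :class:`PixelTimeSeries` (dated six-band surface
reflectance for one pixel) and emits a :class:`DetectionResult` (the calendar
year in which a persistent forest state was first attained, or ``None`` when
no stand establishment is detected).  These two types are the currency of the
whole package, so they live here rather than in any one stage's module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed band order used in every multi-band array and raster this package
#: reads or writes.
BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")

BAND_INDEX = {name: i for i, name in enumerate(BANDS)}

#: QA flag values for observations.
QA_CLEAR = 0
QA_MASKED = 1

#: Analysis span (closed year interval) used by default throughout.
DEFAULT_SPAN = (1986, 2021)

#: Algorithms recognised in DetectionResult.algorithm.
ALGORITHMS = (
    "MACD",
    "LT",
    "VCT",
    "CCDC",
    "CCDC_RF_OLB",
    "CCDC_RF_ALB",
    "ensemble",
)


class SfamapError(Exception):
    """Base class for package errors."""


class CalibrationError(SfamapError):
    """Raised when forest reference statistics cannot be derived."""


@dataclass
class PixelTimeSeries:
    """Dated six-band reflectance observations with QA flags for one pixel.

    Parameters
    ----------
    times
        Fractional calendar years, strictly increasing.
    reflectance
        Array of shape ``(n_obs, 6)`` in band order :data:`BANDS`; values of
        clear observations lie in [0, 1].
    qa
        Per-observation flag, ``QA_CLEAR`` or ``QA_MASKED``.
    pixel_id
        Opaque identifier carried through to detection results.
    """

    times: np.ndarray
    reflectance: np.ndarray
    qa: np.ndarray
    pixel_id: str = "pixel"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.qa = np.asarray(self.qa, dtype=np.uint8)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.reflectance.shape != (self.times.size, len(BANDS)):
            raise ValueError(
                f"reflectance must have shape (n_obs, {len(BANDS)})"
            )
        if self.qa.shape != self.times.shape:
            raise ValueError("qa must match times in shape")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    @property
    def clear(self) -> np.ndarray:
        """Boolean mask of clear (usable) observations."""
        return self.qa == QA_CLEAR

    def clear_subset(self) -> "PixelTimeSeries":
        """Return a copy containing only the clear observations."""
        m = self.clear
        return PixelTimeSeries(
            self.times[m], self.reflectance[m], self.qa[m], self.pixel_id
        )


@dataclass
class DetectionResult:
    """Per-pixel establishment year (or absent) from one algorithm.

    ``establishment_year is None`` means "no stand establishment detected":
    the pixel is either stable forest over the whole span or never forest.
    """

    pixel_id: str
    algorithm: str
    establishment_year: int | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def detected(self) -> bool:
        return self.establishment_year is not None


@dataclass
class AnnualSeries:
    """One index value per consecutive calendar year (NaN = missing)."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape or self.years.ndim != 1:
            raise ValueError("years and values must be matching 1-D arrays")
        if self.years.size > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive and increasing")

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)
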