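"""Data-driven, spatially varying VCT calibration on a coarse grid.

Forest spectra differ across forest types and climate zones, so a single
national forest reference (band means and SDs) and a single IFZ threshold
are inaccurate at scale.  This module tiles the study extent with coarse
cells (3 degrees by default) and, per cell:

1. computes the forest reference statistics from stable-forest samples
   (pooled clear observations on the RED/SWIR1/SWIR2 bands), falling back
   to forest-map points when a cell has too few stable samples;
2. derives the cell's IFZ threshold from secondary-forest samples as a high
   percentile (default 95th) of their mature-phase IFZ — the IFZ attained in
   the final three observed years, when establishment is complete — so that
   ~95% of established secondary forest classifies as forest.

Thresholds are clamped to a configured minimum to avoid degenerate zeros.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra import DEFAULT_IFZ_BANDS, ForestReference, annual_composites, ifz
from .types import BAND_INDEX, CalibrationError, PixelTimeSeries

log = logging.getLogger(__name__)

DEFAULT_CELL_SIZE = 3.0
DEFAULT_MIN_SAMPLES = 100
DEFAULT_PERCENTILE = 0.95
DEFAULT_MIN_THRESHOLD = 0.5
MATURE_YEARS = 3

#: Minimum sample patch area (m^2) retained by the sample filter.
MIN_PATCH_AREA_M2 = 4500.0


@dataclass
class SampleSet:
    """Sample locations with labels and an area filter.

    ``samples`` is a list of dicts with keys ``lon``, ``lat``, ``label``
    (``stable_forest`` or ``secondary_forest``), optional ``patch_area_m2``
    and optional payload keys (e.g. ``series``).
    """

    samples: list = field(default_factory=list)
    min_patch_area_m2: float = MIN_PATCH_AREA_M2

    def filtered(self) -> list:
        return [
            s
            for s in self.samples
            if s.get("patch_area_m2", self.min_patch_area_m2)
            >= self.min_patch_area_m2
        ]

    def by_label(self, label: str) -> list:
        return [s for s in self.filtered() if s["label"] == label]


@dataclass
class GridCell:
    cell_id: str
    bounds: tuple  # (lon_min, lat_min, lon_max, lat_max); half-open upper edges
    reference: ForestReference | None = None
    ifz_threshold: float | None = None
    n_stable_samples: int = 0
    n_secondary_samples: int = 0
    fallback_used: bool = False

    @property
    def calibrated(self) -> bool:
        return self.reference is not None and self.ifz_threshold is not None

    def contains(self, lon: float, lat: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return x0 <= lon < x1 and y0 <= lat < y1


@dataclass
class CalibrationGrid:
    cell_size: float
    extent: tuple  # (lon_min, lat_min, lon_max, lat_max)
    cells: list = field(default_factory=list)

    def cell_for(self, lon: float, lat: float) -> GridCell | None:
        for cell in self.cells:
            if cell.contains(lon, lat):
                return cell
        return None

    def to_geojson(self) -> dict:
        feats = []
        for c in self.cells:
            x0, y0, x1, y1 = c.bounds
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                        ],
                    },
                    "properties": {
                        "cell_id": c.cell_id,
                        "ifz_threshold": c.ifz_threshold,
                        "n_stable_samples": c.n_stable_samples,
                        "n_secondary_samples": c.n_secondary_samples,
                        "fallback_used": c.fallback_used,
                        "ref_mean": None
                        if c.reference is None
                        else list(c.reference.mean),
                        "ref_sd": None
                        if c.reference is None
                        else list(c.reference.sd),
                    },
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def save_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)


def build_grid(
    extent: tuple, cell_size: float = DEFAULT_CELL_SIZE
) -> CalibrationGrid:
    """Tile ``extent`` with half-open cells [lon, lon+cs) x [lat, lat+cs).

    Partial cells at the upper edges are kept, so every point of the extent
    maps to exactly one cell; points on an interior edge belong to the cell
    whose lower bound they equal.
    """
    lon_min, lat_min, lon_max, lat_max = map(float, extent)
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("degenerate extent")
    n_lon = int(np.ceil((lon_max - lon_min) / cell_size))
    n_lat = int(np.ceil((lat_max - lat_min) / cell_size))
    cells = []
    for j in range(n_lat):
        for i in range(n_lon):
            x0 = lon_min + i * cell_size
            y0 = lat_min + j * cell_size
            cells.append(
                GridCell(
                    cell_id=f"cell_{i}_{j}",
                    bounds=(x0, y0, x0 + cell_size, y0 + cell_size),
                )
            )
    return CalibrationGrid(cell_size=cell_size, extent=tuple(extent), cells=cells)


def tail_years(ts: PixelTimeSeries, n_years: int = MATURE_YEARS) -> PixelTimeSeries:
    """Restrict a series to its final ``n_years`` observed calendar years.

    Forest-map fallback points are only known to be forest at the end of
    the record, so their earlier (possibly pre-establishment) observations
    must not enter the forest reference statistics.
    """
    if ts.n_obs == 0:
        return ts
    last_year = int(np.floor(ts.times[-1]))
    sel = ts.times >= last_year - n_years + 1
    return PixelTimeSeries(
        ts.times[sel], ts.reflectance[sel], ts.qa[sel], ts.pixel_id
    )


def _composite_stack(ts: PixelTimeSeries, last_n_years: int | None = None) -> np.ndarray:
    """Annual composites of a sample series (rows with a clear observation).

    The reference statistics and thresholds are computed on the same kind
    of observation the VCT detector consumes — the per-year composite — so
    that the composite's seasonal phase cancels instead of biasing every
    z-score.
    """
    if ts.n_obs == 0:
        return np.empty((0, ts.reflectance.shape[-1]))
    y0 = int(np.floor(ts.times[0]))
    y1 = int(np.floor(ts.times[-1]))
    if last_n_years is not None:
        y0 = max(y0, y1 - last_n_years + 1)
    comps = annual_composites(ts, np.arange(y0, y1 + 1))
    return comps[~np.isnan(comps).any(axis=1)]


def _pooled_composites(series_list: list) -> np.ndarray:
    chunks = [_composite_stack(ts) for ts in series_list]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        raise CalibrationError("no clear observations in any sample")
    return np.vstack(chunks)


def calibrate_reference(
    stable_series: list,
    bands_used: tuple = DEFAULT_IFZ_BANDS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    fallback_series: list | None = None,
) -> tuple[ForestReference, bool]:
    """Forest reference (per-band mean, SD) from stable-forest sample series.

    The statistics pool every sample's annual composites on
    ``bands_used`` (the observation type the detector consumes).  When fewer than ``min_samples`` stable samples are
    available and ``fallback_series`` (forest-map points) is provided, the
    fallback is used instead and flagged.  Returns ``(reference,
    fallback_used)``; raises :class:`CalibrationError` when neither source
    yields usable statistics (detection in such a cell refuses to run).
    """
    fallback_used = False
    series = list(stable_series)
    if len(series) < min_samples:
        if fallback_series:
            series = [tail_years(ts) for ts in fallback_series]
            fallback_used = True
            log.info(
                "calibration fallback: %d stable samples < %d, using %d "
                "forest-map points",
                len(stable_series), min_samples, len(series),
            )
        elif not series:
            raise CalibrationError("no stable samples and no fallback available")
    pooled = _pooled_composites(series)
    idx = [BAND_INDEX[b] for b in bands_used]
    mean = pooled[:, idx].mean(axis=0)
    sd = pooled[:, idx].std(axis=0, ddof=1) if pooled.shape[0] > 1 else np.zeros(len(idx))
    if np.any(sd <= 1e-9):  # identical spectra up to rounding
        raise CalibrationError(
            "degenerate forest reference: zero spectral variance in a band"
        )
    return ForestReference(mean, sd, n_samples=len(series), bands_used=tuple(bands_used)), fallback_used


def mature_phase_ifz(
    ts: PixelTimeSeries, ref: ForestReference, n_years: int = MATURE_YEARS
) -> np.ndarray:
    """IFZ of a sample's annual composites in its final ``n_years`` observed
    years — the attained forest state once establishment is complete."""
    comps = _composite_stack(ts, last_n_years=n_years)
    if comps.size == 0:
        return np.empty(0)
    return ifz(comps, ref)


def derive_threshold(
    secondary_series: list,
    ref: ForestReference,
    percentile: float = DEFAULT_PERCENTILE,
    min_threshold: float = DEFAULT_MIN_THRESHOLD,
    default_threshold: float | None = None,
) -> float:
    """IFZ threshold = ``percentile`` of the pooled mature-phase IFZ of
    secondary samples (linear-interpolation quantile).

    With an empty pool the global ``default_threshold`` is inherited (with
    a warning); degenerate near-zero thresholds are clamped to
    ``min_threshold``.  Monotone non-decreasing in ``percentile``.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    pool = [mature_phase_ifz(ts, ref) for ts in secondary_series]
    pool = [p for p in pool if p.size]
    if not pool:
        if default_threshold is None:
            raise CalibrationError(
                "no secondary samples and no default threshold configured"
            )
        log.warning("empty secondary-sample pool; inheriting global default")
        return float(default_threshold)
    values = np.concatenate(pool)
    thr = float(np.quantile(values, percentile))
    if thr < min_threshold:
        log.warning(
            "derived IFZ threshold %.3f below minimum; clamped to %.2f",
            thr, min_threshold,
        )
        thr = min_threshold
    return thr


def calibrate_grid(
    grid: CalibrationGrid,
    stable_samples: list,
    secondary_samples: list,
    fallback_samples: list | None = None,
    bands_used: tuple = DEFAULT_IFZ_BANDS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    percentile: float = DEFAULT_PERCENTILE,
    min_threshold: float = DEFAULT_MIN_THRESHOLD,
    default_threshold: float | None = None,
) -> CalibrationGrid:
    """Calibrate every grid cell from located sample series.

    Each sample is a dict with ``lon``, ``lat`` and ``series`` (a
    :class:`PixelTimeSeries`).  Cells that cannot be calibrated are left
    uncalibrated (``cell.calibrated`` False) and detection there refuses to
    run.
    """

    def in_cell(cell, samples):
        return [s["series"] for s in samples if cell.contains(s["lon"], s["lat"])]

    for cell in grid.cells:
        stable = in_cell(cell, stable_samples)
        secondary = in_cell(cell, secondary_samples)
        fallback = in_cell(cell, fallback_samples) if fallback_samples else None
        cell.n_stable_samples = len(stable)
        cell.n_secondary_samples = len(secondary)
        try:
            ref, used = calibrate_reference(
                stable, bands_used, min_samples, fallback
            )
            cell.reference = ref
            cell.fallback_used = used
            cell.ifz_threshold = derive_threshold(
                secondary, ref, percentile, min_threshold, default_threshold
            )
        except CalibrationError as exc:
            log.warning("cell %s left uncalibrated: %s", cell.cell_id, exc)
            cell.reference = None
            cell.ifz_threshold = None
    return grid
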