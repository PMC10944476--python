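"""Per-pixel establishment-year detection: MACD, LandTrendr-style, VCT.

All three detectors share one convention: the establishment year is the
first calendar year in which the pixel exhibits a persistent forest spectral
state (not the last non-forest year).  A return of ``None`` means no stand
establishment was detected — the pixel is either forest throughout the span
or never reaches a forest state.
"""

from __future__ import annotations

import logging

import numpy as np

from .spectra import bsi
from .types import AnnualSeries, DetectionResult, PixelTimeSeries

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MACD — moving-average change detection on the BSI 0-crossing
# ---------------------------------------------------------------------------

def detect_macd(
    ts: PixelTimeSeries, window: int = 3, persistence: float = 2.0
) -> DetectionResult:
    """Establishment at the first persistent 0-crossing of the BSI moving
    average.

    The BSI of the clear observations is smoothed with a trailing moving
    average over ``window`` observations.  Establishment is the year of the
    first observation where the average crosses from >= 0 to < 0 and every
    subsequent observation within ``persistence`` years stays below 0 (the
    record must extend at least ``persistence`` years past the crossing).
    """
    if window < 1 or persistence < 1:
        raise ValueError("window and persistence must be >= 1")
    clear = ts.clear_subset()
    vals = bsi(clear.reflectance)
    ok = np.isfinite(vals)
    times, vals = clear.times[ok], vals[ok]
    result = DetectionResult(ts.pixel_id, "MACD")
    if times.size < window:
        log.warning(
            "MACD: pixel %s has %d clear observations (< window %d)",
            ts.pixel_id, times.size, window,
        )
        return result
    kernel = np.ones(window) / window
    ma = np.convolve(vals, kernel, mode="valid")  # ma[j] over obs j..j+window-1
    ma_times = times[window - 1:]
    n = ma.size
    for i in range(1, n):
        if not (ma[i] < 0 <= ma[i - 1]):
            continue
        t0 = ma_times[i]
        if ma_times[-1] < t0 + persistence:
            continue  # record too short to confirm persistence
        after = (ma_times > t0) & (ma_times <= t0 + persistence)
        if np.all(ma[after] < 0):
            result.establishment_year = int(np.floor(t0))
            return result
    return result


# ---------------------------------------------------------------------------
# LT — temporal segmentation of the annual NBR series
# ---------------------------------------------------------------------------

def despike(values: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Damp single-year spikes that are more than ``threshold`` recovered.

    An interior point is a spike when the net change across it is less than
    ``(1 - threshold)`` of the larger one-year departure on either side; the
    spike is replaced by the mean of its neighbours.  All spikes are judged
    against the original series (one parallel pass, not sequential).
    """
    src = np.asarray(values, dtype=float)
    v = src.copy()
    for i in range(1, src.size - 1):
        left, right = src[i] - src[i - 1], src[i + 1] - src[i]
        peak = max(abs(left), abs(right))
        if peak == 0:
            continue
        if abs(src[i + 1] - src[i - 1]) < (1.0 - threshold) * peak:
            v[i] = 0.5 * (src[i - 1] + src[i + 1])
    return v


def _segment_sse(years: np.ndarray, values: np.ndarray, vertices: list[int]) -> float:
    """SSE of linear interpolation through the vertex points."""
    interp = np.interp(years, years[vertices], values[vertices])
    resid = values - interp
    return float(resid @ resid)


def segment_series(
    years: np.ndarray, values: np.ndarray, max_segments: int
) -> list[int]:
    """Bottom-up vertex selection for piecewise-linear segmentation.

    Starts from vertices at every point and greedily removes the interior
    vertex whose removal increases the interpolation SSE the least (ties
    broken toward the earliest vertex) until at most ``max_segments``
    segments remain.  Returns the retained vertex indices.
    """
    n = years.size
    vertices = list(range(n))
    while len(vertices) - 1 > max_segments and len(vertices) > 2:
        best_cost, best_k = None, None
        base = _segment_sse(years, values, vertices)
        for k in range(1, len(vertices) - 1):
            trial = vertices[:k] + vertices[k + 1:]
            cost = _segment_sse(years, values, trial) - base
            if best_cost is None or cost < best_cost - 1e-12:
                best_cost, best_k = cost, k
        vertices.pop(best_k)
    return vertices


def detect_lt(
    series: AnnualSeries,
    max_segments: int = 6,
    recovery_threshold: float = 0.4,
    despike_threshold: float = 0.9,
) -> DetectionResult:
    """Establishment from the longest qualifying recovery segment of an
    annual NBR series.

    After spike damping and piecewise-linear segmentation (bottom-up vertex
    selection, at most ``max_segments`` segments), the qualifying segment is
    the longest positive-slope segment whose total NBR gain exceeds
    ``recovery_threshold``; absent when no segment qualifies.  The
    establishment year is the first year after the segment's base vertex —
    the base vertex is the last pre-recovery year, so recovery (and the
    forest state) begins the following year.  The default minimum gain is
    half the full bare-to-forest NBR contrast (~0.8), which keeps slow
    multi-year index drift in mature stands from qualifying as regrowth.
    """
    result = DetectionResult("pixel", "LT")
    obs = series.observed
    years = series.years[obs]
    values = series.values[obs]
    if years.size < 6:
        log.warning("LT: fewer than 6 observed years; no detection")
        return result
    values = despike(values, despike_threshold)
    vertices = segment_series(years, values, max_segments)
    best_len, best_year = 0, None
    for a, b in zip(vertices[:-1], vertices[1:]):
        gain = values[b] - values[a]
        length = years[b] - years[a]
        if gain > recovery_threshold and gain / length > 0:
            if length > best_len:
                best_len, best_year = length, int(years[a]) + 1
    result.establishment_year = best_year
    return result


# ---------------------------------------------------------------------------
# VCT — IFZ thresholding with a two-consecutive-year forest rule
# ---------------------------------------------------------------------------

def detect_vct(
    series: AnnualSeries,
    threshold: float,
    consecutive: int = 2,
    prior_nonforest_consecutive: int = 3,
) -> DetectionResult:
    """Establishment at the first run of ``consecutive`` observed years with
    IFZ below ``threshold`` that follows a persistent non-forest state.

    State semantics: a run of ``prior_nonforest_consecutive`` observed
    years at or above the threshold confirms the non-forest state, and a
    run of ``consecutive`` observed years below it confirms the forest
    state; shorter excursions in either direction are treated as noise or
    transient canopy disturbance and confirm nothing.  The non-forest
    confirmation is one year longer than the forest confirmation so that
    short-lived canopy damage (one or two low-canopy years) in standing
    forest does not register as a clearing.  The newest establishment is dated at the onset of
    the final forest state: the first below-threshold observed year after
    the last confirmed non-forest run, provided the forest state is
    eventually confirmed.  Missing years are skipped: runs are over
    observed years.  Returns absent for series that never transition
    (never a confirmed non-forest run = stable forest; never a confirmed
    forest run after one = never regrown).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if consecutive < 1 or prior_nonforest_consecutive < 1:
        raise ValueError("consecutive run lengths must be >= 1")
    result = DetectionResult("pixel", "VCT")
    obs = series.observed
    years = series.years[obs]
    values = series.values[obs]
    below = values < threshold

    def last_run_end(mask: np.ndarray, length: int) -> int:
        """Index of the final element of the last run of ``length`` Trues
        in ``mask``; -1 if no such run."""
        run, end = 0, -1
        for i, flag in enumerate(mask):
            run = run + 1 if flag else 0
            if run >= length:
                end = i
        return end

    nonforest_end = last_run_end(~below, prior_nonforest_consecutive)
    if nonforest_end < 0:
        return result
    # forest must be (re)confirmed after the last non-forest period
    run = 0
    confirmed = False
    for i in range(nonforest_end + 1, years.size):
        run = run + 1 if below[i] else 0
        if run >= consecutive:
            confirmed = True
            break
    if not confirmed:
        return result
    onset = nonforest_end + 1 + int(np.argmax(below[nonforest_end + 1 :]))
    result.establishment_year = int(years[onset])
    return result
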