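"""Continuous harmonic-model fitting and break detection on dense series.

Each temporal segment of a pixel's NBR series is modelled as

    y(t) = c0 + c1*(t - t0) + sum_{k=1..3} [a_k cos(2*pi*k*t) + b_k sin(2*pi*k*t)]

with a one-year base period and ``t0`` the segment's first observation time,
so the intercept is the modelled index value at the segment start.  A
breakpoint is declared when ``run_length`` consecutive clear observations
deviate from the model prediction by more than ``k_sigma`` times the segment
RMSE with a consistent sign; the break time is the first observation of the
triggering run and its magnitude (MAG) the mean signed deviation over the
run.  The series is segmented into at most ``max_segments`` segments.

On NBR, a positive MAG (index rises) marks a transition toward forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import DetectionResult

N_HARMONICS = 3
N_COEF = 2 + 2 * N_HARMONICS  # intercept, slope, 3x(cos, sin)

DIRECTION_TO_FOREST = "to_forest"
DIRECTION_TO_NONFOREST = "to_nonforest"


@dataclass
class CcdcModel:
    """One harmonic segment: coefficients, RMSE and fit window."""

    intercept: float
    slope: float
    cos_coef: np.ndarray  # harmonics k = 1..3
    sin_coef: np.ndarray
    rmse: float
    t_start: float
    t_end: float
    n_obs: int

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        y = self.intercept + self.slope * (t - self.t_start)
        for k in range(N_HARMONICS):
            w = 2 * np.pi * (k + 1)
            y = y + self.cos_coef[k] * np.cos(w * t) + self.sin_coef[k] * np.sin(w * t)
        return y

    @property
    def amplitude(self) -> float:
        """Overall seasonal amplitude derived from the three harmonics."""
        return float(np.sqrt(np.sum(self.cos_coef**2 + self.sin_coef**2)))


@dataclass
class Breakpoint:
    """A model break: time, signed magnitude and adjacent segment indices.

    ``post_model`` is a harmonic fit over a fixed-length window immediately
    after the break.  It characterises the immediate post-break trajectory
    and — unlike the full following segment, whose extent depends on where
    the *next* break falls — is comparable across breaks, which matters
    when break features feed a classifier.
    """

    time: float
    mag: float
    pre_segment: int
    post_segment: int
    post_model: "CcdcModel | None" = None

    @property
    def direction(self) -> str:
        return DIRECTION_TO_FOREST if self.mag > 0 else DIRECTION_TO_NONFOREST

    @property
    def year(self) -> int:
        return int(np.floor(self.time))


@dataclass
class CcdcResult:
    """Ordered segments (<= max_segments) and the breaks between them."""

    segments: list = field(default_factory=list)
    breakpoints: list = field(default_factory=list)
    pixel_id: str = "pixel"

    @property
    def latest_break(self) -> Breakpoint | None:
        return self.breakpoints[-1] if self.breakpoints else None


def design_matrix(times: np.ndarray, t0: float) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    cols = [np.ones_like(t), t - t0]
    for k in range(1, N_HARMONICS + 1):
        w = 2 * np.pi * k
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.column_stack(cols)


def fit_harmonic(
    times: np.ndarray, values: np.ndarray, n_init: int = 12
) -> CcdcModel:
    """Least-squares harmonic fit over a window of dated index values.

    Refuses to fit with fewer than ``n_init`` observations (callers relax
    this only for a trailing partial segment).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < n_init:
        raise ValueError(
            f"harmonic fit needs >= {n_init} observations, got {times.size}"
        )
    return _fit(times, values)


def _fit(times: np.ndarray, values: np.ndarray) -> CcdcModel:
    t0 = float(times[0])
    X = design_matrix(times, t0)
    if times.size >= N_COEF:
        # truncate near-zero singular values: short cloudy windows can be
        # numerically rank-deficient, and an untruncated solve explodes the
        # coefficients (and every feature derived from them)
        coef, *_ = np.linalg.lstsq(X, values, rcond=1e-6)
    else:  # degenerate tail: ridge-regularised solve
        XtX = X.T @ X + 1e-6 * np.eye(N_COEF)
        coef = np.linalg.solve(XtX, X.T @ values)
    resid = values - X @ coef
    # dof-corrected residual scale: the initial window barely exceeds the
    # coefficient count, and the population RMSE there is badly biased low,
    # which would inflate the change test's false-alarm rate
    dof = times.size - N_COEF
    ss = float(resid @ resid)
    rmse = float(np.sqrt(ss / dof)) if dof > 0 else float(np.sqrt(ss / times.size))
    return CcdcModel(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        cos_coef=coef[2::2].copy(),
        sin_coef=coef[3::2].copy(),
        rmse=rmse,
        t_start=t0,
        t_end=float(times[-1]),
        n_obs=int(times.size),
    )


def detect_breaks(
    times: np.ndarray,
    values: np.ndarray,
    k_sigma: float = 3.0,
    run_length: int = 6,
    max_segments: int = 6,
    n_init: int = 12,
    refit_stride: int = 4,
    rmse_floor: float = 1e-4,
    pixel_id: str = "pixel",
) -> CcdcResult:
    """Sequential break detection over a dense (clear-observation) series.

    The current segment's model is refitted as observations accrue (every
    ``refit_stride`` new points).  ``rmse_floor`` guards the change test
    against degenerate zero-RMSE fits on noiseless input.  An unbreakable
    series yields one segment and no breakpoints; segmentation stops at
    ``max_segments``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    times, values = times[ok], values[ok]
    result = CcdcResult(pixel_id=pixel_id)
    n = times.size
    if n < n_init:
        if n >= 2:
            result.segments.append(_fit(times, values))
        return result

    seg_start = 0
    while True:
        remaining = n - seg_start
        at_cap = len(result.segments) == max_segments - 1
        if remaining < n_init or at_cap:
            # trailing segment: absorb everything left, no further breaks
            result.segments.append(_fit(times[seg_start:], values[seg_start:]))
            break
        fit_end = seg_start + n_init  # exclusive
        model = _fit(times[seg_start:fit_end], values[seg_start:fit_end])
        resid_all = values - model.predict(times)  # refreshed on each refit
        since_refit = 0
        run: list[int] = []
        run_sign = 0
        broke = False
        i = fit_end
        while i < n:
            sigma = max(model.rmse, rmse_floor)
            r = resid_all[i]
            if abs(r) > k_sigma * sigma:
                sign = 1 if r > 0 else -1
                if run and sign != run_sign:
                    run = []
                run.append(i)
                run_sign = sign
                if len(run) >= run_length:
                    first = run[0]
                    mag = float(np.mean(resid_all[run]))
                    model.t_end = float(times[first - 1])
                    model.n_obs = first - seg_start
                    result.segments.append(model)
                    result.breakpoints.append(
                        Breakpoint(
                            time=float(times[first]),
                            mag=mag,
                            pre_segment=len(result.segments) - 1,
                            post_segment=len(result.segments),
                        )
                    )
                    seg_start = first
                    broke = True
                    break
            else:
                run = []
                since_refit += 1
                fit_end = i + 1
                # while the window is still small the model is poorly
                # determined, so refit on every clear observation; afterwards
                # refitting every few observations is enough
                stride = 1 if fit_end - seg_start < 2 * n_init else refit_stride
                if since_refit >= stride:
                    model = _fit(times[seg_start:fit_end], values[seg_start:fit_end])
                    resid_all = values - model.predict(times)
                    since_refit = 0
            i += 1
        if broke:
            continue
        # reached the end without a break: close the final segment
        model = _fit(times[seg_start:], values[seg_start:])
        result.segments.append(model)
        break
    # canonical post-break models over a fixed window of n_init obs
    for bp in result.breakpoints:
        start = int(np.searchsorted(times, bp.time))
        stop = min(start + n_init, n)
        if stop - start >= 2:
            bp.post_model = _fit(times[start:stop], values[start:stop])
    return result


def establishment_from_breaks(result: CcdcResult) -> DetectionResult:
    """Raw-CCDC establishment: year of the latest to-forest breakpoint.

    This is the unfiltered baseline; the random-forest secondary
    classification refines it in :mod:`sfamap.ccdc_rf`.
    """
    det = DetectionResult(result.pixel_id, "CCDC")
    for bp in reversed(result.breakpoints):
        if bp.direction == DIRECTION_TO_FOREST:
            det.establishment_year = bp.year
            break
    return det
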