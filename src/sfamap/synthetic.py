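"""Synthetic Landsat-like pixel histories and scenes with known truth.

The generator emulates what a dense surface-reflectance stack over a
regrowing forest landscape looks like: per-band archetype spectra for forest
and bare ground, a single annual cosine of seasonality, i.i.d. Gaussian
reflectance noise, i.i.d. Bernoulli cloud gaps flagged in QA, and a logistic
bare-to-forest transition centred on the establishment year.  Each simulated
pixel carries its scenario's ground truth, so every downstream stage of the
pipeline is testable without any satellite download.

Truth encoding for scenes: 0 = never forest, 9999 = stable forest over the
whole span, otherwise the establishment calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import archetypes as arch
from .types import BANDS, DEFAULT_SPAN, QA_CLEAR, QA_MASKED, PixelTimeSeries

TRUTH_NON_FOREST = 0
TRUTH_STABLE_FOREST = 9999

SCENARIO_KINDS = (
    "stable_forest",
    "secondary_forest",
    "non_forest",
    "disturbed_then_recovered",
)


@dataclass
class PixelScenario:
    """Ground-truth description of one simulated pixel.

    ``establishment_year`` is required for ``secondary_forest`` and
    ``disturbed_then_recovered`` pixels and must be absent otherwise;
    ``disturbance_year`` (< establishment_year) is required only for
    ``disturbed_then_recovered``.
    """

    kind: str
    establishment_year: int | None = None
    disturbance_year: int | None = None
    regrowth_rate: float = arch.DEFAULT_REGROWTH_RATE
    noise_sd: float = arch.DEFAULT_NOISE_SD
    cloud_fraction: float = 0.0
    #: Asymptotic forest fraction attained by regrown stands.  Secondary
    #: forest stays spectrally distinguishable from old growth (brighter
    #: SWIR) for decades, so it converges to slightly less than the full
    #: forest archetype; this margin is what the data-driven IFZ threshold
    #: calibration measures.
    mature_weight: float = 0.9
    #: Optional transient canopy disturbance (thinning, insect damage,
    #: drought browning) that does not change land cover: the forest
    #: fraction drops by ``transient_depth`` for ``transient_duration``
    #: years starting at ``transient_year`` and then recovers.  Such events
    #: are what make dense-series break detection over-sensitive: the
    #: recovery registers as a spurious to-forest break.
    transient_year: float | None = None
    transient_depth: float = 0.4
    transient_duration: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        needs_year = self.kind in ("secondary_forest", "disturbed_then_recovered")
        if needs_year and self.establishment_year is None:
            raise ValueError(f"{self.kind} requires establishment_year")
        if not needs_year and self.establishment_year is not None:
            raise ValueError(f"{self.kind} must not set establishment_year")
        if self.kind == "disturbed_then_recovered":
            if self.disturbance_year is None:
                raise ValueError("disturbed_then_recovered requires disturbance_year")
            if self.disturbance_year >= self.establishment_year:
                raise ValueError("disturbance_year must precede establishment_year")
        if not 0.0 <= self.cloud_fraction < 1.0:
            raise ValueError("cloud_fraction must lie in [0, 1)")
        if not 0.0 < self.mature_weight <= 1.0:
            raise ValueError("mature_weight must lie in (0, 1]")
        if self.transient_year is not None:
            if self.kind == "non_forest":
                raise ValueError("non_forest pixels cannot carry a transient")
            if not 0.0 < self.transient_depth < 1.0:
                raise ValueError("transient_depth must lie in (0, 1)")
            if self.transient_duration <= 0:
                raise ValueError("transient_duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.regrowth_rate <= 0:
            raise ValueError("regrowth_rate must be positive")

    @property
    def truth(self) -> int:
        if self.kind == "non_forest":
            return TRUTH_NON_FOREST
        if self.kind == "stable_forest":
            return TRUTH_STABLE_FOREST
        return int(self.establishment_year)


def observation_times(span: tuple[int, int], obs_per_year: int) -> np.ndarray:
    """Regular acquisition grid: ``obs_per_year`` dates per calendar year."""
    y0, y1 = int(span[0]), int(span[1])
    frac = (np.arange(obs_per_year) + 0.5) / obs_per_year
    return (np.arange(y0, y1 + 1)[:, None] + frac[None, :]).ravel()


def forest_weight(scenario: PixelScenario, times: np.ndarray) -> np.ndarray:
    """Fraction of the forest archetype in the spectral mixture at ``times``.

    The logistic transition is centred on the start of the establishment
    year, so the establishment year is the first calendar year the pixel
    spends mostly in the forest spectral state — consistent with the
    "first year of forest state" convention used by every detector.
    """
    t = np.asarray(times, dtype=float)
    if scenario.kind == "non_forest":
        return np.zeros_like(t)
    if scenario.kind == "stable_forest":
        w = np.ones_like(t)
    else:
        mid = float(scenario.establishment_year)
        w = scenario.mature_weight / (
            1.0 + np.exp(-scenario.regrowth_rate * (t - mid))
        )
        if scenario.kind == "disturbed_then_recovered":
            w = np.where(t < scenario.disturbance_year, 1.0, w)
    if scenario.transient_year is not None:
        ty = float(scenario.transient_year)
        dip = (t >= ty) & (t < ty + scenario.transient_duration)
        w = np.where(dip, np.maximum(w - scenario.transient_depth, 0.0), w)
    return w


def noiseless_reflectance(
    scenario: PixelScenario, times: np.ndarray
) -> np.ndarray:
    """Closed-form band trajectories (no noise, no clouds); shape (n, 6)."""
    t = np.asarray(times, dtype=float)
    w = forest_weight(scenario, t)[:, None]
    mean = w * arch.FOREST_MEAN + (1 - w) * arch.BARE_MEAN
    amp = w * arch.FOREST_SEASONAL_AMP + (1 - w) * arch.BARE_SEASONAL_AMP
    season = np.cos(2 * np.pi * (t[:, None] - arch.SEASONAL_PEAK))
    return np.clip(mean + amp * season, 0.0, 1.0)


def simulate_pixel(
    scenario: PixelScenario,
    span: tuple[int, int] = DEFAULT_SPAN,
    obs_per_year: int = 8,
    seed: int | np.random.SeedSequence = 0,
    pixel_id: str = "pixel",
) -> PixelTimeSeries:
    """Simulate one pixel's dated six-band series under ``scenario``.

    Identical ``(scenario, span, obs_per_year, seed)`` reproduce identical
    output.  Masked (cloudy) observations carry cloud-like reflectance and
    ``qa=QA_MASKED``.
    """
    y0, y1 = int(span[0]), int(span[1])
    if y1 - y0 + 1 < 5:
        raise ValueError("span must cover at least 5 years")
    if obs_per_year < 1:
        raise ValueError("obs_per_year must be >= 1")
    if scenario.establishment_year is not None and not (
        y0 <= scenario.establishment_year <= y1
    ):
        raise ValueError(
            f"establishment_year {scenario.establishment_year} outside "
            f"simulated span [{y0}, {y1}]"
        )
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    times = observation_times((y0, y1), obs_per_year)
    refl = noiseless_reflectance(scenario, times)
    if scenario.noise_sd > 0:
        refl = refl + rng.normal(0.0, scenario.noise_sd, size=refl.shape)
    qa = np.full(times.size, QA_CLEAR, dtype=np.uint8)
    if scenario.cloud_fraction > 0:
        cloudy = rng.random(times.size) < scenario.cloud_fraction
        qa[cloudy] = QA_MASKED
        cloud = np.broadcast_to(arch.CLOUD_MEAN, refl.shape).copy()
        if scenario.noise_sd > 0:
            cloud = cloud + rng.normal(0.0, scenario.noise_sd, size=cloud.shape)
        refl[cloudy] = cloud[cloudy]
    return PixelTimeSeries(times, np.clip(refl, 0.0, 1.0), qa, pixel_id)


def pixel_seed(seed: int, row: int, col: int) -> np.random.SeedSequence:
    """Stable per-pixel sub-seed so scenes are reproducible under tiling."""
    return np.random.SeedSequence([int(seed), int(row), int(col)])


@dataclass
class Scene:
    """A simulated raster stack plus its ground truth.

    ``reflectance`` has shape (rows, cols, n_obs, 6) and ``qa``
    (rows, cols, n_obs); all pixels share one acquisition calendar.
    ``transform`` maps array indices to geographic coordinates:
    lon = lon0 + (col + 0.5) * dx, lat = lat0 - (row + 0.5) * dy
    (north-up, pixel centres, WGS84 degrees).
    """

    times: np.ndarray
    reflectance: np.ndarray
    qa: np.ndarray
    truth: np.ndarray
    scenarios: list
    transform: dict = field(
        default_factory=lambda: {"lon0": 0.0, "lat0": 0.0, "dx": 0.01, "dy": 0.01}
    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape

    def pixel(self, row: int, col: int) -> PixelTimeSeries:
        return PixelTimeSeries(
            self.times,
            self.reflectance[row, col],
            self.qa[row, col],
            pixel_id=f"r{row}c{col}",
        )

    def lonlat(self, row: int, col: int) -> tuple[float, float]:
        t = self.transform
        return (
            t["lon0"] + (col + 0.5) * t["dx"],
            t["lat0"] - (row + 0.5) * t["dy"],
        )


def simulate_scene(
    n_rows: int,
    n_cols: int,
    scenario_map,
    span: tuple[int, int] = DEFAULT_SPAN,
    obs_per_year: int = 8,
    seed: int = 0,
    transform: dict | None = None,
) -> Scene:
    """Simulate an ``n_rows x n_cols`` scene from a per-pixel scenario map.

    ``scenario_map`` is indexable as ``scenario_map[row][col]`` and must
    match the stated dimensions.  Each pixel's series is identical to
    ``simulate_pixel`` run with the pixel-derived sub-seed
    :func:`pixel_seed`.
    """
    if len(scenario_map) != n_rows or any(
        len(r) != n_cols for r in scenario_map
    ):
        raise ValueError("scenario_map dimensions do not match (n_rows, n_cols)")
    times = observation_times(span, obs_per_year)
    refl = np.empty((n_rows, n_cols, times.size, len(BANDS)), dtype=np.float32)
    qa = np.empty((n_rows, n_cols, times.size), dtype=np.uint8)
    truth = np.empty((n_rows, n_cols), dtype=np.uint16)
    for r in range(n_rows):
        for c in range(n_cols):
            sc = scenario_map[r][c]
            ts = simulate_pixel(
                sc, span, obs_per_year, pixel_seed(seed, r, c), f"r{r}c{c}"
            )
            refl[r, c] = ts.reflectance
            qa[r, c] = ts.qa
            truth[r, c] = sc.truth
    if transform is None:
        transform = {"lon0": 100.0, "lat0": 30.0, "dx": 0.01, "dy": 0.01}
    return Scene(times, refl, qa, truth, list(scenario_map), transform)


def random_scenario_map(
    n_rows: int,
    n_cols: int,
    seed: int,
    fractions: dict | None = None,
    establishment_range: tuple[int, int] = (1990, 2018),
    noise_sd: float = arch.DEFAULT_NOISE_SD,
    cloud_fraction: float = 0.3,
    regrowth_rate: float = arch.DEFAULT_REGROWTH_RATE,
    span: tuple[int, int] = DEFAULT_SPAN,
    transient_prob_stable: float = 0.05,
    transient_prob_secondary: float = 0.25,
) -> list:
    """Random landscape mix with establishment years uniform in a range.

    Default composition reflects a regrowing landscape: half secondary
    forest, a quarter stable forest, and the remainder split between
    persistent non-forest and disturbed-then-recovered stands.  A fraction
    of forest pixels additionally experience a transient canopy disturbance
    (depth 0.30-0.45, duration 1.5-2.5 years) — young stands more often
    than old growth — which exercises the false-break sensitivity that the
    breakpoint classifier exists to filter.
    """
    if fractions is None:
        fractions = {
            "secondary_forest": 0.50,
            "stable_forest": 0.25,
            "non_forest": 0.125,
            "disturbed_then_recovered": 0.125,
        }
    kinds = list(fractions)
    probs = np.array([fractions[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 917]))
    lo, hi = establishment_range
    grid = []
    for r in range(n_rows):
        row = []
        for c in range(n_cols):
            kind = kinds[rng.choice(len(kinds), p=probs)]
            est = dist = None
            if kind in ("secondary_forest", "disturbed_then_recovered"):
                est = int(rng.integers(lo, hi + 1))
                if kind == "disturbed_then_recovered":
                    dist = int(rng.integers(span[0] + 1, max(span[0] + 2, est - 2)))
                    if dist >= est:
                        dist = est - 1
            ty = None
            depth = 0.4
            duration = 2.0
            p_tr = (
                transient_prob_stable
                if kind == "stable_forest"
                else transient_prob_secondary
                if kind == "secondary_forest"
                else 0.0
            )
            if p_tr > 0 and rng.random() < p_tr:
                # the dip must sit on mature canopy and end before the span
                # does, so the recovery is observable
                first = span[0] + 2 if est is None else est + 3
                last = span[1] - 3
                if first < last:
                    ty = float(rng.uniform(first, last))
                    depth = float(rng.uniform(0.30, 0.45))
                    duration = float(rng.uniform(1.5, 2.5))
            row.append(
                PixelScenario(
                    kind,
                    establishment_year=est,
                    disturbance_year=dist,
                    regrowth_rate=regrowth_rate,
                    noise_sd=noise_sd,
                    cloud_fraction=cloud_fraction,
                    transient_year=ty,
                    transient_depth=depth,
                    transient_duration=duration,
                )
            )
        grid.append(row)
    return grid
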