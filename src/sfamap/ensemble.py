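"""Stacked-generalization / voting combination of detector maps, and the
final age-map encoding.

Detection maps are 2-D ``uint16`` arrays of establishment years with 0
meaning "no detection".  Two combination rules are provided:

* **stack(overlay, baseline)** — the baseline's detections take priority;
  the overlay only fills pixels where the baseline detected nothing.  In
  scheme names "A + B", B is the baseline (so "VCT + MACD" keeps MACD's
  years and fills its gaps with VCT's).
* **vote(maps, m)** — an m-of-n vote: a pixel is detected when the largest
  subset of per-algorithm years that are mutually within a +/-1 year
  tolerance of the subset median has at least m members; the assigned year
  is that median, rounded toward the earlier year on .5 ties (conservative:
  the older stand).

The final product encodes stand age in 2020 as ``uint8``: 0 = non-forest,
1..34 = age (year 2020 -> 1, 1987 -> 34), 36 = forest older than the mapped
span; 35 is never used.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NO_DETECTION = 0
AGE_NON_FOREST = 0
AGE_OLD_FOREST = 36
AGE_NODATA = 255

DEFAULT_REFERENCE_YEAR = 2020
DEFAULT_MIN_YEAR = 1987

#: Named ensemble schemes: either a single algorithm map, a vote rule, or a
#: left-to-right layer list whose right-most member is the baseline.
SCHEMES = {
    "macd": ["MACD"],
    "lt": ["LT"],
    "vct": ["VCT"],
    "ccdc": ["CCDC"],
    "ccdc_rf_olb": ["CCDC_RF_OLB"],
    "ccdc_rf_alb": ["CCDC_RF_ALB"],
    "vct+macd": ["VCT", "MACD"],
    "ccdc_rf_alb+vct": ["CCDC_RF_ALB", "VCT"],
    "vct+ccdc_rf_olb": ["VCT", "CCDC_RF_OLB"],
    "vct+ccdc_rf_alb": ["VCT", "CCDC_RF_ALB"],
    "3_of_4": ["3_of_4"],
    "2_of_4": ["2_of_4"],
    "vcr2": ["VCT", "CCDC_RF_ALB", "2_of_4"],
}

BASIC_MEMBERS = ("MACD", "LT", "VCT", "CCDC")


def _check_registered(maps: dict) -> None:
    shapes = {m.shape for m in maps.values()}
    if len(shapes) > 1:
        raise ValueError(f"detection maps are not co-registered: {shapes}")


def stack(overlay: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Baseline-priority combination: overlay fills the baseline's gaps."""
    overlay = np.asarray(overlay)
    baseline = np.asarray(baseline)
    if overlay.shape != baseline.shape:
        raise ValueError("grid mismatch between overlay and baseline")
    return np.where(baseline != NO_DETECTION, baseline, overlay)


def coherent_vote(years: list[int], m: int, tolerance: int = 1) -> int | None:
    """Vote rule for one pixel: largest mutually-coherent subset of years.

    A subset is coherent when every member lies within ``tolerance`` of the
    subset median.  If the largest coherent subset has >= m members, the
    result is its median year (floored toward the earlier year on .5 ties);
    among equally large subsets the earliest median wins.  Brute-forces all
    subsets, which is exact for the small n used here.
    """
    detected = [int(y) for y in years if y != NO_DETECTION]
    best_size, best_year = 0, None
    for r in range(len(detected), 0, -1):
        if r < best_size:
            break
        for combo in itertools.combinations(detected, r):
            med = float(np.median(combo))
            if all(abs(y - med) <= tolerance for y in combo):
                year = int(math.floor(med))
                if r > best_size or (r == best_size and year < best_year):
                    best_size, best_year = r, year
        if best_size == r:
            break
    if best_size >= m and m >= 1:
        return best_year
    return None


def vote(
    maps: list[np.ndarray],
    m: int,
    tolerance: int = 1,
    status_only: bool = False,
) -> np.ndarray:
    """m-of-n vote across co-registered detection maps.

    With ``status_only`` the vote only requires >= m algorithms to detect
    *some* establishment (no year coherence); the assigned year is then the
    floored median of all detected years.
    """
    if not 1 <= m <= len(maps):
        raise ValueError("need 1 <= m <= number of maps")
    arrs = [np.asarray(a) for a in maps]
    if len({a.shape for a in arrs}) > 1:
        raise ValueError("vote maps are not co-registered")
    out = np.zeros_like(arrs[0], dtype=np.uint16)
    stacked = np.stack(arrs)  # (n, rows, cols)
    n_det = np.sum(stacked != NO_DETECTION, axis=0)
    rows, cols = np.nonzero(n_det >= (m if status_only else m))
    for r, c in zip(rows, cols):
        years = [int(a[r, c]) for a in arrs]
        if status_only:
            det = [y for y in years if y != NO_DETECTION]
            out[r, c] = int(math.floor(float(np.median(det))))
        else:
            y = coherent_vote(years, m, tolerance)
            if y is not None:
                out[r, c] = y
    return out


def run_scheme(
    name: str,
    per_algorithm: dict,
    tolerance: int = 1,
    status_only_vote: bool = False,
) -> np.ndarray:
    """Execute a named ensemble scheme over per-algorithm detection maps.

    ``per_algorithm`` maps algorithm names (MACD, LT, VCT, CCDC,
    CCDC_RF_OLB, CCDC_RF_ALB) to co-registered year maps.  The scheme's
    right-most layer is the baseline; layers are applied leftward via
    :func:`stack`, so ``vcr2 = stack(VCT, stack(CCDC_RF_ALB,
    vote(basics, m=2)))``.
    """
    key = name.lower()
    if key not in SCHEMES:
        raise ValueError(
            f"unknown scheme {name!r}; valid schemes: {', '.join(sorted(SCHEMES))}"
        )
    _check_registered(per_algorithm)

    def layer_map(layer: str) -> np.ndarray:
        if layer in ("2_of_4", "3_of_4"):
            members = [per_algorithm[a] for a in BASIC_MEMBERS]
            return vote(members, int(layer[0]), tolerance, status_only_vote)
        if layer not in per_algorithm:
            raise ValueError(f"scheme {name!r} needs the {layer} map")
        return np.asarray(per_algorithm[layer])

    layers = SCHEMES[key]
    out = layer_map(layers[-1])
    for layer in reversed(layers[:-1]):
        out = stack(layer_map(layer), out)
    return out.astype(np.uint16)


def to_age_map(
    det: np.ndarray,
    forest_mask: np.ndarray,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
    min_year: int = DEFAULT_MIN_YEAR,
) -> np.ndarray:
    """Encode a detection map as a uint8 age map.

    Outside ``forest_mask`` -> 0.  Inside the mask: detection year y in
    [min_year, reference_year] -> age = reference_year - y + 1 (2020 -> 1,
    1987 -> 34); no detection, or a detection earlier than ``min_year``
    (pre-span forest) -> 36.  Detection years after ``reference_year`` are a
    data error.
    """
    det = np.asarray(det)
    mask = np.asarray(forest_mask, dtype=bool)
    if det.shape != mask.shape:
        raise ValueError("forest mask not co-registered with detections")
    detected = det != NO_DETECTION
    if np.any(detected & mask & (det > reference_year)):
        raise ValueError(f"detection year after reference year {reference_year}")
    age = np.full(det.shape, AGE_OLD_FOREST, dtype=np.uint8)
    in_span = detected & (det >= min_year) & (det <= reference_year)
    age[in_span] = (reference_year - det[in_span] + 1).astype(np.uint8)
    age[~mask] = AGE_NON_FOREST
    return age


def decode_age_map(
    age: np.ndarray,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
) -> np.ndarray:
    """Inverse of :func:`to_age_map` for ages 1..34: year = ref - age + 1.

    Non-age codes (0, 36, nodata) decode to 0."""
    age = np.asarray(age)
    years = np.zeros(age.shape, dtype=np.uint16)
    is_age = (age >= 1) & (age <= 34)
    years[is_age] = (reference_year - age[is_age].astype(np.int32) + 1).astype(
        np.uint16
    )
    return years
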