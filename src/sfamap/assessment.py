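"""Accuracy assessment: confusion counts, PA/UA/OA, correct rates, and the
coarse-grid surface-fraction comparison.

Count conventions follow the published validation table this package's
metrics reproduce (see :mod:`sfamap.benchmarks`):

* ``correct_secondary`` — secondary samples detected within the temporal
  tolerance of their true establishment year;
* ``correct_stable`` — stable samples with no detection;
* ``omission = n_stable - correct_stable`` — stable samples falsely
  detected as secondary;
* ``commission = n_secondary - correct_secondary`` — secondary samples
  missed or mistimed.

The producer's, user's and overall accuracies are then

    PA = 100 * cs / (cs + omission)
    UA = 100 * cs / (cs + commission)
    OA = 100 * (cs + cst) / (n_secondary + n_stable)

and the per-class correct rate CR = 100 * correct / detected, with the mean
CR the arithmetic mean of the two class CRs.  Note that "omission" and
"commission" here are swapped relative to the textbook definitions; the
convention is kept so the published metrics are reproducible from the
published counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .ensemble import NO_DETECTION


def round2(x: float) -> float:
    """Round half-up to 2 decimals for reporting (82.955 -> 82.96)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """Correct/omission/commission counts for one scheme."""

    correct_secondary: int
    correct_stable: int
    omission: int
    commission: int
    n_secondary: int = 2072
    n_stable: int = 3000

    def __post_init__(self) -> None:
        for name in ("correct_secondary", "correct_stable", "omission", "commission"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.correct_secondary > self.n_secondary:
            raise ValueError("correct_secondary exceeds n_secondary")
        if self.correct_stable > self.n_stable:
            raise ValueError("correct_stable exceeds n_stable")


@dataclass
class AccuracyMetrics:
    """PA/UA/OA and class correct rates, in percent (2-decimal reporting)."""

    PA: float
    UA: float
    OA: float
    CR_secondary: float | None = None
    CR_stable: float | None = None

    @property
    def mean_CR(self) -> float | None:
        if self.CR_secondary is None or self.CR_stable is None:
            return None
        return mean_cr(self.CR_secondary, self.CR_stable)


def compute_metrics(c: ConfusionCounts) -> AccuracyMetrics:
    """PA, UA and OA from confusion counts, rounded to 2 decimals.

    Raises on zero denominators (undefined metric).
    """
    cs, cst = c.correct_secondary, c.correct_stable
    if cs + c.omission == 0 or cs + c.commission == 0:
        raise ZeroDivisionError("undefined metric: zero denominator")
    total = c.n_secondary + c.n_stable
    if total == 0:
        raise ZeroDivisionError("undefined metric: no samples")
    return AccuracyMetrics(
        PA=round2(100.0 * cs / (cs + c.omission)),
        UA=round2(100.0 * cs / (cs + c.commission)),
        OA=round2(100.0 * (cs + cst) / total),
    )


def correct_rate(correct: int, detected: int) -> float:
    """Percent of detected examples in a class that are correct."""
    if detected <= 0:
        raise ZeroDivisionError("undefined correct rate: nothing detected")
    return round2(100.0 * correct / detected)


def mean_cr(cr_secondary: float, cr_stable: float) -> float:
    """Arithmetic mean of the two class correct rates."""
    return round2((float(cr_secondary) + float(cr_stable)) / 2.0)


def confusion_from_maps(
    predicted: np.ndarray,
    samples: list,
    tolerance: int = 1,
) -> ConfusionCounts:
    """Confusion counts of a detection map against validation samples.

    ``samples`` is a list of dicts with ``row``, ``col``, ``label``
    (``secondary_forest``/``stable_forest``) and, for secondary samples,
    ``year`` (true establishment year).  A secondary sample is correct when
    detected with ``|year - truth| <= tolerance``; a stable sample is
    correct when nothing is detected.  Samples outside the map extent are
    excluded (counted and reported by the caller's logger if needed).
    """
    predicted = np.asarray(predicted)
    n_rows, n_cols = predicted.shape
    cs = cst = n_sec = n_stab = 0
    for s in samples:
        r, c = int(s["row"]), int(s["col"])
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            continue
        year = int(predicted[r, c])
        if s["label"] == "secondary_forest":
            n_sec += 1
            if year != NO_DETECTION and abs(year - int(s["year"])) <= tolerance:
                cs += 1
        elif s["label"] == "stable_forest":
            n_stab += 1
            if year == NO_DETECTION:
                cst += 1
        else:
            raise ValueError(f"unknown sample label {s['label']!r}")
    return ConfusionCounts(
        correct_secondary=cs,
        correct_stable=cst,
        omission=n_stab - cst,
        commission=n_sec - cs,
        n_secondary=n_sec,
        n_stable=n_stab,
    )


def grid_fraction(
    age_map_a: np.ndarray,
    age_map_b: np.ndarray,
    cell_pixels: int,
) -> tuple[np.ndarray, float]:
    """Paired per-cell secondary-forest surface fractions and their R^2.

    Both maps are tiled with ``cell_pixels`` x ``cell_pixels`` blocks (the
    0.05-degree analysis grid expressed in pixels); per cell the fraction of
    pixels carrying age codes 1..34 is computed for each map.  Returns the
    paired fraction table (n_cells, 2) and the coefficient of determination
    of an ordinary least-squares fit of b on a.
    """
    a = np.asarray(age_map_a)
    b = np.asarray(age_map_b)
    if a.shape != b.shape:
        raise ValueError("maps must be co-registered on a common extent")
    if a.size == 0:
        raise ValueError("empty overlap")
    if cell_pixels < 1:
        raise ValueError("cell_pixels must be >= 1")

    def fractions(m: np.ndarray) -> list[float]:
        vals = []
        for r0 in range(0, m.shape[0], cell_pixels):
            for c0 in range(0, m.shape[1], cell_pixels):
                block = m[r0 : r0 + cell_pixels, c0 : c0 + cell_pixels]
                sec = (block >= 1) & (block <= 34)
                vals.append(float(np.mean(sec)))
        return vals

    fa = np.array(fractions(a))
    fb = np.array(fractions(b))
    pairs = np.column_stack([fa, fb])
    # OLS of b on a; degenerate (constant) predictors handled explicitly
    if np.ptp(fa) == 0:
        r2 = 1.0 if np.allclose(fa, fb) else 0.0
    else:
        coef = np.polyfit(fa, fb, 1)
        resid = fb - np.polyval(coef, fa)
        ss_tot = float(np.sum((fb - fb.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return pairs, float(r2)
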