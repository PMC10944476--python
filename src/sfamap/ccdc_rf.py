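"""Random-forest secondary classification of CCDC breakpoints.

The raw CCDC change test fires on anything that departs from the harmonic
model — including subtle disturbance, degeneration or residual noise — so
not every to-forest breakpoint marks a genuine stand establishment.  This
module trains a random forest to separate true establishment breaks from
false ones, with training labels built *without ground truth*: a sample's
latest CCDC break is labelled a true establishment when all four basic
algorithms (MACD, LT, VCT, CCDC) detect an establishment at a consistent
time (within +/-1 year of a common anchor year), and a false break when
none of the other algorithms corroborates it; see :func:`build_labels`.

Two application modes mirror the two published variants:

* OLB ("only latest break") classifies just the latest breakpoint;
* ALB ("all breaks") classifies every breakpoint and keeps the latest one
  classified as a true establishment, so ALB detections are always a
  superset of OLB detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .ccdc import DIRECTION_TO_FOREST, Breakpoint, CcdcResult
from .types import DetectionResult

#: Fixed feature schema (order matters): post-break segment harmonic
#: coefficients, its overall seasonal amplitude and RMSE, the break
#: magnitude, and three topographic attributes.
FEATURE_NAMES = (
    "coef_INTP",
    "slope",
    "coef_COS_1",
    "coef_COS_2",
    "coef_COS_3",
    "coef_SIN_1",
    "coef_SIN_2",
    "coef_SIN_3",
    "amplitude",
    "RMSE",
    "MAG",
    "elevation",
    "slope_topo",
    "aspect",
)

LABEL_TRUE = 1
LABEL_FALSE = 0

BASIC_ALGORITHMS = ("MACD", "LT", "VCT", "CCDC")


def break_features(
    result: CcdcResult,
    bp: Breakpoint,
    topo: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Feature vector for one breakpoint (schema :data:`FEATURE_NAMES`).

    Harmonic-model predictors come from the break's canonical fixed-window
    post-break fit when available (comparable across breaks), otherwise
    from the following segment.  Topographic attributes default to 0 (flat
    terrain) when no co-registered rasters are supplied.
    """
    seg = bp.post_model or result.segments[bp.post_segment]
    return np.array(
        [
            seg.intercept,
            seg.slope,
            *seg.cos_coef,
            *seg.sin_coef,
            seg.amplitude,
            seg.rmse,
            bp.mag,
            *topo,
        ],
        dtype=float,
    )


def consensus_is_true(
    detections: dict, tolerance: int = 1
) -> bool:
    """All four basic algorithms detect at a consistent time: there is a
    common year from which every detection deviates by at most
    ``tolerance`` (equivalently, the detections span at most
    ``2 * tolerance`` years).  Order-independent by construction."""
    years = [detections.get(a) for a in BASIC_ALGORITHMS]
    if any(y is None for y in years):
        return False
    return max(years) - min(years) <= 2 * tolerance


def build_labels(
    samples: list,
    tolerance: int = 1,
) -> pd.DataFrame:
    """Build a labelled-break table from per-sample algorithm outputs.

    ``samples`` is a list of dicts with keys ``detections`` (mapping each of
    the four basic algorithm names to a year or None), ``ccdc`` (the
    sample's :class:`CcdcResult`) and optionally ``topo``.  Samples with no
    CCDC break are excluded.  The latest break of each remaining sample is
    labelled:

    * ``true_establishment`` when it is a to-forest break and all four
      algorithms detect at a consistent time (:func:`consensus_is_true`);
    * ``false_break`` when the other algorithms positively contradict it —
      none of MACD, LT or VCT places an establishment within
      ``2 * tolerance`` years of the break (they are absent or point
      elsewhere), so the break has no independent corroboration;
    * otherwise (partial corroboration without full consensus) the sample
      is ambiguous and excluded from training — labelling such samples
      false would poison the false class with genuine establishments whose
      timing merely scattered across detectors.
    """
    rows, labels = [], []
    for s in samples:
        result: CcdcResult = s["ccdc"]
        bp = result.latest_break
        if bp is None:
            continue
        dets = s["detections"]
        is_true = (
            bp.direction == DIRECTION_TO_FOREST
            and consensus_is_true(dets, tolerance)
        )
        others = [dets.get(a) for a in BASIC_ALGORITHMS if a != "CCDC"]
        corroborated = any(
            y is not None and abs(y - bp.year) <= 2 * tolerance for y in others
        )
        if is_true:
            label = LABEL_TRUE
        elif not corroborated:
            label = LABEL_FALSE
        else:
            continue  # ambiguous; excluded
        rows.append(break_features(result, bp, s.get("topo", (0.0, 0.0, 0.0))))
        labels.append(label)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df["label"] = labels
    return df


@dataclass
class BreakClassifier:
    """A trained break classifier with its feature schema fingerprint."""

    model: RandomForestClassifier
    feature_names: tuple = FEATURE_NAMES

    @property
    def importances(self) -> pd.Series:
        return pd.Series(
            self.model.feature_importances_, index=list(self.feature_names)
        )

    @property
    def oob_score(self) -> float:
        return float(self.model.oob_score_)


def train_rf(
    labeled: pd.DataFrame, n_trees: int = 500, seed: int = 0
) -> BreakClassifier:
    """Train the breakpoint random forest on a labelled-break table.

    Requires both classes present.  No class re-weighting is applied: the
    consensus labelling yields near-balanced classes, and re-weighting
    noisy labels erases the majority vote within a feature cluster.
    Reports the out-of-bag accuracy and per-feature importance scores
    (summing to 1).
    """
    missing = [c for c in FEATURE_NAMES if c not in labeled.columns]
    if missing or "label" not in labeled.columns:
        raise ValueError(f"labelled table missing columns: {missing + ['label']}")
    y = labeled["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    X = labeled[list(FEATURE_NAMES)].to_numpy(dtype=float)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        min_samples_leaf=10,  # consensus labels are noisy; smooth, don't memorise
        random_state=int(seed),
        n_jobs=1,
    )
    model.fit(X, y)
    return BreakClassifier(model)


def classify_breaks(
    clf: BreakClassifier,
    result: CcdcResult,
    mode: str,
    topo: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> DetectionResult:
    """Apply the classifier to a pixel's breakpoints.

    OLB classifies only the latest breakpoint; ALB classifies every
    breakpoint and returns the year of the latest one classified as a true
    establishment.  Absent when there is no breakpoint or none is accepted.
    """
    if mode not in ("OLB", "ALB"):
        raise ValueError("mode must be 'OLB' or 'ALB'")
    algorithm = f"CCDC_RF_{mode}"
    det = DetectionResult(result.pixel_id, algorithm)
    if not result.breakpoints:
        return det
    candidates = (
        [result.latest_break] if mode == "OLB" else list(result.breakpoints)
    )
    X = np.vstack([break_features(result, bp, topo) for bp in candidates])
    pred = clf.model.predict(X)
    for bp, p in zip(reversed(candidates), reversed(pred)):
        if p == LABEL_TRUE:
            det.establishment_year = bp.year
            break
    return det
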