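"""Consensus labelling, classifier training, and OLB/ALB application."""

import numpy as np
import pandas as pd
import pytest

from sfamap import build_labels, classify_breaks, train_rf
from sfamap.ccdc import Breakpoint, CcdcModel, CcdcResult
from sfamap.ccdc_rf import FEATURE_NAMES, LABEL_FALSE, LABEL_TRUE, consensus_is_true


def segment(intercept=0.3, slope=0.1, rmse=0.03):
    return CcdcModel(
        intercept=intercept, slope=slope,
        cos_coef=np.array([0.02, 0.0, 0.0]),
        sin_coef=np.array([0.01, 0.0, 0.0]),
        rmse=rmse, t_start=2000.0, t_end=2005.0, n_obs=40,
    )


def result_with_breaks(break_specs):
    """break_specs: list of (time, mag)."""
    segments = [segment() for _ in range(len(break_specs) + 1)]
    bps = [
        Breakpoint(time=t, mag=m, pre_segment=i, post_segment=i + 1)
        for i, (t, m) in enumerate(break_specs)
    ]
    return CcdcResult(segments=segments, breakpoints=bps)


class TestConsensus:
    def test_tight_agreement_true(self):
        dets = {"MACD": 2005, "LT": 2005, "VCT": 2006, "CCDC": 2004}
        assert consensus_is_true(dets)

    def test_wide_disagreement_false(self):
        dets = {"MACD": 2005, "LT": 2005, "VCT": 2012, "CCDC": 2005}
        assert not consensus_is_true(dets)

    def test_any_absence_fails(self):
        dets = {"MACD": 2005, "LT": None, "VCT": 2005, "CCDC": 2005}
        assert not consensus_is_true(dets)

    def test_order_independent(self):
        years = [2004, 2005, 2005, 2006]
        import itertools

        algs = ("MACD", "LT", "VCT", "CCDC")
        outcomes = {
            consensus_is_true(dict(zip(algs, perm)))
            for perm in itertools.permutations(years)
        }
        assert outcomes == {True}


class TestBuildLabels:
    def test_consensus_sample_labelled_true(self):
        res = result_with_breaks([(2005.2, +0.4)])
        dets = {"MACD": 2005, "LT": 2004, "VCT": 2006, "CCDC": 2005}
        df = build_labels([{"detections": dets, "ccdc": res}])
        assert df["label"].tolist() == [LABEL_TRUE]

    def test_uncorroborated_break_labelled_false(self):
        res = result_with_breaks([(2012.0, +0.3)])
        dets = {"MACD": 2005, "LT": 2005, "VCT": 2005, "CCDC": 2012}
        df = build_labels([{"detections": dets, "ccdc": res}])
        assert df["label"].tolist() == [LABEL_FALSE]

    def test_partially_corroborated_sample_excluded(self):
        res = result_with_breaks([(2005.0, +0.4)])
        dets = {"MACD": 2005, "LT": None, "VCT": 2006, "CCDC": 2005}
        df = build_labels([{"detections": dets, "ccdc": res}])
        assert len(df) == 0

    def test_no_break_excluded(self):
        res = CcdcResult(segments=[segment()])
        dets = {"MACD": 2005, "LT": 2005, "VCT": 2005, "CCDC": None}
        df = build_labels([{"detections": dets, "ccdc": res}])
        assert len(df) == 0

    def test_feature_schema(self):
        res = result_with_breaks([(2005.0, +0.4)])
        dets = {"MACD": 2005, "LT": 2005, "VCT": 2005, "CCDC": 2005}
        df = build_labels([{"detections": dets, "ccdc": res}])
        assert list(df.columns) == list(FEATURE_NAMES) + ["label"]
        assert df.notna().all().all()


def synthetic_table(rng, n=400, separation=6.0):
    """Two feature clusters split on MAG and intercept."""
    rows = []
    for i in range(n):
        true = i % 2 == 0
        mu = separation if true else 0.0
        feats = rng.normal(mu, 1.0, len(FEATURE_NAMES))
        rows.append(list(feats) + [LABEL_TRUE if true else LABEL_FALSE])
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label"])


class TestTrainRf:
    def test_separable_features_high_oob(self):
        rng = np.random.default_rng(0)
        clf = train_rf(synthetic_table(rng), n_trees=200, seed=1)
        assert clf.oob_score >= 0.99
        assert clf.importances.sum() == pytest.approx(1.0)

    def test_shuffled_labels_chance_oob(self):
        rng = np.random.default_rng(1)
        df = synthetic_table(rng, separation=0.0)
        assert 0.4 <= train_rf(df, n_trees=200, seed=1).oob_score <= 0.6

    def test_same_seed_identical_importances(self):
        rng = np.random.default_rng(2)
        df = synthetic_table(rng)
        a = train_rf(df, n_trees=100, seed=5).importances
        b = train_rf(df, n_trees=100, seed=5).importances
        assert a.equals(b)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(3)
        df = synthetic_table(rng)
        df["label"] = LABEL_TRUE
        with pytest.raises(ValueError, match="both classes"):
            train_rf(df)


@pytest.fixture(scope="module")
def trained():
    """Classifier that accepts breaks with a low, rising, high-magnitude
    post-break trajectory and rejects flat mature-canopy breaks."""
    rng = np.random.default_rng(4)
    rows = []
    for i in range(400):
        true = i % 2 == 0
        feats = dict.fromkeys(FEATURE_NAMES, 0.0)
        feats["coef_INTP"] = rng.normal(0.2 if true else 0.65, 0.03)
        feats["slope"] = rng.normal(0.15 if true else 0.0, 0.02)
        feats["MAG"] = rng.normal(0.45 if true else 0.2, 0.03)
        feats["RMSE"] = abs(rng.normal(0.04, 0.005))
        rows.append(
            [feats[k] for k in FEATURE_NAMES]
            + [LABEL_TRUE if true else LABEL_FALSE]
        )
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label"])
    return train_rf(df, n_trees=200, seed=0)


def establishment_like(time):
    return CcdcModel(
        intercept=0.2, slope=0.15,
        cos_coef=np.zeros(3), sin_coef=np.zeros(3),
        rmse=0.04, t_start=time, t_end=time + 5, n_obs=40,
    )


def transient_like(time):
    return CcdcModel(
        intercept=0.65, slope=0.0,
        cos_coef=np.zeros(3), sin_coef=np.zeros(3),
        rmse=0.04, t_start=time, t_end=time + 5, n_obs=40,
    )


class TestClassifyBreaks:
    def test_no_breaks_absent_in_both_modes(self, trained):
        res = CcdcResult(segments=[segment()])
        for mode in ("OLB", "ALB"):
            assert classify_breaks(trained, res, mode).establishment_year is None

    def test_latest_false_earlier_true_split(self, trained):
        segs = [
            transient_like(1995),
            establishment_like(2002),
            transient_like(2015),
        ]
        bps = [
            Breakpoint(time=2002.3, mag=0.45, pre_segment=0, post_segment=1),
            Breakpoint(time=2015.1, mag=0.2, pre_segment=1, post_segment=2),
        ]
        res = CcdcResult(segments=segs, breakpoints=bps)
        assert classify_breaks(trained, res, "OLB").establishment_year is None
        assert classify_breaks(trained, res, "ALB").establishment_year == 2002

    def test_single_true_break_modes_agree(self, trained):
        segs = [transient_like(1990), establishment_like(2002)]
        bps = [Breakpoint(time=2002.3, mag=0.45, pre_segment=0, post_segment=1)]
        res = CcdcResult(segments=segs, breakpoints=bps)
        olb = classify_breaks(trained, res, "OLB").establishment_year
        alb = classify_breaks(trained, res, "ALB").establishment_year
        assert olb == alb == 2002

    def test_alb_detections_superset_of_olb(self, trained):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_breaks = int(rng.integers(1, 4))
            segs, bps = [transient_like(1986)], []
            t = 1990.0
            for k in range(n_breaks):
                est = rng.random() < 0.5
                segs.append(establishment_like(t) if est else transient_like(t))
                bps.append(
                    Breakpoint(
                        time=t, mag=0.45 if est else 0.2,
                        pre_segment=k, post_segment=k + 1,
                    )
                )
                t += float(rng.integers(2, 8))
            res = CcdcResult(segments=segs, breakpoints=bps)
            olb = classify_breaks(trained, res, "OLB").establishment_year
            alb = classify_breaks(trained, res, "ALB").establishment_year
            if olb is not None:
                assert alb == olb  # latest accepted in both
            # ALB can only add detections, never remove them
            assert not (alb is None and olb is not None)

    def test_invalid_mode_rejected(self, trained):
        with pytest.raises(ValueError):
            classify_breaks(trained, CcdcResult(), "XXX")
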