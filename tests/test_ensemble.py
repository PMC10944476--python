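"""Stacking/voting algebra and the age-map encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfamap import run_scheme, stack, to_age_map, vote
from sfamap.ensemble import (
    AGE_NON_FOREST,
    AGE_OLD_FOREST,
    SCHEMES,
    coherent_vote,
    decode_age_map,
)

from .oracles import oracle_vote


def rand_maps(rng, n=4, shape=(6, 6), p_detect=0.6):
    maps = []
    for _ in range(n):
        m = rng.integers(1990, 2021, size=shape).astype(np.uint16)
        m[rng.random(shape) > p_detect] = 0
        maps.append(m)
    return maps


class TestStack:
    def test_baseline_priority(self):
        base = np.array([[2001]], dtype=np.uint16)
        over = np.array([[1995]], dtype=np.uint16)
        assert stack(over, base)[0, 0] == 2001

    def test_overlay_fills_gap(self):
        base = np.array([[0]], dtype=np.uint16)
        over = np.array([[1995]], dtype=np.uint16)
        assert stack(over, base)[0, 0] == 1995

    def test_both_absent(self):
        z = np.zeros((1, 1), dtype=np.uint16)
        assert stack(z, z)[0, 0] == 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stack(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_idempotent_and_associative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, _ = rand_maps(rng)
            assert np.array_equal(stack(a, a), a)
            assert np.array_equal(
                stack(a, stack(b, c)), stack(stack(a, b), c)
            )

    def test_coverage_monotone(self):
        rng = np.random.default_rng(1)
        a, b, *_ = rand_maps(rng)
        out = stack(a, b)
        assert np.all((out != 0) | ((a == 0) & (b == 0)))


class TestVote:
    def test_two_agreeing_round_to_earlier(self):
        assert coherent_vote([2000, 2001, 0, 0], m=2) == 2000

    def test_largest_coherent_subset_wins(self):
        assert coherent_vote([2000, 2010, 2011, 0], m=2) == 2010

    def test_insufficient_detections_absent(self):
        assert coherent_vote([2000, 2001, 0, 0], m=3) is None

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(400):
            years = [
                int(rng.integers(1995, 2005)) if rng.random() < 0.7 else 0
                for _ in range(4)
            ]
            for m in (2, 3):
                assert coherent_vote(years, m) == oracle_vote(years, m), years

    def test_vote_maps_and_m_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            maps = rand_maps(rng)
            v2 = vote(maps, m=2)
            v3 = vote(maps, m=3)
            det2 = v2 != 0
            det3 = v3 != 0
            assert np.all(det2 | ~det3)  # detections(2of4) superset of 3of4

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            vote([np.zeros((2, 2))], m=2)


class TestRunScheme:
    def test_single_layer_identity(self):
        rng = np.random.default_rng(4)
        maps = dict(zip(("MACD", "LT", "VCT", "CCDC"), rand_maps(rng)))
        maps["CCDC_RF_ALB"] = maps["CCDC"].copy()
        maps["CCDC_RF_OLB"] = maps["CCDC"].copy()
        assert np.array_equal(run_scheme("vct", maps), maps["VCT"])

    def test_vct_macd_layering(self):
        maps = {
            "MACD": np.array([[0, 2001]], dtype=np.uint16),
            "VCT": np.array([[1995, 1990]], dtype=np.uint16),
        }
        out = run_scheme("vct+macd", maps)
        assert out.tolist() == [[1995, 2001]]

    def test_vcr2_fallthrough_to_vct(self):
        shape = (1, 1)
        zero = np.zeros(shape, dtype=np.uint16)
        maps = {
            "MACD": zero, "LT": zero, "CCDC": zero,
            "CCDC_RF_ALB": zero.copy(),
            "VCT": np.full(shape, 1999, dtype=np.uint16),
        }
        assert run_scheme("vcr2", maps)[0, 0] == 1999

    def test_vcr2_equals_explicit_chain(self):
        rng = np.random.default_rng(5)
        maps = dict(zip(("MACD", "LT", "VCT", "CCDC"), rand_maps(rng)))
        maps["CCDC_RF_ALB"] = rand_maps(rng, n=1)[0]
        expected = stack(
            maps["VCT"],
            stack(
                maps["CCDC_RF_ALB"],
                vote([maps[a] for a in ("MACD", "LT", "VCT", "CCDC")], m=2),
            ),
        )
        assert np.array_equal(run_scheme("vcr2", maps), expected)

    def test_unknown_scheme_lists_valid_names(self):
        with pytest.raises(ValueError, match="valid schemes"):
            run_scheme("bogus", {})

    def test_all_named_schemes_run(self):
        rng = np.random.default_rng(6)
        maps = dict(zip(("MACD", "LT", "VCT", "CCDC"), rand_maps(rng)))
        maps["CCDC_RF_ALB"] = rand_maps(rng, n=1)[0]
        maps["CCDC_RF_OLB"] = rand_maps(rng, n=1)[0]
        for name in SCHEMES:
            out = run_scheme(name, maps)
            assert out.shape == maps["VCT"].shape


class TestAgeMap:
    def test_published_encoding_anchors(self):
        det = np.array([[1987, 2020, 0]], dtype=np.uint16)
        mask = np.array([[True, True, True]])
        age = to_age_map(det, mask)
        assert age.tolist() == [[34, 1, AGE_OLD_FOREST]]

    def test_outside_mask_is_non_forest(self):
        det = np.array([[2000]], dtype=np.uint16)
        age = to_age_map(det, np.array([[False]]))
        assert age[0, 0] == AGE_NON_FOREST

    def test_pre_span_detection_is_old_forest(self):
        det = np.array([[1980]], dtype=np.uint16)
        age = to_age_map(det, np.array([[True]]))
        assert age[0, 0] == AGE_OLD_FOREST

    def test_post_reference_detection_rejected(self):
        det = np.array([[2021]], dtype=np.uint16)
        with pytest.raises(ValueError, match="reference"):
            to_age_map(det, np.array([[True]]))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.one_of(st.just(0), st.integers(1900, 2020)),
            min_size=9, max_size=9,
        ),
        st.lists(st.booleans(), min_size=9, max_size=9),
    )
    def test_age_code_closure_and_roundtrip(self, years, mask):
        det = np.array(years, dtype=np.uint16).reshape(3, 3)
        m = np.array(mask).reshape(3, 3)
        age = to_age_map(det, m)
        codes = set(np.unique(age).tolist())
        assert codes <= ({0, AGE_OLD_FOREST} | set(range(1, 35)))
        assert 35 not in codes
        # decode recovers the year wherever an age 1..34 was assigned
        decoded = decode_age_map(age)
        in_age = (age >= 1) & (age <= 34)
        assert np.array_equal(decoded[in_age], det[in_age])
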