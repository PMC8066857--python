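import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caedge.ca_core import (
    MOORE_OFFSETS,
    DetectorParams,
    apply_detector,
    decode_rule,
    difference_sum,
    edge_membership,
    encode_rule,
    threshold_membership,
)
from .conftest import naive_detector

CENTER_BIT = 1 << MOORE_OFFSETS.index((0, 0))


class TestRuleCoding:
    def test_edge_rules(self):
        assert decode_rule(0) == frozenset()
        assert decode_rule(511) == frozenset(MOORE_OFFSETS)
        assert decode_rule(1) == frozenset({(-1, -1)})

    def test_roundtrip_exhaustive(self):
        for rule in range(512):
            assert encode_rule(decode_rule(rule)) == rule

    @pytest.mark.parametrize("bad", [-1, 512, 1000])
    def test_out_of_range_rule_rejected(self, bad):
        with pytest.raises(ValueError):
            decode_rule(bad)

    def test_invalid_offset_rejected(self):
        with pytest.raises(ValueError):
            encode_rule({(2, 0)})


class TestLocalRule:
    def test_difference_sum_uniform_is_zero(self):
        img = np.full((5, 5), 37.0)
        assert difference_sum(img, 2, 2, decode_rule(511)) == 0.0

    def test_difference_sum_center_spike(self):
        img = np.zeros((3, 3))
        img[1, 1] = 255.0
        eight = decode_rule(511 - CENTER_BIT)
        assert difference_sum(img, 1, 1, eight) == 2040.0
        assert difference_sum(img, 1, 1, {(0, 0)}) == 0.0

    def test_membership_values(self):
        assert edge_membership(0.0, 100) == 0.0
        assert edge_membership(2040.0, 255) == pytest.approx(2040 / 2295)
        assert edge_membership(500.0, 0) == 1.0
        assert edge_membership(0.0, 0) == 0.0  # 0/0 limit: flat is not an edge
        with pytest.raises(ValueError):
            edge_membership(-1.0, 10)

    @given(
        phi=st.floats(min_value=0.01, max_value=5000),
        bump=st.floats(min_value=0.01, max_value=100),
        delta=st.integers(min_value=1, max_value=255),
    )
    @settings(derandomize=True, max_examples=50)
    def test_membership_monotone_in_phi_and_delta(self, phi, bump, delta):
        assert edge_membership(phi + bump, delta) > edge_membership(phi, delta)
        if delta < 255:
            assert edge_membership(phi, delta + 1) <= edge_membership(phi, delta)

    def test_threshold_is_strict(self):
        assert threshold_membership(0.5, 0.5) == 0
        assert threshold_membership(0.5001, 0.5) == 1
        assert threshold_membership(0.0, 0.0) == 0
        with pytest.raises(ValueError):
            threshold_membership(0.5, 1.0)


class TestApplyDetector:
    def test_uniform_image_no_edges(self):
        img = np.full((8, 8), 120.0)
        out = apply_detector(img, DetectorParams(delta=10, tau=0.1, rule=495))
        assert out.sum() == 0

    def test_empty_rule_no_edges(self, rng):
        img = rng.uniform(0, 255, size=(8, 8))
        out = apply_detector(img, DetectorParams(delta=0, tau=0.0, rule=0))
        assert out.sum() == 0

    def test_vertical_step_marks_adjacent_columns(self):
        img = np.zeros((5, 5))
        img[:, 2:] = 255.0
        out = apply_detector(img, DetectorParams(delta=255, tau=0.4, rule=511 - CENTER_BIT))
        expected = np.zeros((5, 5), dtype=np.uint8)
        expected[:, 1:3] = 1  # the two columns adjacent to the 0->255 step
        np.testing.assert_array_equal(out, expected)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            apply_detector(np.zeros((2, 5)), DetectorParams(delta=1, tau=0.1, rule=511))

    def test_matches_naive_reference(self, rng):
        for _ in range(25):
            img = rng.uniform(0, 255, size=(8, 8))
            params = DetectorParams(
                delta=int(rng.integers(0, 256)),
                tau=float(rng.uniform(0, 0.999)),
                rule=int(rng.integers(0, 512)),
            )
            np.testing.assert_array_equal(apply_detector(img, params),
                                          naive_detector(img, params))


class TestDetectorInvariants:
    def test_center_bit_neutrality(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        for rule in rng.integers(0, 512, size=10):
            rule = int(rule)
            a = apply_detector(img, DetectorParams(delta=50, tau=0.3, rule=rule))
            b = apply_detector(img, DetectorParams(delta=50, tau=0.3, rule=rule ^ CENTER_BIT))
            np.testing.assert_array_equal(a, b)

    def test_tau_monotonicity(self, rng):
        img = rng.uniform(0, 255, size=(12, 12))
        lo = apply_detector(img, DetectorParams(delta=80, tau=0.2, rule=341))
        hi = apply_detector(img, DetectorParams(delta=80, tau=0.6, rule=341))
        assert np.all(hi <= lo)  # raising tau can only shrink the edge set

    def test_delta_monotonicity(self, rng):
        img = rng.uniform(0, 255, size=(12, 12))
        counts = [
            apply_detector(img, DetectorParams(delta=d, tau=0.3, rule=495)).sum()
            for d in (0, 40, 120, 255)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_mask_monotonicity(self, rng):
        img = rng.uniform(0, 255, size=(10, 10))
        sub = encode_rule({(-1, 0), (0, 1)})
        sup = encode_rule({(-1, 0), (0, 1), (1, 0), (1, 1)})
        a = apply_detector(img, DetectorParams(delta=60, tau=0.4, rule=sub))
        b = apply_detector(img, DetectorParams(delta=60, tau=0.4, rule=sup))
        assert np.all(a <= b)  # larger mask => pointwise larger phi => superset edges

    def test_pure_function_of_input(self, rng):
        img = rng.uniform(0, 255, size=(9, 9))
        p = DetectorParams(delta=30, tau=0.25, rule=170)
        np.testing.assert_array_equal(apply_detector(img, p), apply_detector(img, p))


def test_params_serialization_roundtrip(tmp_path):
    p = DetectorParams(delta=128, tau=0.375, rule=300)
    for name in ("p.yaml", "p.json"):
        p.save(tmp_path / name)
        assert DetectorParams.load(tmp_path / name) == p
    with pytest.raises(ValueError):
        DetectorParams(delta=256, tau=0.1, rule=0)
    with pytest.raises(ValueError):
        DetectorParams(delta=0, tau=1.0, rule=0)
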