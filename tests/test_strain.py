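"""Length series, DP and peak ED/ES detection, strain estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import enumerate_best_chain

from echostrain.contours import ContourSequence
from echostrain.strain import (CyclePair, DPConfig, LengthSeries,
                               average_gls, contour_length,
                               detect_ed_es_dp, detect_ed_es_peaks,
                               length_series, pair_extrema,
                               relative_difference, strain_dp,
                               strain_mean_length, strain_pairwise)


def two_cycle_cosine(n_per=20, base=10.0, amp=2.0, n_cycles=2, rate=20.0):
    t = np.arange(n_cycles * n_per)
    return LengthSeries(base - amp * (0.5 - 0.5 * np.cos(2 * np.pi * t / n_per)),
                        frame_rate=rate)


class TestContourLength:
    def test_unit_collinear_chain_has_length_48(self):
        pts = np.column_stack([np.arange(49.0), np.zeros(49)])
        assert contour_length(pts) == pytest.approx(48.0)

    def test_length_is_homogeneous_under_scaling(self):
        pts = np.random.default_rng(0).random((49, 2)) * 100
        assert contour_length(pts * 2) == pytest.approx(
            2 * contour_length(pts), rel=1e-12)

    def test_semicircle_matches_chord_sum_oracle(self):
        theta = np.linspace(0, np.pi, 49)
        pts = 10.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        chords = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert contour_length(pts) == pytest.approx(chords, rel=1e-12)
        assert contour_length(pts) == pytest.approx(np.pi * 10, rel=1e-3)

    def test_spacing_converts_to_millimetres(self):
        pts = np.column_stack([np.arange(49.0), np.zeros(49)])
        assert contour_length(pts, spacing=0.5) == pytest.approx(24.0)

    def test_wrong_point_count_rejected(self):
        with pytest.raises(ValueError):
            contour_length(np.zeros((10, 2)))


class TestLengthSeries:
    def test_series_tracks_per_frame_lengths(self):
        r = np.random.default_rng(1)
        pts = r.random((6, 49, 2)) * 50 + 10
        ls = length_series(ContourSequence(pts), frame_rate=30.0)
        assert len(ls) == 6
        for i in range(6):
            assert ls.lengths[i] == pytest.approx(contour_length(pts[i]),
                                                  abs=1e-9)

    def test_constant_contour_gives_constant_series(self):
        pts = np.tile(np.column_stack([np.arange(49.0), np.zeros(49)]),
                      (4, 1, 1))
        ls = length_series(ContourSequence(pts))
        assert np.allclose(ls.lengths, 48.0)


class TestDPDetection:
    def test_two_cycle_cosine_yields_the_analytic_pairs(self):
        pairs = detect_ed_es_dp(two_cycle_cosine())
        assert [(p.ed_frame, p.es_frame) for p in pairs] == [(0, 10), (20, 30)]

    def test_constant_series_yields_no_pairs(self):
        assert detect_ed_es_dp(LengthSeries(np.full(30, 7.0), 25.0)) == []

    def test_single_monotone_descent_pairs_the_endpoints(self):
        ls = LengthSeries(np.linspace(10, 8, 20), frame_rate=20.0)
        pairs = detect_ed_es_dp(ls)
        assert [(p.ed_frame, p.es_frame) for p in pairs] == [(0, 19)]

    @pytest.mark.parametrize("seed", range(20))
    def test_dp_matches_exhaustive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(12, 26))
        lengths = 50 + np.cumsum(r.normal(0, 1.5, size=n))
        lengths = np.maximum(lengths, 1.0)
        ls = LengthSeries(lengths, frame_rate=30.0)
        cfg = DPConfig(min_duration=5)
        lam, d_min = cfg.resolve(ls)
        _, oracle_pairs = enumerate_best_chain(lengths, lam, d_min)
        pairs = [(p.ed_frame, p.es_frame) for p in detect_ed_es_dp(ls, cfg)]
        assert pairs == oracle_pairs

    def test_pairs_alternate_and_never_overlap(self):
        r = np.random.default_rng(99)
        ls = LengthSeries(50 + np.cumsum(r.normal(0, 2, 80)).clip(-40, 40),
                          frame_rate=40.0)
        pairs = detect_ed_es_dp(ls)
        flat = [f for p in pairs for f in (p.ed_frame, p.es_frame)]
        assert flat == sorted(flat)
        assert len(set(flat)) == len(flat)

    def test_invariant_to_additive_and_multiplicative_rescaling(self):
        ls = two_cycle_cosine()
        base = [(p.ed_frame, p.es_frame) for p in detect_ed_es_dp(ls)]
        shifted = LengthSeries(ls.lengths + 100.0, ls.frame_rate)
        scaled = LengthSeries(ls.lengths * 7.3, ls.frame_rate)
        for variant in (shifted, scaled):
            assert [(p.ed_frame, p.es_frame)
                    for p in detect_ed_es_dp(variant)] == base

    def test_cycle_pair_ordering_enforced(self):
        with pytest.raises(ValueError):
            CyclePair(5, 5)


class TestPeakDetection:
    def test_interior_cosine_extrema_are_found(self):
        # phase-shifted so maxima/minima are interior frames
        t = np.arange(50)
        ls = LengthSeries(10 + 2 * np.cos(2 * np.pi * (t - 5) / 20), 25.0)
        ed, es = detect_ed_es_peaks(ls, prominence=0.5, min_distance=5)
        assert ed == [5, 25, 45][:len(ed)] and len(ed) >= 2
        assert es == [15, 35]

    def test_monotone_series_has_no_interior_extrema(self):
        ls = LengthSeries(np.linspace(5, 10, 30))
        ed, es = detect_ed_es_peaks(ls, prominence=0.1, min_distance=2)
        assert ed == [] and es == []

    def test_excessive_prominence_filters_everything(self):
        ls = two_cycle_cosine()
        ed, es = detect_ed_es_peaks(ls, prominence=10.0, min_distance=2)
        assert ed == [] and es == []

    def test_pairing_skips_cycles_without_an_es(self):
        pairs = pair_extrema([0, 20], [10, 30])
        assert [(p.ed_frame, p.es_frame) for p in pairs] == [(0, 10), (20, 30)]
        assert pair_extrema([0, 5], [10]) == [
            CyclePair(5, 10)]  # no ES inside cycle [0, 5)


class TestStrainEstimators:
    def test_pairwise_strain_averages_per_cycle_values(self):
        ls = LengthSeries(np.array([10.0, 8.0, 12.0, 9.0]))
        res = strain_pairwise(ls, [CyclePair(0, 1), CyclePair(2, 3)])
        assert res.per_cycle_strain == pytest.approx([-20.0, -25.0])
        assert res.gls == pytest.approx(-22.5)

    def test_single_pair_and_no_shortening_cases(self):
        ls = LengthSeries(np.array([10.0, 8.0, 10.0, 10.0]))
        assert strain_pairwise(ls, [CyclePair(0, 1)]).gls == pytest.approx(-20)
        assert strain_pairwise(ls, [CyclePair(2, 3)]).gls == 0.0
        with pytest.raises(ValueError):
            strain_pairwise(ls, [])

    def test_mean_length_strain_from_averaged_phases(self):
        ls = LengthSeries(np.array([10.0, 8.0, 12.0, 9.0]))
        res = strain_mean_length(ls, [0, 2], [1, 3])
        assert res.gls == pytest.approx(100 * (8.5 - 11) / 11)

    def test_single_cycle_estimators_coincide(self):
        ls = LengthSeries(np.array([10.0, 9.5, 8.0, 9.0]))
        a = strain_pairwise(ls, [CyclePair(0, 2)]).gls
        b = strain_mean_length(ls, [0], [2]).gls
        assert a == pytest.approx(b, abs=1e-9) == pytest.approx(-20.0)

    def test_dp_strain_on_two_cycle_cosine(self):
        res = strain_dp(two_cycle_cosine())
        assert res.gls == pytest.approx(-20.0, abs=1e-9)
        assert res.algorithm == "dp"

    def test_dp_strain_raises_on_constant_series(self):
        with pytest.raises(ValueError):
            strain_dp(LengthSeries(np.full(40, 9.0), 30.0))

    @given(st.floats(0.1, 50.0))
    def test_all_estimators_invariant_to_uniform_scaling(self, factor):
        ls = two_cycle_cosine()
        scaled = LengthSeries(ls.lengths * factor, ls.frame_rate)
        assert strain_dp(scaled).gls == pytest.approx(
            strain_dp(ls).gls, abs=1e-9)
        pairs = [CyclePair(0, 10), CyclePair(20, 30)]
        assert strain_pairwise(scaled, pairs).gls == pytest.approx(
            strain_pairwise(ls, pairs).gls, abs=1e-9)
        assert strain_mean_length(scaled, [0, 20], [10, 30]).gls == \
            pytest.approx(strain_mean_length(ls, [0, 20], [10, 30]).gls,
                          abs=1e-9)


class TestSummaries:
    def test_relative_difference_formula(self):
        assert relative_difference(-18, -18) == 0.0
        assert relative_difference(-17, -20) == pytest.approx(-0.15)
        assert relative_difference(-22, -20) == pytest.approx(0.10)
        with pytest.raises(ValueError):
            relative_difference(-17, 0.0)

    def test_average_gls_over_views(self):
        assert average_gls([-18, -18, -18]) == -18.0
        assert average_gls([-15, -18, -21]) == pytest.approx(-18.0)
        assert average_gls([-12.5]) == -12.5
        with pytest.raises(ValueError):
            average_gls([])
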