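"""Thorpe-scale overturn detection and diffusivity averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gomflux.hydrography import (DegenerateProfileError, DensityProfile,
                                 DiffusivityProfile, MixingParams,
                                 OverturnSegment, average_kz, cast_kz_profile,
                                 detect_overturns, layer_geomean,
                                 preprocess_profile, thorpe_displacements)

from conftest import brute_force_displacements


class TestPreprocess:
    def test_clean_profile_unchanged(self, stable_profile, params):
        out = preprocess_profile(stable_profile, params)
        np.testing.assert_array_equal(out.depth, stable_profile.depth)
        np.testing.assert_array_equal(out.sigma, stable_profile.sigma)

    def test_pressure_reversal_dropped(self, params):
        # depth stalls at 3 m: the second occurrence must be dropped
        z = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        s = 23.0 + 0.01 * np.arange(6)
        raw = DensityProfile("rev", "t0", z, s, validate=False)
        out = preprocess_profile(raw, params)
        assert out.depth.size == 5
        assert np.all(np.diff(out.depth) > 0)

    def test_spike_removed(self, params):
        z = np.arange(0.0, 20.0)
        s = 23.0 + 0.01 * z
        s[10] += 10 * params.noise_threshold * 1.5  # beyond the window-median rule
        out = preprocess_profile(DensityProfile("spike", "t0", z, s), params)
        assert out.depth.size == 19
        assert 10.0 not in out.depth
        # window-median oracle: every kept sample is within tolerance of
        # the median of its 5-point neighbourhood
        for i in range(out.sigma.size):
            lo, hi = max(0, i - 2), min(out.sigma.size, i + 3)
            assert abs(out.sigma[i] - np.median(out.sigma[lo:hi])) <= \
                params.despike_factor * params.noise_threshold

    def test_degenerate_after_cleaning(self, params):
        z = np.array([1.0, 2.0, 3.0])
        s = np.array([23.0, 23.0 + 0.1, 23.0 + 0.01])
        s[1] += 1.0  # spike; only 2 samples survive
        with pytest.raises(DegenerateProfileError):
            preprocess_profile(DensityProfile("bad", "t0", z, s), params)


class TestDisplacements:
    def test_stable_profile_all_zero(self, stable_profile):
        d = thorpe_displacements(stable_profile)
        np.testing.assert_array_equal(d.displacement, 0.0)

    def test_worked_example(self, five_point_profile):
        d = thorpe_displacements(five_point_profile)
        np.testing.assert_array_equal(d.displacement, [0.0, 2.0, -1.0, -1.0, 0.0])

    def test_adjacent_inversion_symmetry(self):
        p = DensityProfile("pair", "t0", np.array([1.0, 2.0, 3.0]),
                          np.array([1025.2, 1025.1, 1025.4]))
        d = thorpe_displacements(p)
        np.testing.assert_array_equal(d.displacement, [1.0, -1.0, 0.0])

    def test_ties_produce_zero_displacement(self):
        p = DensityProfile("tie", "t0", np.arange(4.0),
                          np.array([23.0, 23.5, 23.5, 24.0]))
        d = thorpe_displacements(p)
        np.testing.assert_array_equal(d.displacement, 0.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1020.0, max_value=1030.0,
                              allow_nan=False), min_size=10, max_size=50),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_bruteforce_oracle(self, sigmas, seed):
        rng = np.random.default_rng(seed)
        sigma = rng.permutation(np.asarray(sigmas))
        depth = np.cumsum(rng.uniform(0.2, 2.0, sigma.size))
        p = DensityProfile("h", "t0", depth, sigma)
        d = thorpe_displacements(p)
        np.testing.assert_array_equal(
            d.displacement, brute_force_displacements(depth, sigma))
        assert abs(d.displacement.sum()) < 1e-9 * max(1.0, depth.max())


class TestDetectOverturns:
    def test_stable_profile_empty(self, stable_profile, params):
        d = thorpe_displacements(stable_profile)
        assert detect_overturns(d, stable_profile, params) == []

    def test_five_point_patch(self, five_point_profile, params):
        d = thorpe_displacements(five_point_profile)
        segs = detect_overturns(d, five_point_profile, params)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.start_depth == 2.0 and seg.end_depth == 4.0
        assert seg.L_T == pytest.approx(np.sqrt((4 + 1 + 1) / 3), rel=1e-12)

    def test_kz_closed_form(self, params):
        # full inversion engineered so L_T = 1 m and N = 5e-3 s^-1:
        # K_z = 0.2 * 0.8^2 * 1^2 * 5e-3 = 6.4e-4 m^2 s^-1
        n, d = 4, np.sqrt(3.0 / (4 ** 2 - 1))
        seg_z = np.arange(n) * d + 10.0
        span = seg_z[-1] - seg_z[0]
        dsig = (5e-3) ** 2 * params.rho0 / params.g * span
        seg_s = 25.0 + np.linspace(dsig, 0.0, n)  # inverted
        z = np.concatenate([[5.0], seg_z, [15.0]])
        s = np.concatenate([[24.0], seg_s, [26.0]])
        p = DensityProfile("eng", "t0", z, s)
        segs = detect_overturns(thorpe_displacements(p), p, params)
        assert len(segs) == 1
        assert segs[0].L_T == pytest.approx(1.0, rel=1e-9)
        assert segs[0].N == pytest.approx(5e-3, rel=1e-9)
        assert segs[0].K_z == pytest.approx(6.4e-4, rel=1e-9)

    def test_patch_kz_consistent_with_formula(self, five_point_profile, params):
        segs = detect_overturns(thorpe_displacements(five_point_profile),
                                five_point_profile, params)
        seg = segs[0]
        assert seg.K_z == pytest.approx(
            params.gamma * params.ozmidov_ratio ** 2 * seg.L_T ** 2 * seg.N,
            rel=1e-12)
        assert seg.epsilon == pytest.approx(
            (params.ozmidov_ratio * seg.L_T) ** 2 * seg.N ** 3, rel=1e-12)

    def test_noise_range_rejected(self, params):
        # inversion spanning less density range than the noise threshold
        z = np.arange(0.0, 10.0)
        s = 23.0 + 1e-5 * z
        s[4], s[5] = s[5], s[4]
        p = DensityProfile("noise", "t0", z, s)
        assert detect_overturns(thorpe_displacements(p), p, params) == []

    def test_linear_inversion_recovers_h_over_sqrt3(self, params):
        # fully inverting a linearly stratified segment of height h gives
        # rms displacement ~ h/sqrt(3); verify against the sorting oracle
        h, dz = 8.0, 0.25
        z = np.arange(0.0, 40.0 + dz / 2, dz)
        s = 23.0 + 0.012 * z
        i0, i1 = np.searchsorted(z, 16.0), np.searchsorted(z, 16.0 + h)
        s[i0:i1 + 1] = s[i0:i1 + 1][::-1]
        p = DensityProfile("inv", "t0", z, s)
        segs = detect_overturns(thorpe_displacements(p), p, params)
        assert len(segs) == 1
        oracle = brute_force_displacements(z, s)
        lt_oracle = np.sqrt(np.mean(oracle[i0:i1 + 1] ** 2))
        assert segs[0].L_T == pytest.approx(lt_oracle, rel=1e-12)
        assert segs[0].L_T == pytest.approx(h / np.sqrt(3), rel=0.10)


class TestBinningAndAveraging:
    def test_no_segments_all_background(self, params):
        edges = np.arange(0.0, 50.0, 5.0)
        kz = cast_kz_profile([], edges, params)
        np.testing.assert_array_equal(kz, params.background_kz)

    def test_single_patch_fills_its_bins(self, params):
        edges = np.arange(0.0, 50.0, 5.0)
        seg = OverturnSegment(25.0, 40.0, 1.0, 5e-3, 1e-7, 1e-4)
        kz = cast_kz_profile([seg], edges, params)
        covered = (edges[:-1] < 40.0) & (edges[1:] > 25.0)
        np.testing.assert_allclose(kz[covered], 1e-4)
        np.testing.assert_allclose(kz[~covered], params.background_kz)

    def test_overlapping_patches_weighted_mean(self, params):
        edges = np.array([0.0, 10.0])
        a = OverturnSegment(0.0, 10.0, 2.0, 5e-3, 0, 1e-4)
        b = OverturnSegment(5.0, 10.0, 1.0, 5e-3, 0, 1e-5)
        kz = cast_kz_profile([a, b], edges, params)
        # weights: L_T * overlap = 2*10 and 1*5
        expect = (20 * 1e-4 + 5 * 1e-5) / 25
        assert kz[0] == pytest.approx(expect, rel=1e-12)

    def test_geomean_single_and_pair(self, params):
        edges = np.arange(0.0, 20.0, 5.0)
        one = np.full(3, 2e-5)
        prof = average_kz([one], edges)
        np.testing.assert_allclose(prof.kz_geomean, 2e-5)
        np.testing.assert_array_equal(prof.n_casts, 1)
        two = average_kz([np.full(3, 1e-6), np.full(3, 1e-4)], edges)
        np.testing.assert_allclose(two.kz_geomean, 1e-5, rtol=1e-12)

    def test_geomean_below_arithmetic_mean(self):
        rng = np.random.default_rng(7)
        edges = np.arange(0.0, 60.0, 5.0)
        casts = [10 ** rng.uniform(-6, -4, edges.size - 1) for _ in range(14)]
        prof = average_kz(casts, edges)
        am = np.mean(np.vstack(casts), axis=0)
        assert np.all(prof.kz_geomean <= am + 1e-18)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            average_kz([], np.arange(0.0, 10.0, 5.0))

    def test_layer_geomean(self):
        prof = DiffusivityProfile(np.array([2.5, 7.5, 12.5]),
                                  np.array([1e-6, 1e-4, 1e-5]),
                                  np.array([3, 3, 3]))
        assert layer_geomean(prof, (0.0, 10.0)) == pytest.approx(1e-5, rel=1e-12)
        with pytest.raises(ValueError):
            layer_geomean(prof, (100.0, 120.0))
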