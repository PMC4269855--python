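import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import helpers
from multicna.io import MarkerMap, SignalMatrix, concatenate_chromosomes, split_by_chromosome
from multicna.segmentation import (
    PenaltySpec,
    SegmentationModel,
    calibrate_rho,
    lavielle_penalty,
    pelt,
    segment_cost,
    segment_fixed_k,
    segment_profile,
    select_k_slope_heuristic,
    smooth_by_segmentation,
    penalty_shape,
)


class TestSegmentCost:
    def test_constant_segment_costs_zero(self):
        assert segment_cost([1.0, 1.0, 1.0], 1, 3) == 0.0

    def test_hand_arithmetic(self):
        assert segment_cost([0.0, 2.0], 1, 2) == pytest.approx(2.0)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            segment_cost([1.0, 2.0], 2, 1)

    def test_matches_two_pass_oracle(self, rng):
        y = rng.normal(size=25)
        for i in range(1, 26):
            for j in range(i, 26):
                assert segment_cost(y, i, j) == pytest.approx(
                    helpers.direct_sse(y, i - 1, j - 1), abs=1e-10
                )


class TestFixedK:
    def test_noiseless_step_recovered(self):
        y = np.concatenate([np.zeros(50), np.full(50, 3.0)])
        seg = segment_fixed_k(y, 3)[1]
        assert seg.K == 2
        assert seg.ends[0] == 50
        assert seg.sse == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_flat_at_k1(self):
        seg = segment_fixed_k(np.full(20, 1.3), 1)[0]
        assert seg.sse == pytest.approx(0.0, abs=1e-9)
        assert seg.means[0] == pytest.approx(1.3)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(15):
            P = int(rng.integers(5, 13))
            y = rng.normal(size=P)
            kmax = min(4, P)
            for seg in segment_fixed_k(y, kmax):
                sse_b, _ = helpers.best_partition_exhaustive(y, seg.K)
                assert seg.sse == pytest.approx(sse_b, abs=1e-9)

    def test_sse_non_increasing_in_k(self, rng):
        y = rng.normal(size=60)
        sses = [s.sse for s in segment_fixed_k(y, 10)]
        assert (np.diff(sses) <= 1e-9).all()

    def test_kmax_validation(self):
        with pytest.raises(ValueError):
            segment_fixed_k(np.ones(3), 4)
        with pytest.raises(ValueError):
            segment_fixed_k(np.array([]), 1)

    def test_fit_reconstruction_matches_sse(self, rng):
        y = rng.normal(size=40)
        for seg in segment_fixed_k(y, 5):
            assert ((y - seg.fitted()) ** 2).sum() == pytest.approx(seg.sse, rel=1e-9)


class TestLaviellePenalty:
    def test_unit_case_is_3_5(self):
        assert lavielle_penalty(1, np.e, 1.0) == pytest.approx(3.5)

    def test_k_equals_p_log_term_vanishes(self):
        assert lavielle_penalty(100, 100, 2.0) == pytest.approx(2.0 * 100 * 2.5)

    def test_direct_arithmetic(self):
        assert lavielle_penalty(2, 100, 1.0) == pytest.approx(2 * (2.5 + np.log(50)))

    def test_validation(self):
        with pytest.raises(ValueError):
            lavielle_penalty(0, 10, 1.0)
        with pytest.raises(ValueError):
            lavielle_penalty(11, 10, 1.0)
        with pytest.raises(ValueError):
            lavielle_penalty(1, 10, -1.0)


class TestSlopeHeuristic:
    def test_exact_line_gives_factor_two(self):
        P, Kmax, s = 500, 20, 0.7
        shape = penalty_shape(np.arange(1, Kmax + 1), P)
        sse = 1000.0 - s * shape
        k_star, c_hat = select_k_slope_heuristic(sse, P)
        assert c_hat == pytest.approx(2 * s, rel=1e-9)
        assert k_star == 1  # penalized criterion increases once C = 2s

    def test_pure_noise_selects_one_segment(self, rng):
        hits = 0
        for _ in range(20):
            y = rng.normal(size=600)
            sse = [s.sse for s in segment_fixed_k(y, 25)]
            k_star, _ = select_k_slope_heuristic(sse, 600)
            hits += k_star == 1
        assert hits >= 18

    def test_planted_segments_recovered(self, rng):
        # 4 segments, gaps of 5 sd
        hits = 0
        for _ in range(20):
            y = np.repeat([0.0, 5.0, 0.0, 5.0], 100) + rng.normal(size=400)
            sse = [s.sse for s in segment_fixed_k(y, 20)]
            k_star, _ = select_k_slope_heuristic(sse, 400)
            hits += k_star == 4
        assert hits >= 18

    def test_rejects_increasing_sse(self):
        with pytest.raises(ValueError):
            select_k_slope_heuristic([5.0, 7.0, 9.0], 100)
        with pytest.raises(ValueError):
            select_k_slope_heuristic([5.0], 100)


class TestPelt:
    def test_noiseless_step(self):
        y = np.concatenate([np.zeros(30), np.full(30, 4.0)])
        seg = pelt(y, 1.0)
        assert seg.K == 2 and seg.ends[0] == 30

    def test_huge_penalty_single_segment(self, rng):
        y = rng.normal(size=100)
        seg = pelt(y, 10 * 100 * y.var())
        assert seg.K == 1

    def test_matches_unpruned_dp(self, rng):
        for _ in range(10):
            P = int(rng.integers(20, 200))
            y = rng.normal(size=P) + np.repeat(
                rng.normal(scale=2, size=4), int(np.ceil(P / 4))
            )[:P]
            for rho in (0.2, 1.0, 5.0):
                ends = pelt(y, rho).ends
                oracle = helpers.penalized_partition_dp(y, rho * np.log(P))
                np.testing.assert_array_equal(ends, oracle)

    def test_rho_validation(self):
        with pytest.raises(ValueError):
            pelt(np.ones(5), 0.0)


class TestCalibrateRho:
    def test_noiseless_three_segments(self):
        y = np.repeat([0.0, 1.0, 2.0], 40)
        rho = calibrate_rho(y)
        assert pelt(y, rho).K == 3

    def test_pure_noise_single_segment(self, rng):
        hits = sum(
            pelt(y, calibrate_rho(y)).K == 1
            for y in rng.normal(size=(20, 500))
        )
        assert hits >= 18

    def test_scale_equivariance(self, rng):
        y = rng.normal(size=300)
        assert calibrate_rho(4.0 * y) == pytest.approx(16.0 * calibrate_rho(y),
                                                       rel=1e-9)

    def test_short_series_fallback_warns(self, rng):
        y = rng.normal(size=10)
        with pytest.warns(UserWarning, match="shorter than 20"):
            calibrate_rho(y)


def _two_chrom_step_signal():
    markers = MarkerMap(
        np.array([f"m{i}" for i in range(200)]),
        np.array(["1"] * 100 + ["2"] * 100),
        np.array(list(range(1000, 101000, 1000)) * 2)[:200],
    )
    y = np.concatenate(
        [np.full(50, 2.0), np.full(50, 3.0), np.full(50, 2.0), np.full(50, 1.0)]
    )
    return SignalMatrix(markers, ["S01"], y[:, None], "copy_number")


class TestSegmentProfile:
    def test_clean_steps_per_chromosome(self):
        sig = _two_chrom_step_signal()
        table = segment_profile(sig, "S01")
        assert len(table) == 4
        assert list(table["chromosome"]) == ["1", "1", "2", "2"]
        np.testing.assert_allclose(table["mean"], [2.0, 3.0, 2.0, 1.0])
        # intervals bounded by their marker positions (0-based half-open)
        assert table.loc[0, "end"] == 50_000          # last marker of segment 1
        assert table.loc[1, "start"] == 51_000 - 1    # first marker of segment 2

    def test_pelt_route_matches_on_noiseless_input(self):
        sig = _two_chrom_step_signal()
        a = segment_profile(sig, "S01", "lavielle_slope_heuristic")
        b = segment_profile(sig, "S01", "pelt_log")
        pd.testing.assert_frame_equal(a, b)

    def test_chromosome_independence(self, rng):
        sig = _two_chrom_step_signal()
        noisy = SignalMatrix(
            sig.markers, sig.samples, sig.values + rng.normal(0, 0.1, sig.values.shape),
            "copy_number",
        )
        whole = segment_profile(noisy, "S01")
        parts = split_by_chromosome(noisy)
        per_chrom = pd.concat(
            [segment_profile(p, "S01") for p in parts], ignore_index=True
        )
        pd.testing.assert_frame_equal(whole, per_chrom)

    def test_unknown_sample(self):
        with pytest.raises(KeyError, match="unknown sample"):
            segment_profile(_two_chrom_step_signal(), "nope")

    def test_tiny_chromosome_trivial_segment(self, rng):
        markers = MarkerMap(np.array(["a", "b"]), np.array(["1", "2"]),
                            np.array([100, 100]))
        sig = SignalMatrix(markers, ["S"], rng.normal(2, 0.1, (2, 1)), "copy_number")
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = segment_profile(sig, "S")
        assert len(table) == 2
        assert (table["n_probes"] == 1).all()


class TestShiftInvariance:
    @given(st.floats(-50, 50), st.integers(0, 2**31 - 1))
    def test_breakpoints_unchanged_by_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        y = np.repeat(rng.normal(scale=3, size=3), 30) + rng.normal(size=90)
        sse = [s.sse for s in segment_fixed_k(y, 10)]
        k1, _ = select_k_slope_heuristic(sse, 90)
        a = segment_fixed_k(y, 10)[k1 - 1]
        b_all = segment_fixed_k(y + shift, 10)
        sse2 = [s.sse for s in b_all]
        k2, _ = select_k_slope_heuristic(sse2, 90)
        assert k1 == k2
        np.testing.assert_array_equal(a.ends, b_all[k2 - 1].ends)
        np.testing.assert_array_equal(pelt(y, 2.0).ends, pelt(y + shift, 2.0).ends)


class TestSmoothing:
    def test_single_segment_gives_global_mean(self, toy_signal):
        res = SegmentationModel(toy_signal, "cghseg").fit()
        sm = smooth_by_segmentation(toy_signal, res.segments)
        assert sm.values.shape == toy_signal.values.shape

    def test_idempotence_and_sse_identity(self):
        sig = _two_chrom_step_signal()
        rng = np.random.default_rng(4)
        noisy = SignalMatrix(
            sig.markers, sig.samples, sig.values + rng.normal(0, 0.15, sig.values.shape),
            "copy_number",
        )
        res = SegmentationModel(noisy).fit()
        once = smooth_by_segmentation(noisy, res.segments)
        twice = smooth_by_segmentation(once, res.segments)
        np.testing.assert_allclose(once.values, twice.values)
        # SSE between raw and smoothed equals the summed per-segment SSE
        sse = float(((noisy.values - once.values) ** 2).sum())
        assert sse == pytest.approx(res.sse("S01"), rel=1e-9)

    def test_uncovered_marker_is_error(self, toy_signal):
        res = SegmentationModel(toy_signal).fit()
        partial = res.segments.iloc[:-1]
        with pytest.raises(ValueError, match="not covered"):
            smooth_by_segmentation(toy_signal, partial)


class TestModelInterface:
    def test_results_summary_and_penalty_spec(self, toy_signal):
        res = SegmentationModel(toy_signal, "pelt", rho=1.0).fit(["S01"])
        assert "pelt" in res.summary()
        assert set(res.segments["sample"]) == {"S01"}
        with pytest.raises(ValueError):
            PenaltySpec(method="nope")
        with pytest.raises(ValueError):
            PenaltySpec(rho=-1.0, method="pelt_log")
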