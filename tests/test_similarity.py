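"""Overlap integral, weight decomposition, and uncertainty profiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import roafit as rf
from roafit.similarity import _FitKernel, simplex_grid_iter

GRID = rf.DEFAULT_GRID


def noisy_spectrum(seed: int) -> rf.ContinuousSpectrum:
    rng = np.random.default_rng(seed)
    return rf.ContinuousSpectrum(GRID, rng.normal(size=GRID.n_points), "raman")


class TestOverlap:
    def test_self_overlap_is_one(self):
        s = noisy_spectrum(0)
        assert rf.overlap(s, s) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(1e-6, 1e6), seed=st.integers(0, 100))
    def test_scale_invariance(self, scale, seed):
        s = noisy_spectrum(seed)
        scaled = rf.ContinuousSpectrum(GRID, scale * s.values, "raman")
        assert rf.overlap(s, scaled) == pytest.approx(1.0, abs=1e-9)

    def test_sign_flip(self):
        s = noisy_spectrum(1)
        neg = rf.ContinuousSpectrum(GRID, -s.values, "raman")
        assert rf.overlap(s, neg) == pytest.approx(-1.0, abs=1e-12)

    def test_bounded_and_symmetric_on_random_pairs(self):
        for seed in range(50):
            a, b = noisy_spectrum(2 * seed), noisy_spectrum(2 * seed + 1)
            s_ab = rf.overlap(a, b)
            assert -1.0 <= s_ab <= 1.0
            assert s_ab == pytest.approx(rf.overlap(b, a), abs=1e-14)

    def test_lorentzian_closed_form(self, fine_grid):
        # equal-width unit-area Lorentzians: S = 1 / (1 + (delta/gamma)^2)
        gamma = 7.5
        for delta in (3.75, 7.5, 15.0):
            a = rf.broaden(rf.LineSpectrum([1000.0], [1.0], [0.0]), fine_grid, gamma)
            b = rf.broaden(rf.LineSpectrum([1000.0 + delta], [1.0], [0.0]), fine_grid, gamma)
            expect = 1.0 / (1.0 + (delta / gamma) ** 2)
            assert rf.overlap(a.raman, b.raman) == pytest.approx(expect, abs=5e-3)

    def test_zero_norm_rejected(self):
        zero = rf.ContinuousSpectrum(GRID, np.zeros(GRID.n_points), "raman")
        with pytest.raises(ValueError):
            rf.overlap(zero, noisy_spectrum(3))

    def test_window_restricts_integral(self):
        a, b = noisy_spectrum(4), noisy_spectrum(5)
        w = rf.WavenumberGrid(400.0, 800.0, 1.0)
        sel = (GRID.points >= 400) & (GRID.points <= 800)
        manual = np.trapezoid(a.values[sel] * b.values[sel], GRID.points[sel]) / np.sqrt(
            np.trapezoid(a.values[sel] ** 2, GRID.points[sel])
            * np.trapezoid(b.values[sel] ** 2, GRID.points[sel])
        )
        assert rf.overlap(a, b, w) == pytest.approx(manual, abs=1e-12)


class TestCompose:
    def test_single_label_identity(self, conformers4):
        one = rf.ConformerSpectra((conformers4.labels[0],), (conformers4.pairs[0],))
        out = rf.compose({conformers4.labels[0]: 1.0}, one)
        np.testing.assert_array_equal(out.raman.values, conformers4.pairs[0].raman.values)

    def test_weighted_sum_matches_arithmetic(self, conformers4):
        w = np.array([0.7, 0.3, 0.0, 0.0])
        out = rf.compose(w, conformers4)
        manual = 0.7 * conformers4.pairs[0].raman.values + 0.3 * conformers4.pairs[1].raman.values
        np.testing.assert_allclose(out.raman.values, manual, rtol=1e-14)

    def test_equal_spectra_any_simplex_weights(self, conformers4):
        dup = rf.ConformerSpectra(("a", "b"), (conformers4.pairs[0], conformers4.pairs[0]))
        out = rf.compose(np.array([0.2, 0.8]), dup)
        np.testing.assert_allclose(out.roa.values, conformers4.pairs[0].roa.values, rtol=1e-12)

    def test_label_mismatch_rejected(self, conformers4):
        with pytest.raises(ValueError):
            rf.compose({"bogus": 1.0}, conformers4)


class TestCost:
    def test_zero_for_exact_composition(self, conformers4):
        w = np.array([0.25, 0.25, 0.25, 0.25])
        exp = rf.compose(w, conformers4)
        assert rf.cost(w, conformers4, exp) == pytest.approx(0.0, abs=1e-12)

    def test_printed_overlap_arithmetic(self):
        # S_Raman = 0.950, S_ROA = 0.844 combine to F = 0.026836
        sol = rf.WeightSolution(
            labels=("x",), weights=np.array([1.0]), s_raman=0.950, s_roa=0.844, f=0.026836
        )
        assert sol.f == pytest.approx((1 - 0.950) ** 2 + (1 - 0.844) ** 2, abs=1e-12)

    def test_anticorrelated_roa_costs_four(self, conformers4):
        pair = conformers4.pairs[0]
        flipped = rf.SpectrumPair(
            pair.raman, rf.ContinuousSpectrum(pair.grid, -pair.roa.values, "roa")
        )
        one = rf.ConformerSpectra(("a",), (pair,))
        assert rf.cost(np.array([1.0]), one, flipped) == pytest.approx(4.0, abs=1e-9)


class TestFitWeights:
    def test_vertex_optimum(self, conformers3):
        exp = conformers3.pairs[1]
        sol = rf.fit_weights(conformers3, exp, compute_intervals=False)
        assert sol.weights[1] == pytest.approx(1.0, abs=1e-3)

    def test_four_conformer_recovery_and_oracle(self, conformers4):
        w_true = np.array([0.48, 0.31, 0.07, 0.12])
        w_true = w_true / w_true.sum()
        mix, _ = rf.gen_mixture(conformers4, w_true, 0.0, seed=1)
        sol = rf.fit_weights(conformers4, mix, compute_intervals=False)
        np.testing.assert_allclose(sol.weights, w_true, atol=1e-2)
        kernel = _FitKernel(conformers4, mix, None)
        f_grid = min(
            float(
                np.min(
                    (1 - kernel.s_batch(W, "raman")) ** 2 + (1 - kernel.s_batch(W, "roa")) ** 2
                )
            )
            for W in simplex_grid_iter(4, 100)
        )
        assert sol.f <= f_grid + 1e-6

    def test_noisy_recovery_and_oracle(self, conformers3):
        w_true = np.array([0.5, 0.3, 0.2])
        mix, _ = rf.gen_mixture(conformers3, w_true, 0.05, seed=2)
        sol = rf.fit_weights(conformers3, mix, compute_intervals=False)
        np.testing.assert_allclose(sol.weights, w_true, atol=0.05)
        kernel = _FitKernel(conformers3, mix, None)
        f_grid = min(
            float(
                np.min(
                    (1 - kernel.s_batch(W, "raman")) ** 2 + (1 - kernel.s_batch(W, "roa")) ** 2
                )
            )
            for W in simplex_grid_iter(3, 100)
        )
        assert sol.f <= f_grid + 1e-6

    def test_never_worse_than_any_vertex(self, conformers4):
        mix, _ = rf.gen_mixture(conformers4, np.array([0.4, 0.3, 0.2, 0.1]), 0.1, seed=3)
        sol = rf.fit_weights(conformers4, mix, compute_intervals=False)
        kernel = _FitKernel(conformers4, mix, None)
        for i in range(4):
            assert sol.f <= kernel.cost(np.eye(4)[i]) + 1e-12

    def test_duplicate_conformer_never_increases_f(self, conformers3):
        mix, _ = rf.gen_mixture(conformers3, np.array([0.6, 0.3, 0.1]), 0.02, seed=4)
        base = rf.fit_weights(conformers3, mix, compute_intervals=False)
        extended = rf.ConformerSpectra(
            conformers3.labels + ("dup",), conformers3.pairs + (conformers3.pairs[0],)
        )
        ext = rf.fit_weights(extended, mix, compute_intervals=False)
        assert ext.f <= base.f + 1e-9

    def test_degenerate_spectra_flagged(self, conformers4):
        dup = rf.ConformerSpectra(("a", "b"), (conformers4.pairs[0], conformers4.pairs[0]))
        sol = rf.fit_weights(dup, conformers4.pairs[0], compute_intervals=False)
        assert not sol.identifiable
        assert sol.f == pytest.approx(0.0, abs=1e-10)

    def test_single_label_returns_weight_one(self, conformers4):
        one = rf.ConformerSpectra(("only",), (conformers4.pairs[0],))
        sol = rf.fit_weights(one, conformers4.pairs[1], compute_intervals=False)
        assert sol.weights[0] == 1.0

    def test_deterministic_given_seed(self, conformers3):
        mix, _ = rf.gen_mixture(conformers3, np.array([0.5, 0.25, 0.25]), 0.05, seed=5)
        a = rf.fit_weights(conformers3, mix, random_state=42, compute_intervals=False)
        b = rf.fit_weights(conformers3, mix, random_state=42, compute_intervals=False)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestWeightUncertainty:
    def test_duplicate_spectra_full_intervals(self, conformers4):
        dup = rf.ConformerSpectra(("a", "b"), (conformers4.pairs[0], conformers4.pairs[0]))
        sol = rf.fit_weights(dup, conformers4.pairs[0])
        np.testing.assert_allclose(sol.intervals[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(sol.intervals[:, 1], 1.0, atol=1e-9)

    def test_threshold_one_collapses_to_cooptima(self, conformers3):
        w_true = np.array([0.5, 0.3, 0.2])
        mix, _ = rf.gen_mixture(conformers3, w_true, 0.0, seed=6)
        sol = rf.fit_weights(conformers3, mix, threshold=1.0)
        widths = sol.intervals[:, 1] - sol.intervals[:, 0]
        assert np.all(widths <= 0.02 + 1e-9)

    def test_interval_nesting(self, conformers3):
        mix, _ = rf.gen_mixture(conformers3, np.array([0.5, 0.3, 0.2]), 0.02, seed=7)
        lo = rf.fit_weights(conformers3, mix, threshold=0.99)
        hi = rf.fit_weights(conformers3, mix, threshold=0.999)
        assert np.all(hi.intervals[:, 0] >= lo.intervals[:, 0] - 1e-12)
        assert np.all(hi.intervals[:, 1] <= lo.intervals[:, 1] + 1e-12)

    def test_intervals_contain_best_fit(self, conformers4):
        mix, _ = rf.gen_mixture(conformers4, np.array([0.4, 0.3, 0.2, 0.1]), 0.05, seed=8)
        sol = rf.fit_weights(conformers4, mix)
        assert np.all(sol.weights >= sol.intervals[:, 0] - 1e-12)
        assert np.all(sol.weights <= sol.intervals[:, 1] + 1e-12)

    def test_function_wrapper_matches_estimator(self, conformers3):
        mix, _ = rf.gen_mixture(conformers3, np.array([0.6, 0.2, 0.2]), 0.0, seed=9)
        sol = rf.fit_weights(conformers3, mix)
        iv = rf.weight_uncertainty(sol, conformers3, mix)
        np.testing.assert_allclose(iv, sol.intervals, atol=1e-12)


def test_simplex_grid_enumeration_count():
    # compositions of 10 into 3 parts: C(12, 2) = 66
    total = sum(len(W) for W in simplex_grid_iter(3, 10))
    assert total == 66
    for W in simplex_grid_iter(3, 10):
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)


def test_estimator_sklearn_params_roundtrip():
    est = rf.SpectralDecomposer(threshold=0.95, random_state=3)
    params = est.get_params()
    clone = rf.SpectralDecomposer(**params)
    assert clone.get_params() == params
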