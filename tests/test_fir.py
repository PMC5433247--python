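"""FIR fitting, AIC order selection, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcorrnet import (
    aic,
    fit_fir,
    least_squares_cost,
    max_taps_from_seconds,
    predict,
    select_order,
)
from pcorrnet.errors import InputError
from pcorrnet.fir import FirFit, lagged_design


def normal_equation_solve(x_src, x_tgt, n_taps):
    """Independent dense linear-algebra oracle for the unconstrained fit."""
    X = np.zeros((len(x_src), n_taps))
    for m in range(n_taps):
        X[m:, m] = x_src[: len(x_src) - m]
    return np.linalg.solve(X.T @ X, X.T @ x_tgt)


class TestPredict:
    @pytest.mark.parametrize(
        "x_src, h, expected",
        [
            ([1, 0, 0, 0], [0, 0.5], [0, 0.5, 0, 0]),  # impulse through delay tap
            ([3.0, -1.0, 2.0], [1.0], [3.0, -1.0, 2.0]),  # identity filter
            ([1, 2, 3], [1, 1], [1, 3, 5]),  # hand convolution, zero-padded
        ],
    )
    def test_known_convolutions(self, x_src, h, expected):
        out = predict(np.asarray(x_src, float), np.asarray(h, float))
        assert np.allclose(out, expected)

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            predict(np.array([]), np.array([1.0]))


class TestLeastSquaresCost:
    def test_perfect_and_simple_costs(self):
        assert least_squares_cost(np.ones(5), np.ones(5)) == 0.0
        assert least_squares_cost(np.array([1.0, 1.0]), np.zeros(2)) == 2.0

    def test_exact_two_tap_fit_reaches_zero_cost(self):
        x_src = np.array([1.0, 0, 0, 0, 0, 0])
        x_tgt = np.array([0, 0.5, 0, 0, 0, 0])
        fit = fit_fir(x_src, x_tgt, 2, constrained=False)
        assert fit.cost == pytest.approx(0.0, abs=1e-24)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            least_squares_cost(np.ones(3), np.ones(4))


class TestFitFir:
    def test_identity_pair_single_tap(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        fit = fit_fir(x, x, 1, constrained=False)
        assert np.allclose(fit.coefficients, [1.0])
        assert fit.cost == pytest.approx(0.0, abs=1e-20)

    def test_nnls_clips_negated_pair_to_zero(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        fit = fit_fir(x, -x, 1, constrained=True)
        assert np.allclose(fit.coefficients, [0.0])
        assert fit.cost == pytest.approx(np.sum(x**2))

    def test_unconstrained_matches_normal_equations(self, rng):
        x_src = rng.standard_normal(200)
        x_tgt = rng.standard_normal(200)
        fit = fit_fir(x_src, x_tgt, 3, constrained=False)
        assert np.allclose(fit.coefficients, normal_equation_solve(x_src, x_tgt, 3))

    def test_constrained_cost_never_below_unconstrained(self, rng):
        for _ in range(10):
            x_src = rng.standard_normal(100)
            x_tgt = rng.standard_normal(100)
            j_un = fit_fir(x_src, x_tgt, 4, constrained=False).cost
            j_con = fit_fir(x_src, x_tgt, 4, constrained=True).cost
            assert j_con >= j_un - 1e-10

    def test_constrained_fit_satisfies_kkt(self, rng):
        for _ in range(20):
            x_src = rng.standard_normal(150)
            x_tgt = rng.standard_normal(150)
            fit = fit_fir(x_src, x_tgt, 6, constrained=True)
            X = lagged_design(x_src, 6)
            grad = X.T @ (X @ fit.coefficients - x_tgt)  # half-gradient of J
            active = fit.coefficients > 0
            assert np.all(np.abs(grad[active]) < 1e-8 * max(1, np.abs(grad).max()))
            assert np.all(grad[~active] >= -1e-8 * max(1, np.abs(grad).max()))

    def test_single_tap_closed_form(self, rng):
        x_src = rng.standard_normal(80)
        x_tgt = rng.standard_normal(80)
        x_src -= x_src.mean()
        x_tgt -= x_tgt.mean()
        beta = (x_tgt @ x_src) / (x_src @ x_src)
        assert fit_fir(x_src, x_tgt, 1, False).coefficients[0] == pytest.approx(beta)
        assert fit_fir(x_src, x_tgt, 1, True).coefficients[0] == pytest.approx(
            max(beta, 0.0)
        )

    def test_constant_zero_source_constrained_gives_zero_filter(self):
        fit = fit_fir(np.zeros(20), np.ones(20), 2, constrained=True)
        assert np.allclose(fit.coefficients, 0.0)

    def test_too_many_taps_rejected(self):
        with pytest.raises(InputError):
            fit_fir(np.ones(4), np.ones(4), 5, constrained=False)


class TestAic:
    def test_frozen_large_sample_value(self):
        # independently transcribed: 1000*log(2*pi*100/997) + 1000 + 3
        assert aic(100.0, 1000, 3) == pytest.approx(541.2964824355986, rel=1e-12)

    def test_small_sample_branch_adds_correction_term(self):
        # Nx/Nh = 33.3 < 40: branch-2 = branch-1 + 2*3*4/96
        base = 100 * np.log(2 * np.pi * 100.0 / 97) + 100 + 3
        assert aic(100.0, 100, 3) == pytest.approx(base + 2 * 3 * 4 / 96, rel=1e-12)

    def test_monotone_in_taps_for_fixed_cost(self):
        values = [aic(50.0, 1000, n_h) for n_h in range(1, 10)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_perfect_fit_returns_neg_inf(self):
        assert aic(0.0, 100, 2) == -np.inf

    def test_degenerate_sample_size_rejected(self):
        with pytest.raises(InputError):
            aic(1.0, 4, 3)


class TestSelectOrder:
    def test_single_candidate_returned(self, rng):
        x_src = rng.standard_normal(50)
        x_tgt = rng.standard_normal(50)
        fit = select_order(x_src, x_tgt, 1, constrained=False)
        assert fit.n_taps == 1

    def test_detects_two_sample_delay(self, rng):
        # y[n] = x[n-2] + small noise: the selected filter must reach lag 2;
        # AIC occasionally overfits by a tap (P(chi2_1 > 2) ~ 0.16) but the
        # exact order should still win most replicates
        exact = 0
        for _ in range(10):
            x = rng.standard_normal(2000)
            y = np.roll(x, 2)
            y[:2] = 0.0
            y = y + 0.05 * rng.standard_normal(2000)
            fit = select_order(x, y, 5, constrained=False)
            assert fit.n_taps >= 3  # never misses the true lag
            exact += fit.n_taps == 3
        assert exact >= 6

    def test_exhaustive_aic_minimum(self, rng):
        x_src = rng.standard_normal(300)
        x_tgt = rng.standard_normal(300)
        fits = [fit_fir(x_src, x_tgt, k, True) for k in range(1, 6)]
        best = min(fits, key=lambda f: f.aic_value)
        assert select_order(x_src, x_tgt, 5, True).n_taps == best.n_taps

    def test_scale_invariance_of_selection(self, rng):
        x_src = rng.standard_normal(400)
        x_tgt = 0.5 * np.roll(x_src, 1) + rng.standard_normal(400)
        a = select_order(x_src, x_tgt, 4, constrained=False)
        b = select_order(7.5 * x_src, x_tgt, 4, constrained=False)
        assert a.n_taps == b.n_taps
        assert np.allclose(b.coefficients * 7.5, a.coefficients)
        assert a.cost == pytest.approx(b.cost, rel=1e-9)
        assert a.aic_value == pytest.approx(b.aic_value, rel=1e-9)

    def test_excessive_max_taps_rejected(self, rng):
        with pytest.raises(InputError):
            select_order(rng.standard_normal(10), rng.standard_normal(10), 5, False)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 6))
def test_unconstrained_cost_non_increasing_in_taps(seed, max_taps):
    rng = np.random.default_rng(seed)
    x_src = rng.standard_normal(60)
    x_tgt = rng.standard_normal(60)
    costs = [fit_fir(x_src, x_tgt, k, False).cost for k in range(1, max_taps + 1)]
    assert all(b <= a + 1e-9 for a, b in zip(costs, costs[1:]))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_constrained_equals_unconstrained_when_solution_nonnegative(seed):
    rng = np.random.default_rng(seed)
    x_src = rng.standard_normal(120)
    x_tgt = 0.8 * x_src + 0.3 * np.roll(x_src, 1) + 0.1 * rng.standard_normal(120)
    un = fit_fir(x_src, x_tgt, 2, False)
    con = fit_fir(x_src, x_tgt, 2, True)
    if np.all(un.coefficients >= 0):
        assert np.allclose(con.coefficients, un.coefficients, atol=1e-8)
        assert con.cost == pytest.approx(un.cost, rel=1e-9)


class TestMaxTapsFromSeconds:
    @pytest.mark.parametrize(
        "window, tr, expected", [(15, 3, 5), (1, 3, 1), (15, 1, 15), (10, 2.5, 4)]
    )
    def test_conversion(self, window, tr, expected):
        assert max_taps_from_seconds(window, tr) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            max_taps_from_seconds(0, 1)


def test_firfit_validates_consistency():
    with pytest.raises(InputError):
        FirFit(np.array([1.0, 2.0]), 3, 0.0, 0.0, False)
    with pytest.raises(InputError):
        FirFit(np.array([-1.0]), 1, 0.0, 0.0, True)
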