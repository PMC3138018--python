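import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmbme.covariance import (
    CovarianceModel,
    EmpiricalCovariance,
    covariance_matrix,
    empirical_covariance_matrix,
    evaluate_covariance,
    fit_nested_exponential,
    safe_cholesky,
)
from pmbme.synthetic import simulate_st_field


class TestEvaluate:
    def test_zero_lag_is_total_sill(self, nested_model):
        # c0 + c1 = 10.5 + 3.729
        assert evaluate_covariance(nested_model, 0.0, 0.0) == pytest.approx(14.229)

    def test_short_spatial_range_value(self, nested_model):
        # at h = ar1: c0 e^-3 + c1 e^(-3 h / ar2)
        expected = 10.5 * np.exp(-3.0) + 3.729 * np.exp(-3.0 * 11.092 / 50.0)
        got = evaluate_covariance(nested_model, 11.092, 0.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.4395, abs=5e-4)

    def test_decay_limit(self, nested_model):
        assert evaluate_covariance(nested_model, 1e6, 0.0) < 1e-12

    def test_negative_lag_rejected(self, nested_model):
        with pytest.raises(ValueError):
            evaluate_covariance(nested_model, -1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        h=st.floats(0, 100), tau=st.floats(0, 60),
        dh=st.floats(0, 50), dt=st.floats(0, 20),
    )
    def test_monotone_nonincreasing_in_each_lag(self, h, tau, dh, dt):
        from pmbme.covariance import PM25_NESTED_MODEL as model

        base = evaluate_covariance(model, h, tau)
        assert evaluate_covariance(model, h + dh, tau) <= base + 1e-12
        assert evaluate_covariance(model, h, tau + dt) <= base + 1e-12

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CovarianceModel(c0=-1, c1=1, ar1=1, ar2=2, at1=1, at2=2)
        with pytest.raises(ValueError, match="ordering"):
            CovarianceModel(c0=1, c1=1, ar1=5, ar2=2, at1=1, at2=2)


class TestEmpirical:
    def test_two_station_hand_value(self):
        # one month, values (+a, -a), global mean removed -> product -a^2
        a = 3.0
        vals = np.array([[a, a], [-a, -a]])  # need >= 2 months
        coords = np.array([[0.0, 0.0], [4.0, 0.0]])
        emp = empirical_covariance_matrix(vals, coords, spatial_bin_width=2.0,
                                          max_tau=1, max_h=6.0)
        # h = 4 falls in the (2, 4] bin (index 2 after the h=0 cell)
        assert emp.h_centers[0] == 0.0
        assert emp.values[2, 0] == pytest.approx(-a * a)
        assert emp.counts[2, 0] == 2  # one pair x two months

    def test_empty_cells_are_missing_not_zero(self):
        vals = np.array([[1.0, -1.0], [0.5, 2.0]])
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        emp = empirical_covariance_matrix(vals, coords, spatial_bin_width=0.4,
                                          max_tau=1, max_h=2.0)
        empty = emp.counts == 0
        assert empty.any()
        assert np.isnan(emp.values[empty]).all()

    def test_white_noise_structure(self, rng):
        n_sites, n_months = 40, 10
        coords = rng.uniform(0, 50, size=(n_sites, 2))
        vals = rng.normal(0, 2.0, size=(n_sites, n_months))
        emp = empirical_covariance_matrix(vals, coords, spatial_bin_width=5.0, max_tau=3)
        assert emp.values[0, 0] == pytest.approx(vals.var(), rel=0.05)
        # off-origin cells: mean 0 with SE ~ sigma^2 / sqrt(n_pairs)
        se = 4.0 / np.sqrt(np.maximum(emp.counts[1:, 1:], 1))
        ok = emp.counts[1:, 1:] > 30
        assert np.all(np.abs(emp.values[1:, 1:][ok]) < 3 * se[ok] + 1e-12)

    def test_simulate_then_estimate_consistency(self, nested_model):
        # moderate grid: empirical curve tracks the closed form at key lags
        xs = np.linspace(0, 150, 16)
        X, Y = np.meshgrid(xs, xs)
        coords = np.column_stack([X.ravel(), Y.ravel()])
        probes = [(0.0, 0), (10.0, 0), (0.0, 1), (0.0, 3)]
        rel_errs = {p: [] for p in probes}
        for seed in range(3):
            f = simulate_st_field(nested_model, coords, 80, seed=seed)
            emp = empirical_covariance_matrix(f, coords, 2.0, 4)
            for h, tau in probes:
                i = 0 if h == 0 else int(h / 2.0)
                truth = evaluate_covariance(nested_model, emp.h_centers[i], float(tau))
                rel_errs[(h, tau)].append(emp.values[i, tau] / truth - 1.0)
        for p, errs in rel_errs.items():
            assert abs(np.mean(errs)) < 0.25, (p, errs)


class TestFit:
    def test_exact_recovery_from_closed_form_cells(self, nested_model):
        h = np.arange(0, 60, 2.0)
        tau = np.arange(0, 13.0)
        hh, tt = np.meshgrid(h, tau, indexing="ij")
        vals = evaluate_covariance(nested_model, hh, tt)
        emp = EmpiricalCovariance(h_centers=h, tau_lags=tau, values=vals,
                                  counts=np.full(vals.shape, 100.0))
        fit = fit_nested_exponential(emp, random_state=0)
        for name in ("c0", "c1", "ar1", "ar2", "at1", "at2"):
            assert getattr(fit, name) == pytest.approx(
                getattr(nested_model, name), rel=5e-4
            ), name

    def test_single_structure_boundary(self):
        truth = CovarianceModel(c0=8.0, c1=1e-8, ar1=10.0, ar2=10.0, at1=2.0, at2=2.0)
        h = np.arange(0, 40, 2.0)
        tau = np.arange(0, 9.0)
        hh, tt = np.meshgrid(h, tau, indexing="ij")
        vals = evaluate_covariance(truth, hh, tt)
        emp = EmpiricalCovariance(h_centers=h, tau_lags=tau, values=vals,
                                  counts=np.full(vals.shape, 50.0))
        fit = fit_nested_exponential(emp, random_state=1)
        assert fit.c1 <= 0.01 * fit.c0
        assert fit.c0 == pytest.approx(8.0, rel=0.01)

    def test_too_few_cells_rejected(self):
        emp = EmpiricalCovariance(
            h_centers=np.array([0.0, 2.0]), tau_lags=np.array([0.0]),
            values=np.array([[5.0], [3.0]]), counts=np.array([[4.0], [4.0]]),
        )
        with pytest.raises(ValueError, match="6"):
            fit_nested_exponential(emp)


class TestPositiveDefiniteness:
    def test_factorization_with_bounded_jitter(self, nested_model, rng):
        pts = np.column_stack([
            rng.uniform(0, 40, 60), rng.uniform(0, 40, 60), rng.integers(0, 36, 60),
        ])
        mat = covariance_matrix(nested_model, pts)
        L = safe_cholesky(mat)  # raises if jitter > 1e-8 * c(0,0) would be needed
        err = np.max(np.abs(L @ L.T - mat))
        assert err <= 1e-7 * nested_model.sill
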