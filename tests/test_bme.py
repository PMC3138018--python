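import numpy as np
import pytest
from scipy import stats

from pmbme.bme import (
    BMEInterpolator,
    GeneralKB,
    HardData,
    SoftIntervalData,
    bme_estimate,
    gaussian_rectangle_prob,
    posterior_pdf,
    select_neighborhood,
    simple_kriging,
)
from pmbme.covariance import covariance_matrix, safe_cholesky


@pytest.fixture
def kb(nested_model):
    return GeneralKB(mean=5.0, covariance=nested_model)


def random_config(gen, n, spread=40.0):
    pts = np.column_stack([
        gen.uniform(0, spread, n), gen.uniform(0, spread, n),
        gen.integers(0, 36, n).astype(float),
    ])
    vals = gen.normal(5.0, 3.0, n)
    return pts, vals


class TestNeighborhood:
    def test_all_selected_when_fewer_than_cap(self, kb, rng):
        pts, vals = random_config(rng, 3)
        hard = HardData(pts, vals)
        nb = select_neighborhood([1.0, 1.0, 0.0], hard, None, 10, 0, kb.covariance)
        assert set(nb.hard_idx) == {0, 1, 2}

    def test_colocated_point_ranked_first(self, kb, rng):
        pts, vals = random_config(rng, 6)
        pk = pts[4].copy()
        hard = HardData(pts, vals)
        nb = select_neighborhood(pk, hard, None, 3, 0, kb.covariance)
        assert nb.hard_idx[0] == 4
        assert nb.hard_dist[0] == 0.0

    def test_matches_brute_force_sort(self, kb, rng):
        pts, vals = random_config(rng, 50)
        pk = np.array([20.0, 20.0, 18.0])
        nb = select_neighborhood(pk, HardData(pts, vals), None, 50, 0, kb.covariance)
        m = kb.covariance
        d = np.sqrt(
            (np.hypot(pts[:, 0] - pk[0], pts[:, 1] - pk[1]) / m.ar1) ** 2
            + (np.abs(pts[:, 2] - pk[2]) / m.at1) ** 2
        )
        assert np.array_equal(nb.hard_idx, np.argsort(d, kind="stable"))


class TestRectangleProb:
    def test_against_independent_mvn_oracle(self, rng):
        # deterministic Genz/QMC vs scipy's multivariate normal CDF
        for dim in (2, 3, 4):
            A = rng.normal(size=(dim, dim))
            cov = A @ A.T + dim * np.eye(dim)
            means = rng.normal(0, 1, size=(5, dim))
            lower = -rng.uniform(0.5, 2, dim)
            upper = rng.uniform(0.5, 2, dim)
            mine = gaussian_rectangle_prob(lower, upper, means, cov)
            from scipy.stats import multivariate_normal as mvn

            ref = np.array([
                mvn.cdf(upper, mean=m, cov=cov, lower_limit=lower) for m in means
            ])
            assert np.allclose(mine, ref, atol=2e-3), dim

    def test_deterministic(self, rng):
        cov = np.array([[2.0, 0.8], [0.8, 1.5]])
        means = rng.normal(size=(3, 2))
        a = gaussian_rectangle_prob([-1, -1], [1, 1], means, cov)
        b = gaussian_rectangle_prob([-1, -1], [1, 1], means, cov)
        assert np.array_equal(a, b)


class TestPosterior:
    def test_hard_only_equals_simple_kriging(self, kb):
        gen = np.random.default_rng(0)
        for _ in range(100):
            pts, vals = random_config(gen, int(gen.integers(1, 11)))
            pk = np.array([gen.uniform(0, 40), gen.uniform(0, 40),
                           float(gen.integers(0, 36))])
            pdf = posterior_pdf(pk, pts, vals, None, kb)
            est = bme_estimate(pdf)
            m, v = simple_kriging(pk, pts, vals, kb)
            assert abs(est.mean - m) < 1e-6
            assert abs(est.variance - v) < 1e-6

    def test_colocated_soft_is_truncated_normal(self, kb, nested_model):
        pk = np.array([10.0, 10.0, 5.0])
        soft = SoftIntervalData(pk[None, :], [4.0], [7.0])
        pdf = posterior_pdf(pk, np.empty((0, 3)), np.empty(0), soft, kb)
        est = bme_estimate(pdf)
        s = np.sqrt(nested_model.sill)
        tn = stats.truncnorm((4 - 5) / s, (7 - 5) / s, loc=5.0, scale=s)
        assert est.mean == pytest.approx(tn.mean(), abs=1e-6)
        assert est.variance == pytest.approx(tn.var(), abs=1e-6)

    def test_vacuous_interval_ignored(self, kb, rng):
        pts, vals = random_config(rng, 5)
        pk = np.array([12.0, 9.0, 3.0])
        soft = SoftIntervalData(np.array([[15.0, 15.0, 3.0]]), [-1e6], [1e6])
        with_soft = posterior_pdf(pk, pts, vals, soft, kb)
        without = posterior_pdf(pk, pts, vals, None, kb)
        assert np.max(np.abs(with_soft.density - without.density)) < 1e-6

    def test_normalization_across_random_corpus(self, kb):
        gen = np.random.default_rng(42)
        for _ in range(30):
            pts, vals = random_config(gen, int(gen.integers(0, 8)))
            n_soft = int(gen.integers(0, 4))
            soft = None
            if n_soft:
                spts, _ = random_config(gen, n_soft)
                mid = gen.normal(5, 2, n_soft)
                w = gen.uniform(0.5, 4, n_soft)
                soft = SoftIntervalData(spts, mid - w / 2, mid + w / 2)
            pk = np.array([gen.uniform(0, 40), gen.uniform(0, 40),
                           float(gen.integers(0, 36))])
            pdf = posterior_pdf(pk, pts, vals, soft, kb)
            integral = np.trapezoid(pdf.density, pdf.grid)
            assert abs(integral - 1.0) < 1e-6

    def test_soft_to_hard_continuity(self, kb):
        v0 = 6.0
        pk = np.array([11.0, 10.0, 5.0])
        sk_mean, _ = simple_kriging(pk, np.array([[10.0, 10.0, 5.0]]), [v0], kb)
        gaps = []
        for w in (1.0, 0.1, 0.01, 0.001):
            soft = SoftIntervalData(np.array([[10.0, 10.0, 5.0]]),
                                    [v0 - w / 2], [v0 + w / 2])
            pdf = posterior_pdf(pk, np.empty((0, 3)), np.empty(0), soft, kb)
            gaps.append(abs(bme_estimate(pdf).mean - sk_mean))
        assert all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))

    def test_soft_point_never_inflates_variance(self, kb):
        gen = np.random.default_rng(9)
        for _ in range(10):
            pts, vals = random_config(gen, 6)
            pk = np.array([20.0, 20.0, 10.0])
            base = bme_estimate(posterior_pdf(pk, pts, vals, None, kb)).variance
            spts, _ = random_config(gen, 1)
            soft = SoftIntervalData(spts, [3.0], [8.0])
            with_soft = bme_estimate(posterior_pdf(pk, pts, vals, soft, kb)).variance
            assert with_soft <= base + 1e-6

    def test_contradictory_co_located_intervals_raise(self, kb):
        pk = np.array([10.0, 10.0, 5.0])
        pts = pk[None, :]
        soft = SoftIntervalData(np.vstack([pts, pts]),
                                [0.0, 10.0], [1.0, 11.0])
        with pytest.raises(ValueError, match="contradictory"):
            posterior_pdf(pk, np.empty((0, 3)), np.empty(0), soft, kb)


class TestEstimate:
    def test_symmetric_posterior_mean_equals_mode(self, kb, rng):
        pts, vals = random_config(rng, 4)
        pk = np.array([18.0, 25.0, 2.0])
        pdf = posterior_pdf(pk, pts, vals, None, kb)
        est = bme_estimate(pdf)
        m, _ = simple_kriging(pk, pts, vals, kb)
        assert est.mean == pytest.approx(m, abs=1e-6)
        assert est.mode == pytest.approx(m, abs=1e-4)

    def test_truncated_support_bounds_mean(self, kb):
        pk = np.array([10.0, 10.0, 5.0])
        kb_hi = GeneralKB(mean=20.0, covariance=kb.covariance)
        soft = SoftIntervalData(pk[None, :], [0.0], [1.0])
        pdf = posterior_pdf(pk, np.empty((0, 3)), np.empty(0), soft, kb_hi)
        est = bme_estimate(pdf)
        assert est.mean < 1.0


class TestSimpleKriging:
    def test_exact_interpolation_at_datum(self, kb):
        pts = np.array([[10.0, 10.0, 5.0]])
        mean, var = simple_kriging(pts[0], pts, [7.3], kb)
        assert mean == pytest.approx(7.3, abs=1e-9)
        assert var == pytest.approx(0.0, abs=1e-9)

    def test_prior_limit_far_from_data(self, kb, nested_model):
        pts = np.array([[10.0, 10.0, 5.0]])
        far = np.array([1e5, 1e5, 5.0])
        mean, var = simple_kriging(far, pts, [50.0], kb)
        assert mean == pytest.approx(5.0, abs=1e-8)
        assert var == pytest.approx(nested_model.sill, abs=1e-8)

    def test_five_point_system_matches_direct_solve(self, kb, nested_model, rng):
        pts, vals = random_config(rng, 5)
        pk = np.array([17.0, 23.0, 11.0])
        mean, var = simple_kriging(pk, pts, vals, kb)
        # independent solve by explicit matrix inversion
        C = covariance_matrix(nested_model, pts)
        c = covariance_matrix(nested_model, pk[None, :], pts).ravel()
        w = np.linalg.inv(C) @ c
        exp_mean = 5.0 + w @ (vals - 5.0)
        exp_var = nested_model.sill - c @ np.linalg.inv(C) @ c
        assert mean == pytest.approx(exp_mean, abs=1e-10)
        assert var == pytest.approx(exp_var, abs=1e-10)


class TestInterpolatorAPI:
    def test_sklearn_params_roundtrip(self, nested_model):
        est = BMEInterpolator(covariance=nested_model, n_hard=7)
        params = est.get_params()
        assert params["n_hard"] == 7
        est.set_params(n_soft=2)
        assert est.n_soft == 2

    def test_degenerate_soft_promoted_to_hard(self, kb, nested_model):
        pk = np.array([[10.0, 10.0, 5.0]])
        est = BMEInterpolator(covariance=nested_model, mean=5.0)
        est.fit(None, None, soft_points=pk, soft_lower=[6.0], soft_upper=[6.0])
        assert len(est.hard_) == 1
        assert est.soft_ is None
        pred = est.predict(pk)
        assert pred[0] == pytest.approx(6.0, abs=1e-8)
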