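import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from pmbme.geodata import LanduseMap
from pmbme.lur import (
    RatioLUR,
    compute_buffer_features,
    ratio_to_interval,
    stepwise_select,
)


def rasterized_halfplane_area(radius_m: float, cell_m: float = 1.0) -> float:
    """Independent oracle: area (m^2) of the half-plane x>0 within a disk of
    ``radius_m`` around the origin, by counting fine raster cells."""
    xs = np.arange(-radius_m, radius_m, cell_m) + cell_m / 2
    X, Y = np.meshgrid(xs, xs)
    inside = (X**2 + Y**2 <= radius_m**2) & (X > 0)
    return float(inside.sum()) * cell_m**2


class TestBufferFeatures:
    def test_full_annulus_closed_form(self):
        # point surrounded by road in all directions: area = pi (o^2 - i^2)
        lu = LanduseMap(geoms=[box(0, 0, 4, 4)], classes=["road"])
        feats = compute_buffer_features(lu, np.array([[2.0, 2.0]]), ((50.0, 100.0),))
        expected = np.pi * (100.0**2 - 50.0**2)  # 23,561.94 m^2
        assert feats["road_50_100"][0] == pytest.approx(expected, rel=1e-3)

    def test_empty_map_all_zero(self):
        lu = LanduseMap()
        feats = compute_buffer_features(
            lu, np.array([[1.0, 1.0]]), ((0.0, 50.0),), classes=["road"]
        )
        assert (feats.to_numpy() == 0).all()

    def test_halfplane_against_rasterization_oracle(self):
        # road fills the half-plane x > 2 km; point on its edge, ring 0-50 m
        lu = LanduseMap(geoms=[box(2, -10, 20, 14)], classes=["road"])
        feats = compute_buffer_features(lu, np.array([[2.0, 2.0]]), ((0.0, 50.0),))
        oracle = rasterized_halfplane_area(50.0, cell_m=1.0)
        closed = np.pi * 50.0**2 / 2
        assert oracle == pytest.approx(closed, rel=5e-3)  # oracle sanity
        assert feats["road_0_50"][0] == pytest.approx(closed, rel=2e-3)

    def test_ring_additivity(self, rng):
        geoms = [box(x, y, x + 0.1, y + 0.1)
                 for x in np.arange(0, 2, 0.25) for y in np.arange(0, 2, 0.25)]
        lu = LanduseMap(geoms=geoms, classes=["industry"] * len(geoms))
        pts = rng.uniform(0.3, 1.7, size=(5, 2))
        split = compute_buffer_features(lu, pts, ((0.0, 50.0), (50.0, 100.0)))
        joint = compute_buffer_features(lu, pts, ((0.0, 100.0),))
        combined = split["industry_0_50"] + split["industry_50_100"]
        assert np.allclose(combined, joint["industry_0_100"], rtol=1e-6, atol=1e-3)

    def test_overlapping_rings_rejected(self, square_road_map):
        with pytest.raises(ValueError, match="overlapping"):
            compute_buffer_features(square_road_map, np.array([[1.0, 1.0]]),
                                    ((0.0, 50.0), (40.0, 100.0)))


class TestStepwise:
    def test_planted_predictor_recovered(self):
        hits = 0
        for seed in range(10):
            gen = np.random.default_rng(seed)
            X = pd.DataFrame(gen.normal(size=(300, 20)),
                             columns=[f"v{i:02d}" for i in range(20)])
            X = X.rename(columns={"v00": "x_road"})
            y = X["x_road"] + gen.normal(0, X["x_road"].std() / 5, 300)
            model = RatioLUR().fit(X, y)
            hits += model.terms_ == ["x_road"]
        assert hits >= 9

    def test_duplicate_predictor_only_one_retained(self, rng):
        X = pd.DataFrame({"x_road": rng.normal(size=200)})
        X["x_dup"] = X["x_road"]
        y = X["x_road"] + rng.normal(0, 0.2, 200)
        model = RatioLUR().fit(X, y)
        assert len(model.terms_) == 1
        assert model.terms_[0] in ("x_road", "x_dup")

    def test_pure_noise_mostly_intercept_only(self):
        keeps = 0
        for seed in range(10):
            gen = np.random.default_rng(100 + seed)
            X = pd.DataFrame(gen.normal(size=(300, 20)),
                             columns=[f"n{i:02d}" for i in range(20)])
            model = RatioLUR().fit(X, gen.normal(size=300))
            keeps += not model.terms_
        assert keeps >= 7

    def test_noiseless_coefficients_exact(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        y = 0.4 + 1.25 * X["b"] - 0.7 * X["d"]
        model = stepwise_select(X, y)
        assert sorted(model.terms_) == ["b", "d"]
        coefs = dict(zip(model.terms_, model.coef_))
        assert coefs["b"] == pytest.approx(1.25, abs=1e-6)
        assert coefs["d"] == pytest.approx(-0.7, abs=1e-6)
        assert model.intercept_ == pytest.approx(0.4, abs=1e-6)

    def test_selection_trace_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(150, 8)),
                         columns=[f"c{i}" for i in range(8)])
        y = 0.8 * X["c3"] - 0.5 * X["c6"] + rng.normal(0, 0.3, 150)
        m1 = RatioLUR().fit(X, y)
        m2 = RatioLUR().fit(X.copy(), y.copy())
        assert m1.terms_ == m2.terms_
        assert [(e["action"], e["term"]) for e in m1.trace_] == [
            (e["action"], e["term"]) for e in m2.trace_
        ]
        # p-values agree up to BLAS-kernel rounding jitter
        assert np.allclose([e["p"] for e in m1.trace_],
                           [e["p"] for e in m2.trace_], rtol=1e-9)

    def test_zero_variance_response_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        with pytest.raises(ValueError, match="zero-variance"):
            RatioLUR().fit(X, np.ones(20))


class TestPrediction:
    @pytest.fixture
    def fitted(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=120), "b": rng.normal(size=120)})
        y = 0.5 + 0.3 * X["a"] + rng.normal(0, 0.1, 120)
        return X, y, RatioLUR().fit(X, y)

    def test_prediction_at_feature_mean_is_response_mean(self, fitted):
        X, y, model = fitted
        Xm = pd.DataFrame({c: [X[c].mean()] for c in X.columns})
        assert model.predict(Xm)[0] == pytest.approx(np.mean(y), abs=1e-10)

    def test_sd_reduces_to_residual_se_without_coef_uncertainty(self, fitted):
        X, _, model = fitted
        model.coef_covariance_ = np.zeros_like(model.coef_covariance_)
        _, sd = model.predict_with_sd(X.iloc[:3])
        assert np.allclose(sd, model.resid_se_)

    def test_sd_matches_bootstrap(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)})
        y = 0.5 + 0.3 * X["a"] + rng.normal(0, 0.15, 80)
        model = RatioLUR().fit(X, y)
        Xnew = pd.DataFrame({"a": [1.2], "b": [0.3]})
        _, sd = model.predict_with_sd(Xnew)
        boots = []
        for _ in range(200):
            idx = rng.integers(0, 80, 80)
            mb = RatioLUR().fit(X.iloc[idx].reset_index(drop=True), y.to_numpy()[idx])
            boots.append(mb.predict(Xnew)[0] + rng.normal(0, mb.resid_se_))
        assert sd[0] == pytest.approx(np.std(boots), rel=0.15)


class TestSoftInterval:
    def test_plain_arithmetic(self):
        iv = ratio_to_interval(0.60, 0.08)
        assert (iv.lower, iv.upper) == (pytest.approx(0.52), pytest.approx(0.68))
        assert not iv.hard_equivalent

    def test_upper_clamp(self):
        iv = ratio_to_interval(0.95, 0.10)
        assert iv.lower == pytest.approx(0.85)
        assert iv.upper == 1.0

    def test_degenerate_is_hard_equivalent(self):
        iv = ratio_to_interval(0.50, 0.0)
        assert iv.lower == iv.upper == 0.5
        assert iv.hard_equivalent

    def test_implausible_ratio_rejected(self):
        with pytest.raises(ValueError, match="implausible"):
            ratio_to_interval(2.5, 0.1)
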