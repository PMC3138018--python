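"""Bayesian Maximum Entropy estimation with hard data and uniform-interval
soft data under a Gaussian general knowledge base.

With general knowledge limited to a mean function and a covariance model,
the maximum-entropy prior over any collection of space-time points is the
multivariate Gaussian with those moments, so the general BME machinery
(constraint functions and their Lagrange multipliers) reduces to closed
form and is never materialized explicitly.  The posterior at an estimation
point p_k given hard values and interval soft data is

    f_K(x)  proportional to  f_G(x | hard) * P(soft in rectangle | hard, x)

where the rectangle is the Cartesian product of the soft intervals
(uniform weighting inside, zero outside).  The normalization constant A is
carried explicitly on a quadrature grid.

Simple kriging — the best linear predictor with known mean and covariance —
is both the baseline comparison method and the exact hard-data-only special
case of this posterior (the posterior is then the Gaussian with the simple
kriging mean and variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .covariance import CovarianceModel, covariance_matrix, safe_cholesky

__all__ = [
    "GeneralKB",
    "HardData",
    "SoftIntervalData",
    "Neighborhood",
    "PosteriorPDF",
    "BMEEstimate",
    "select_neighborhood",
    "posterior_pdf",
    "bme_estimate",
    "simple_kriging",
    "gaussian_rectangle_prob",
    "SimpleKriging",
    "BMEInterpolator",
]


@dataclass
class GeneralKB:
    """General knowledge base: a mean function over space-time points and a
    covariance model.  ``mean`` is a constant or a callable mapping an
    (n, 3) point array to n mean values."""

    mean: float | Callable[[np.ndarray], np.ndarray]
    covariance: CovarianceModel

    def mean_at(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if callable(self.mean):
            return np.asarray(self.mean(pts), dtype=float)
        return np.full(pts.shape[0], float(self.mean))


@dataclass
class HardData:
    """Exact measurements at space-time points (x, y, t)."""

    points: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float)).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.points.shape[0] != self.values.size:
            raise ValueError("points and values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("hard data values must be finite")
        if self.points.shape[0]:
            uniq, inv = np.unique(self.points, axis=0, return_inverse=True)
            if uniq.shape[0] < self.points.shape[0]:
                for u in range(uniq.shape[0]):
                    vals = self.values[inv == u]
                    if np.ptp(vals) > 1e-9:
                        raise ValueError(
                            f"conflicting hard values {vals} at duplicate point {uniq[u]}"
                        )

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class SoftIntervalData:
    """Interval soft data: value at each point lies in [lower, upper] with
    uniform weighting."""

    points: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float)).reshape(-1, 3)
        self.lower = np.asarray(self.lower, dtype=float).ravel()
        self.upper = np.asarray(self.upper, dtype=float).ravel()
        if not (self.points.shape[0] == self.lower.size == self.upper.size):
            raise ValueError("points/lower/upper length mismatch")
        if np.any(self.lower >= self.upper):
            bad = np.nonzero(self.lower >= self.upper)[0]
            raise ValueError(f"soft intervals must satisfy lower < upper (indices {bad.tolist()})")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class Neighborhood:
    """Data selected around an estimation point by scaled space-time distance."""

    point: np.ndarray
    hard_idx: np.ndarray
    soft_idx: np.ndarray
    hard_dist: np.ndarray
    soft_dist: np.ndarray


@dataclass
class PosteriorPDF:
    """Gridded BME posterior density at one estimation point.

    ``norm_const`` is the normalization A: the integral of the unnormalized
    density over the grid; ``density`` integrates to 1 by trapezoid rule.
    """

    grid: np.ndarray
    density: np.ndarray
    norm_const: float


@dataclass
class BMEEstimate:
    mean: float
    variance: float
    mode: float
    estimator: str = "mean"


def _scaled_distance(pk: np.ndarray, pts: np.ndarray, model: CovarianceModel) -> np.ndarray:
    """d = sqrt((h/ar1)^2 + (tau/at1)^2): space-time distance scaled by the
    short-range structure's practical ranges."""
    pts = np.atleast_2d(pts)
    h = np.hypot(pts[:, 0] - pk[0], pts[:, 1] - pk[1])
    tau = np.abs(pts[:, 2] - pk[2])
    return np.sqrt((h / model.ar1) ** 2 + (tau / model.at1) ** 2)


def select_neighborhood(
    pk,
    hard: HardData | None,
    soft: SoftIntervalData | None,
    n_hard: int,
    n_soft: int,
    model: CovarianceModel,
) -> Neighborhood:
    """Nearest hard and soft points by the scaled space-time metric.

    Deterministic tie-break: equal distances are ordered by data index
    (stable sort).  An empty selection is a valid prior-only neighborhood.
    """
    pk = np.asarray(pk, dtype=float).ravel()
    if hard is not None and len(hard):
        dh = _scaled_distance(pk, hard.points, model)
        order = np.argsort(dh, kind="stable")[: max(n_hard, 0)]
        hard_idx, hard_dist = order, dh[order]
    else:
        hard_idx, hard_dist = np.empty(0, dtype=int), np.empty(0)
    if soft is not None and len(soft):
        ds = _scaled_distance(pk, soft.points, model)
        order = np.argsort(ds, kind="stable")[: max(n_soft, 0)]
        soft_idx, soft_dist = order, ds[order]
    else:
        soft_idx, soft_dist = np.empty(0, dtype=int), np.empty(0)
    return Neighborhood(point=pk, hard_idx=hard_idx, soft_idx=soft_idx,
                        hard_dist=hard_dist, soft_dist=soft_dist)


# ---------------------------------------------------------------------------
# multivariate normal rectangle probabilities


_HALTON_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _halton(dim: int, n: int) -> np.ndarray:
    key = (dim, n)
    if key not in _HALTON_CACHE:
        # fixed, unscrambled sequence: fully deterministic rectangle masses
        _HALTON_CACHE[key] = qmc.Halton(d=dim, scramble=False, seed=0).random(n)[1:]
    return _HALTON_CACHE[key]


def gaussian_rectangle_prob(
    lower: np.ndarray,
    upper: np.ndarray,
    means: np.ndarray,
    cov: np.ndarray,
    n_qmc: int = 512,
) -> np.ndarray:
    """P(lower <= Z <= upper) for Z ~ N(mean_k, cov), vectorized over the
    rows of ``means``.

    One dimension is exact (normal CDF differences).  Higher dimensions use
    the separation-of-variables transformation of Genz evaluated on a fixed
    Halton point set, which is deterministic and accurate to ~1e-4 relative
    for the well-conditioned low-dimensional rectangles arising here
    (soft-data neighborhoods are capped at a handful of points).
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    lower = np.asarray(lower, dtype=float).ravel()
    upper = np.asarray(upper, dtype=float).ravel()
    m = lower.size
    if m == 0:
        return np.ones(means.shape[0])
    if m == 1:
        from scipy.special import ndtr

        s = max(np.sqrt(cov[0, 0]), 1e-150)  # ~zero variance: indicator limit
        return ndtr((upper[0] - means[:, 0]) / s) - ndtr((lower[0] - means[:, 0]) / s)
    from scipy.special import ndtr, ndtri

    L = safe_cholesky(np.asarray(cov, dtype=float))
    K = means.shape[0]
    w = _halton(m - 1, n_qmc)  # (N, m-1)
    N = w.shape[0]
    a = (lower[None, :] - means)  # (K, m)
    b = (upper[None, :] - means)
    # sequential conditioning: y_j = Phi^-1(d_j + w_j (e_j - d_j))
    prob = np.ones((K, N))
    y = np.zeros((K, N, m - 1))
    for j in range(m):
        if j == 0:
            shift = 0.0
        else:
            shift = np.einsum("knj,j->kn", y[:, :, :j], L[j, :j])
        d = ndtr((a[:, j, None] - shift) / L[j, j])
        e = ndtr((b[:, j, None] - shift) / L[j, j])
        diff = np.clip(e - d, 0.0, 1.0)
        prob *= diff
        if j < m - 1:
            u = d + w[None, :, j] * diff
            y[:, :, j] = ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    return prob.mean(axis=1)


# ---------------------------------------------------------------------------
# posterior


def _condition_on_hard(
    pk: np.ndarray,
    hard_pts: np.ndarray,
    hard_vals: np.ndarray,
    soft_pts: np.ndarray,
    kb: GeneralKB,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of (X_k, X_soft) | hard under the Gaussian prior."""
    pk = np.asarray(pk, dtype=float).reshape(1, 3)
    tgt = np.vstack([pk, soft_pts]) if soft_pts.size else pk
    mu_t = kb.mean_at(tgt)
    c_tt = covariance_matrix(kb.covariance, tgt)
    if hard_pts.shape[0] == 0:
        return mu_t, c_tt
    mu_h = kb.mean_at(hard_pts)
    c_hh = covariance_matrix(kb.covariance, hard_pts)
    c_th = covariance_matrix(kb.covariance, tgt, hard_pts)
    L = safe_cholesky(c_hh)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, hard_vals - mu_h))
    w = np.linalg.solve(L.T, np.linalg.solve(L, c_th.T))  # C_hh^-1 C_ht
    mean = mu_t + c_th @ alpha
    cov = c_tt - c_th @ w
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def posterior_pdf(
    pk,
    hard_pts,
    hard_vals,
    soft: SoftIntervalData | None,
    kb: GeneralKB,
    n_nodes: int = 401,
    sd_span: float = 8.0,
    n_qmc: int = 512,
) -> PosteriorPDF:
    """BME posterior density of the attribute at ``pk``.

    Computed on an adaptive grid spanning the hard-conditional mean plus or
    minus ``sd_span`` conditional SDs (extended if more than 1e-9 of the
    mass sits at either edge), with the soft-rectangle mass at each node
    obtained from the deterministic Gaussian rectangle algorithm.

    A soft point whose value is (numerically) determined by the estimation
    value itself — a co-located interval — has zero conditional variance:
    its interval is applied exactly as a truncation of the grid support
    rather than through the rectangle integral, so the closed-form
    truncated-Gaussian limit is reproduced to quadrature accuracy.
    """
    pk = np.asarray(pk, dtype=float).ravel()
    hard_pts = np.atleast_2d(np.asarray(hard_pts, dtype=float)).reshape(-1, 3)
    hard_vals = np.asarray(hard_vals, dtype=float).ravel()
    soft_pts = soft.points if soft is not None and len(soft) else np.empty((0, 3))
    mean, cov = _condition_on_hard(pk, hard_pts, hard_vals, soft_pts, kb)
    mu_k = float(mean[0])
    var_k = max(float(cov[0, 0]), 1e-300)
    # exact interpolation (a co-located hard datum) collapses the
    # conditional variance; a tiny floor keeps the quadrature grid proper
    sd_k = max(np.sqrt(var_k), 1e-9 * np.sqrt(kb.covariance.sill))

    lo_support, hi_support = -np.inf, np.inf
    n_soft = soft_pts.shape[0]
    keep = np.empty(0, dtype=int)
    if n_soft:
        mu_s = mean[1:]
        c_ks = cov[0, 1:]
        c_ss = cov[1:, 1:]
        beta = c_ks / var_k  # regression of soft on x_k
        cond_var = np.diag(c_ss) - c_ks**2 / var_k
        degenerate = cond_var <= 1e-12 * np.maximum(np.diag(c_ss), var_k)
        for i in np.nonzero(degenerate)[0]:
            b, m0 = beta[i], mu_s[i] - beta[i] * mu_k
            l_i, u_i = soft.lower[i], soft.upper[i]
            if abs(b) < 1e-12:
                if not (l_i <= m0 <= u_i):
                    raise ValueError(
                        f"soft interval [{l_i}, {u_i}] contradicts the value {m0} "
                        "implied by the hard data"
                    )
                continue
            bnds = sorted(((l_i - m0) / b, (u_i - m0) / b))
            lo_support = max(lo_support, bnds[0])
            hi_support = min(hi_support, bnds[1])
        keep = np.nonzero(~degenerate)[0]
        if keep.size:
            mu_s, beta = mu_s[keep], beta[keep]
            cov_s_given_k = c_ss[np.ix_(keep, keep)] - np.outer(c_ks[keep], c_ks[keep]) / var_k
            cov_s_given_k = 0.5 * (cov_s_given_k + cov_s_given_k.T)
    if lo_support >= hi_support:
        raise ValueError("soft intervals are jointly contradictory (empty support)")

    span = sd_span
    for _ in range(4):
        g_lo = max(mu_k - span * sd_k, lo_support)
        g_hi = min(mu_k + span * sd_k, hi_support)
        if g_lo >= g_hi:  # support entirely outside the span: widen to cover it
            g_lo, g_hi = lo_support, hi_support
            if not np.isfinite(g_lo) or not np.isfinite(g_hi):
                raise ValueError("posterior support unbounded but mass not located")
        grid = np.linspace(g_lo, g_hi, n_nodes)
        base = stats.norm.pdf(grid, loc=mu_k, scale=sd_k)
        if keep.size:
            cond_means = mu_s[None, :] + (grid - mu_k)[:, None] * beta[None, :]
            mass = gaussian_rectangle_prob(soft.lower[keep], soft.upper[keep],
                                           cond_means, cov_s_given_k, n_qmc=n_qmc)
            if np.all(mass < 1e-300):
                raise ValueError(
                    "soft intervals are jointly contradictory under the model: "
                    f"lower={soft.lower}, upper={soft.upper}"
                )
            raw = base * mass
        else:
            raw = base
        A = float(np.trapezoid(raw, grid))
        if A <= 0:
            raise ValueError("non-normalizable posterior (zero mass on the grid)")
        dens = raw / A
        truncated_lo = np.isfinite(lo_support) and grid[0] <= lo_support + 1e-12 * sd_k
        truncated_hi = np.isfinite(hi_support) and grid[-1] >= hi_support - 1e-12 * sd_k
        edge_mass = (0.0 if truncated_lo else dens[0]) + (0.0 if truncated_hi else dens[-1])
        edge_mass *= grid[1] - grid[0]
        if edge_mass < 1e-9 or span >= 32:
            return PosteriorPDF(grid=grid, density=dens, norm_const=A)
        span *= 1.6
    return PosteriorPDF(grid=grid, density=dens, norm_const=A)


def bme_estimate(pdf: PosteriorPDF, estimator: str = "mean") -> BMEEstimate:
    """Posterior mean/variance by composite quadrature (Simpson); mode by
    grid argmax refined with a local quadratic fit."""
    from scipy.integrate import simpson

    g, f = pdf.grid, pdf.density
    total = float(simpson(f, x=g))
    if not np.isfinite(total) or total <= 0:
        raise ValueError("non-normalizable posterior density")
    mean = float(simpson(f * g, x=g) / total)
    var = float(simpson(f * (g - mean) ** 2, x=g) / total)
    i = int(np.argmax(f))
    if 0 < i < len(g) - 1:
        y0, y1, y2 = f[i - 1], f[i], f[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        mode = float(g[i] + delta * (g[1] - g[0]))
    else:
        mode = float(g[i])
    return BMEEstimate(mean=mean, variance=max(var, 0.0), mode=mode, estimator=estimator)


def simple_kriging(pk, hard_pts, hard_vals, kb: GeneralKB) -> tuple[float, float]:
    """Simple kriging mean and variance at ``pk``: the classical best linear
    predictor with known mean and covariance.  With no data the prior mean
    and zero-lag variance are returned."""
    pk = np.asarray(pk, dtype=float).reshape(1, 3)
    hard_pts = np.atleast_2d(np.asarray(hard_pts, dtype=float)).reshape(-1, 3)
    hard_vals = np.asarray(hard_vals, dtype=float).ravel()
    mu_k = float(kb.mean_at(pk)[0])
    c00 = float(covariance_matrix(kb.covariance, pk)[0, 0])
    if hard_pts.shape[0] == 0:
        return mu_k, c00
    mu_h = kb.mean_at(hard_pts)
    c_hh = covariance_matrix(kb.covariance, hard_pts)
    c_kh = covariance_matrix(kb.covariance, pk, hard_pts).ravel()
    L = safe_cholesky(c_hh)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, hard_vals - mu_h))
    w = np.linalg.solve(L.T, np.linalg.solve(L, c_kh))
    mean = mu_k + float(c_kh @ alpha)
    var = c00 - float(c_kh @ w)
    return mean, max(var, 0.0)


# ---------------------------------------------------------------------------
# estimators


class SimpleKriging(BaseEstimator, RegressorMixin):
    """Simple kriging regressor over space-time points.

    ``fit(X, y)`` stores hard data (X is (n, 3) of (x, y, t)); ``predict``
    solves the kriging system within a nearest-neighbor window of
    ``n_hard`` points under the scaled space-time metric.
    """

    def __init__(self, covariance: CovarianceModel = None, mean: float | None = None,
                 n_hard: int = 10):
        self.covariance = covariance
        self.mean = mean
        self.n_hard = n_hard

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float)).reshape(-1, 3)
        y = np.asarray(y, dtype=float).ravel()
        self.hard_ = HardData(X, y)
        mean = float(np.mean(y)) if self.mean is None else float(self.mean)
        self.kb_ = GeneralKB(mean=mean, covariance=self.covariance)
        return self

    def predict(self, X, return_std: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float)).reshape(-1, 3)
        means = np.empty(X.shape[0])
        sds = np.empty(X.shape[0])
        for i, pk in enumerate(X):
            nb = select_neighborhood(pk, self.hard_, None, self.n_hard, 0, self.covariance)
            m, v = simple_kriging(pk, self.hard_.points[nb.hard_idx],
                                  self.hard_.values[nb.hard_idx], self.kb_)
            means[i], sds[i] = m, np.sqrt(v)
        return (means, sds) if return_std else means


class BMEInterpolator(BaseEstimator, RegressorMixin):
    """BME regressor combining hard data and uniform-interval soft data.

    ``fit(X, y, soft_points=, soft_lower=, soft_upper=)`` stores the data;
    degenerate (zero-width) soft intervals are promoted to hard data.
    ``predict`` builds a local neighborhood (``n_hard`` hard, ``n_soft``
    soft points by scaled space-time distance), computes the posterior pdf
    and returns its mean (default) or mode; ``return_std`` adds the
    posterior SD.
    """

    def __init__(self, covariance: CovarianceModel = None, mean: float | None = None,
                 n_hard: int = 10, n_soft: int = 4, estimator: str = "mean",
                 n_nodes: int = 401, sd_span: float = 8.0, n_qmc: int = 512):
        self.covariance = covariance
        self.mean = mean
        self.n_hard = n_hard
        self.n_soft = n_soft
        self.estimator = estimator
        self.n_nodes = n_nodes
        self.sd_span = sd_span
        self.n_qmc = n_qmc

    def fit(self, X, y, soft_points=None, soft_lower=None, soft_upper=None):
        X = np.atleast_2d(np.asarray(X, dtype=float)).reshape(-1, 3) if X is not None else np.empty((0, 3))
        y = np.asarray(y, dtype=float).ravel() if y is not None else np.empty(0)
        if soft_points is None:
            soft_points = np.empty((0, 3))
            soft_lower = np.empty(0)
            soft_upper = np.empty(0)
        soft_points = np.atleast_2d(np.asarray(soft_points, dtype=float)).reshape(-1, 3)
        soft_lower = np.asarray(soft_lower, dtype=float).ravel()
        soft_upper = np.asarray(soft_upper, dtype=float).ravel()
        degenerate = soft_upper - soft_lower <= 1e-12
        if degenerate.any():
            X = np.vstack([X, soft_points[degenerate]])
            y = np.concatenate([y, 0.5 * (soft_lower + soft_upper)[degenerate]])
            soft_points = soft_points[~degenerate]
            soft_lower = soft_lower[~degenerate]
            soft_upper = soft_upper[~degenerate]
        self.hard_ = HardData(X, y)
        self.soft_ = (
            SoftIntervalData(soft_points, soft_lower, soft_upper)
            if soft_points.shape[0]
            else None
        )
        mean = float(np.mean(y)) if (self.mean is None and y.size) else float(self.mean or 0.0)
        self.kb_ = GeneralKB(mean=mean, covariance=self.covariance)
        return self

    def predict_pdf(self, pk) -> PosteriorPDF:
        nb = select_neighborhood(pk, self.hard_, self.soft_, self.n_hard, self.n_soft,
                                 self.covariance)
        soft_nb = None
        if self.soft_ is not None and nb.soft_idx.size:
            soft_nb = SoftIntervalData(
                self.soft_.points[nb.soft_idx],
                self.soft_.lower[nb.soft_idx],
                self.soft_.upper[nb.soft_idx],
            )
        return posterior_pdf(
            pk,
            self.hard_.points[nb.hard_idx],
            self.hard_.values[nb.hard_idx],
            soft_nb,
            self.kb_,
            n_nodes=self.n_nodes,
            sd_span=self.sd_span,
            n_qmc=self.n_qmc,
        )

    def predict(self, X, return_std: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float)).reshape(-1, 3)
        means = np.empty(X.shape[0])
        sds = np.empty(X.shape[0])
        for i, pk in enumerate(X):
            est = bme_estimate(self.predict_pdf(pk), estimator=self.estimator)
            means[i] = est.mean if self.estimator == "mean" else est.mode
            sds[i] = np.sqrt(est.variance)
        return (means, sds) if return_std else means
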