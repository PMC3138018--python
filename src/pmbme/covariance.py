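"""Space-time covariance modelling for monthly particulate-matter fields.

The working model is a *nested* sum of two separable exponential structures

    c(h, tau) = c0 exp(-3h/a_r1) exp(-3tau/a_t1)
              + c1 exp(-3h/a_r2) exp(-3tau/a_t2)

with h a spatial lag (km) and tau a temporal lag (months).  The ``-3h/a``
scaling makes each ``a`` a *practical range*: the correlation of that
structure decays to e^-3 (about 5%) at lag a.  Range conventions differ
across the geostatistics literature, so this one is stated prominently:
ranges here are practical ranges, not the exponential's e-folding scale.

The short-range structure (a_r1, a_t1) captures local transport of the
pollutant; the long-range structure (a_r2, a_t2) captures slow regional
processes such as long-distance mass transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator

__all__ = [
    "CovarianceModel",
    "PM25_NESTED_MODEL",
    "EmpiricalCovariance",
    "evaluate_covariance",
    "empirical_covariance",
    "empirical_covariance_matrix",
    "NestedCovarianceWLS",
    "fit_nested_exponential",
    "covariance_matrix",
    "safe_cholesky",
    "plot_covariance",
]


@dataclass(frozen=True)
class CovarianceModel:
    """Parameters of the nested exponential space-time covariance.

    c0, c1   sills of the two structures ((ug/m3)^2, or dimensionless^2)
    ar1, ar2 spatial practical ranges (km), ar1 <= ar2
    at1, at2 temporal practical ranges (months), at1 <= at2
    """

    c0: float
    c1: float
    ar1: float
    ar2: float
    at1: float
    at2: float

    def __post_init__(self) -> None:
        for name in ("c0", "c1", "ar1", "ar2", "at1", "at2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"covariance parameter {name} must be > 0")
        if self.ar1 > self.ar2:
            raise ValueError("identifiability ordering requires ar1 <= ar2")
        if self.at1 > self.at2:
            raise ValueError("identifiability ordering requires at1 <= at2")

    @property
    def sill(self) -> float:
        """Variance at zero lag, c(0, 0) = c0 + c1."""
        return self.c0 + self.c1

    def __call__(self, h, tau):
        return evaluate_covariance(self, h, tau)

    def as_array(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.ar1, self.ar2, self.at1, self.at2])


#: Reference fitted model for monthly urban PM2.5 residual variation:
#: a local structure (11.092 km, 3 months) and a regional structure
#: (50 km, 50 months) with sills 10.5 and 3.729 (ug/m3)^2.
PM25_NESTED_MODEL = CovarianceModel(c0=10.5, c1=3.729, ar1=11.092, ar2=50.0, at1=3.0, at2=50.0)


def evaluate_covariance(model: CovarianceModel, h, tau):
    """Closed-form nested exponential covariance, vectorized over lag grids.

    Raises for negative lags; ``h`` in km, ``tau`` in months.
    """
    h = np.asarray(h, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if (h < 0).any() or (tau < 0).any():
        raise ValueError("lags must be non-negative")
    out = model.c0 * np.exp(-3.0 * h / model.ar1) * np.exp(-3.0 * tau / model.at1)
    out = out + model.c1 * np.exp(-3.0 * h / model.ar2) * np.exp(-3.0 * tau / model.at2)
    return out if out.shape else float(out)


def covariance_matrix(model: CovarianceModel, pts_a: np.ndarray, pts_b: np.ndarray | None = None) -> np.ndarray:
    """Covariance between space-time points given as (n, 3) arrays (x, y, t)."""
    pts_a = np.atleast_2d(np.asarray(pts_a, dtype=float))
    pts_b = pts_a if pts_b is None else np.atleast_2d(np.asarray(pts_b, dtype=float))
    dx = pts_a[:, None, 0] - pts_b[None, :, 0]
    dy = pts_a[:, None, 1] - pts_b[None, :, 1]
    h = np.hypot(dx, dy)
    tau = np.abs(pts_a[:, None, 2] - pts_b[None, :, 2])
    return evaluate_covariance(model, h, tau)


def safe_cholesky(mat: np.ndarray, rel_jitter: float = 1e-8) -> np.ndarray:
    """Cholesky factor with escalating diagonal jitter up to rel_jitter*c(0,0).

    Positive-definiteness guard: matrices assembled from a fitted model on any
    point set must factor with jitter <= 1e-8 of the zero-lag variance.
    """
    scale = float(np.max(np.diag(mat)))
    for jit in (0.0, 1e-12, 1e-10, rel_jitter):
        try:
            return np.linalg.cholesky(mat + jit * scale * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance matrix not positive definite even with jitter; "
        "check for duplicate points or an invalid model"
    )


# ---------------------------------------------------------------------------
# empirical covariance


@dataclass
class EmpiricalCovariance:
    """Method-of-moments space-time covariance surface.

    values[i, j] estimates c(h_centers[i], tau_lags[j]); cells with no pairs
    are NaN (never zero-filled) with counts[i, j] == 0.
    """

    h_centers: np.ndarray
    tau_lags: np.ndarray
    values: np.ndarray
    counts: np.ndarray

    def cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Non-missing cells as ((n,2) lag array, values, counts)."""
        hh, tt = np.meshgrid(self.h_centers, self.tau_lags, indexing="ij")
        ok = self.counts > 0
        lags = np.column_stack([hh[ok], tt[ok]])
        return lags, self.values[ok], self.counts[ok]


def empirical_covariance_matrix(
    values: np.ndarray,
    coords: np.ndarray,
    spatial_bin_width: float = 2.0,
    max_tau: int = 12,
    max_h: float | None = None,
    center: str = "global",
) -> EmpiricalCovariance:
    """Empirical covariance from a (n_sites, n_months) value matrix.

    For each (h, tau) cell: the average of ``(x_i - m)(x_j - m)`` over all
    station-month pairs whose spatial distance falls in the h bin and whose
    month offset is tau, with ``m`` the global mean (``center='global'``) or
    per-month means (``center='month'``).  NaN entries are allowed and simply
    excluded from every pair.  The h = 0 bin includes a site paired with
    itself, so cell (0, 0) is the plain variance.
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n_sites, n_months = x.shape
    if n_sites < 2 or n_months < 2:
        raise ValueError("need at least 2 sites and 2 months")
    if np.isnan(x).all():
        raise ValueError("all observations missing")
    if center == "global":
        xc = x - np.nanmean(x)
    elif center == "month":
        xc = x - np.nanmean(x, axis=0, keepdims=True)
    else:
        raise ValueError("center must be 'global' or 'month'")
    valid = np.isfinite(xc)
    xz = np.where(valid, xc, 0.0)

    dx = coords[:, None, 0] - coords[None, :, 0]
    dy = coords[:, None, 1] - coords[None, :, 1]
    dist = np.hypot(dx, dy)
    if max_h is None:
        max_h = 0.5 * float(dist.max())
    # bin 0 holds exact zero-distance pairs (the variance cell); bin k >= 1
    # covers ((k-1) w, k w], so cell (0, 0) is never diluted by short but
    # nonzero lags
    n_bins = max(1, int(np.ceil(max_h / spatial_bin_width))) + 1
    bin_idx = np.where(
        dist == 0.0, 0, np.ceil(dist / spatial_bin_width).astype(int)
    )
    # upper triangle incl. diagonal: each unordered site pair once
    iu, ju = np.triu_indices(n_sites)
    pair_bin = bin_idx[iu, ju]
    in_range = pair_bin < n_bins

    max_tau = min(max_tau, n_months - 1)
    sums = np.zeros((n_bins, max_tau + 1))
    cnts = np.zeros((n_bins, max_tau + 1))
    for tau in range(max_tau + 1):
        a = xz[:, : n_months - tau]
        b = xz[:, tau:]
        va = valid[:, : n_months - tau]
        vb = valid[:, tau:]
        prod = a @ b.T  # (i, j): sum_t x[i,t] x[j,t+tau]
        nobs = va.astype(float) @ vb.T.astype(float)
        if tau > 0:
            prod = 0.5 * (prod + prod.T)  # symmetrize over lag direction
            nobs = 0.5 * (nobs + nobs.T)
        p = prod[iu, ju][in_range]
        n = nobs[iu, ju][in_range]
        np.add.at(sums[:, tau], pair_bin[in_range], p)
        np.add.at(cnts[:, tau], pair_bin[in_range], n)

    with np.errstate(invalid="ignore"):
        vals = np.where(cnts > 0, sums / np.where(cnts > 0, cnts, 1.0), np.nan)
    h_centers = np.concatenate(
        [[0.0], (np.arange(1, n_bins) - 0.5) * spatial_bin_width]
    )
    return EmpiricalCovariance(
        h_centers=h_centers,
        tau_lags=np.arange(max_tau + 1, dtype=float),
        values=vals,
        counts=cnts,
    )


def empirical_covariance(
    series,
    stations,
    pollutant: str = "pm25",
    spatial_bin_width: float = 2.0,
    max_tau: int = 12,
    max_h: float | None = None,
    center: str = "global",
) -> EmpiricalCovariance:
    """Empirical covariance from a long-format observation table.

    ``series`` has columns (station_id, month, pollutant, value); ``stations``
    has (station_id, x, y).  Missing station-months are excluded pairwise.
    """
    sub = series[series["pollutant"] == pollutant]
    if sub.empty:
        raise ValueError(f"no records for pollutant {pollutant!r}")
    wide = sub.pivot(index="station_id", columns="month", values="value")
    order = [sid for sid in stations["station_id"] if sid in wide.index]
    wide = wide.reindex(order)
    coords = stations.set_index("station_id").loc[order, ["x", "y"]].to_numpy(float)
    return empirical_covariance_matrix(
        wide.to_numpy(float), coords, spatial_bin_width, max_tau, max_h, center
    )


# ---------------------------------------------------------------------------
# weighted least-squares fit


def _theta_to_model(theta: np.ndarray) -> CovarianceModel:
    c0, c1, ar1, dr, at1, dt = theta
    return CovarianceModel(c0=c0, c1=c1, ar1=ar1, ar2=ar1 + dr, at1=at1, at2=at1 + dt)


class NestedCovarianceWLS(BaseEstimator):
    """Weighted least-squares fit of the nested exponential covariance.

    scikit-learn style estimator: ``fit(X, y, sample_weight)`` with
    ``X`` an (n, 2) array of (h, tau) lags, ``y`` empirical covariance values
    and ``sample_weight`` the pair counts.  Minimizes

        sum_cells  n_pairs * (c_hat - c(h, tau; theta))^2

    bounds-constrained, with multi-start initial points from a bound-scaled
    Latin hypercube (fixed sub-seed).  The orderings ar1 <= ar2 and
    at1 <= at2 are enforced by fitting (ar1, ar2-ar1) and (at1, at2-at1).

    Attributes
    ----------
    model_ : CovarianceModel        best-fit parameters
    objective_ : float              weighted SSE at the optimum
    trace_ : list of dict           per-start init, objective, success
    """

    def __init__(self, n_starts: int = 5, init: CovarianceModel | None = None,
                 bounds: dict | None = None, random_state: int = 0):
        self.n_starts = n_starts
        self.init = init
        self.bounds = bounds
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(y)
        X, y = X[ok], y[ok]
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)[ok]
        if y.size < 6:
            raise ValueError("need at least 6 non-missing covariance cells (6 parameters)")
        sw = np.sqrt(w)

        sill0 = float(y[np.lexsort((X[:, 1], X[:, 0]))][0])
        sill0 = max(sill0, float(np.nanmax(y)), 1e-6)
        h_max = max(float(X[:, 0].max()), 1.0)
        t_max = max(float(X[:, 1].max()), 1.0)
        default_bounds = {
            "c": (1e-6 * sill0, 10.0 * sill0),
            "ar1": (1e-2, 5.0 * h_max),
            "dr": (0.0, 10.0 * h_max),
            "at1": (1e-2, 10.0 * t_max),
            "dt": (0.0, 20.0 * t_max),
        }
        b = {**default_bounds, **(self.bounds or {})}
        lo = np.array([b["c"][0], b["c"][0], b["ar1"][0], b["dr"][0], b["at1"][0], b["dt"][0]])
        hi = np.array([b["c"][1], b["c"][1], b["ar1"][1], b["dr"][1], b["at1"][1], b["dt"][1]])

        def resid(theta):
            c0, c1, ar1, dr, at1, dt = theta
            model = (
                c0 * np.exp(-3.0 * X[:, 0] / ar1) * np.exp(-3.0 * X[:, 1] / at1)
                + c1 * np.exp(-3.0 * X[:, 0] / (ar1 + dr)) * np.exp(-3.0 * X[:, 1] / (at1 + dt))
            )
            return sw * (model - y)

        starts = []
        if self.init is not None:
            m = self.init
            starts.append(np.array([m.c0, m.c1, m.ar1, m.ar2 - m.ar1, m.at1, m.at2 - m.at1]))
        n_lhs = max(self.n_starts - len(starts), 0)
        if n_lhs:
            sampler = qmc.LatinHypercube(d=6, seed=self.random_state)
            unit = sampler.random(n_lhs)
            span = qmc.scale(unit, np.maximum(lo, 1e-8 * hi), hi)
            starts.extend(span)
        # one moment-based start: split the sill 3:1, short ranges from the grid
        starts.append(np.array([0.75 * sill0, 0.25 * sill0, 0.2 * h_max, 0.5 * h_max,
                                0.3 * t_max, 2.0 * t_max]))

        self.trace_ = []
        best = None
        for x0 in starts:
            x0 = np.clip(x0, lo + 1e-12, hi)
            obj0 = float(np.sum(resid(x0) ** 2))
            try:
                res = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
            except Exception as exc:  # pragma: no cover - optimizer failure path
                self.trace_.append({"init": x0, "objective": np.inf, "error": str(exc)})
                continue
            obj = float(np.sum(res.fun ** 2))
            self.trace_.append({"init": x0, "init_objective": obj0, "objective": obj,
                                "success": bool(res.success)})
            if obj > obj0 + 1e-9:  # optimizer sanity: never worse than its start
                obj, res = obj0, None
            if best is None or obj < best[0]:
                best = (obj, res.x if res is not None else x0)
        if best is None:
            raise RuntimeError(f"no optimizer start converged; trace: {self.trace_}")
        self.objective_ = best[0]
        theta = np.maximum(best[1], [1e-12, 1e-12, 1e-6, 0.0, 1e-6, 0.0])
        theta[1] = max(theta[1], 1e-9 * theta[0])  # keep model constructible at c1 -> 0
        theta[0] = max(theta[0], 1e-9 * theta[1])
        self.model_ = _theta_to_model(theta)
        return self

    def fit_empirical(self, emp: EmpiricalCovariance) -> "NestedCovarianceWLS":
        lags, vals, counts = emp.cells()
        return self.fit(lags, vals, sample_weight=counts)


def fit_nested_exponential(
    emp: EmpiricalCovariance,
    init: CovarianceModel | None = None,
    bounds: dict | None = None,
    n_starts: int = 5,
    random_state: int = 0,
) -> CovarianceModel:
    """Fit the nested exponential model to an empirical covariance surface
    by pair-count-weighted least squares with multi-start optimization."""
    est = NestedCovarianceWLS(n_starts=n_starts, init=init, bounds=bounds,
                              random_state=random_state)
    est.fit_empirical(emp)
    return est.model_


def plot_covariance(emp: EmpiricalCovariance, model: CovarianceModel | None, path) -> None:
    """Export spatial (tau=0) and temporal (h=0) marginal covariance curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ok_s = emp.counts[:, 0] > 0
    ax1.plot(emp.h_centers[ok_s], emp.values[ok_s, 0], "ko", label="empirical")
    ok_t = emp.counts[0, :] > 0
    ax2.plot(emp.tau_lags[ok_t], emp.values[0, ok_t], "ko", label="empirical")
    if model is not None:
        hs = np.linspace(0, emp.h_centers.max(), 200)
        ts = np.linspace(0, emp.tau_lags.max(), 200)
        ax1.plot(hs, evaluate_covariance(model, hs, 0.0), "r-", label="fitted")
        ax2.plot(ts, evaluate_covariance(model, 0.0, ts), "r-", label="fitted")
    ax1.set_xlabel("spatial lag h (km)")
    ax1.set_ylabel("covariance")
    ax1.set_title("pure spatial covariance")
    ax2.set_xlabel("temporal lag (months)")
    ax2.set_title("pure temporal covariance")
    ax1.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
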