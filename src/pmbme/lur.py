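"""Land-use regression of PM2.5/PM10 ratios on ring-buffer landuse features.

Features are the areas (m^2) of each landuse class intersected with annuli
around a point (half-open rings (inner, outer], radii in meters).  A
forward-entry / backward-removal stepwise procedure on partial-F p-values
selects regressors, with variance-inflation-factor screening: after each
entry, if any retained term's VIF exceeds the cap, the newly entered term
(the later-entering member of the collinear pair) is rejected and barred.

The fitted model predicts a ratio with a standard deviation that includes
the residual variance (a prediction interval scale, not a confidence
interval scale), because the downstream soft interval must cover a single
month's ratio rather than its mean.  Intervals [r_hat - SD, r_hat + SD]
feed the estimation stage as uniform-interval soft evidence, clamped to the
physically admissible ratio support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely import STRtree
from sklearn.base import BaseEstimator, RegressorMixin

from .geodata import DEFAULT_BUFFER_RINGS, LanduseMap

__all__ = [
    "compute_buffer_features",
    "RatioLUR",
    "stepwise_select",
    "predict_with_sd",
    "ratio_to_interval",
    "SoftInterval",
    "RATIO_FLOOR",
    "RATIO_CAP",
]

#: Clamp bounds for ratio soft intervals: PM2.5 cannot exceed PM10, and a
#: strictly positive floor keeps downstream multiplicative trends positive.
RATIO_FLOOR = 0.01
RATIO_CAP = 1.0

_BUFFER_QUAD_SEGS = 64  # polygonal circle approximation, area error ~1e-4


def _ring_name(cls: str, ring: tuple[float, float]) -> str:
    return f"{cls}_{int(ring[0])}_{int(ring[1])}"


def compute_buffer_features(
    landuse: LanduseMap,
    points: np.ndarray,
    rings: tuple[tuple[float, float], ...] = DEFAULT_BUFFER_RINGS,
    classes: list[str] | None = None,
    intensity_weighted: bool = False,
) -> pd.DataFrame:
    """Ring-buffer feature matrix.

    Entry (point, class_inner_outer) is the area in m^2 of that class
    intersected with the annulus (inner, outer] centered at the point
    (point coordinates in km, radii in meters).  With
    ``intensity_weighted=True`` areas are weighted by the per-polygon
    intensity attribute (e.g. vehicle volume per unit road area), yielding a
    volume-style covariate instead of an area.

    Rings must be ordered and non-overlapping; annulus areas are exact up to
    the polygonal circle approximation (64 segments per quadrant).
    """
    for (i0, o0), (i1, o1) in zip(rings, rings[1:]):
        if o0 > i1:
            raise ValueError(f"overlapping rings ({i0},{o0}) and ({i1},{o1})")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if classes is None:
        classes = sorted(set(landuse.classes))
    cols = {_ring_name(c, r): np.zeros(points.shape[0]) for c in classes for r in rings}
    if len(landuse) == 0 or not classes:
        return pd.DataFrame(cols)

    keep = [i for i, c in enumerate(landuse.classes) if c in classes]
    geoms = np.array([landuse.geoms[i] for i in keep], dtype=object)
    labels = [landuse.classes[i] for i in keep]
    weights = (
        np.array([landuse.intensity[i] for i in keep])
        if (intensity_weighted and landuse.intensity)
        else np.ones(len(keep))
    )
    for gi, g in enumerate(geoms):
        if not g.is_valid:
            raise ValueError(f"invalid polygon (class {labels[gi]})")
    tree = STRtree(geoms)
    class_idx = {c: i for i, c in enumerate(classes)}
    label_idx = np.array([class_idx[c] for c in labels])

    pts = shapely.points(points[:, 0], points[:, 1])
    km2_to_m2 = 1e6
    for ring in rings:
        inner_m, outer_m = ring
        disks = shapely.buffer(pts, outer_m / 1000.0, quad_segs=_BUFFER_QUAD_SEGS)
        if inner_m > 0:
            holes = shapely.buffer(pts, inner_m / 1000.0, quad_segs=_BUFFER_QUAD_SEGS)
            annuli = shapely.difference(disks, holes)
        else:
            annuli = disks
        a_idx, g_idx = tree.query(annuli)
        if len(a_idx) == 0:
            continue
        areas = shapely.area(shapely.intersection(annuli[a_idx], geoms[g_idx]))
        vals = areas * km2_to_m2 * weights[g_idx]
        # accumulate per (point, class)
        acc = np.zeros((points.shape[0], len(classes)))
        np.add.at(acc, (a_idx, label_idx[g_idx]), vals)
        for c in classes:
            cols[_ring_name(c, ring)] = acc[:, class_idx[c]]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# stepwise regression


def _ols(Xd: np.ndarray, y: np.ndarray):
    """Least squares with intercept column prepended; returns (beta, rss, dof)."""
    n = Xd.shape[0]
    A = np.column_stack([np.ones(n), Xd]) if Xd.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid), n - rank


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors 1/(1-R^2) of each column on the others
    (with intercept); an exactly collinear column yields +inf."""
    n, k = X.shape
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        _, rss, _ = _ols(others, yj)
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - rss / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


class RatioLUR(BaseEstimator, RegressorMixin):
    """Stepwise-selected linear land-use regression with VIF screening.

    scikit-learn style: ``fit(X, y)`` with ``X`` a DataFrame of candidate
    ring-buffer features (and optional time-varying covariates) and ``y``
    the observed ratios.  Selection is forward entry on the smallest
    partial-F p-value (ties broken by p-value then lexicographic term name),
    followed after every entry by backward removal of terms whose p-value
    exceeds ``p_remove``.  The entry test is calibrated at the step level:
    the best candidate's p-value is Sidak-adjusted for the number of
    candidates scanned before comparison with ``p_enter``, so the chance of
    admitting a pure-noise regressor per step is ``p_enter`` however many
    candidates compete (a raw per-candidate threshold would admit noise with
    probability 1 - (1-p_enter)^m).  A term whose entry pushes any VIF above
    ``vif_max`` is rejected and permanently barred.

    Attributes
    ----------
    terms_ : list of selected column names
    coef_ : ndarray of coefficients (order of ``terms_``)
    intercept_ : float
    coef_covariance_ : (k+1, k+1) covariance of [intercept, coefs]
    resid_se_ : residual standard error
    r2_ : coefficient of determination
    trace_ : list of selection events (dicts)
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10, vif_max: float = 10.0):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.vif_max = vif_max

    # -- selection machinery ------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if X.shape[0] != n:
            raise ValueError("X and y length mismatch")
        if np.std(y) == 0:
            raise ValueError("zero-variance response")
        names = list(X.columns)
        data = {c: X[c].to_numpy(float) for c in names}
        selected: list[str] = []
        barred: set[str] = set()
        trace: list[dict] = []

        def design(cols: list[str]) -> np.ndarray:
            return (
                np.column_stack([data[c] for c in cols]) if cols else np.empty((n, 0))
            )

        def qr_state(cols: list[str]):
            """Thin QR of [1 | X_cols]; returns (Q, residual vector, rss, dof)."""
            A = np.column_stack([np.ones(n)] + [data[c] for c in cols])
            Q, _ = np.linalg.qr(A)
            r = y - Q @ (Q.T @ y)
            return Q, r, float(r @ r), n - A.shape[1]

        Q, r_cur, rss_cur, dof_cur = qr_state(selected)

        while True:
            candidates = [
                c for c in names
                if c not in selected and c not in barred and np.std(data[c]) > 0
            ]
            if len(selected) + 2 >= n:
                break
            if rss_cur <= 1e-12 * float(np.sum((y - y.mean()) ** 2)):
                break  # response already fit to numerical precision
            # forward scan: partial F of each candidate from its component
            # orthogonal to the current design (exact single-column update)
            entries = []
            for c in candidates:
                z = data[c]
                z_perp = z - Q @ (Q.T @ z)
                zz = float(z_perp @ z_perp)
                if zz <= 1e-12 * float(z @ z):
                    continue  # numerically inside the current column space
                gain = float(r_cur @ z_perp) ** 2 / zz
                rss_new = max(rss_cur - gain, 0.0)
                dof_new = dof_cur - 1
                if dof_new <= 0:
                    continue
                if rss_new <= 1e-12 * rss_cur:  # (near-)perfect fit
                    p = 0.0
                else:
                    f = gain / (rss_new / dof_new)
                    p = float(stats.f.sf(f, 1, dof_new))
                entries.append((p, c))
            entries.sort(key=lambda t: (t[0], t[1]))
            # entry is tested at the step level: the smallest candidate
            # p-value is Sidak-adjusted for the number of candidates scanned,
            # so the probability of admitting any pure-noise term per step is
            # p_enter, regardless of how many candidates compete
            n_scanned = max(len(entries), 1)
            entered = False
            for p, c in entries:
                p_step = 1.0 - (1.0 - p) ** n_scanned
                if p_step > self.p_enter:
                    break
                trial = selected + [c]
                vifs = _vif(design(trial)) if len(trial) > 1 else np.array([1.0])
                if np.any(vifs > self.vif_max):
                    barred.add(c)
                    trace.append({"action": "bar", "term": c, "p": p,
                                  "vif": float(np.max(vifs))})
                    continue
                selected = trial
                Q, r_cur, rss_cur, dof_cur = qr_state(selected)
                trace.append({"action": "enter", "term": c, "p": p})
                entered = True
                break
            if not entered:
                break
            # backward removal on coefficient t-tests (t^2 = partial F)
            while len(selected) > 0:
                A = np.column_stack([np.ones(n)] + [data[c] for c in selected])
                beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
                resid = y - A @ beta
                dof_full = n - A.shape[1]
                if dof_full <= 0:
                    break
                s2 = float(resid @ resid) / dof_full
                cov_b = s2 * np.linalg.inv(A.T @ A)
                tstat = beta[1:] / np.sqrt(np.maximum(np.diag(cov_b)[1:], 1e-300))
                pvals = 2.0 * stats.t.sf(np.abs(tstat), dof_full)
                worst_i = int(np.lexsort((np.array(selected, dtype=object), -pvals))[0])
                if pvals[worst_i] > self.p_remove:
                    removed = selected[worst_i]
                    selected = [s for s in selected if s != removed]
                    trace.append({"action": "remove", "term": removed,
                                  "p": float(pvals[worst_i])})
                    Q, r_cur, rss_cur, dof_cur = qr_state(selected)
                else:
                    break

        # final fit via statsmodels for coefficient covariance and diagnostics
        import statsmodels.api as sm

        A = sm.add_constant(design(selected), has_constant="add")
        res = sm.OLS(y, A).fit()
        self.terms_ = selected
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.coef_covariance_ = np.asarray(res.cov_params(), dtype=float)
        self.resid_se_ = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0
        self.r2_ = float(res.rsquared) if np.std(y) > 0 else 0.0
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)
        self.trace_ = trace
        self.n_obs_ = n
        self.train_feature_range_ = (
            {c: (float(np.min(data[c])), float(np.max(data[c]))) for c in selected}
        )
        self.train_response_mean_ = float(np.mean(y))
        return self

    # -- prediction ---------------------------------------------------------

    def _design_row(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.terms_ if c not in X.columns]
        if missing:
            raise ValueError(f"feature matrix missing selected terms: {missing}")
        mat = X[self.terms_].to_numpy(float) if self.terms_ else np.empty((len(X), 0))
        for c in self.terms_:
            lo, hi = self.train_feature_range_[c]
            span = max(hi - lo, 1e-300)
            vals = X[c].to_numpy(float)
            if np.any(vals > hi + 2 * span) or np.any(vals < lo - 2 * span):
                warnings.warn(
                    f"extrapolating term {c} beyond 3x its training range", stacklevel=2
                )
        return np.column_stack([np.ones(len(X)), mat])

    def predict(self, X) -> np.ndarray:
        A = self._design_row(pd.DataFrame(X))
        return A @ np.concatenate([[self.intercept_], self.coef_])

    def predict_with_sd(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Prediction and its standard deviation sqrt(x'Vx + s^2), where V is
        the coefficient covariance and s the residual standard error — the
        scale of a single new observation, not of the mean."""
        A = self._design_row(pd.DataFrame(X))
        pred = A @ np.concatenate([[self.intercept_], self.coef_])
        var_mean = np.einsum("ij,jk,ik->i", A, self.coef_covariance_, A)
        sd = np.sqrt(np.maximum(var_mean, 0.0) + self.resid_se_**2)
        return pred, sd

    def coefficient_table(self) -> pd.DataFrame:
        """Selected terms with coefficients at the 1e-7 reporting scale."""
        return pd.DataFrame(
            {
                "term": self.terms_,
                "coefficient_1e-7": self.coef_ / 1e-7,
                "p_value": self.pvalues_[1:],
            }
        )


def stepwise_select(X: pd.DataFrame, y, p_enter: float = 0.05, p_remove: float = 0.10,
                    vif_max: float = 10.0) -> RatioLUR:
    """Fit a stepwise LUR; thin wrapper over :class:`RatioLUR`."""
    return RatioLUR(p_enter=p_enter, p_remove=p_remove, vif_max=vif_max).fit(X, y)


def predict_with_sd(model: RatioLUR, X) -> tuple[np.ndarray, np.ndarray]:
    return model.predict_with_sd(X)


# ---------------------------------------------------------------------------
# soft intervals


@dataclass(frozen=True)
class SoftInterval:
    """Uniform soft interval [lower, upper] for one space-time point; a
    zero-width interval is hard-equivalent (treated as an exact datum)."""

    lower: float
    upper: float
    hard_equivalent: bool = False


def ratio_to_interval(r_hat: float, sd: float, floor: float = RATIO_FLOOR,
                      cap: float = RATIO_CAP) -> SoftInterval:
    """Uniform soft interval [r_hat - SD, r_hat + SD] for a ratio estimate,
    clamped to the admissible support [floor, cap].

    SD = 0 yields a degenerate, hard-equivalent interval.  Ratio estimates
    outside (0, 2) are rejected as implausible.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not (0.0 < r_hat < 2.0):
        raise ValueError(f"implausible ratio estimate {r_hat!r} (outside (0, 2))")
    if sd == 0:
        v = float(np.clip(r_hat, floor, cap))
        return SoftInterval(v, v, hard_equivalent=True)
    lo = float(np.clip(r_hat - sd, floor, cap))
    hi = float(np.clip(r_hat + sd, floor, cap))
    if lo == hi:
        return SoftInterval(lo, hi, hard_equivalent=True)
    return SoftInterval(lo, hi, hard_equivalent=False)
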