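"""End-to-end orchestration of the two-stage PM2.5 analysis.

Stages: (0) monthly aggregation of daily records and hard-data-only
estimation of PM2.5 at PM10-only stations; (1) PM2.5/PM10 ratios regressed
on ring-buffer landuse features (stepwise LUR), giving a ratio estimate and
SD at every target point; (2) the uncertain trend m = r_hat * PM10 with
interval bounds [l*Y, u*Y]; hard residuals (observation minus trend) at
PM2.5 stations and interval soft residuals elsewhere feed a BME estimate of
the residual field under a nested exponential covariance fitted to the
residuals; trend plus residual estimate is the PM2.5 map.

The comparison design mirrors the standard three-way benchmark: simple
kriging of the PM2.5 observations alone, the LUR trend alone, and the full
LUR + BME combination, scored by leave-one-station-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bme import BMEInterpolator, GeneralKB, HardData, SimpleKriging, simple_kriging
from .covariance import (
    CovarianceModel,
    empirical_covariance,
    fit_nested_exponential,
)
from .geodata import Config, GridSpec, LanduseMap
from .lur import RatioLUR, compute_buffer_features, ratio_to_interval

logger = logging.getLogger(__name__)

__all__ = [
    "CVStats",
    "aggregate_monthly",
    "infer_pm25_at_pm10_only_stations",
    "compute_ratios",
    "build_soft_residuals",
    "fit_residual_covariance",
    "estimate_pm25_field",
    "cross_validate",
    "METHODS",
]

METHODS = ("kriging", "lur", "lur_bme")


@dataclass
class CVStats:
    """Cross-validation error summary (signed errors: predicted - observed)."""

    errors: pd.DataFrame  # columns: station_id, month, observed, predicted, error
    method: str

    @property
    def summary(self) -> dict[str, float]:
        e = self.errors["error"].to_numpy(float)
        n = e.size
        return {
            "n": int(n),
            "mean_error": float(np.mean(e)),
            "sd": float(np.std(e, ddof=1)) if n > 1 else 0.0,
            "median": float(np.median(e)),
            "max": float(np.max(e)),
            "min": float(np.min(e)),
            "mse": float(np.mean(e**2)),
            "mae": float(np.mean(np.abs(e))),
        }


# ---------------------------------------------------------------------------
# stage 0


def aggregate_monthly(daily: pd.DataFrame, completeness: float = 0.75) -> pd.DataFrame:
    """Aggregate daily records to monthly means.

    ``daily`` has columns (station_id, date, pollutant, value) with ISO
    dates.  A station-month is reported only if the fraction of calendar
    days with a value is at least ``completeness`` (data-completeness rule
    for monthly summary statistics); months are re-indexed to a 0-based
    integer and the index -> YYYY-MM mapping is attached as
    ``result.attrs['month_map']``.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["ym"] = df["date"].dt.to_period("M")
    months = sorted(df["ym"].unique())
    month_index = {m: i for i, m in enumerate(months)}
    rows = []
    for (sid, pol, ym), grp in df.groupby(["station_id", "pollutant", "ym"]):
        n_days = ym.days_in_month
        frac = grp["date"].dt.day.nunique() / n_days
        if frac < completeness:
            logger.info("dropping %s %s %s: completeness %.3f < %.2f",
                        sid, pol, ym, frac, completeness)
            continue
        rows.append({"station_id": sid, "month": month_index[ym], "pollutant": pol,
                     "value": float(grp["value"].mean())})
    out = pd.DataFrame(rows, columns=["station_id", "month", "pollutant", "value"])
    out.attrs["month_map"] = {i: str(m) for m, i in month_index.items()}
    return out


def infer_pm25_at_pm10_only_stations(
    monthly: pd.DataFrame,
    stations: pd.DataFrame,
    kb: GeneralKB,
    n_hard: int = 10,
) -> pd.DataFrame:
    """Estimate PM2.5 at PM10-only stations month by month by hard-data-only
    estimation (identical to simple kriging), and append the estimates with
    an ``estimated=True`` provenance flag."""
    from .covariance import covariance_matrix, safe_cholesky

    roles = {
        sid: set(str(r).split(";"))
        for sid, r in zip(stations["station_id"], stations["roles"])
    }
    coords = stations.set_index("station_id")[["x", "y"]]
    pm25 = monthly[monthly["pollutant"] == "pm25"]
    targets = [s for s, r in roles.items() if "pm25" not in r]
    if pm25["station_id"].nunique() < 2:
        raise ValueError("need at least 2 PM2.5-observing stations for stage-0 estimation")
    out = monthly.copy()
    out["estimated"] = False
    new_rows = []
    tgt_xy = coords.loc[targets].to_numpy(float) if targets else np.empty((0, 2))
    for t, grp in pm25.groupby("month"):
        if grp.empty or not targets:
            if grp.empty:
                logger.info("month %s: no PM2.5 data, skipped", t)
            continue
        # one kriging system per month, solved jointly for all target stations
        pts = np.column_stack([
            coords.loc[grp["station_id"], "x"],
            coords.loc[grp["station_id"], "y"],
            np.full(len(grp), float(t)),
        ])
        vals = grp["value"].to_numpy(float)
        tgt = np.column_stack([tgt_xy, np.full(len(targets), float(t))])
        if len(grp) <= n_hard:
            c_hh = covariance_matrix(kb.covariance, pts)
            c_th = covariance_matrix(kb.covariance, tgt, pts)
            L = safe_cholesky(c_hh)
            alpha = np.linalg.solve(L.T, np.linalg.solve(L, vals - kb.mean_at(pts)))
            means = kb.mean_at(tgt) + c_th @ alpha
        else:
            # per-target nearest-station window (scaled metric is spatial here)
            means = np.empty(len(targets))
            d2 = (
                (tgt_xy[:, None, 0] - pts[None, :, 0]) ** 2
                + (tgt_xy[:, None, 1] - pts[None, :, 1]) ** 2
            )
            for i in range(len(targets)):
                idx = np.argsort(d2[i], kind="stable")[:n_hard]
                c_hh = covariance_matrix(kb.covariance, pts[idx])
                c_th = covariance_matrix(kb.covariance, tgt[i], pts[idx])
                L = safe_cholesky(c_hh)
                alpha = np.linalg.solve(L.T, np.linalg.solve(L, vals[idx] - kb.mean_at(pts[idx])))
                means[i] = kb.mean_at(tgt[i])[0] + float(c_th.ravel() @ alpha)
        for sid, mean in zip(targets, means):
            new_rows.append({"station_id": sid, "month": int(t), "pollutant": "pm25",
                             "value": max(float(mean), 0.0), "estimated": True})
    return pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)


def compute_ratios(series: pd.DataFrame, flag_threshold: float = 1.5) -> pd.DataFrame:
    """Per station-month ratio r = PM2.5 / PM10.

    Zero-PM10 months are skipped (count logged); ratios above
    ``flag_threshold`` are kept but flagged — physically a ratio cannot
    exceed 1, but measurement noise can push observed ratios past it.
    """
    pm25 = series[series["pollutant"] == "pm25"].set_index(["station_id", "month"])["value"]
    pm10 = series[series["pollutant"] == "pm10"].set_index(["station_id", "month"])["value"]
    joined = pd.concat([pm25.rename("x"), pm10.rename("y")], axis=1, join="inner")
    zero_y = joined["y"] == 0
    if zero_y.any():
        logger.info("skipping %d station-months with PM10 = 0", int(zero_y.sum()))
    joined = joined[~zero_y]
    r = (joined["x"] / joined["y"]).rename("value")
    out = r.reset_index()
    out["pollutant"] = "ratio"
    out["flagged"] = out["value"] > flag_threshold
    n_over = int((out["value"] > 1.0).sum())
    if n_over:
        logger.info("kept %d station-months with observed ratio > 1", n_over)
    return out[["station_id", "month", "pollutant", "value", "flagged"]]


# ---------------------------------------------------------------------------
# soft residual construction


@dataclass
class SoftResiduals:
    """Trend field with its interval bounds, plus residual evidence.

    trend: DataFrame (station_id, month, x, y, trend, lower, upper)
    hard: DataFrame (station_id, month, x, y, residual) at PM2.5 stations
    soft: DataFrame (station_id, month, x, y, lower, upper) elsewhere
    """

    trend: pd.DataFrame
    hard: pd.DataFrame
    soft: pd.DataFrame


def build_soft_residuals(
    lur_model: RatioLUR,
    features: pd.DataFrame,
    points: pd.DataFrame,
    pm10: pd.Series,
    pm25_obs: pd.Series | None,
) -> SoftResiduals:
    """Trend and residual evidence for the estimation stage.

    ``points`` carries (station_id, month, x, y) rows aligned with
    ``features``; ``pm10`` gives Y at each row (observed or stage-0
    estimated); ``pm25_obs`` gives X at the rows where it is observed (NaN
    elsewhere).  The trend is m = r_hat * Y with bounds [l*Y, u*Y] from the
    clamped ratio interval; rows with observed PM2.5 yield hard residuals
    X - m, the rest yield interval soft residuals [l*Y - m, u*Y - m].
    """
    r_hat, sd = lur_model.predict_with_sd(features)
    y = pm10.to_numpy(float)
    keep = np.isfinite(y)
    if not keep.all():
        logger.info("skipping %d points with missing PM10", int((~keep).sum()))
    lo = np.empty(len(points))
    hi = np.empty(len(points))
    hard_flag = np.zeros(len(points), dtype=bool)
    for i, (r, s) in enumerate(zip(r_hat, sd)):
        iv = ratio_to_interval(float(np.clip(r, 1e-6, 2 - 1e-6)), float(s))
        lo[i], hi[i] = iv.lower, iv.upper
        hard_flag[i] = iv.hard_equivalent
    trend = np.clip(r_hat, lo, hi) * y
    t_lo, t_hi = lo * y, hi * y
    base = points.copy()
    base["trend"] = trend
    base["lower"] = t_lo
    base["upper"] = t_hi
    base = base[keep]

    x = pm25_obs.to_numpy(float) if pm25_obs is not None else np.full(len(points), np.nan)
    has_x = np.isfinite(x) & keep
    hard = base.loc[has_x, ["station_id", "month", "x", "y"]].copy()
    hard["residual"] = x[has_x] - trend[has_x]
    soft_mask = keep & ~has_x
    soft = base.loc[soft_mask, ["station_id", "month", "x", "y"]].copy()
    soft["lower"] = (t_lo - trend)[soft_mask]
    soft["upper"] = (t_hi - trend)[soft_mask]
    return SoftResiduals(trend=base, hard=hard, soft=soft)


def fit_residual_covariance(
    hard: pd.DataFrame,
    stations: pd.DataFrame,
    spatial_bin_width: float = 2.0,
    max_tau: int = 12,
    random_state: int = 0,
) -> CovarianceModel:
    """Fit the nested exponential model to hard-residual covariance."""
    series = hard.rename(columns={"residual": "value"}).copy()
    series["pollutant"] = "pm25"
    emp = empirical_covariance(series, stations, pollutant="pm25",
                               spatial_bin_width=spatial_bin_width, max_tau=max_tau)
    return fit_nested_exponential(emp, random_state=random_state)


# ---------------------------------------------------------------------------
# full-field estimation


def _station_points(stations: pd.DataFrame, months: np.ndarray) -> pd.DataFrame:
    rows = []
    for _, st in stations.iterrows():
        for t in months:
            rows.append({"station_id": st["station_id"], "month": int(t),
                         "x": st["x"], "y": st["y"]})
    return pd.DataFrame(rows)


def estimate_pm25_field(
    method: str,
    monthly: pd.DataFrame,
    stations: pd.DataFrame,
    landuse: LanduseMap,
    grid: GridSpec,
    months: list[int],
    config: Config | None = None,
    pm25_covariance: CovarianceModel | None = None,
    residual_covariance: CovarianceModel | None = None,
    lur_model: RatioLUR | None = None,
) -> dict[str, np.ndarray]:
    """Mean (and, for the geostatistical methods, variance) grids of PM2.5.

    ``kriging``: simple kriging of the PM2.5 observations with a covariance
    fitted to them, ignoring their uncertainty.  ``lur``: the trend field
    m = r_hat * Y alone (Y kriged onto the grid from PM10 observations).
    ``lur_bme``: m plus the BME estimate of the residual field from hard and
    interval soft residuals.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    cfg = config or Config()
    cells = grid.cell_centers()
    n_cells = cells.shape[0]
    pm25 = monthly[monthly["pollutant"] == "pm25"]
    pm10 = monthly[monthly["pollutant"] == "pm10"]
    coords = stations.set_index("station_id")[["x", "y"]]

    def hard_xyz(df):
        return np.column_stack([
            coords.loc[df["station_id"], "x"],
            coords.loc[df["station_id"], "y"],
            df["month"].to_numpy(float),
        ])

    out: dict[str, np.ndarray] = {}
    if method == "kriging":
        if pm25_covariance is None:
            emp = empirical_covariance(pm25, stations)
            pm25_covariance = fit_nested_exponential(emp, random_state=cfg.seed)
        sk = SimpleKriging(covariance=pm25_covariance, n_hard=cfg.n_hard)
        sk.fit(hard_xyz(pm25), pm25["value"].to_numpy(float))
        mean = np.empty((n_cells, len(months)))
        sd = np.empty((n_cells, len(months)))
        for j, t in enumerate(months):
            pts = np.column_stack([cells, np.full(n_cells, float(t))])
            mean[:, j], sd[:, j] = sk.predict(pts, return_std=True)
        out["mean"] = mean
        out["variance"] = sd**2
        return out

    # both LUR-based methods need the trend at grid cells
    months_arr = np.asarray(months, dtype=int)
    if lur_model is None:
        lur_model, _ = fit_ratio_lur(monthly, stations, landuse, cfg)
    cell_feats = compute_buffer_features(landuse, cells, cfg.buffer_rings)
    r_hat, r_sd = lur_model.predict_with_sd(cell_feats)
    ivs = [ratio_to_interval(float(np.clip(r, 1e-6, 2 - 1e-6)), float(s))
           for r, s in zip(r_hat, r_sd)]
    lo = np.array([iv.lower for iv in ivs])
    hi = np.array([iv.upper for iv in ivs])
    r_mid = np.clip(r_hat, lo, hi)

    # PM10 on the grid by simple kriging of PM10 observations
    emp10 = empirical_covariance(pm10, stations, pollutant="pm10")
    cov10 = fit_nested_exponential(emp10, random_state=cfg.seed)
    sk10 = SimpleKriging(covariance=cov10, n_hard=cfg.n_hard)
    sk10.fit(hard_xyz(pm10), pm10["value"].to_numpy(float))
    trend = np.empty((n_cells, len(months)))
    y_grid = np.empty((n_cells, len(months)))
    for j, t in enumerate(months_arr):
        pts = np.column_stack([cells, np.full(n_cells, float(t))])
        y_grid[:, j] = np.maximum(sk10.predict(pts), 0.0)
        trend[:, j] = r_mid * y_grid[:, j]
    out["trend"] = trend
    if method == "lur":
        out["mean"] = trend
        return out

    # lur_bme: residual evidence at stations, BME back onto the grid
    st_pts = _station_points(stations, months_arr)
    st_feats = compute_station_features(stations, landuse, cfg).loc[
        st_pts["station_id"]
    ].reset_index(drop=True)
    key = ["station_id", "month"]
    pm10_at = st_pts.merge(pm10, on=key, how="left")["value"]
    pm25_at = st_pts.merge(pm25, on=key, how="left")["value"]
    sr = build_soft_residuals(lur_model, st_feats, st_pts, pm10_at, pm25_at)
    if residual_covariance is None:
        residual_covariance = fit_residual_covariance(sr.hard, stations,
                                                      random_state=cfg.seed)
    bme = BMEInterpolator(
        covariance=residual_covariance,
        mean=float(sr.hard["residual"].mean()),
        n_hard=cfg.n_hard, n_soft=cfg.n_soft,
        n_nodes=cfg.quad_nodes, sd_span=cfg.quad_sd_span, n_qmc=cfg.quad_qmc_points,
    )
    bme.fit(
        sr.hard[["x", "y", "month"]].to_numpy(float),
        sr.hard["residual"].to_numpy(float),
        soft_points=sr.soft[["x", "y", "month"]].to_numpy(float),
        soft_lower=sr.soft["lower"].to_numpy(float),
        soft_upper=sr.soft["upper"].to_numpy(float),
    )
    resid_mean = np.empty((n_cells, len(months)))
    resid_sd = np.empty((n_cells, len(months)))
    for j, t in enumerate(months_arr):
        pts = np.column_stack([cells, np.full(n_cells, float(t))])
        resid_mean[:, j], resid_sd[:, j] = bme.predict(pts, return_std=True)
    out["residual_mean"] = resid_mean
    out["mean"] = trend + resid_mean
    out["variance"] = resid_sd**2
    return out


# ---------------------------------------------------------------------------
# LUR fitting from monthly data


def fit_ratio_lur(
    monthly: pd.DataFrame,
    stations: pd.DataFrame,
    landuse: LanduseMap,
    cfg: Config,
    exclude_station: str | None = None,
    pm25_covariance: CovarianceModel | None = None,
    station_features: pd.DataFrame | None = None,
) -> tuple[RatioLUR, pd.DataFrame]:
    """Stage-0 infill + ratio computation + stepwise LUR fit.

    Returns the fitted model and the augmented monthly table (with stage-0
    PM2.5 estimates).  ``exclude_station``'s PM2.5 records are withheld from
    every step (stage-0 estimation, ratios, regression)."""
    data = monthly.copy()
    if exclude_station is not None:
        data = data[~((data["station_id"] == exclude_station)
                      & (data["pollutant"] == "pm25"))]
    pm25 = data[data["pollutant"] == "pm25"]
    cov25 = pm25_covariance
    if cov25 is None:
        emp = empirical_covariance(pm25, stations)
        cov25 = fit_nested_exponential(emp, random_state=cfg.seed)
    kb = GeneralKB(mean=float(pm25["value"].mean()), covariance=cov25)
    augmented = infer_pm25_at_pm10_only_stations(data, stations, kb, n_hard=cfg.n_hard)
    ratios = compute_ratios(augmented)
    if exclude_station is not None:
        ratios = ratios[ratios["station_id"] != exclude_station]
    if station_features is None:
        station_features = compute_station_features(stations, landuse, cfg)
    # The candidate features are station-static, so the regression is fit on
    # station-mean ratios: pooled monthly rows would give identical
    # coefficients but 36-fold pseudo-replicated significance (months of one
    # station share its features and its correlated residuals), under which
    # stepwise selection badly overfits the ~26 true spatial units.
    grp = ratios.groupby("station_id")["value"]
    mean_ratio = grp.mean()
    within_var = float(grp.var(ddof=1).fillna(0.0).mean())
    feats = station_features.loc[mean_ratio.index]
    model = RatioLUR(p_enter=cfg.p_enter, p_remove=cfg.p_remove, vif_max=cfg.vif_max)
    model.fit(feats.reset_index(drop=True), mean_ratio.to_numpy(float))
    # prediction SD must cover a single month's ratio, not the station mean:
    # add the pooled within-station monthly variance to the residual scale
    model.resid_se_ = float(np.sqrt(model.resid_se_**2 + within_var))
    return model, augmented


def compute_station_features(stations: pd.DataFrame, landuse: LanduseMap,
                             cfg: Config) -> pd.DataFrame:
    """Ring-buffer features at each station (time-invariant), indexed by id."""
    feats = compute_buffer_features(
        landuse, stations[["x", "y"]].to_numpy(float), cfg.buffer_rings
    )
    feats.index = stations["station_id"].to_numpy()
    return feats


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    method: str,
    monthly: pd.DataFrame,
    stations: pd.DataFrame,
    landuse: LanduseMap,
    config: Config | None = None,
) -> CVStats:
    """Leave-one-station-out cross-validation of a PM2.5 estimation method.

    For each PM2.5-observing station, its entire PM2.5 series is withheld;
    the method's data-dependent parts are refit without it (LUR always;
    covariance refit only if ``config.covariance_refit_per_fold``), its
    station-months are predicted, and signed errors (predicted - observed)
    are pooled.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    cfg = config or Config()
    coords = stations.set_index("station_id")[["x", "y"]]
    pm25 = monthly[monthly["pollutant"] == "pm25"]
    pm10 = monthly[monthly["pollutant"] == "pm10"]
    pm25_sids = sorted(pm25["station_id"].unique())
    if len(pm25_sids) < 3:
        raise ValueError("need at least 3 PM2.5-observing stations")

    station_features = (
        compute_station_features(stations, landuse, cfg) if method != "kriging" else None
    )

    # covariances fitted once on all stations by default (refit is a flag)
    global_cov25 = None
    global_resid_cov = None
    global_lur = None
    if not cfg.covariance_refit_per_fold:
        emp = empirical_covariance(pm25, stations)
        global_cov25 = fit_nested_exponential(emp, random_state=cfg.seed)
        if method == "lur_bme":
            global_lur, augmented = fit_ratio_lur(monthly, stations, landuse, cfg,
                                                  pm25_covariance=global_cov25,
                                                  station_features=station_features)
            st_pts = _station_points(stations, pm25["month"].unique())
            feats = station_features.loc[st_pts["station_id"]].reset_index(drop=True)
            key = ["station_id", "month"]
            y_at = st_pts.merge(augmented[augmented["pollutant"] == "pm10"],
                                on=key, how="left")["value"]
            x_at = st_pts.merge(pm25, on=key, how="left")["value"]
            sr_all = build_soft_residuals(global_lur, feats, st_pts, y_at, x_at)
            global_resid_cov = fit_residual_covariance(sr_all.hard, stations,
                                                       random_state=cfg.seed)

    records = []
    for sid in pm25_sids:
        held = pm25[pm25["station_id"] == sid]
        train25 = pm25[pm25["station_id"] != sid]
        pk_xy = coords.loc[sid].to_numpy(float)

        if method == "kriging":
            cov = global_cov25
            if cov is None:
                emp = empirical_covariance(train25, stations[stations["station_id"] != sid])
                cov = fit_nested_exponential(emp, random_state=cfg.seed)
            sk = SimpleKriging(covariance=cov, n_hard=cfg.n_hard)
            pts = np.column_stack([
                coords.loc[train25["station_id"], "x"],
                coords.loc[train25["station_id"], "y"],
                train25["month"].to_numpy(float),
            ])
            sk.fit(pts, train25["value"].to_numpy(float))
            tgt = np.column_stack([
                np.full(len(held), pk_xy[0]),
                np.full(len(held), pk_xy[1]),
                held["month"].to_numpy(float),
            ])
            pred = sk.predict(tgt)
        else:
            lur_model, augmented = fit_ratio_lur(monthly, stations, landuse, cfg,
                                                 exclude_station=sid,
                                                 pm25_covariance=global_cov25,
                                                 station_features=station_features)
            feats_k = station_features.loc[[sid]].reset_index(drop=True)
            r_hat, r_sd = lur_model.predict_with_sd(feats_k)
            iv = ratio_to_interval(float(np.clip(r_hat[0], 1e-6, 2 - 1e-6)), float(r_sd[0]))
            r_mid = float(np.clip(r_hat[0], iv.lower, iv.upper))
            y_held = held.merge(pm10[pm10["station_id"] == sid], on="month",
                                suffixes=("", "_y"))
            y_map = dict(zip(y_held["month"], y_held["value_y"]))
            months_t = held["month"].to_numpy(int)
            y_vec = np.array([y_map.get(t, np.nan) for t in months_t])
            trend_k = r_mid * y_vec
            if method == "lur":
                pred = trend_k
            else:
                # residual evidence from training stations
                train_st = stations[stations["station_id"] != sid]
                st_pts = _station_points(train_st, pm25["month"].unique())
                feats = station_features.loc[st_pts["station_id"]].reset_index(drop=True)
                key = ["station_id", "month"]
                y_at = st_pts.merge(augmented[augmented["pollutant"] == "pm10"],
                                    on=key, how="left")["value"]
                x_at = st_pts.merge(train25, on=key, how="left")["value"]
                sr = build_soft_residuals(lur_model, feats, st_pts, y_at, x_at)
                resid_cov = global_resid_cov
                if resid_cov is None:
                    resid_cov = fit_residual_covariance(sr.hard, train_st,
                                                        random_state=cfg.seed)
                bme = BMEInterpolator(
                    covariance=resid_cov,
                    mean=float(sr.hard["residual"].mean()),
                    n_hard=cfg.n_hard, n_soft=cfg.n_soft,
                    n_nodes=cfg.quad_nodes, sd_span=cfg.quad_sd_span,
                    n_qmc=cfg.quad_qmc_points,
                )
                bme.fit(
                    sr.hard[["x", "y", "month"]].to_numpy(float),
                    sr.hard["residual"].to_numpy(float),
                    soft_points=sr.soft[["x", "y", "month"]].to_numpy(float),
                    soft_lower=sr.soft["lower"].to_numpy(float),
                    soft_upper=sr.soft["upper"].to_numpy(float),
                )
                tgt = np.column_stack([
                    np.full(len(held), pk_xy[0]),
                    np.full(len(held), pk_xy[1]),
                    held["month"].to_numpy(float),
                ])
                pred = trend_k + bme.predict(tgt)

        for (t, obs), p in zip(zip(held["month"], held["value"]), pred):
            if np.isfinite(p):
                records.append({"station_id": sid, "month": int(t), "observed": float(obs),
                                "predicted": float(p), "error": float(p - obs)})
    errors = pd.DataFrame(records)
    errors["error"] = errors["predicted"] - errors["observed"]
    return CVStats(errors=errors, method=method)
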