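"""Readers and writers for station tables, observation series, landuse layers,
gridded outputs and run configuration.

Conventions shared across the package:

* Coordinates are planar kilometers with Euclidean distance.  Buffer radii
  are given in meters and converted internally (1 km = 1000 m).
* Time is a 0-based monthly integer index.  Calendar arithmetic never enters
  the numerics; a sidecar ``month index -> YYYY-MM`` mapping may accompany
  reports.
* Gridded fields are exchanged as ESRI ASCII grids (plain text, nodata
  -9999), which round-trip losslessly to float32 precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape, mapping
from shapely.geometry.base import BaseGeometry

__all__ = [
    "ConfigError",
    "ValidationError",
    "Config",
    "GridSpec",
    "LanduseMap",
    "DEFAULT_BUFFER_RINGS",
    "LANDUSE_CLASSES",
    "NODATA",
    "load_config",
    "save_config",
    "read_pm_csv",
    "write_pm_csv",
    "read_stations_csv",
    "write_stations_csv",
    "read_landuse_geojson",
    "write_landuse_geojson",
    "read_grid_asc",
    "write_estimate_grid",
]


class ConfigError(ValueError):
    """Raised for missing or inconsistent configuration values."""


class ValidationError(ValueError):
    """Raised when an input table violates a declared invariant."""


#: Buffer annuli (inner m, outer m) used for landuse feature extraction.
DEFAULT_BUFFER_RINGS: tuple[tuple[float, float], ...] = (
    (0.0, 50.0),
    (50.0, 100.0),
    (100.0, 300.0),
    (300.0, 500.0),
    (500.0, 1000.0),
)

#: Declared vocabulary of landuse class labels.
LANDUSE_CLASSES = frozenset(
    {
        "road",
        "forest",
        "industry",
        "park",
        "railroad",
        "government",
        "public_equipment",
        "port",
        "farm",
        "residence",
        "commerce",
        "school",
        "hospital",
        "freeway",
        "highway",
        "utilities",
        "water",
    }
)

POLLUTANTS = ("pm25", "pm10", "ratio")

NODATA = -9999.0


@dataclass
class Config:
    """Run configuration with documented defaults.

    Parameters are grouped as: spatial domain, LUR buffer rings and stepwise
    thresholds, BME neighborhood sizes and quadrature, and the RNG seed.
    """

    domain_extent: tuple[float, float, float, float] = (0.0, 0.0, 40.0, 40.0)
    grid_resolution: float = 1.0  # km
    month_range: tuple[int, int] = (0, 36)  # half-open [start, stop)
    buffer_rings: tuple[tuple[float, float], ...] = DEFAULT_BUFFER_RINGS
    p_enter: float = 0.05
    p_remove: float = 0.10
    vif_max: float = 10.0
    n_hard: int = 10
    n_soft: int = 4
    quad_nodes: int = 401
    quad_sd_span: float = 8.0
    quad_qmc_points: int = 512
    covariance_refit_per_fold: bool = False
    loo_level: str = "station"  # or "station_month"
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.domain_extent
        if not (x1 > x0 and y1 > y0):
            raise ConfigError("domain_extent must be (x0, y0, x1, y1) with positive area")
        if self.grid_resolution <= 0:
            raise ConfigError("grid_resolution must be > 0")
        if self.month_range[1] <= self.month_range[0]:
            raise ConfigError("month_range must be a non-empty half-open range")
        rings = [tuple(map(float, r)) for r in self.buffer_rings]
        for (i0, o0), (i1, o1) in zip(rings, rings[1:]):
            if o0 > i1:
                raise ConfigError(f"overlapping rings: ({i0}, {o0}) and ({i1}, {o1})")
        for inner, outer in rings:
            if not (0 <= inner < outer):
                raise ConfigError(f"ring ({inner}, {outer}) must satisfy 0 <= inner < outer")
        self.buffer_rings = tuple(rings)
        if not self.p_enter < self.p_remove:
            raise ConfigError("p_enter must be < p_remove")
        if self.loo_level not in ("station", "station_month"):
            raise ConfigError("loo_level must be 'station' or 'station_month'")

    def grid_spec(self) -> "GridSpec":
        x0, y0, x1, y1 = self.domain_extent
        res = self.grid_resolution
        return GridSpec(
            x0=x0, y0=y0, nx=int(round((x1 - x0) / res)), ny=int(round((y1 - y0) / res)), cell_km=res
        )


@dataclass(frozen=True)
class GridSpec:
    """Regular raster geometry: origin (lower-left corner), cell counts, size."""

    x0: float
    y0: float
    nx: int
    ny: int
    cell_km: float

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ConfigError("GridSpec requires nx, ny >= 1")
        if self.cell_km <= 0:
            raise ConfigError("GridSpec requires cell_km > 0")

    def cell_centers(self) -> np.ndarray:
        """(nx*ny, 2) array of cell-center coordinates, row-major from the
        top row (north) downwards, matching ESRI ASCII raster order."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_km
        ys = self.y0 + (np.arange(self.ny)[::-1] + 0.5) * self.cell_km
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class LanduseMap:
    """Polygon landuse layer in planar km coordinates.

    ``geoms`` and ``classes`` are parallel lists; ``intensity`` is an optional
    per-polygon scalar (e.g. vehicle volume per unit road area).
    """

    geoms: list[BaseGeometry] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)
    intensity: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.geoms) != len(self.classes):
            raise ValidationError("geoms and classes must be parallel lists")
        if self.intensity and len(self.intensity) != len(self.geoms):
            raise ValidationError("intensity must be empty or parallel to geoms")
        for i, g in enumerate(self.geoms):
            if not g.is_valid:
                raise ValidationError(f"invalid polygon at feature {i} (class {self.classes[i]})")

    def __len__(self) -> int:
        return len(self.geoms)

    def total_area_km2(self) -> float:
        return float(sum(g.area for g in self.geoms))

    def subset(self, cls: str) -> "LanduseMap":
        idx = [i for i, c in enumerate(self.classes) if c == cls]
        return LanduseMap(
            geoms=[self.geoms[i] for i in idx],
            classes=[cls] * len(idx),
            intensity=[self.intensity[i] for i in idx] if self.intensity else [],
        )


# ---------------------------------------------------------------------------
# configuration


_TUPLE_KEYS = {"domain_extent", "month_range"}


def load_config(path: str | Path) -> Config:
    """Load a YAML configuration, filling documented defaults.

    Unknown keys raise :class:`ConfigError` (typo guard); invariants are
    checked by :class:`Config`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in raw.items():
        if key in _TUPLE_KEYS:
            val = tuple(val)
        elif key == "buffer_rings":
            val = tuple(tuple(r) for r in val)
        kwargs[key] = val
    return Config(**kwargs)


def save_config(cfg: Config, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["domain_extent"] = list(data["domain_extent"])
    data["month_range"] = list(data["month_range"])
    data["buffer_rings"] = [list(r) for r in data["buffer_rings"]]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# observation tables


def _validate_pm(df: pd.DataFrame) -> pd.DataFrame:
    required = {"station_id", "month", "pollutant", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    df = df.copy()
    df["station_id"] = df["station_id"].astype(str)
    df["month"] = df["month"].astype(int)
    df["value"] = df["value"].astype(float)
    bad = ~df["pollutant"].isin(POLLUTANTS)
    if bad.any():
        raise ValidationError(f"unknown pollutant labels: {sorted(df.loc[bad, 'pollutant'].unique())}")
    dup = df.duplicated(["station_id", "month", "pollutant"])
    if dup.any():
        rows = df.loc[dup, ["station_id", "month", "pollutant"]].head(5).to_dict("records")
        raise ValidationError(f"duplicate (station, month, pollutant) keys, e.g. {rows}")
    conc = df["pollutant"].isin(("pm25", "pm10"))
    neg = conc & (df["value"] < 0)
    if neg.any():
        raise ValidationError(f"negative concentrations at rows {df.index[neg].tolist()[:10]}")
    nonpos = (df["pollutant"] == "ratio") & (df["value"] <= 0)
    if nonpos.any():
        raise ValidationError(f"non-positive ratios at rows {df.index[nonpos].tolist()[:10]}")
    return df


def read_pm_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format observation table.

    Columns: ``station_id, month, pollutant, value`` with pollutant in
    {pm25, pm10, ratio}; (station, month, pollutant) keys must be unique and
    concentrations non-negative.
    """
    return _validate_pm(pd.read_csv(path))


def write_pm_csv(df: pd.DataFrame, path: str | Path) -> None:
    _validate_pm(df)[["station_id", "month", "pollutant", "value"]].to_csv(path, index=False)


def _validate_stations(df: pd.DataFrame) -> pd.DataFrame:
    required = {"station_id", "x", "y", "roles"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    df = df.copy()
    df["station_id"] = df["station_id"].astype(str)
    if df["station_id"].duplicated().any():
        raise ValidationError("duplicate station ids")
    df[["x", "y"]] = df[["x", "y"]].astype(float)
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValidationError("non-finite station coordinates")
    for sid, roles in zip(df["station_id"], df["roles"]):
        parts = [p for p in str(roles).split(";") if p]
        if not parts or any(p not in ("pm25", "pm10") for p in parts):
            raise ValidationError(f"station {sid}: roles must be ';'-joined subset of pm25;pm10")
    return df


def read_stations_csv(path: str | Path) -> pd.DataFrame:
    """Read a station table with columns ``station_id, x, y, roles`` where
    roles is a ';'-joined subset of {pm25, pm10} (e.g. ``pm25;pm10``)."""
    return _validate_stations(pd.read_csv(path))


def write_stations_csv(df: pd.DataFrame, path: str | Path) -> None:
    _validate_stations(df)[["station_id", "x", "y", "roles"]].to_csv(path, index=False)


def station_roles(df: pd.DataFrame) -> dict[str, frozenset[str]]:
    return {
        sid: frozenset(p for p in str(roles).split(";") if p)
        for sid, roles in zip(df["station_id"], df["roles"])
    }


# ---------------------------------------------------------------------------
# landuse


def read_landuse_geojson(
    path: str | Path,
    class_property: str = "class",
    class_map: dict[str, str] | None = None,
) -> LanduseMap:
    """Read a GeoJSON FeatureCollection of landuse polygons.

    Coordinates are planar km unless the collection carries a top-level
    ``"units": "m"`` member, in which case they are scaled to km on read.
    Unknown class labels raise unless ``class_map`` translates them.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValidationError("expected a GeoJSON FeatureCollection")
    scale = 0.001 if gj.get("units") == "m" else 1.0
    geoms, classes, intensity = [], [], []
    has_intensity = False
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if class_property not in props:
            raise ValidationError(f"feature {i} missing '{class_property}' property")
        cls = props[class_property]
        if class_map is not None:
            cls = class_map.get(cls, cls)
        if cls not in LANDUSE_CLASSES:
            raise ValidationError(
                f"feature {i}: unknown landuse class '{cls}' (supply a class_map to translate)"
            )
        geom = shape(feat["geometry"])
        if scale != 1.0:
            from shapely import affinity

            geom = affinity.scale(geom, xfact=scale, yfact=scale, origin=(0, 0))
        geoms.append(geom)
        classes.append(cls)
        val = props.get("intensity")
        if val is not None:
            has_intensity = True
        intensity.append(float(val) if val is not None else 0.0)
    return LanduseMap(geoms=geoms, classes=classes, intensity=intensity if has_intensity else [])


def write_landuse_geojson(lmap: LanduseMap, path: str | Path) -> None:
    feats = []
    for i, (g, c) in enumerate(zip(lmap.geoms, lmap.classes)):
        props = {"class": c}
        if lmap.intensity:
            props["intensity"] = lmap.intensity[i]
        feats.append({"type": "Feature", "geometry": mapping(g), "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# grids (ESRI ASCII)


def write_estimate_grid(values: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write a field as an ESRI ASCII grid (text; nodata -9999).

    ``values`` is length nx*ny in the row-major top-down order of
    :meth:`GridSpec.cell_centers`; NaN cells become the nodata value.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size != grid.nx * grid.ny:
        raise ValidationError(f"expected {grid.nx * grid.ny} values, got {values.size}")
    arr = values.reshape(grid.ny, grid.nx).copy()
    arr[~np.isfinite(arr)] = NODATA
    try:
        with open(path, "w") as fh:
            fh.write(f"ncols {grid.nx}\n")
            fh.write(f"nrows {grid.ny}\n")
            fh.write(f"xllcorner {grid.x0!r}\n")
            fh.write(f"yllcorner {grid.y0!r}\n")
            fh.write(f"cellsize {grid.cell_km!r}\n")
            fh.write(f"NODATA_value {NODATA}\n")
            for row in arr:
                fh.write(" ".join(f"{v:.7g}" for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing grid to {path}: {exc}") from exc


def read_grid_asc(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    grid = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        nx=int(header["ncols"]),
        ny=int(header["nrows"]),
        cell_km=header["cellsize"],
    )
    arr = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", NODATA)
    arr[arr == nodata] = np.nan
    return arr.ravel(), grid
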