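"""Geodesy and I/O primitives shared by all spatial modules.

All distances are great-circle on a sphere of radius 6371.0088 km (the
IUGG mean Earth radius); at foraging-trip scales (tens of km) the error
relative to the WGS-84 ellipsoid is negligible. Coordinates are decimal
degrees (lon, lat); timestamps are UTC throughout, with a configurable
local offset used only for civil-date assignment.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

FIX_COLUMNS = ["bird_id", "group", "timestamp", "lon", "lat"]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon1, lat1) and (lon2, lat2).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection centred on (lon0, lat0).

    Forward maps lon/lat degrees to (x, y) in km on a plane tangent at the
    centre; distances from the centre and azimuths are preserved exactly,
    which is what the movement models need.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._l0 = np.radians(lon0)
        self._p0 = np.radians(lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dl = lam - self._l0
        cosc = (np.sin(self._p0) * np.sin(phi)
                + np.cos(self._p0) * np.cos(phi) * np.cos(dl))
        c = np.arccos(np.clip(cosc, -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dl)
        y = EARTH_RADIUS_KM * k * (np.cos(self._p0) * np.sin(phi)
                                   - np.sin(self._p0) * np.cos(phi) * np.cos(dl))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        c = rho
        safe = np.where(rho > 1e-12, rho, 1.0)
        phi = np.arcsin(np.clip(
            np.cos(c) * np.sin(self._p0)
            + np.where(rho > 1e-12, y * np.sin(c) / safe, 0.0) * np.cos(self._p0),
            -1.0, 1.0))
        lam = self._l0 + np.arctan2(
            x * np.sin(c),
            safe * np.cos(c) * np.cos(self._p0) - y * np.sin(c) * np.sin(self._p0))
        lam = np.where(rho > 1e-12, lam, self._l0)
        phi = np.where(rho > 1e-12, phi, self._p0)
        return np.degrees(lam), np.degrees(phi)


@dataclass
class ColonyPolygon:
    """A colony boundary: closed lon/lat ring with a reference centre point.

    A fix exactly on the boundary counts as inside, so trip endpoints are
    deterministic under the segmentation rule (last fix inside / first fix
    back inside).
    """

    colony_id: str
    ring: np.ndarray  # (n, 2) lon/lat, closed (first == last)
    center: tuple[float, float] | None = None
    _poly: Polygon = field(init=False, repr=False, default=None)
    _prepared: object = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.ring = np.asarray(self.ring, dtype=float)
        if not np.allclose(self.ring[0], self.ring[-1]):
            self.ring = np.vstack([self.ring, self.ring[:1]])
        self._poly = Polygon(self.ring)
        if not self._poly.is_valid:
            raise ValueError(f"colony ring for {self.colony_id!r} is not a simple polygon")
        if self.center is None:
            c = self._poly.centroid
            self.center = (c.x, c.y)
        if not self._poly.covers(Point(*self.center)):
            raise ValueError(f"centre of colony {self.colony_id!r} lies outside its ring")
        self._prepared = prep(self._poly)

    @property
    def polygon(self) -> Polygon:
        return self._poly

    def contains(self, lon, lat) -> np.ndarray:
        """Boundary-inclusive point-in-polygon test (vectorised)."""
        import shapely
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        # covers() (unlike contains) counts boundary points as inside
        return shapely.covers(self._poly, shapely.points(lon, lat))


def point_in_polygon(lon, lat, poly: ColonyPolygon):
    """Even-odd point-in-polygon with boundary points counted as inside."""
    out = poly.contains(lon, lat)
    return bool(out[0]) if np.isscalar(lon) or np.asarray(lon).ndim == 0 else out


def square_colony(colony_id: str, center: tuple[float, float],
                  halfwidth_m: float = 250.0) -> ColonyPolygon:
    """Square colony polygon of the given half-width centred on ``center``."""
    proj = AzimuthalEquidistant(*center)
    h = halfwidth_m / 1000.0
    xs = np.array([-h, h, h, -h, -h])
    ys = np.array([-h, -h, h, h, -h])
    lon, lat = proj.inverse(xs, ys)
    return ColonyPolygon(colony_id, np.column_stack([lon, lat]), center=center)


# ---------------------------------------------------------------------------
# Fix-table I/O


def read_fixes(path) -> dict[str, pd.DataFrame]:
    """Read a GPS fix CSV into per-bird trajectories.

    Returns a dict mapping bird_id to a DataFrame sorted by timestamp with
    exact duplicates dropped. Rows that fail to parse are skipped with a
    logged warning carrying their line numbers.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in ("bird_id", "timestamp", "lon", "lat") if c not in raw.columns]
    if missing:
        raise ValueError(f"fix table {path} is missing required columns: {missing}")
    if raw.empty:
        warnings.warn(f"fix table {path} contains a header but no rows")
        return {}
    ts = pd.to_datetime(raw["timestamp"], utc=True, errors="coerce", format="ISO8601")

    def _to_float(series):
        # float() is correctly rounded, so written tables re-read exactly
        def conv(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan
        return series.map(conv)

    lon = _to_float(raw["lon"])
    lat = _to_float(raw["lat"])
    bad = ts.isna() | lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    if bad.any():
        lines = (raw.index[bad] + 2).tolist()  # header is line 1
        log.warning("skipped %d unparseable fix rows (lines %s%s)",
                    bad.sum(), lines[:10], "..." if len(lines) > 10 else "")
    df = raw.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    df["lon"] = lon[~bad]
    df["lat"] = lat[~bad]
    df = df.drop_duplicates(subset=["bird_id", "timestamp", "lon", "lat"])
    out = {}
    for bird, sub in df.groupby("bird_id", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        sub = sub.drop_duplicates(subset="timestamp", keep="first").reset_index(drop=True)
        out[str(bird)] = sub
    return out


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write a fix table CSV with ISO-8601 UTC timestamps."""
    df = fixes.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    df["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S%z").str.replace(
        r"\+0000$", "+00:00", regex=True)
    cols = [c for c in FIX_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Colony polygon I/O (GeoJSON, RFC 7946)


def write_colonies(colonies: dict[str, ColonyPolygon], path) -> None:
    features = []
    for cid, poly in colonies.items():
        features.append({
            "type": "Feature",
            "properties": {"colony": cid,
                           "center": list(poly.center)},
            "geometry": {"type": "Polygon",
                         "coordinates": [poly.ring.tolist()]},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_colonies(path) -> dict[str, ColonyPolygon]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    out = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        cid = str(props.get("colony", f"colony_{len(out)}"))
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        center = tuple(props["center"]) if "center" in props else None
        out[cid] = ColonyPolygon(cid, ring, center=center)
    return out
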