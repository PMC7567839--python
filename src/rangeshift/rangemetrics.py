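"""Distribution-shift metrics: centroids, weighted-KDE ranges, edges.

For each species and season, haul locations weighted by CPUE summarize
the distribution in two comparison periods:

* biomass-weighted centroid (weighted mean latitude/longitude) and the
  great-circle distance between the two period centroids (``shift_km``);
* the 95% range — the smallest-area set of grid cells holding 95% of the
  CPUE-weighted Gaussian kernel-density mass — its area in km^2, and the
  percentage change ``100 * (area2 - area1) / area1``;
* the southern and northern range-edge latitudes (min / max cell-center
  latitude of the 95% region) and their change between periods.

The KDE is evaluated in lon/lat degrees with independent per-axis
bandwidths (weighted Scott's rule by default); cell areas carry a
cos(latitude) correction so reported areas are physically meaningful.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geo import KM_PER_DEG, haversine_km

logger = logging.getLogger(__name__)

geodesic_km_point = haversine_km  # re-export under the operation's name


def geodesic_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points."""
    return float(haversine_km(p1[0], p1[1], p2[0], p2[1]))


@dataclass(frozen=True)
class PeriodSpec:
    """Two non-overlapping year windows to compare (inclusive bounds)."""
    period1: tuple[int, int] = (1986, 1990)
    period2: tuple[int, int] = (2014, 2018)

    def __post_init__(self):
        for p in (self.period1, self.period2):
            if p[0] > p[1]:
                raise ValueError(f"period {p} is empty")
        if not (self.period1[1] < self.period2[0] or self.period2[1] < self.period1[0]):
            raise ValueError("periods overlap")


@dataclass(frozen=True)
class KdeOptions:
    """Weighted-KDE evaluation settings.

    ``bandwidth`` is None for the weighted Scott rule (per axis:
    sigma_w * n_eff^(-1/6), with effective sample size
    n_eff = (sum w)^2 / sum w^2) or an explicit (h_lon, h_lat) pair in
    degrees. With ``variance_matched`` (default), kernel centers are
    shrunk toward the weighted mean so the smoothed density keeps the
    sample variance instead of inflating it by (1 + h^2/sigma^2); without
    it, smoothing systematically enlarges isopleth areas by roughly that
    factor. The grid spans the data extent padded by ``pad_bandwidths``
    bandwidths on each side. ``planar=True`` treats coordinates as flat
    units (unit cell areas, no cos-lat correction) — used for analytic
    checks, not geographic data.
    """
    bandwidth: tuple[float, float] | None = None
    variance_matched: bool = True
    grid_size: int = 200
    pad_bandwidths: float = 3.0
    level: float = 0.95
    planar: bool = False


@dataclass(frozen=True)
class DensitySurface:
    """Normalized KDE mass on a lon/lat grid (mass sums to 1)."""
    lon_centers: np.ndarray
    lat_centers: np.ndarray
    mass: np.ndarray          # (nlat, nlon), sums to 1
    cell_area: np.ndarray     # (nlat, nlon), km^2 (or planar units^2)
    bandwidth: tuple[float, float]


@dataclass(frozen=True)
class RangeMetrics:
    species: str
    season: str
    centroid1: tuple[float, float]   # (lat, lon)
    centroid2: tuple[float, float]
    shift_km: float
    area1_km2: float | None
    area2_km2: float | None
    pct_area_change: float | None
    north1: float | None
    north2: float | None
    south1: float | None
    south2: float | None
    d_north: float | None
    d_south: float | None


def weighted_centroid(lats, lons, weights) -> tuple[float, float]:
    """CPUE-weighted mean position, (lat, lon) in degrees.

    Plain arithmetic weighted means; a guard asserts the longitude span
    is below 180 deg so antimeridian wrap-around cannot corrupt the mean.
    """
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if not total > 0:
        raise ValueError("centroid undefined: all weights are zero")
    if lons.max() - lons.min() >= 180.0:
        raise ValueError("longitude span >= 180 deg; too close to the antimeridian")
    return float(np.average(lats, weights=w)), float(np.average(lons, weights=w))


def _scott_bandwidth(x: np.ndarray, w: np.ndarray) -> float:
    n_eff = w.sum() ** 2 / np.sum(w * w)
    mean = np.average(x, weights=w)
    sd = np.sqrt(np.average((x - mean) ** 2, weights=w))
    return float(sd * n_eff ** (-1.0 / 6.0))  # d = 2 -> n^(-1/(d+4))


def weighted_kde(lons, lats, weights,
                 options: KdeOptions = KdeOptions()) -> DensitySurface:
    """CPUE-weighted Gaussian KDE evaluated on a regular grid.

    The product-Gaussian kernel with per-axis bandwidths makes the grid
    evaluation separable: mass[a, b] = sum_i w_i K((lat_a - lat_i)/h_lat)
    K((lon_b - lon_i)/h_lon), then normalized to unit total mass.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    w = np.asarray(weights, float)
    keep = w > 0
    if not np.any(keep):
        raise ValueError("KDE undefined: all weights are zero")
    lons, lats, w = lons[keep], lats[keep], w[keep]

    if options.bandwidth is None:
        h_lon = _scott_bandwidth(lons, w)
        h_lat = _scott_bandwidth(lats, w)
        if h_lon <= 0 or h_lat <= 0:
            raise ValueError("degenerate surface: zero bandwidth "
                             "(all points coincide along one axis)")
    else:
        h_lon, h_lat = options.bandwidth
        if h_lon <= 0 or h_lat <= 0:
            raise ValueError("bandwidth must be positive per axis")

    if options.variance_matched:
        # shrink kernel centers so Var(smoothed) = Var(sample) per axis:
        # c^2 sigma^2 + (c h)^2-style scaling with f = h / sigma
        for ax, h in (("lon", h_lon), ("lat", h_lat)):
            x = lons if ax == "lon" else lats
            m = np.average(x, weights=w)
            sd = np.sqrt(np.average((x - m) ** 2, weights=w))
            if sd > 0:
                c = 1.0 / np.sqrt(1.0 + (h / sd) ** 2)
                x_new = m + (x - m) * c
                if ax == "lon":
                    lons, h_lon = x_new, h * c
                else:
                    lats, h_lat = x_new, h * c

    ng = options.grid_size
    pad = options.pad_bandwidths
    lon_g = np.linspace(lons.min() - pad * h_lon, lons.max() + pad * h_lon, ng)
    lat_g = np.linspace(lats.min() - pad * h_lat, lats.max() + pad * h_lat, ng)

    k_lon = np.exp(-0.5 * ((lon_g[:, None] - lons[None, :]) / h_lon) ** 2)  # (ng, n)
    k_lat = np.exp(-0.5 * ((lat_g[:, None] - lats[None, :]) / h_lat) ** 2)
    mass = k_lat @ (w[:, None] * k_lon.T)          # (nlat, nlon)
    mass /= mass.sum()

    d_lon = lon_g[1] - lon_g[0]
    d_lat = lat_g[1] - lat_g[0]
    if options.planar:
        cell_area = np.full_like(mass, d_lon * d_lat)
    else:
        cell_area = (d_lat * KM_PER_DEG) * (d_lon * KM_PER_DEG
                     * np.cos(np.radians(lat_g)))[:, None] * np.ones_like(mass)
    return DensitySurface(lon_centers=lon_g, lat_centers=lat_g, mass=mass,
                          cell_area=cell_area, bandwidth=(h_lon, h_lat))


def isopleth(surface: DensitySurface, level: float = 0.95
             ) -> tuple[np.ndarray, float]:
    """Smallest-area region holding ``level`` of the KDE mass.

    Cells are ranked by density (mass per area) in stable descending
    order and accumulated until the cumulative mass first reaches the
    level; the stable sort makes the cut deterministic under exact ties.
    Returns (boolean cell mask, region area).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    density = (surface.mass / surface.cell_area).ravel()
    order = np.argsort(-density, kind="stable")
    csum = np.cumsum(surface.mass.ravel()[order])
    n_in = int(np.searchsorted(csum, level - 1e-12) + 1)
    mask = np.zeros(density.shape, dtype=bool)
    mask[order[:n_in]] = True
    mask = mask.reshape(surface.mass.shape)
    return mask, float(surface.cell_area[mask].sum())


def range_extent(surface: DensitySurface, mask: np.ndarray
                 ) -> tuple[float, float]:
    """(south, north) cell-center latitudes of a region mask."""
    if not np.any(mask):
        raise ValueError("empty region")
    row_any = mask.any(axis=1)
    lats = surface.lat_centers[row_any]
    return float(lats.min()), float(lats.max())


def _period_slice(records: pd.DataFrame, period: tuple[int, int]) -> pd.DataFrame:
    return records[records["year"].between(period[0], period[1])]


def compute_range_metrics(records: pd.DataFrame,
                          periods: PeriodSpec = PeriodSpec(),
                          options: KdeOptions = KdeOptions(),
                          include_area: bool = True) -> RangeMetrics:
    """All shift metrics for one species-season slice of haul records.

    ``records`` needs columns year, lat, lon, cpue (single species and
    season). With ``include_area=False`` only the centroids and
    ``shift_km`` are computed (KDE skipped); area and edge fields are
    None. Raises ValueError when a period has zero total CPUE.
    """
    species = str(records["species"].iloc[0]) if "species" in records else ""
    season = str(records["season"].iloc[0]) if "season" in records else ""
    parts = []
    for p in (periods.period1, periods.period2):
        sl = _period_slice(records, p)
        if sl.empty or not sl["cpue"].sum() > 0:
            raise ValueError(f"{species}/{season}: no positive CPUE in period {p}")
        parts.append(sl)

    cents = [weighted_centroid(sl["lat"], sl["lon"], sl["cpue"]) for sl in parts]
    shift = geodesic_km(cents[0], cents[1])

    if not include_area:
        return RangeMetrics(species=species, season=season,
                            centroid1=cents[0], centroid2=cents[1], shift_km=shift,
                            area1_km2=None, area2_km2=None, pct_area_change=None,
                            north1=None, north2=None, south1=None, south2=None,
                            d_north=None, d_south=None)

    areas, norths, souths = [], [], []
    for sl in parts:
        surf = weighted_kde(sl["lon"], sl["lat"], sl["cpue"], options)
        mask, area = isopleth(surf, options.level)
        s, n = range_extent(surf, mask)
        areas.append(area)
        souths.append(s)
        norths.append(n)
    pct = 100.0 * (areas[1] - areas[0]) / areas[0]
    return RangeMetrics(
        species=species, season=season,
        centroid1=cents[0], centroid2=cents[1], shift_km=shift,
        area1_km2=areas[0], area2_km2=areas[1], pct_area_change=pct,
        north1=norths[0], north2=norths[1], south1=souths[0], south2=souths[1],
        d_north=norths[1] - norths[0], d_south=souths[1] - souths[0])


def range_metrics_table(records: pd.DataFrame,
                        periods: PeriodSpec = PeriodSpec(),
                        options: KdeOptions = KdeOptions(),
                        include_area: bool = True) -> pd.DataFrame:
    """Metrics for every (species, season); failures become logged gaps."""
    rows = []
    for (species, season), g in records.groupby(["species", "season"]):
        try:
            m = compute_range_metrics(g, periods, options, include_area)
        except ValueError as exc:
            logger.info("range_metrics_table: skipped %s/%s (%s)", species, season, exc)
            continue
        rows.append({
            "species": m.species, "season": m.season,
            "lat1": m.centroid1[0], "lon1": m.centroid1[1],
            "lat2": m.centroid2[0], "lon2": m.centroid2[1],
            "shift_km": m.shift_km,
            "area1_km2": m.area1_km2, "area2_km2": m.area2_km2,
            "pct_area_change": m.pct_area_change,
            "south1": m.south1, "north1": m.north1,
            "south2": m.south2, "north2": m.north2,
            "d_north": m.d_north, "d_south": m.d_south,
        })
    return pd.DataFrame(rows)


def region_geojson(surface: DensitySurface, mask: np.ndarray,
                   properties: dict | None = None) -> dict:
    """Cell-union polygons of a region mask as a GeoJSON FeatureCollection.

    Convenience export for mapping the 95% range in GIS tools; each
    selected cell becomes one rectangle feature (WGS84 lon/lat).
    """
    d_lon = surface.lon_centers[1] - surface.lon_centers[0]
    d_lat = surface.lat_centers[1] - surface.lat_centers[0]
    feats = []
    ii, jj = np.nonzero(mask)
    for i, j in zip(ii.tolist(), jj.tolist()):
        lon, lat = float(surface.lon_centers[j]), float(surface.lat_centers[i])
        ring = [[lon - d_lon / 2, lat - d_lat / 2], [lon + d_lon / 2, lat - d_lat / 2],
                [lon + d_lon / 2, lat + d_lat / 2], [lon - d_lon / 2, lat + d_lat / 2],
                [lon - d_lon / 2, lat - d_lat / 2]]
        feats.append({"type": "Feature", "properties": dict(properties or {}),
                      "geometry": {"type": "Polygon", "coordinates": [ring]}})
    return {"type": "FeatureCollection", "features": feats}
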