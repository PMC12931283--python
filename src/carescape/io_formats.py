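"""Domain types and file formats.

Coordinates are planar kilometers throughout the package. Longitude/latitude
inputs are projected once, at read time, to an azimuthal equidistant plane
centered on the data centroid, so that downstream nearest-neighbor distances,
kernel bandwidths and polygon areas are all ordinary Euclidean quantities.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, shape

EARTH_RADIUS_KM = 6371.0088


class FormatError(ValueError):
    """A file did not conform to the expected format."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PointSet:
    """Planar facility locations in kilometers."""

    points: np.ndarray  # shape (n, 2)
    crs_label: str = "planar_km"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("all coordinates must be finite")
        if not self.crs_label:
            raise ValueError("crs_label must be non-empty")
        self.points = pts

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    def __len__(self) -> int:
        return self.n


@dataclass
class Region:
    """One study-area polygon (possibly multi-part), vertices in km."""

    region_id: str
    name: str
    polygon: Polygon | MultiPolygon
    area_km2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"region {self.region_id!r}: invalid geometry")
        computed = float(self.polygon.area)
        if computed <= 0:
            raise ValueError(f"region {self.region_id!r}: zero-area geometry")
        if self.area_km2 is None:
            self.area_km2 = computed
        elif abs(self.area_km2 - computed) > 1e-3 * computed:
            raise ValueError(
                f"region {self.region_id!r}: declared area {self.area_km2} "
                f"differs from polygon area {computed} by more than 0.1%"
            )


@dataclass
class CityRecord:
    """One city's demand, supply and covariates.

    ``elderly_pop`` is the demand side (persons aged 60+), ``facility_count``
    the supply side (number of care facilities). ``covariates`` carries the
    explanatory indicators (population, GDP, amenity counts, climate, ...)
    used by the geographical detector.
    """

    region_id: str
    elderly_pop: float
    total_pop: float | None = None
    facility_count: int = 0
    area_km2: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.elderly_pop < 0:
            raise ValueError(f"{self.region_id}: elderly_pop must be >= 0")
        if self.total_pop is not None and self.elderly_pop > self.total_pop:
            raise ValueError(
                f"{self.region_id}: elderly_pop exceeds total_pop"
            )
        if self.facility_count < 0 or int(self.facility_count) != self.facility_count:
            raise ValueError(f"{self.region_id}: facility_count must be a non-negative integer")
        self.facility_count = int(self.facility_count)


# ---------------------------------------------------------------------------
# projection


def project_lonlat(
    lon: np.ndarray, lat: np.ndarray, center: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray, str]:
    """Project lon/lat degrees to planar km (spherical azimuthal equidistant).

    Distances from the projection center are exact great-circle distances;
    distortion elsewhere is negligible at the (sub-provincial) extents this
    package targets. Returns (x_km, y_km, crs_label).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if center is None:
        center = (float(np.mean(lon)), float(np.mean(lat)))
    lon0, lat0 = math.radians(center[0]), math.radians(center[1])
    lam, phi = np.radians(lon), np.radians(lat)
    cos_c = np.sin(lat0) * np.sin(phi) + np.cos(lat0) * np.cos(phi) * np.cos(lam - lon0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    # k -> 1 as c -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lon0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(lat0) * np.sin(phi) - np.sin(lat0) * np.cos(phi) * np.cos(lam - lon0)
    )
    label = f"aeqd:{center[0]:.6f},{center[1]:.6f}"
    return x, y, label


def _normalize_projection(projection) -> dict:
    if projection is None:
        return {"kind": "planar"}
    if isinstance(projection, str):
        return {"kind": projection}
    return dict(projection)


# ---------------------------------------------------------------------------
# point tables


def read_point_table(
    path: str | Path,
    x_field: str = "x",
    y_field: str = "y",
    projection=None,
) -> PointSet:
    """Read a CSV of point coordinates into a :class:`PointSet`.

    ``projection`` is either ``"planar"`` (coordinates already planar km,
    the default), ``"lonlat"``, or a mapping like
    ``{"kind": "lonlat", "center": (lon0, lat0)}``. Row order is preserved.
    """
    path = Path(path)
    proj = _normalize_projection(projection)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        for fld in (x_field, y_field):
            if fld not in reader.fieldnames:
                raise FormatError(f"{path}: missing field {fld!r}")
        xs: list[float] = []
        ys: list[float] = []
        for i, row in enumerate(reader):
            try:
                x = float(row[x_field])
                y = float(row[y_field])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: row {i}: unparseable coordinate") from exc
            if not (math.isfinite(x) and math.isfinite(y)):
                raise FormatError(f"{path}: row {i}: non-finite coordinate")
            xs.append(x)
            ys.append(y)
    if proj["kind"] == "lonlat":
        px, py, label = project_lonlat(np.array(xs), np.array(ys), proj.get("center"))
        return PointSet(np.column_stack([px, py]), crs_label=label)
    return PointSet(np.column_stack([xs, ys]).reshape(-1, 2), crs_label="planar_km")


def write_point_table(
    points: PointSet, path: str | Path, x_field: str = "x", y_field: str = "y"
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([x_field, y_field])
        for x, y in points.points:
            writer.writerow([f"{x:.12f}", f"{y:.12f}"])


# ---------------------------------------------------------------------------
# regions (GeoJSON)


def read_regions(path: str | Path, projection=None) -> list[Region]:
    """Read a GeoJSON FeatureCollection of (Multi)Polygons into Regions.

    Each feature needs a ``region_id`` property (``id`` accepted as a
    fallback); duplicate ids are a format error. With ``projection="lonlat"``
    vertex coordinates are projected to planar km first.
    """
    path = Path(path)
    proj = _normalize_projection(projection)
    with path.open(encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    regions: list[Region] = []
    seen: set[str] = set()
    center = proj.get("center")
    if proj["kind"] == "lonlat" and center is None:
        # centroid of all vertices so every feature shares one plane
        allx, ally = [], []
        for feat in doc.get("features", []):
            geom = shape(feat["geometry"])
            xs, ys = _geometry_vertices(geom)
            allx.extend(xs)
            ally.extend(ys)
        center = (float(np.mean(allx)), float(np.mean(ally)))
    for idx, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        rid = props.get("region_id", props.get("id", feat.get("id")))
        if rid is None:
            raise FormatError(f"{path}: feature {idx} has no region_id property")
        rid = str(rid)
        if rid in seen:
            raise FormatError(f"{path}: duplicate region_id {rid!r}")
        seen.add(rid)
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise FormatError(f"{path}: feature {rid!r}: bad geometry") from exc
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise FormatError(f"{path}: feature {rid!r}: geometry must be (Multi)Polygon")
        if proj["kind"] == "lonlat":
            geom = _project_geometry(geom, center)
        if not geom.is_valid:
            raise FormatError(f"{path}: feature {rid!r}: invalid geometry")
        regions.append(Region(region_id=rid, name=str(props.get("name", rid)), polygon=geom))
    return regions


def _geometry_vertices(geom) -> tuple[list[float], list[float]]:
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    xs, ys = [], []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            rx, ry = zip(*ring.coords)
            xs.extend(rx)
            ys.extend(ry)
    return xs, ys


def _project_geometry(geom, center):
    def proj_ring(coords):
        lon, lat = np.array([c[0] for c in coords]), np.array([c[1] for c in coords])
        x, y, _ = project_lonlat(lon, lat, center)
        return list(zip(x, y))

    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    out = [
        Polygon(proj_ring(p.exterior.coords), [proj_ring(r.coords) for r in p.interiors])
        for p in polys
    ]
    return MultiPolygon(out) if len(out) > 1 else out[0]


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    """Write Regions back out as a planar-km GeoJSON FeatureCollection."""
    feats = []
    for reg in regions:
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "region_id": reg.region_id,
                    "name": reg.name,
                    "area_km2": reg.area_km2,
                },
                "geometry": reg.polygon.__geo_interface__,
            }
        )
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# spatial join


def assign_points_to_regions(
    points: PointSet, regions: list[Region]
) -> dict[str, PointSet]:
    """Partition points by containing region.

    Every point lands in exactly one bucket: the first region (in input
    order) that covers it, or ``"unassigned"``. Boundary points therefore
    resolve deterministically to the earliest listed region.
    """
    import shapely

    geoms = shapely.points(points.points)
    remaining = np.ones(points.n, dtype=bool)
    out: dict[str, PointSet] = {}
    for reg in regions:
        mask = remaining & shapely.covers(reg.polygon, geoms)
        out[reg.region_id] = PointSet(
            points.points[mask].reshape(-1, 2), crs_label=points.crs_label
        )
        remaining &= ~mask
    out["unassigned"] = PointSet(
        points.points[remaining].reshape(-1, 2), crs_label=points.crs_label
    )
    return out


# ---------------------------------------------------------------------------
# city tables


_CITY_FIELDS = ("region_id", "elderly_pop", "total_pop", "facility_count", "area_km2")


def read_city_table(path: str | Path) -> list[CityRecord]:
    """Read a city-level CSV (region_id, elderly_pop, facility_count, ...).

    Any column beyond the reserved ones is kept as a covariate.
    """
    path = Path(path)
    records: list[CityRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "region_id" not in reader.fieldnames:
            raise FormatError(f"{path}: city table needs a region_id column")
        for row in reader:
            cov = {
                k: float(v)
                for k, v in row.items()
                if k not in _CITY_FIELDS and v not in (None, "")
            }
            records.append(
                CityRecord(
                    region_id=row["region_id"],
                    elderly_pop=float(row.get("elderly_pop") or 0.0),
                    total_pop=float(row["total_pop"]) if row.get("total_pop") else None,
                    facility_count=int(float(row.get("facility_count") or 0)),
                    area_km2=float(row["area_km2"]) if row.get("area_km2") else None,
                    covariates=cov,
                )
            )
    return records


def write_city_table(cities: list[CityRecord], path: str | Path) -> None:
    cov_names = sorted({k for c in cities for k in c.covariates})
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_CITY_FIELDS) + cov_names)
        for c in cities:
            writer.writerow(
                [
                    c.region_id,
                    c.elderly_pop,
                    "" if c.total_pop is None else c.total_pop,
                    c.facility_count,
                    "" if c.area_km2 is None else c.area_km2,
                ]
                + [c.covariates.get(k, "") for k in cov_names]
            )


# ---------------------------------------------------------------------------
# ESRI ASCII grid


def write_ascii_grid(grid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a DensityGrid as an ESRI ASCII raster (.asc)."""
    values = np.asarray(grid.values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot write an empty grid")
    nrows, ncols = values.shape
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.x0:.10f}\n")
        fh.write(f"yllcorner {grid.y0:.10f}\n")
        fh.write(f"cellsize {grid.cell_km:.10f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        # ASCII grids are written north-to-south: top row first
        for row in values[::-1]:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path: str | Path):
    """Read an ESRI ASCII raster back into a DensityGrid."""
    from .density_surface import DensityGrid

    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with Path(path).open(encoding="utf-8") as fh:
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
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing ASCII grid header field {key}")
    values = np.array(rows, dtype=float)[::-1]
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(f"{path}: grid body does not match declared shape")
    return DensityGrid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_km=header["cellsize"],
        values=values,
        bandwidth_km=float("nan"),
        kernel="unknown",
    )
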