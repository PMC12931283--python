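"""End-to-end orchestration: points + regions + city table -> four reports.

Stages (each independent; one failing stage does not stop the others):

1. nearest-neighbor statistics, whole-area and per-region;
2. kernel-density raster over the region extent;
3. CRP supply-demand matching with threshold sensitivity;
4. geographical-detector factor and interaction analysis.

A manifest records the resolved configuration, the seed, and a SHA-256 hash
of every output file, so identical inputs are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .density_surface import kernel_density, silverman_bandwidth
from .geodetector import DEFAULT_K_RANGE, METHODS, run_factor_detection
from .io_formats import (
    CityRecord,
    assign_points_to_regions,
    read_city_table,
    read_point_table,
    read_regions,
    write_ascii_grid,
)
from .point_pattern import nearest_neighbor_index
from .supply_demand import compute_crp, sensitivity_analysis


@dataclass
class PipelineConfig:
    out_dir: str
    points_path: str | None = None
    regions_path: str | None = None
    city_table_path: str | None = None
    projection: str | dict | None = None
    band: tuple[float, float] = (0.9, 1.1)
    alt_bands: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.85, 1.15), (0.95, 1.05)]
    )
    kde_bandwidth_km: float | None = None
    kde_cell_km: float = 1.0
    response_field: str = "facility_count"
    factors: list[str] | None = None
    k_range: tuple[int, int] = DEFAULT_K_RANGE
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError(f"invalid band {self.band}")
        for b in self.alt_bands:
            if not (0 < b[0] < b[1]):
                raise ValueError(f"invalid alternative band {b}")
        for path in (self.points_path, self.regions_path, self.city_table_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    def resolved(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "points_path": self.points_path,
            "regions_path": self.regions_path,
            "city_table_path": self.city_table_path,
            "projection": self.projection,
            "band": list(self.band),
            "alt_bands": [list(b) for b in self.alt_bands],
            "kde_bandwidth_km": self.kde_bandwidth_km,
            "kde_cell_km": self.kde_cell_km,
            "response_field": self.response_field,
            "factors": self.factors,
            "k_range": list(self.k_range),
            "methods": list(self.methods),
            "seed": self.seed,
        }


def _dump(obj: dict, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_city_table(
    cities: list[CityRecord],
    expected_total_facilities: int | None = None,
    expected_total_elderly: float | None = None,
) -> dict:
    """Report-only consistency checks on a city table."""
    violations: list[str] = []
    total_fac = sum(c.facility_count for c in cities)
    total_eld = sum(c.elderly_pop for c in cities)
    for c in cities:
        if c.total_pop is not None and c.elderly_pop > c.total_pop:
            violations.append(f"{c.region_id}: elderly_pop exceeds total_pop")
        if c.facility_count < 0:
            violations.append(f"{c.region_id}: negative facility_count")
    if expected_total_facilities is not None and total_fac != expected_total_facilities:
        violations.append(
            f"total facility_count {total_fac} != declared {expected_total_facilities}"
        )
    if expected_total_elderly is not None and total_eld != expected_total_elderly:
        violations.append(
            f"total elderly_pop {total_eld} != declared {expected_total_elderly}"
        )
    return {
        "n_cities": len(cities),
        "total_facilities": total_fac,
        "total_elderly_pop": total_eld,
        "violations": violations,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the config provides inputs for; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.resolved(),
        "stages": {},
        "outputs": {},
    }

    # inputs are read lazily so that a corrupt file fails only the stages
    # that need it
    def make_loader(path, reader):
        cache: list = []

        def load():
            if not path:
                return None
            if not cache:
                cache.append(reader(path))
            return cache[0]

        return load

    load_points = make_loader(
        config.points_path,
        lambda p: read_point_table(p, x_field="x", y_field="y", projection=config.projection),
    )
    load_regions = make_loader(config.regions_path, read_regions)
    load_cities = make_loader(config.city_table_path, read_city_table)

    def run_stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            detail = fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                **(detail or {}),
            }
        except Exception as exc:  # stage isolation: record, continue
            manifest["stages"][name] = {"status": "error", "error": f"{name}: {exc}"}

    # --- stage 1: nearest-neighbor statistics
    def stage_nni():
        if not config.points_path:
            return {"status_note": "skipped: no points input"}
        points = load_points()
        regions = load_regions()
        report: dict = {}
        if regions:
            total_area = sum(r.area_km2 for r in regions)
            report["whole_area"] = nearest_neighbor_index(points, total_area).to_dict()
            per_region = {}
            assigned = assign_points_to_regions(points, regions)
            for reg in regions:
                sub = assigned.get(reg.region_id)
                if sub is not None and sub.n >= 2:
                    per_region[reg.region_id] = nearest_neighbor_index(
                        sub, reg.area_km2
                    ).to_dict()
            report["per_region"] = per_region
            report["unassigned_points"] = assigned["unassigned"].n
        else:
            # convex hull area fallback
            from shapely.geometry import MultiPoint

            hull_area = MultiPoint([tuple(p) for p in points.points]).convex_hull.area
            report["whole_area"] = nearest_neighbor_index(points, hull_area).to_dict()
        _dump(report, out / "nni.json")
        return {"n_points": points.n}

    # --- stage 2: kernel density
    def stage_kde():
        if not config.points_path:
            return {"status_note": "skipped: no points input"}
        points = load_points()
        regions = load_regions()
        h = config.kde_bandwidth_km or silverman_bandwidth(points)
        if regions:
            xs = [b for r in regions for b in (r.polygon.bounds[0], r.polygon.bounds[2])]
            ys = [b for r in regions for b in (r.polygon.bounds[1], r.polygon.bounds[3])]
            extent = (min(xs), min(ys), max(xs), max(ys))
        else:
            xmin, ymin = points.points.min(axis=0) - h
            xmax, ymax = points.points.max(axis=0) + h
            extent = (xmin, ymin, xmax, ymax)
        grid = kernel_density(points, h, config.kde_cell_km, extent)
        write_ascii_grid(grid, out / "density.asc")
        _dump({**grid.summary(), "n": points.n}, out / "kde.json")
        return {"bandwidth_km": h}

    # --- stage 3: CRP matching
    def stage_crp():
        if not config.city_table_path:
            return {"status_note": "skipped: no city table input"}
        cities = load_cities()
        results = compute_crp(cities, band=config.band)
        report = sensitivity_analysis(results, config.band, config.alt_bands)
        _dump(
            {
                "cities": [r.to_dict() for r in results],
                "sensitivity": report.to_dict(),
                "validation": validate_city_table(cities),
            },
            out / "crp.json",
        )
        return {"n_cities": len(cities)}

    # --- stage 4: geographical detector
    def stage_detect():
        if not config.city_table_path:
            return {"status_note": "skipped: no city table input"}
        cities = load_cities()
        factor_results, interactions = run_factor_detection(
            cities,
            response_field=config.response_field,
            factors=config.factors,
            methods=config.methods,
            k_range=config.k_range,
        )
        _dump(
            {
                "factors": [r.to_dict() for r in factor_results],
                "interactions": [r.to_dict() for r in interactions],
                "response": config.response_field,
            },
            out / "detector.json",
        )
        return {"n_factors": len(factor_results)}

    run_stage("nni", stage_nni)
    run_stage("kde", stage_kde)
    run_stage("crp", stage_crp)
    run_stage("detector", stage_detect)

    for name in ("nni.json", "kde.json", "density.asc", "crp.json", "detector.json"):
        path = out / name
        if path.exists():
            manifest["outputs"][name] = _sha256(path)
    _dump(manifest, out / "manifest.json")
    return manifest
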