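"""Bundled example data: Liaoning Province city-level tables.

Two small public tables for the 14 prefecture-level cities of Liaoning
Province (China), the package's worked example:

* elderly population (persons aged 60+, approximate, 2023) and verified
  elderly-care facility counts (2024 POI census after deduplication and
  status checks) — the inputs of the supply-demand matching analysis;
* per-city observed and CSR-expected mean nearest-neighbor distances (km)
  of the facility point patterns, with the published nearest-neighbor
  index for cross-checking.
"""

from __future__ import annotations

from .io_formats import CityRecord

# city -> (elderly_pop, facility_count, published CRP)
#
# The population column is published as an *approximate* value; the published
# CRP column was computed from unrounded inputs. All rows except Yingkou
# regenerate the published CRP to 3 decimals from the approximate columns
# (Yingkou recomputes to 1.111 vs the published 1.099), so the published CRP
# is kept alongside the inputs: it is the authoritative value the
# classification analysis was run on.
LIAONING_CITY_TABLE: dict[str, tuple[float, int, float]] = {
    "Benxi": (470_000, 188, 1.544),
    "Jinzhou": (879_000, 318, 1.396),
    "Dandong": (716_000, 242, 1.304),
    "Panjin": (345_000, 115, 1.286),
    "Fushun": (683_600, 220, 1.242),
    "Fuxin": (519_000, 152, 1.130),
    "Yingkou": (646_000, 186, 1.099),
    "Anshan": (1_011_000, 283, 1.080),
    "Dalian": (1_826_900, 488, 1.031),
    "Liaoyang": (528_000, 139, 1.016),
    "Chaoyang": (862_000, 197, 0.882),
    "Tieling": (799_000, 155, 0.749),
    "Shenyang": (2_240_000, 385, 0.663),
    "Huludao": (774_500, 119, 0.593),
}

# city -> (observed mean NN distance km, expected mean NN distance km, published R)
LIAONING_NN_TABLE: dict[str, tuple[float, float, float]] = {
    "Benxi": (0.97, 3.46, 0.280),
    "Dandong": (1.54, 4.49, 0.342),
    "Tieling": (1.82, 4.97, 0.367),
    "Jinzhou": (1.10, 2.97, 0.370),
    "Dalian": (1.39, 3.71, 0.375),
    "Panjin": (0.87, 2.25, 0.386),
    "Shenyang": (1.30, 3.12, 0.416),
    "Yingkou": (1.19, 2.80, 0.426),
    "Fushun": (1.78, 3.82, 0.467),
    "Anshan": (1.52, 3.18, 0.479),
    "Liaoyang": (1.55, 3.00, 0.518),
    "Chaoyang": (3.65, 6.03, 0.607),
    "Fuxin": (2.48, 4.01, 0.618),
    "Huludao": (3.11, 4.79, 0.650),
    "Liaoning Province": (1.58, 4.29, 0.369),
}


def liaoning_city_records() -> list[CityRecord]:
    """The Liaoning example as CityRecords (demand and supply columns only)."""
    return [
        CityRecord(region_id=city, elderly_pop=pop, facility_count=cnt)
        for city, (pop, cnt, _) in LIAONING_CITY_TABLE.items()
    ]


def liaoning_published_crp() -> dict[str, float]:
    """The published per-city CRP values (see the module-level caveat)."""
    return {city: crp for city, (_, _, crp) in LIAONING_CITY_TABLE.items()}
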