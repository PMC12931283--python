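"""Supply-demand matching via the consistency-rate percentage (CRP).

For city i with facility count res_i and elderly population pop_i,

    CRP_i = (res_i / sum_j res_j) / (pop_i / sum_j pop_j)

i.e. a location quotient of the city's share of care supply against its
share of care demand. Area terms cancel algebraically, so only the two
shares enter. Cities are classified against a band (lo, hi):
CRP > hi resource-advanced, lo <= CRP <= hi resource-matched (boundaries
inclusive), CRP < lo resource-lagging. The default band is (0.9, 1.1),
a +/-10% elasticity around exact parity.

A weighted identity pins the scale: the population-share-weighted mean of
the CRPs is exactly 1 for any table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import CityRecord

BASELINE_BAND = (0.9, 1.1)

CLASSES = ("advanced", "matched", "lagging")


@dataclass
class CRPResult:
    region_id: str
    crp: float
    res_share: float
    pop_share: float
    classification: str
    band: tuple[float, float]

    @property
    def crp_3dp(self) -> float:
        """Display value: round half away from zero to 3 decimals."""
        return round_half_away(self.crp, 3)

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "crp": self.crp,
            "crp_3dp": self.crp_3dp,
            "res_share": self.res_share,
            "pop_share": self.pop_share,
            "classification": self.classification,
            "band": list(self.band),
        }


@dataclass
class SensitivityReport:
    baseline_band: tuple[float, float]
    bands: list[tuple[float, float]]
    counts: dict[tuple[float, float], dict[str, int]]
    agreement: dict[tuple[float, float], float]
    changed: dict[tuple[float, float], list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def key(band):
            return f"{band[0]:g}-{band[1]:g}"

        return {
            "baseline_band": list(self.baseline_band),
            "bands": [
                {
                    "band": list(b),
                    "counts": self.counts[b],
                    "agreement": self.agreement[b],
                    "changed_regions": self.changed.get(b, []),
                }
                for b in self.bands
            ],
        }


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed tables)."""
    import math

    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def classify_matching(crp: float, band: tuple[float, float] = BASELINE_BAND) -> str:
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"invalid band {band}: need 0 < lo < hi")
    if crp > hi:
        return "advanced"
    if crp < lo:
        return "lagging"
    return "matched"


def compute_crp(
    cities: list[CityRecord], band: tuple[float, float] = BASELINE_BAND
) -> list[CRPResult]:
    """CRP and matching class for every city in the table."""
    if not cities:
        raise ValueError("city table is empty")
    total_res = float(sum(c.facility_count for c in cities))
    total_pop = float(sum(c.elderly_pop for c in cities))
    if total_res <= 0:
        raise ValueError("total facility count must be positive")
    results = []
    for c in cities:
        if c.elderly_pop <= 0:
            raise ValueError(f"city {c.region_id!r}: elderly population must be positive")
        res_share = c.facility_count / total_res
        pop_share = c.elderly_pop / total_pop
        crp = res_share / pop_share
        results.append(
            CRPResult(
                region_id=c.region_id,
                crp=crp,
                res_share=res_share,
                pop_share=pop_share,
                classification=classify_matching(crp, band),
                band=tuple(band),
            )
        )
    return results


def class_counts(results: list[CRPResult]) -> dict[str, int]:
    counts = {cls: 0 for cls in CLASSES}
    for r in results:
        counts[r.classification] += 1
    return counts


def sensitivity_analysis(
    results: list[CRPResult],
    baseline: tuple[float, float] = BASELINE_BAND,
    alternatives: list[tuple[float, float]] = ((0.85, 1.15), (0.95, 1.05)),
) -> SensitivityReport:
    """Reclassify every city under alternative bands and measure agreement.

    Agreement for a band is the fraction of cities whose class is unchanged
    relative to the baseline band. Note that widening only the matched band
    can move cities *into* the matched class, never out of it, so matched
    counts are monotone in the band width — a structural check on any
    externally supplied count table.
    """
    if not results:
        raise ValueError("no CRP results to analyze")
    baseline = tuple(baseline)
    base_cls = {r.region_id: classify_matching(r.crp, baseline) for r in results}
    bands = [baseline] + [tuple(b) for b in alternatives]
    counts: dict[tuple[float, float], dict[str, int]] = {}
    agreement: dict[tuple[float, float], float] = {}
    changed: dict[tuple[float, float], list[str]] = {}
    for band in bands:
        cls = {r.region_id: classify_matching(r.crp, band) for r in results}
        band_counts = {c: 0 for c in CLASSES}
        for v in cls.values():
            band_counts[v] += 1
        counts[band] = band_counts
        diffs = [rid for rid in cls if cls[rid] != base_cls[rid]]
        changed[band] = sorted(diffs)
        agreement[band] = 1.0 - len(diffs) / len(results)
    return SensitivityReport(
        baseline_band=baseline,
        bands=bands,
        counts=counts,
        agreement=agreement,
        changed=changed,
    )
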