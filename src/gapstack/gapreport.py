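"""Gap statistics: hotspot classes overlaid on reserve management zones.

For each scenario the three hotspot classes are intersected with five
mutually exclusive zones — core, buffer, experimental, a 1-km margin ring
immediately outside the reserve perimeter, and the remaining outside — and
reported as the percentage of each class's area falling in each zone.  All
overlay arithmetic runs on integer cell counts; areas are derived last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .hotspot import CLASS_CODES, HotspotMap
from .synthgen import ZONE_CODES, ZoneMask

__all__ = ["GapReport", "ZONES", "margin_ring", "coverage", "summarize_scenarios"]

#: Zone report order (mutually exclusive, exhaustive).
ZONES = ("core", "buffer_zone", "experimental", "margin_1km", "outside")
RESERVE_ZONES = ("core", "buffer_zone", "experimental")


@dataclass
class GapReport:
    scenario: str
    class_areas: dict[str, float]                      # class -> km^2
    coverage: dict[tuple[str, str], float]             # (class, zone) -> % of class area (NaN if class empty)
    reserve_total: dict[str, float]                    # class -> % inside the reserve

    def to_frame(self) -> pd.DataFrame:
        rows = [{"scenario": self.scenario, "class": c,
                 "area_km2": self.class_areas[c], "zone": z,
                 "percent": self.coverage[(c, z)]}
                for c in CLASS_CODES for z in ZONES]
        return pd.DataFrame(rows)


def margin_ring(zone_mask: ZoneMask, width: float = 1000.0) -> ZoneMask:
    """Relabel outside cells within ``width`` m of the reserve as the 1-km
    margin ring.  Distance is measured between cell centers; reserve cells
    are never relabeled."""
    reserve = zone_mask.reserve_mask()
    if not reserve.any():
        raise ValueError("empty reserve")
    zone = zone_mask.zone.copy()
    if width <= 0:
        return ZoneMask(zone=zone, grid=zone_mask.grid)
    cs = zone_mask.grid.cell_size
    dist = distance_transform_edt(~reserve, sampling=cs)
    ring = (zone == ZONE_CODES["outside"]) & (dist <= width)
    zone[ring] = ZONE_CODES["margin_1km"]
    return ZoneMask(zone=zone, grid=zone_mask.grid)


def coverage(hotspot: HotspotMap, zones: ZoneMask) -> GapReport:
    """Per-class zone coverage percentages from exact integer cell counts.

    An empty class reports NaN (0/0 is undefined, not "no coverage")."""
    hotspot.grid.require_congruent(zones.grid)
    cell_km2 = hotspot.grid.cell_area_km2
    class_areas: dict[str, float] = {}
    cov: dict[tuple[str, str], float] = {}
    reserve_total: dict[str, float] = {}
    for cls, code in CLASS_CODES.items():
        in_class = hotspot.classes == code
        n_class = int(in_class.sum())
        class_areas[cls] = n_class * cell_km2
        for z in ZONES:
            if n_class == 0:
                cov[(cls, z)] = float("nan")
            else:
                n_zone = int((in_class & (zones.zone == ZONE_CODES[z])).sum())
                cov[(cls, z)] = 100.0 * n_zone / n_class
        reserve_total[cls] = (float("nan") if n_class == 0
                              else sum(cov[(cls, z)] for z in RESERVE_ZONES))
    return GapReport(scenario=hotspot.scenario, class_areas=class_areas,
                     coverage=cov, reserve_total=reserve_total)


def summarize_scenarios(reports: list[GapReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format table plus per-class summary across scenarios.

    Summary rows carry min/max/mean class area and the simple (unweighted)
    mean zone coverage over scenarios, NaN-skipping for empty classes.
    """
    if not reports:
        raise ValueError("need at least one report")
    long = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    rows = []
    for cls in CLASS_CODES:
        areas = np.array([r.class_areas[cls] for r in reports])
        row = {"class": cls,
               "area_min_km2": float(areas.min()),
               "area_max_km2": float(areas.max()),
               "area_mean_km2": float(areas.mean())}
        for z in ZONES:
            vals = np.array([r.coverage[(cls, z)] for r in reports])
            with np.errstate(invalid="ignore"):
                row[f"mean_pct_{z}"] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
        vals = np.array([r.reserve_total[cls] for r in reports])
        row["mean_pct_reserve"] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
        rows.append(row)
    return long, pd.DataFrame(rows)
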