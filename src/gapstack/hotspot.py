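"""Stacked richness maps, hotspot classification, and elevation profiles.

Binarized per-species distributions are summed cell-wise into a scenario
richness raster.  Cells holding the potential distributions of at least 80%
of the scenario's species are "priority areas", at least 50% "important
areas", and the rest "normal areas".  Class comparisons use exact rational
arithmetic on integer richness counts, so threshold boundaries carry no
floating-point artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import BinaryDistribution
from .grid import Grid

__all__ = ["ScenarioStack", "HotspotMap", "CLASS_CODES", "CLASS_LABELS",
           "stack_scenario", "classify_hotspots", "elevation_profile",
           "area_richness_correlation"]

#: Integer codes in hotspot class rasters.
CLASS_CODES = {"normal": 0, "important": 1, "priority": 2}
CLASS_LABELS = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class ScenarioStack:
    scenario: str
    richness: np.ndarray          # int raster, 0..n_species
    n_species: int
    member_species: list[str]
    grid: Grid


@dataclass
class HotspotMap:
    scenario: str
    classes: np.ndarray           # int raster per CLASS_CODES
    richness: np.ndarray
    n_species: int
    thresholds: tuple[float, float]
    grid: Grid

    def class_mask(self, label: str) -> np.ndarray:
        return self.classes == CLASS_CODES[label]


def stack_scenario(binaries: dict[str, BinaryDistribution | np.ndarray],
                   scenario_species: list[str],
                   scenario: str = "all",
                   grid: Grid | None = None) -> ScenarioStack:
    """Cell-wise integer sum of exactly the scenario's species' binaries."""
    missing = [s for s in scenario_species if s not in binaries]
    if missing:
        raise KeyError(f"missing species binaries: {missing}")
    if not scenario_species:
        raise ValueError("scenario has no species")
    richness = None
    for sp in scenario_species:
        b = binaries[sp]
        if isinstance(b, BinaryDistribution):
            arr, g = b.presence, b.grid
        else:
            arr, g = np.asarray(b), grid
        if grid is None:
            grid = g
        elif g is not None:
            grid.require_congruent(g)
        if richness is None:
            richness = np.zeros(arr.shape, dtype=int)
        if arr.shape != richness.shape:
            raise ValueError(f"grid mismatch for species {sp!r}")
        richness += arr.astype(int)
    if grid is None:
        raise ValueError("no grid available; pass grid= when stacking raw arrays")
    return ScenarioStack(scenario=scenario, richness=richness,
                         n_species=len(scenario_species),
                         member_species=list(scenario_species), grid=grid)


def _as_fraction(x: float | str | Fraction) -> Fraction:
    # via str so 0.8 means the decimal 8/10, not its binary float neighbour
    return x if isinstance(x, Fraction) else Fraction(str(x))


def classify_hotspots(stack: ScenarioStack,
                      thresholds: tuple[float, float] = (0.8, 0.5)) -> HotspotMap:
    """Three-class map: priority iff richness/n >= 0.8, important iff
    >= 0.5, else normal — compared as exact rationals."""
    if stack.n_species < 1:
        raise ValueError("cannot classify with zero species")
    hi, lo = (_as_fraction(t) for t in thresholds)
    if not hi >= lo:
        raise ValueError(f"thresholds must be (high, low), got {thresholds}")
    r = stack.richness.astype(np.int64)
    n = int(stack.n_species)
    # r/n >= p/q  <=>  r*q >= p*n (all non-negative integers)
    pri = r * hi.denominator >= hi.numerator * n
    imp = r * lo.denominator >= lo.numerator * n
    classes = np.where(pri, CLASS_CODES["priority"],
                       np.where(imp, CLASS_CODES["important"], CLASS_CODES["normal"]))
    return HotspotMap(scenario=stack.scenario, classes=classes,
                      richness=stack.richness, n_species=n,
                      thresholds=(float(hi), float(lo)), grid=stack.grid)


def elevation_profile(stack: ScenarioStack, elevation: np.ndarray,
                      band_width: float = 100.0) -> pd.DataFrame:
    """Per elevation band [lo, lo + band_width): area (km^2) and mean richness."""
    if band_width <= 0:
        raise ValueError("band_width must be positive")
    if elevation.shape != stack.richness.shape:
        raise ValueError("elevation raster not congruent with richness")
    e = elevation.ravel()
    r = stack.richness.ravel()
    band_lo = np.floor(e / band_width) * band_width
    df = pd.DataFrame({"band_lo": band_lo, "richness": r})
    g = df.groupby("band_lo", sort=True)
    out = pd.DataFrame({
        "band_lo": g.size().index.to_numpy(),
        "band_area_km2": g.size().to_numpy() * stack.grid.cell_area_km2,
        "mean_richness": g["richness"].mean().to_numpy(),
    })
    out["band_mid"] = out["band_lo"] + band_width / 2.0
    return out[["band_lo", "band_mid", "band_area_km2", "mean_richness"]]


def area_richness_correlation(profile: pd.DataFrame) -> float:
    """Pearson correlation between elevation-band area and mean richness."""
    a = profile["band_area_km2"].to_numpy(dtype=float)
    r = profile["mean_richness"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(r)
    if ok.sum() < 3:
        raise ValueError("need at least 3 bands with defined richness")
    if np.ptp(a[ok]) == 0 or np.ptp(r[ok]) == 0:
        raise ValueError("zero-variance column")
    return float(stats.pearsonr(a[ok], r[ok]).statistic)
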