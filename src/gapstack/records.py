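"""Effective-record filtering and scenario species lists.

Raw multi-source observations become "effective records" through three rules:

* camera: one detection per species per site per 30-minute window (a record
  is retained iff >= 30 min elapsed since the last retained record of that
  species at that site);
* transect: records of a species closer than 30 m to an already-retained
  record are merged (greedy, in survey order; exactly 30 m keeps both);
* interview: retained only for species already confirmed by an effective
  camera or transect record.

Specimen records pass through unfiltered.  Each filter is idempotent and
never fabricates records.  Species enter modeling only with a known phenology
group and at least ``min_records`` effective records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesDataset",
    "filter_camera_detections", "dedup_transect_records", "crossvalidate_interviews",
    "apply_effective_filters", "build_species_datasets",
    "build_scenario_lists", "select_modeling_species",
    "SCENARIO_GROUPS",
]

#: Phenology groups pooled by each seasonal scenario.
SCENARIO_GROUPS = {
    "all": ("mammal", "resident_bird", "summer_bird", "winter_bird"),
    "resident": ("mammal", "resident_bird"),
    "summer": ("mammal", "summer_bird"),
    "winter": ("mammal", "winter_bird"),
}


@dataclass
class SpeciesDataset:
    species_id: str
    group: str
    effective_records: pd.DataFrame

    @property
    def n_effective(self) -> int:
        return len(self.effective_records)


def filter_camera_detections(records: pd.DataFrame, window_minutes: float = 30.0) -> pd.DataFrame:
    """Apply the detection-independence rule to camera records.

    Camera rows are grouped by (species, site), sorted by timestamp (ties
    broken by coordinates so the result is input-order invariant), and a row
    is retained iff at least ``window_minutes`` elapsed since the previously
    retained row.  Non-camera rows pass through untouched.
    """
    cam = records["source"] == "camera"
    if cam.any():
        sub = records.loc[cam]
        if sub["timestamp"].isna().any():
            i = sub.index[sub["timestamp"].isna()][0]
            raise ValueError(f"camera record at index {i} has no timestamp")
        if sub["site_id"].isna().any():
            i = sub.index[sub["site_id"].isna()][0]
            raise ValueError(f"camera record at index {i} has no site_id")
    keep = np.ones(len(records), dtype=bool)
    window = pd.Timedelta(minutes=window_minutes)
    pos = {idx: k for k, idx in enumerate(records.index)}
    for (_, _), g in records.loc[cam].groupby(["species_id", "site_id"], sort=False):
        g = g.sort_values(["timestamp", "x", "y"], kind="mergesort")
        last_kept = None
        for idx, ts in zip(g.index, g["timestamp"]):
            if last_kept is None or ts - last_kept >= window:
                last_kept = ts
            else:
                keep[pos[idx]] = False
    return records.loc[keep]


def dedup_transect_records(records: pd.DataFrame, radius_m: float = 30.0) -> pd.DataFrame:
    """Greedy spatial deduplication of transect records, per species, in
    input (survey) order: a row is dropped iff it lies strictly within
    ``radius_m`` of an already-retained row of the same species."""
    keep = np.ones(len(records), dtype=bool)
    tra = records["source"] == "transect"
    pos = {idx: k for k, idx in enumerate(records.index)}
    for _, g in records.loc[tra].groupby("species_id", sort=False):
        xy = g[["x", "y"]].to_numpy(dtype=float)
        kept: list[int] = []
        for i in range(len(g)):
            if kept:
                d = np.hypot(xy[kept, 0] - xy[i, 0], xy[kept, 1] - xy[i, 1])
                if (d < radius_m).any():
                    keep[pos[g.index[i]]] = False
                    continue
            kept.append(i)
    return records.loc[keep]


def crossvalidate_interviews(records: pd.DataFrame,
                             field_confirmed_species: set[str]) -> pd.DataFrame:
    """Drop interview rows whose species lacks an effective field record."""
    drop = (records["source"] == "interview") & ~records["species_id"].isin(field_confirmed_species)
    return records.loc[~drop]


def apply_effective_filters(records: pd.DataFrame,
                            window_minutes: float = 30.0,
                            radius_m: float = 30.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full raw -> effective funnel; returns (effective, audit).

    Order: drop records flagged invalid (conflicting metadata), apply the
    camera 30-min rule, the transect 30-m rule, then cross-validate interview
    records against the species confirmed by camera/transect.  The audit
    table holds every dropped row with a ``dropped_by`` provenance column.
    """
    df = records.reset_index(drop=True)
    dropped_by = pd.Series("", index=df.index, dtype=object)

    if "valid" in df.columns:
        bad = ~df["valid"].astype(bool)
        dropped_by[bad] = "conflicting_metadata"
        stage = df.loc[~bad]
    else:
        stage = df

    after_cam = filter_camera_detections(stage, window_minutes=window_minutes)
    dropped_by[stage.index.difference(after_cam.index)] = "camera_30min"

    after_tra = dedup_transect_records(after_cam, radius_m=radius_m)
    dropped_by[after_cam.index.difference(after_tra.index)] = "transect_30m"

    confirmed = set(after_tra.loc[after_tra["source"].isin(["camera", "transect"]),
                                  "species_id"])
    effective = crossvalidate_interviews(after_tra, confirmed)
    dropped_by[after_tra.index.difference(effective.index)] = "interview_unconfirmed"

    audit = df.loc[dropped_by != ""].copy()
    audit["dropped_by"] = dropped_by[dropped_by != ""]
    return effective.reset_index(drop=True), audit.reset_index(drop=True)


def build_species_datasets(effective: pd.DataFrame) -> list[SpeciesDataset]:
    out = []
    for sp, g in effective.groupby("species_id", sort=True):
        groups = g["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"species {sp!r} carries multiple groups: {sorted(groups)}")
        out.append(SpeciesDataset(species_id=str(sp), group=str(groups[0]),
                                  effective_records=g.reset_index(drop=True)))
    return out


def build_scenario_lists(species_datasets: list[SpeciesDataset]) -> dict[str, list[str]]:
    """Scenario -> species list: all species; resident = mammals + resident
    birds; summer = mammals + summer birds; winter = mammals + winter birds.
    Mammals appear in every scenario."""
    for ds in species_datasets:
        if ds.group not in SCENARIO_GROUPS["all"]:
            raise ValueError(f"species {ds.species_id!r}: unknown group {ds.group!r}")
    return {scen: [ds.species_id for ds in species_datasets if ds.group in groups]
            for scen, groups in SCENARIO_GROUPS.items()}


def select_modeling_species(species_datasets: list[SpeciesDataset],
                            min_records: int = 10) -> list[SpeciesDataset]:
    """Species modeled: known phenology group (stragglers/travelers are
    ``other`` and excluded) and at least ``min_records`` effective records."""
    return [ds for ds in species_datasets
            if ds.group != "other" and ds.group in SCENARIO_GROUPS["all"]
            and ds.n_effective >= min_records]
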