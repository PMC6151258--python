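"""End-to-end orchestration: simulate -> filter -> select variables -> fit ->
stack -> classify -> report.

A single master seed fans out into per-stage, per-species sub-seeds through a
documented counter scheme (``SeedSequence([master, stage, index])``), so a
rerun with the same config is bit-identical while stages stay independently
reproducible.  All artifacts are text (ASCII grids, CSV, GeoJSON, JSON) and
carry provenance (config hash + seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import background as bg
from . import envstack as es
from . import gapreport as gr
from . import hotspot as hs
from . import io as gio
from . import records as rec
from . import synthgen as sg
from .ensemble import TECHNIQUES, build_ensemble, cross_evaluate, predict_and_binarize

__all__ = ["RunConfig", "RunResult", "run_pipeline", "derive_seed"]

# stage indices for the seed counter scheme
_STAGES = {"landscape": 0, "zones": 1, "sites": 2, "species": 3, "sampling": 4,
           "background": 5, "training": 6, "evaluate": 7, "ensemble": 8}


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic sub-seed for (master seed, stage, index), < 2**31."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, _STAGES[stage], int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """All pipeline parameters.  Defaults follow the study protocol where it
    states a value (30-min camera window, 30-m transect radius, 2-km road
    buffer with 2,000 points, VIF threshold 10, 10 evaluation runs,
    0.8/0.5 hotspot thresholds, 1-km margin ring)."""

    mode: str = "synthetic"
    seed: int = 0
    # landscape
    extent: tuple[float, float, float, float] = (0.0, 0.0, 12000.0, 12000.0)
    cell_size: float = 200.0
    elev_range: tuple[float, float] = (375.0, 2118.0)
    length_scale_m: float = 2500.0
    climate_noise_scale: float = 1.0
    # zoning / roads
    zone_fractions: tuple[float, float, float] | None = None
    n_roads: int = 2
    # community & sampling
    group_mix: dict[str, int] = field(default_factory=lambda: {
        "mammal": 2, "resident_bird": 3, "summer_bird": 2, "winter_bird": 1})
    n_occurrences_per_species: int = 150
    bias_strength: float = 0.001          # m^-1; 0 disables road bias
    prevalence_threshold: float = 0.5
    invalid_fraction: float = 0.0
    camera_spacing_m: float = 600.0
    # record filters
    camera_window_minutes: float = 30.0
    transect_radius_m: float = 30.0
    min_records: int = 10
    # background / pseudo-absences
    buffer_width_m: float = 2000.0
    n_background: int = 2000
    pa_per_set: int | None = 1000
    # variable selection
    vif_threshold: float = 10.0
    # ensemble
    techniques: tuple[str, ...] = TECHNIQUES
    n_runs: int = 10
    split_fraction: float = 0.7
    tss_floor: float = 0.40
    combination: str = "tss_weighted"
    # hotspots & gaps
    scenarios: tuple[str, ...] = ("all", "resident", "summer", "winter")
    hotspot_thresholds: tuple[float, float] = (0.8, 0.5)
    band_width_m: float = 100.0
    margin_width_m: float = 1000.0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for t in self.techniques:
            if t not in TECHNIQUES:
                raise ValueError(f"unknown technique {t!r}; expected one of {TECHNIQUES}")
        for s in self.scenarios:
            if s not in es.SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}; expected one of {es.SCENARIOS}")
        for g in self.group_mix:
            if g not in sg.GROUP_SEASON:
                raise ValueError(f"unknown group {g!r}")

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        for k in ("extent", "elev_range", "zone_fractions", "techniques",
                  "scenarios", "hotspot_thresholds"):
            if k in kw and kw[k] is not None:
                kw[k] = tuple(kw[k])
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunResult:
    config: RunConfig
    outdir: Path
    landscape: sg.SyntheticLandscape
    zones: sg.ZoneMask
    effective: pd.DataFrame
    species_summary: pd.DataFrame
    model_report: pd.DataFrame
    hotspots: dict[str, hs.HotspotMap]
    gap_reports: dict[str, gr.GapReport]
    gap_summary: pd.DataFrame
    profiles: dict[str, pd.DataFrame]
    log_lines: list[str]


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute the full synthetic-mode pipeline and write all artifacts.

    Stages run in order; a failing stage raises with the stage name and the
    offending species/layer in the message.  Reruns with the same config are
    bit-identical.
    """
    config.validate()
    if config.mode != "synthetic":
        raise NotImplementedError("real mode requires external occurrence/raster inputs")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = config.seed
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    # ---- stage 1: landscape, zoning, roads, camera design -----------------
    land = sg.generate_landscape(
        extent=config.extent, cell_size=config.cell_size,
        elev_range=config.elev_range, length_scale_m=config.length_scale_m,
        noise_scale=config.climate_noise_scale,
        seed=derive_seed(master, "landscape"))
    zones, roads = sg.generate_zones_and_roads(
        land, zone_fractions=config.zone_fractions, n_roads=config.n_roads,
        seed=derive_seed(master, "zones"))
    sites = sg.generate_camera_sites(
        land, spacing_m=config.camera_spacing_m, zone_mask=zones,
        seed=derive_seed(master, "sites"))
    env = land.env_stack()
    note(f"landscape: {land.grid.nrows}x{land.grid.ncols} cells, "
         f"{land.grid.area_km2:.2f} km2, {len(roads)} roads, {len(sites)} camera sites")

    # ---- stage 2: virtual community and biased sampling -------------------
    community = sg.default_virtual_species(
        land, group_mix=config.group_mix,
        prevalence_threshold=config.prevalence_threshold,
        seed=derive_seed(master, "species"))
    raw_frames = []
    truths: dict[str, np.ndarray] = {}
    for i, vs in enumerate(community):
        truths[vs.species_id] = sg.true_distribution(vs, env)
        raw_frames.append(sg.sample_occurrences(
            vs, land, n=config.n_occurrences_per_species,
            bias_strength=config.bias_strength,
            seed=derive_seed(master, "sampling", i), sites=sites,
            invalid_fraction=config.invalid_fraction))
    raw = pd.concat(raw_frames, ignore_index=True)
    note(f"sampling: {len(raw)} raw records for {len(community)} virtual species")

    # ---- stage 3: effective-record filtering ------------------------------
    effective, audit = rec.apply_effective_filters(
        raw, window_minutes=config.camera_window_minutes,
        radius_m=config.transect_radius_m)
    datasets = rec.build_species_datasets(effective)
    modeled = rec.select_modeling_species(datasets, min_records=config.min_records)
    scenario_lists = rec.build_scenario_lists(modeled)
    note(f"filtering: {len(raw)} raw -> {len(effective)} effective "
         f"({len(audit)} dropped); {len(modeled)} species modeled")

    # ---- stage 4: background pool -----------------------------------------
    mask = bg.buffer_roads(roads, land.grid, width=config.buffer_width_m)
    background = bg.sample_background(
        mask, land.grid, n=config.n_background,
        seed=derive_seed(master, "background"), buffer_width=config.buffer_width_m)
    note(f"background: {int(mask.sum())} buffer cells, {background.n} points")

    # ---- stage 5: per-species ensemble models -----------------------------
    binaries: dict[str, object] = {}
    summary_rows = []
    report_rows = []
    vif_rows = []
    for i, ds in enumerate(modeled):
        sp = ds.species_id
        scen_env = es.seasonal_subset(env, sg.GROUP_SEASON[ds.group]
                                      if sg.GROUP_SEASON[ds.group] != "annual"
                                      else "resident")
        pres_xy = ds.effective_records[["x", "y"]].to_numpy(dtype=float)
        sample_pts = np.vstack([pres_xy, background.points])
        diag = es.select_variables_vif(scen_env, sample_pts,
                                       threshold=config.vif_threshold)
        vif_df = diag.to_frame()
        vif_df.insert(0, "species_id", sp)
        vif_rows.append(vif_df)
        sp_env = scen_env.subset(diag.selected)
        try:
            training = bg.build_training_set(
                sp, pres_xy, background, sp_env, pa_per_set=config.pa_per_set,
                seed=derive_seed(master, "training", i))
            evals = cross_evaluate(
                training, techniques=config.techniques, n_runs=config.n_runs,
                split_fraction=config.split_fraction,
                seed=derive_seed(master, "evaluate", i))
            model = build_ensemble(
                training, evals, seed=derive_seed(master, "ensemble", i),
                tss_floor=config.tss_floor, combination=config.combination)
            binary = predict_and_binarize(model, sp_env)
        except Exception as exc:  # annotate with the failing stage/species
            raise RuntimeError(f"modeling stage failed for species {sp!r}: {exc}") from exc
        binaries[sp] = binary
        for ev in evals:
            report_rows.append({"species_id": sp, "technique": ev.technique,
                                "run": ev.run_index, "tss": ev.tss,
                                "sensitivity": ev.sensitivity,
                                "specificity": ev.specificity,
                                "threshold": ev.best_threshold})
        truth = truths[sp]
        pred = binary.presence
        inter = int((truth & pred).sum())
        union = int((truth | pred).sum())
        summary_rows.append({
            "species_id": sp, "group": ds.group, "n_effective": ds.n_effective,
            "n_features": len(diag.selected),
            "selected_members": "+".join(model.selected_members),
            "ensemble_tss": model.ensemble_tss, "cutoff_P": model.cutoff_P,
            "area_km2": binary.area_km2,
            "mean_elevation_m": binary.mean_elevation(land.elevation),
            "true_area_km2": float(truth.sum()) * land.grid.cell_area_km2,
            "jaccard_vs_truth": (inter / union) if union else float("nan"),
        })
    species_summary = pd.DataFrame(summary_rows)
    model_report = pd.DataFrame(report_rows)
    note(f"modeling: {len(modeled)} species x {len(config.techniques)} techniques "
         f"x {config.n_runs} runs = {len(model_report)} evaluations")

    # ---- stage 6: hotspots, elevation profiles ----------------------------
    hotspots: dict[str, hs.HotspotMap] = {}
    profiles: dict[str, pd.DataFrame] = {}
    for scen in config.scenarios:
        stack = hs.stack_scenario(binaries, scenario_lists[scen], scenario=scen)
        hotspots[scen] = hs.classify_hotspots(stack, thresholds=config.hotspot_thresholds)
        prof = hs.elevation_profile(stack, land.elevation, band_width=config.band_width_m)
        try:
            prof_r = hs.area_richness_correlation(prof)
        except ValueError:
            prof_r = float("nan")
        prof["scenario"] = scen
        prof.attrs["pearson_area_richness"] = prof_r
        profiles[scen] = prof
        note(f"hotspot[{scen}]: {stack.n_species} species, "
             f"priority {float(hotspots[scen].class_mask('priority').sum()) * land.grid.cell_area_km2:.2f} km2")

    # ---- stage 7: gap analysis --------------------------------------------
    zones_m = gr.margin_ring(zones, width=config.margin_width_m)
    gap_reports = {scen: gr.coverage(hotspots[scen], zones_m)
                   for scen in config.scenarios}
    gap_long, gap_summary = gr.summarize_scenarios(list(gap_reports.values()))
    note("gap analysis: margin ring "
         f"{zones_m.zone_areas()['margin_1km']:.2f} km2, {len(gap_reports)} scenarios")

    # ---- write artifacts ---------------------------------------------------
    config.to_yaml(outdir / "config.yaml")
    gio.write_ascii_grid(outdir / "landscape" / "elevation.asc", land.elevation, land.grid)
    gio.write_ascii_grid(outdir / "landscape" / "slope.asc", land.slope, land.grid)
    gio.write_ascii_grid(outdir / "zones.asc", zones_m.zone.astype(float), land.grid)
    gio.write_roads_geojson(roads, outdir / "roads.geojson")
    gio.write_occurrences(raw, outdir / "records" / "raw.csv")
    gio.write_occurrences(effective, outdir / "records" / "effective.csv")
    _df_to_csv(audit, outdir / "records" / "audit.csv")
    _df_to_csv(pd.DataFrame({"x": background.points[:, 0], "y": background.points[:, 1],
                             "set_id": 0, "seed": background.seed}),
               outdir / "background" / "background.csv")
    _df_to_csv(pd.concat(vif_rows, ignore_index=True), outdir / "models" / "vif_diagnostics.csv")
    _df_to_csv(model_report, outdir / "models" / "model_report.csv")
    _df_to_csv(species_summary, outdir / "models" / "species_summary.csv")
    for sp, b in binaries.items():
        gio.write_ascii_grid(outdir / "rasters" / f"{sp}_binary.asc",
                             b.presence.astype(float), land.grid)
    for scen in config.scenarios:
        gio.write_ascii_grid(outdir / "hotspots" / f"{scen}_richness.asc",
                             hotspots[scen].richness.astype(float), land.grid)
        gio.write_ascii_grid(outdir / "hotspots" / f"{scen}_classes.asc",
                             hotspots[scen].classes.astype(float), land.grid)
        _df_to_csv(profiles[scen], outdir / "profiles" / f"{scen}_profile.csv")
    _df_to_csv(gap_long, outdir / "gap_long.csv")
    _df_to_csv(gap_summary, outdir / "gap_summary.csv")
    def _jnum(x: float) -> float | None:
        return None if (isinstance(x, float) and np.isnan(x)) else x

    gap_json = {scen: {"class_areas_km2": {c: _jnum(a) for c, a in r.class_areas.items()},
                       "coverage_pct": {f"{c}|{z}": _jnum(r.coverage[(c, z)])
                                        for c, z in r.coverage},
                       "reserve_total_pct": {c: _jnum(v) for c, v in r.reserve_total.items()}}
                for scen, r in gap_reports.items()}
    with open(outdir / "gapreport.json", "w") as fh:
        json.dump(gap_json, fh, sort_keys=True, indent=1)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump({"config_hash": config.config_hash(), "seed": master,
                   "stages": sorted(_STAGES)}, fh, sort_keys=True, indent=1)
    (outdir / "log.txt").write_text("\n".join(log) + "\n")

    return RunResult(config=config, outdir=outdir, landscape=land, zones=zones_m,
                     effective=effective, species_summary=species_summary,
                     model_report=model_report, hotspots=hotspots,
                     gap_reports=gap_reports, gap_summary=gap_summary,
                     profiles=profiles, log_lines=log)
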