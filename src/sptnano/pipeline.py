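"""End-to-end orchestration: config, seed fan-out, staged outputs, manifest.

A run executes (optionally) simulate → metrics → motion → nanodomains →
compartments → stats, writing each stage's outputs before the next starts.
One global seed is fanned out to fixed per-stage child seeds so toggling a
stage never perturbs another stage's randomness.  The manifest echoes the
config verbatim and records per-stage output checksums and wall-clock time;
deterministic stages are checksum-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as spio
from .compartments import assign_trajectories, assignments_table, compartment_report, load_rois
from .geometry import CompartmentLayout, build_default_layout
from .motion import collect_displacements, fit_three_state_global, mss_table
from .nanodomains import find_nanodomains, nanodomains_per_roi
from .synthetic import SimulationConfig, simulate_cell
from .trajectories import summarize_cell, trajectories_from_table

STAGES = ("simulate", "metrics", "motion", "nanodomains", "compartments", "stats")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All tunables of every stage; defaults are the documented analysis defaults."""

    # inputs (either simulate, or provide a localization table)
    localizations: str | None = None
    rois: str | None = None
    unit_hint: str = "um"
    output_dir: str = "sptnano_out"
    seed: int = 0
    stages: tuple = STAGES
    # simulate
    simulate_n_spines: int = 4
    simulate_n_molecules: int = 2000
    simulate_state_diffusion: tuple = (0.003, 0.03, 0.3)
    simulate_state_occupancy: tuple = (0.3, 0.3, 0.4)
    simulate_localization_sigma: float = 25.0
    # metrics
    frame_interval: float = 0.02
    min_track_frames: int = 8
    min_trajectories_cell: int = 1000
    msd_fit_points: int = 4
    auc_max_lag: int = 12
    immobile_threshold_log10: float = -1.6
    # motion
    mss_min_frames: int = 20
    mss_nu_max: int = 6
    mss_n_lag_fit: int = 5
    cdf_max_per_track: int = 7
    cdf_n_starts: int = 10
    # nanodomains
    nanodomain_min_detections: int = 50
    nanodomain_density_factor: float = 2.0
    object_factor: float = 1.0
    # compartments
    roi_majority: float = 0.5
    min_trajectories_roi: int = 50

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        payload = {
            k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
        }
        return cls(**payload)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def stage_seeds(seed: int) -> dict:
    """Fixed fan-out of the global seed into independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {outputs: {file: sha256}, seconds}
    warnings: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "version": self.version,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                indent=1,
                sort_keys=True,
            )
        )


def run_pipeline(config: RunConfig) -> RunManifest:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(config=config.echo(), version=__version__)
    dt = config.frame_interval

    def record(stage, outputs, t0):
        manifest.stages[stage] = {
            "outputs": {Path(p).name: spio.sha256_of(p) for p in outputs},
            "seconds": round(time.perf_counter() - t0, 3),
        }
        manifest.save(outdir / "manifest.json")

    loc_path = config.localizations
    roi_path = config.rois

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        layout = build_default_layout(config.simulate_n_spines, seed=seeds["simulate"])
        sim_cfg = SimulationConfig(
            geometry=layout,
            seed=seeds["simulate"],
            n_molecules=config.simulate_n_molecules,
            state_diffusion=tuple(config.simulate_state_diffusion),
            state_occupancy=tuple(config.simulate_state_occupancy),
            localization_sigma=config.simulate_localization_sigma,
            frame_interval=dt,
            min_track_length=config.min_track_frames,
        )
        result = simulate_cell(sim_cfg, cell_id="sim")
        loc_path = outdir / "localizations.csv"
        roi_path = outdir / "layout.json"
        truth_path = outdir / "ground_truth.csv"
        spio.write_localization_table(result.localizations, loc_path)
        spio.write_ground_truth(result.ground_truth, truth_path)
        layout.to_json(roi_path, cell_id="sim")
        record("simulate", [loc_path, truth_path, roi_path], t0)

    if loc_path is None:
        raise ConfigError("no localization table: provide 'localizations' or enable simulate")
    table = spio.read_localization_table(loc_path, unit_hint=config.unit_hint)
    trajectories = trajectories_from_table(table)

    if "metrics" in config.stages:
        t0 = time.perf_counter()
        cell_rows, track_frames = [], []
        for cell_id in sorted(table["cell_id"].unique(), key=str):
            cell_tracks = [t for t in trajectories if t.cell_id == cell_id]
            s = summarize_cell(
                cell_tracks,
                dt=dt,
                min_track_frames=config.min_track_frames,
                min_trajectories=config.min_trajectories_cell,
                auc_max_lag=config.auc_max_lag,
                n_fit_points=config.msd_fit_points,
                threshold_log10=config.immobile_threshold_log10,
            )
            if s is None:
                manifest.warnings.append(f"cell {cell_id}: empty summary")
                continue
            if s.below_min_trajectories:
                manifest.warnings.append(
                    f"cell {cell_id}: below the {config.min_trajectories_cell}-trajectory inclusion rule"
                )
            cell_rows.append(
                {
                    "cell_id": cell_id,
                    "n_trajectories": s.n_trajectories,
                    "auc": s.auc,
                    "immobile_fraction": s.immobile_fraction,
                    "below_min_trajectories": s.below_min_trajectories,
                }
            )
            tt = s.track_table.copy()
            tt.insert(0, "cell_id", cell_id)
            track_frames.append(tt)
        per_cell = outdir / "per_cell_summary.csv"
        per_track = outdir / "per_track.csv"
        pd.DataFrame(cell_rows).to_csv(per_cell, index=False, float_format=spio.FLOAT_FORMAT)
        (pd.concat(track_frames, ignore_index=True) if track_frames else pd.DataFrame()).to_csv(
            per_track, index=False, float_format=spio.FLOAT_FORMAT
        )
        record("metrics", [per_cell, per_track], t0)

    if "motion" in config.stages:
        t0 = time.perf_counter()
        mss = mss_table(
            trajectories,
            nu_max=config.mss_nu_max,
            n_lag_fit=config.mss_n_lag_fit,
            dt=dt,
            min_frames=config.mss_min_frames,
        )
        mss_path = outdir / "mss.csv"
        mss.to_csv(mss_path, index=False, float_format=spio.FLOAT_FORMAT)
        samples = [
            collect_displacements(
                [t for t in trajectories if t.cell_id == cid],
                cid,
                max_per_track=config.cdf_max_per_track,
                min_track_frames=config.min_track_frames,
            )
            for cid in sorted(table["cell_id"].unique(), key=str)
        ]
        samples = [s for s in samples if s.displacements.size > 0]
        model_path = outdir / "three_state.json"
        if samples:
            model = fit_three_state_global(
                samples, dt=dt, n_starts=config.cdf_n_starts, seed=seeds["motion"]
            )
            model_path.write_text(json.dumps(model.to_json_dict(), indent=1, sort_keys=True))
        else:
            manifest.warnings.append("motion: no displacements collected")
            model_path.write_text("{}")
        record("motion", [mss_path, model_path], t0)

    rois = load_rois(roi_path) if roi_path else []

    if "nanodomains" in config.stages:
        t0 = time.perf_counter()
        pts = table[["x_um", "y_um"]].to_numpy()
        _, objects, domains = find_nanodomains(
            pts,
            object_factor=config.object_factor,
            min_detections=config.nanodomain_min_detections,
            density_factor=config.nanodomain_density_factor,
        )
        dom_path = outdir / "nanodomains.csv"
        pd.DataFrame(
            [
                {
                    "centroid_x_um": d.centroid[0],
                    "centroid_y_um": d.centroid[1],
                    "diameter_nm": d.diameter_nm,
                    "area_um2": d.area_um2,
                    "n_detections": d.members.size,
                    "diameter_convention": d.diameter_convention,
                }
                for d in domains
            ]
        ).to_csv(dom_path, index=False, float_format=spio.FLOAT_FORMAT)
        outputs = [dom_path]
        if rois:
            counts = nanodomains_per_roi(domains, [r for r in rois if r.label == "spine"])
            counts_path = outdir / "nanodomains_per_spine.csv"
            counts.to_csv(counts_path, index=False)
            outputs.append(counts_path)
        record("nanodomains", outputs, t0)

    report = None
    if "compartments" in config.stages and rois:
        t0 = time.perf_counter()
        assignments = assign_trajectories(trajectories, rois, majority=config.roi_majority)
        assign_path = outdir / "assignments.csv"
        assignments_table(assignments).to_csv(assign_path, index=False, float_format=spio.FLOAT_FORMAT)
        report = compartment_report(
            assignments,
            trajectories,
            rois,
            dt=dt,
            min_track_frames=config.min_track_frames,
            min_trajectories_cell=config.min_trajectories_cell,
            min_trajectories_roi=config.min_trajectories_roi,
        )
        comp_path = outdir / "compartment_report.csv"
        roi_d_path = outdir / "roi_d_eff.csv"
        report["per_compartment"].to_csv(comp_path, index=False, float_format=spio.FLOAT_FORMAT)
        report["per_roi"].to_csv(roi_d_path, index=False, float_format=spio.FLOAT_FORMAT)
        record("compartments", [assign_path, comp_path, roi_d_path], t0)

    if "stats" in config.stages:
        t0 = time.perf_counter()
        from .stats import comparison_table, run_comparisons, text_summary

        stats_path = outdir / "comparisons.csv"
        if report is not None and not report["per_roi"].empty:
            per_roi = report["per_roi"].dropna(subset=["d_eff"])
            spine = per_roi.loc[per_roi["label"] == "spine", "d_eff"].to_numpy()
            shaft = per_roi.loc[per_roi["label"] == "shaft", "d_eff"].to_numpy()
            if len(spine) >= 3 and len(shaft) >= 3:
                results = run_comparisons(
                    {"spine": {"d_eff": spine}, "shaft": {"d_eff": shaft}},
                    metrics=["d_eff"],
                )
                comparison_table(results).to_csv(stats_path, index=False, float_format=spio.FLOAT_FORMAT)
                (outdir / "comparisons.txt").write_text(text_summary(results) + "\n")
            else:
                manifest.warnings.append("stats: too few populated ROIs per compartment; skipped")
                stats_path.write_text("")
        else:
            manifest.warnings.append("stats: no compartment report available; skipped")
            stats_path.write_text("")
        record("stats", [stats_path], t0)

    manifest.save(outdir / "manifest.json")
    return manifest
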