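"""Parameter-recovery benchmarks: the package analysing its own generator.

Every function builds a synthetic dataset with known ground truth, runs the
corresponding analysis stage, and returns the measured quantities.  These
benchmarks are what the test suite asserts tolerances on and what the
acceptance script reports; all randomness is derived from one seed.

Fixture conventions (see docs/methods.md for rationale):

- free-diffusion recovery uses noise-free tracks with bleaching mean 30
  frames (the 4-point MSD fit's median is skewed low on very short tracks);
- the three-state fit uses layouts without trapping discs, so the generator
  is exactly the static three-exponential mixture the model assumes;
- nanodomain recovery uses a 10×10 μm footprint at 20 localizations/μm²
  inside a 14×14 μm field with planted 100-detection discs at 10× density.
"""

from __future__ import annotations

import numpy as np

from .geometry import box_layout, build_default_layout
from .motion import collect_displacements, compute_mss, fit_three_state_global, mss_table, three_state_cdf
from .nanodomains import find_nanodomains, nanodomain_geometry
from .stats import run_test, select_test
from .synthetic import (
    SimulationConfig,
    planted_cluster_field,
    simulate_cell,
    uniform_point_field,
)
from .trajectories import (
    Trajectory,
    classify_mobility,
    compute_msd,
    effective_diffusion,
    fit_diffusion,
    summarize_cell,
)

DT = 0.02


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


# ------------------------------------------------------------------ msd oracle agreement

def msd_oracle_deviation(seed: int, n_tracks: int = 100) -> dict:
    """Max |optimized MSD − naive all-pairs double loop| over random tracks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for ti in range(n_tracks):
        n = int(rng.integers(5, 20))
        frames = np.sort(rng.choice(60, size=n, replace=False))
        xy = rng.normal(0.0, 0.5, (n, 2))
        traj = Trajectory(ti, "c", frames, xy)
        prof = compute_msd(traj, dt=DT)
        for lag, msd in zip(prof.lags, prof.msd):
            sq = [
                np.sum((xy[j] - xy[i]) ** 2)
                for i in range(n)
                for j in range(n)
                if frames[j] - frames[i] == lag
            ]
            worst = max(worst, abs(np.mean(sq) - msd))
    return {"max_abs_deviation": worst, "n": n_tracks}


# ------------------------------------------------------------------ free-diffusion recovery

def free_diffusion_recovery(seed: int, d_true: float = 0.1, n_molecules: int = 2600) -> dict:
    """Median fitted D and mobile fraction for noise-free free tracks."""
    cfg = SimulationConfig(
        geometry=box_layout(40, 40),
        state_occupancy=(0.0, 0.0, 1.0),
        state_diffusion=(d_true / 100, d_true / 10, d_true),
        localization_sigma=0.0,
        mean_track_length=30,
        n_molecules=n_molecules,
        seed=seed,
    )
    res = simulate_cell(cfg)
    Ds, mobile = [], []
    for t in res.trajectories:
        fit = fit_diffusion(compute_msd(t, dt=DT))
        Ds.append(fit.D)
        mobile.append(classify_mobility(fit) == "mobile")
    return {
        "median_D": float(np.median(Ds)),
        "d_true": d_true,
        "mobile_fraction": float(np.mean(mobile)),
        "n": len(Ds),
    }


# ------------------------------------------------------------------ immobile-fraction recovery

def immobile_fraction_mixture(seed: int, n_molecules: int = 3300) -> dict:
    """Immobile fraction of a 50/50 mixture of D = 0.003 and 0.3 μm²/s."""
    cfg = SimulationConfig(
        geometry=box_layout(40, 40),
        state_occupancy=(0.5, 0.0, 0.5),
        state_diffusion=(0.003, 0.03, 0.3),
        localization_sigma=0.0,
        n_molecules=n_molecules,
        seed=seed,
    )
    res = simulate_cell(cfg)
    summary = summarize_cell(res.trajectories, dt=DT, min_trajectories=2000)
    return {
        "immobile_fraction": summary.immobile_fraction,
        "target": 0.5,
        "n": summary.n_trajectories,
    }


# ------------------------------------------------------------------ three-state global fit

def three_state_recovery(
    seed: int,
    d_true: tuple = (0.003, 0.03, 0.3),
    n_cells: int = 10,
    n_molecules: int = 2600,
    n_starts: int = 10,
) -> dict:
    """Global three-state CDF fit against per-cell simplex-drawn occupancies.

    Occupancy errors are measured against the realized per-molecule state
    frequencies of each cell (the quantity the displacement mixture actually
    reflects).
    """
    seeds = _subseeds(seed, n_cells + 2)
    rng = np.random.default_rng(seeds[-1])
    samples, realized = [], []
    for c in range(n_cells):
        occ = rng.dirichlet((1.0, 1.0, 1.0))
        cfg = SimulationConfig(
            geometry=box_layout(40, 40),
            state_occupancy=tuple(occ),
            state_diffusion=d_true,
            localization_sigma=0.0,
            n_molecules=n_molecules,
            seed=seeds[c],
        )
        res = simulate_cell(cfg, cell_id=f"cell{c}")
        gt = res.ground_truth
        realized.append([(gt["true_state"] == k).mean() for k in (1, 2, 3)])
        samples.append(collect_displacements(res.trajectories, f"cell{c}"))
    model = fit_three_state_global(samples, dt=DT, n_starts=n_starts, seed=seeds[-2])
    occ_err = np.abs(model.occupancies.to_numpy() - np.array(realized))
    d_rel = np.abs(model.D / np.array(d_true) - 1.0)
    # model-form invariants of the fitted CDF
    r = np.linspace(0.0, 10.0, 2000)
    C = three_state_cdf(r, DT, model.D, model.occupancies.iloc[0].to_numpy())
    return {
        "D_fitted": [float(d) for d in model.D],
        "D_rel_err_max": float(d_rel.max()),
        "occupancy_abs_err_max": float(occ_err.max()),
        "cdf_at_zero": float(C[0]),
        "cdf_at_inf": float(C[-1]),
        "cdf_monotone": bool(np.all(np.diff(C) >= -1e-12)),
        "n_displacements": int(sum(s.displacements.size for s in samples)),
        "n_cells": n_cells,
    }


# ------------------------------------------------------------------ mss calibration

def mss_calibration(seed: int, n_molecules: int = 700) -> dict:
    """Ensemble-mean MSS slopes for ballistic, free, confined, immobile motion."""
    seeds = _subseeds(seed, 3)

    def ensemble_mean(occ, diffusion, layout, sigma, s):
        cfg = SimulationConfig(
            geometry=layout,
            state_occupancy=occ,
            state_diffusion=diffusion,
            localization_sigma=sigma,
            mean_track_length=40,
            min_track_length=20,
            n_molecules=n_molecules,
            seed=s,
        )
        res = simulate_cell(cfg)
        tab = mss_table(res.trajectories, dt=DT)
        return float(tab["s_mss"].mean()), len(tab)

    xy = np.column_stack([np.arange(40) * 0.05, np.zeros(40)])
    ballistic = compute_mss(Trajectory(0, "c", np.arange(40), xy), dt=DT).s_mss
    free_mean, n_free = ensemble_mean(
        (0, 0, 1), (0.001, 0.01, 0.1), box_layout(40, 40), 0.0, seeds[0]
    )
    immobile_mean, n_imm = ensemble_mean(
        (1, 0, 0), (1e-5, 0.01, 0.1), box_layout(40, 40), 25.0, seeds[1]
    )
    confined_layout = build_default_layout(0, seed=seeds[2])  # 170 nm shaft discs
    confined_mean, n_conf = ensemble_mean(
        (0, 1, 0), (0.001, 0.1, 0.3), confined_layout, 0.0, seeds[2]
    )
    return {
        "ballistic": float(ballistic),
        "free_mean": free_mean,
        "confined_mean": confined_mean,
        "immobile_mean": immobile_mean,
        "n_tracks": min(n_free, n_imm, n_conf),
    }


# ------------------------------------------------------------------ nanodomain recovery

FIELD = (-2.0, -2.0, 12.0, 12.0)


def nanodomain_recovery(seed: int, n_replicates: int = 3, n_csr: int = 100) -> dict:
    """Planted-cluster recovery, minimum-size rejection, CSR false-positive
    control, and PCA disc-diameter calibration."""
    seeds = _subseeds(seed, 4)
    bg_density = 20.0
    centres = ((3, 3), (7, 7), (3, 7), (7, 3))
    r100 = np.sqrt(100 / (np.pi * 10.0 * bg_density))

    recalls, posthoc_ok, counts = [], True, []
    rep_seeds = _subseeds(seeds[0], n_replicates)
    for s in rep_seeds:
        pts, labels = planted_cluster_field(
            int(100 * bg_density), 10, 10, list(centres), [100] * 4,
            cluster_diameter_um=2 * r100, seed=s,
        )
        tmap, objs, doms = find_nanodomains(pts, field=FIELD)
        counts.append(len(doms))
        obj = objs[0]
        for d in doms:
            posthoc_ok &= d.members.size >= 50
            posthoc_ok &= d.mean_density >= 2.0 * obj.mean_density
        for ci in range(4):
            planted = set(np.nonzero(labels == ci)[0])
            best = max((len(planted & set(d.members)) for d in doms), default=0)
            recalls.append(best / len(planted))

    r40 = np.sqrt(40 / (np.pi * 10.0 * bg_density))
    pts40, _ = planted_cluster_field(
        int(100 * bg_density), 10, 10, [(5, 5)], [40],
        cluster_diameter_um=2 * r40, seed=seeds[1],
    )
    _, _, doms40 = find_nanodomains(pts40, field=FIELD)

    csr_clean = 0
    for s in _subseeds(seeds[2], n_csr):
        pts_csr = uniform_point_field(1000, 10, 10, seed=s)
        _, _, doms_csr = find_nanodomains(pts_csr, field=FIELD)
        csr_clean += len(doms_csr) == 0

    rng = np.random.default_rng(seeds[3])
    u, th = rng.uniform(0, 1, 2000), rng.uniform(0, 2 * np.pi, 2000)
    disc = np.column_stack(
        [0.1 * np.sqrt(u) * np.cos(th), 0.1 * np.sqrt(u) * np.sin(th)]
    )
    diam, _ = nanodomain_geometry(disc)
    return {
        "recall_mean": float(np.mean(recalls)),
        "domains_per_replicate": counts,
        "n_planted_per_replicate": 4,
        "posthoc_rules_satisfied": bool(posthoc_ok),
        "forty_detection_domains": len(doms40),
        "csr_clean_fraction": csr_clean / n_csr,
        "disc_diameter_nm": float(diam),
        "disc_diameter_true_nm": 200.0,
    }


# ------------------------------------------------------------------ compartment ordering

def compartment_recovery(seed: int, n_replicates: int = 20, n_molecules: int = 600) -> dict:
    """Spine-trapped vs shaft-free simulation: fraction of replicates with the
    expected mobility ordering, plus the 50-trajectory D_eff floor check."""
    from .compartments import CompartmentROI, assign_trajectories, compartment_report

    ok_deff, ok_imm = 0, 0
    for s in _subseeds(seed, n_replicates):
        layout = build_default_layout(2, seed=s)
        cfg = SimulationConfig(
            geometry=layout,
            n_molecules=n_molecules,
            spine_fraction=0.4,
            spine_occupancy=(0.45, 0.45, 0.10),
            state_occupancy=(0.10, 0.20, 0.70),
            seed=s,
        )
        res = simulate_cell(cfg, cell_id="c")
        rois = [CompartmentROI("shaft", "shaft", layout.shaft, cell_id="c")]
        rois += [
            CompartmentROI(sid, "spine", poly, cell_id="c", paired_shaft_id="shaft")
            for sid, poly in layout.spines.items()
        ]
        assigns = assign_trajectories(res.trajectories, rois)
        rep = compartment_report(
            assigns, res.trajectories, rois, dt=DT, min_trajectories_cell=50
        )
        per = rep["per_compartment"].set_index("compartment")
        roi_tab = rep["per_roi"].dropna(subset=["d_eff"])
        spine_d = roi_tab.loc[roi_tab["label"] == "spine", "d_eff"]
        shaft_d = roi_tab.loc[roi_tab["label"] == "shaft", "d_eff"]
        if len(spine_d) and len(shaft_d) and spine_d.mean() < shaft_d.mean():
            ok_deff += 1
        if per.loc["spine", "immobile_fraction"] > per.loc["shaft", "immobile_fraction"]:
            ok_imm += 1

    # the D_eff floor: 49 tracks -> no value, 50 -> value
    rng = np.random.default_rng(seed)
    tracks = []
    for i in range(50):
        steps = rng.normal(0, np.sqrt(2 * 0.05 * DT), (14, 2))
        xy = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
        tracks.append(Trajectory(i, "c", np.arange(15), xy))
    floor_ok = (
        effective_diffusion(tracks[:49], dt=DT) is None
        and effective_diffusion(tracks, dt=DT) is not None
    )
    return {
        "deff_ordering_fraction": ok_deff / n_replicates,
        "immobile_ordering_fraction": ok_imm / n_replicates,
        "floor_excludes_under_50": bool(floor_ok),
        "n_replicates": n_replicates,
    }


# ------------------------------------------------------------------ statistics calibration

def stats_type_i_calibration(seed: int, n_replicates: int = 1000, n_per_group: int = 15) -> dict:
    """Rejection rate of the routed two-group test under identical normal
    distributions (nominal level 0.05)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(0.0, 1.0, n_per_group)
        res = run_test([a, b], select_test([a, b]))
        rejections += res.p_value < 0.05
    return {
        "rejection_rate": rejections / n_replicates,
        "nominal": 0.05,
        "n_replicates": n_replicates,
    }
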