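"""Synthetic sptPALM data generator with ground truth.

Emulates stochastic photoconversion single-molecule acquisitions: molecules
appear at random frames, diffuse in one of three mobility states (immobile,
confined, free — a static mixture, no switching by default), are bounded by
their compartment polygon (specular reflection) and, for the confined state,
by a trapping nanodomain disc (radial reflection).  Photobleaching limits
track length (geometric law); an isotropic Gaussian localization error is
added to every reported position.  Every output carries a per-molecule
ground-truth record so each downstream estimator can be tested by parameter
recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .geometry import (
    CompartmentLayout,
    build_default_layout,
    sample_points_in_polygon,
)
from . import io as spio


class EmptySimulationError(RuntimeError):
    """No trajectory survived the minimum-length filter."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror the acquisition regime being emulated.

    Units: ``frame_interval`` seconds, diffusion coefficients μm²/s,
    ``nanodomain_diameter_mean`` and ``localization_sigma`` nanometres
    (converted to μm internally), track lengths in frames.
    """

    frame_interval: float = 0.02
    n_frames: int = 16000
    state_diffusion: tuple = (0.003, 0.03, 0.3)
    state_occupancy: tuple = (0.3, 0.3, 0.4)
    nanodomain_diameter_mean: float = 170.0
    nanodomains_per_spine: int = 1
    localization_sigma: float = 25.0
    mean_track_length: float = 15.0
    min_track_length: int = 8
    n_molecules: int = 2000
    seed: int = 0
    geometry: CompartmentLayout | None = None
    spine_fraction: float | None = None  # None -> area-weighted compartment choice
    spine_occupancy: tuple | None = None  # override occupancies for spine molecules

    def __post_init__(self):
        occ = np.asarray(self.state_occupancy, dtype=float)
        if occ.shape != (3,) or np.any(occ < 0) or np.any(occ > 1):
            raise ValueError("state_occupancy must be three probabilities")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError(f"state_occupancy must sum to 1, got {occ.sum()!r}")
        D = np.asarray(self.state_diffusion, dtype=float)
        if D.shape != (3,) or np.any(D <= 0) or np.any(np.diff(D) <= 0):
            raise ValueError("state_diffusion must be strictly positive and increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.spine_occupancy is not None:
            so = np.asarray(self.spine_occupancy, dtype=float)
            if so.shape != (3,) or abs(so.sum() - 1.0) > 1e-9:
                raise ValueError("spine_occupancy must be three probabilities summing to 1")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")

    def resolved_geometry(self) -> CompartmentLayout:
        if self.geometry is not None:
            return self.geometry
        return build_default_layout(
            0, seed=self.seed, nanodomain_diameter=self.nanodomain_diameter_mean / 1000.0
        )


@dataclass
class SimulationResult:
    localizations: pd.DataFrame  # cell_id, track_id, frame, x_um, y_um
    trajectories: list  # list[Trajectory]
    ground_truth: pd.DataFrame  # track_id, true_state, nanodomain_id, compartment_id


# ---------------------------------------------------------------- reflection

def _polygon_edges(poly: Polygon) -> np.ndarray:
    c = np.asarray(poly.exterior.coords)
    return np.stack([c[:-1], c[1:]], axis=1)  # (E, 2, 2)


def _reflect_in_polygon(poly: Polygon, edges: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                        max_bounce: int = 16) -> np.ndarray:
    """Specular reflection of the step p0→p1 off the polygon boundary.

    Iterates over bounces; if the step cannot be resolved (pathologically long
    jump or numerical corner case) the molecule stays at its last valid
    position — a rare, conservative fallback.
    """
    a = edges[:, 0]
    ab = edges[:, 1] - edges[:, 0]
    origin = p0.copy()  # strictly interior; every failure path falls back here
    last_edge = -1
    for _ in range(max_bounce):
        if shapely.contains_xy(poly, p1[0], p1[1]):
            return p1
        d = p1 - p0
        denom = ab[:, 0] * d[1] - ab[:, 1] * d[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            ap = p0 - a
            t = (ab[:, 0] * ap[:, 1] - ab[:, 1] * ap[:, 0]) / denom
            s = (d[0] * ap[:, 1] - d[1] * ap[:, 0]) / denom
        ok = (denom != 0) & (t > 1e-12) & (t <= 1.0) & (s >= 0.0) & (s <= 1.0)
        if last_edge >= 0:
            ok[last_edge] = False
        if not np.any(ok):
            return origin
        idx = np.nonzero(ok)[0]
        hit_edge = idx[np.argmin(t[idx])]
        th = t[hit_edge]
        hit = p0 + th * d
        rem = (1.0 - th) * d
        e = ab[hit_edge]
        e = e / np.hypot(e[0], e[1])
        rem_ref = 2.0 * (rem @ e) * e - rem
        p0, p1 = hit, hit + rem_ref
        last_edge = hit_edge
    return origin


# ---------------------------------------------------------------- simulation

def simulate_cell(config: SimulationConfig, cell_id: str = "cell0") -> SimulationResult:
    """Simulate one cell's localization table, trajectories, and ground truth.

    Each molecule draws a state from the occupancy vector (no switching), a
    home compartment, a start frame uniform over the acquisition, and a
    geometric track length.  Confined (state-2) molecules start inside a
    nanodomain disc of their compartment and reflect radially at its rim; in
    compartments with no disc they diffuse freely at D2 (recorded with
    nanodomain_id = -1).  All molecules reflect specularly at their
    compartment boundary.  Reported positions carry independent Gaussian
    localization error; tracks shorter than ``min_track_length`` localizations
    are discarded.
    """
    from .trajectories import Trajectory

    rng = np.random.default_rng(config.seed)
    layout = config.resolved_geometry()
    dt = config.frame_interval
    D = np.asarray(config.state_diffusion, dtype=float)
    sigma_um = config.localization_sigma / 1000.0
    n = config.n_molecules

    comp_ids = layout.compartment_ids
    spine_ids = [c for c in comp_ids if c != "shaft"]
    areas = np.array([layout.compartment(c).area for c in comp_ids])
    if config.spine_fraction is not None and spine_ids:
        p_shaft = 1.0 - config.spine_fraction
        spine_areas = areas[1:] / areas[1:].sum()
        probs = np.concatenate([[p_shaft], config.spine_fraction * spine_areas])
    else:
        probs = areas / areas.sum()
    comp_choice = rng.choice(len(comp_ids), size=n, p=probs)

    occ = np.asarray(config.state_occupancy, dtype=float)
    states = np.empty(n, dtype=np.int64)
    for i in range(n):
        cid = comp_ids[comp_choice[i]]
        o = occ
        if config.spine_occupancy is not None and cid != "shaft":
            o = np.asarray(config.spine_occupancy, dtype=float)
        states[i] = rng.choice(3, p=o) + 1  # 1-based state index

    start_frames = rng.integers(0, config.n_frames, size=n)
    # geometric(p) on {1, 2, ...} with mean 1/p = mean_track_length
    lengths = rng.geometric(1.0 / config.mean_track_length, size=n)
    lengths = np.minimum(lengths, config.n_frames - start_frames)

    edges_cache = {c: _polygon_edges(layout.compartment(c)) for c in comp_ids}
    domain_lists = {c: layout.domains_in(c) for c in comp_ids}

    loc_rows: list[pd.DataFrame] = []
    gt_rows = []
    trajs = []
    track_counter = 0
    for i in range(n):
        L = int(lengths[i])
        if L < config.min_track_length:
            continue
        cid = comp_ids[comp_choice[i]]
        poly = layout.compartment(cid)
        state = int(states[i])
        Ds = D[state - 1]
        step_sd = np.sqrt(2.0 * Ds * dt)
        steps = rng.normal(0.0, step_sd, size=(L - 1, 2))

        nd_id = -1
        if state == 2 and domain_lists[cid]:
            k = rng.integers(len(domain_lists[cid]))
            nd = domain_lists[cid][k]
            nd_id = layout.nanodomains.index(nd)
            centre = np.array([nd.x, nd.y])
            # uniform start in the disc
            u, th = rng.uniform(0, 1), rng.uniform(0, 2 * np.pi)
            start = centre + nd.radius * np.sqrt(u) * np.array([np.cos(th), np.sin(th)])
            pos = np.empty((L, 2))
            pos[0] = start
            rel = start - centre
            for t in range(1, L):
                rel = rel + steps[t - 1]
                r = np.hypot(rel[0], rel[1])
                while r > nd.radius:
                    rel = rel * (2.0 * nd.radius - r) / r
                    r = abs(2.0 * nd.radius - r)
                pos[t] = centre + rel
        else:
            start = sample_points_in_polygon(poly, 1, rng)[0]
            cand = start + np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
            inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
            if inside.all():
                pos = cand
            else:
                pos = np.empty((L, 2))
                pos[0] = start
                edges = edges_cache[cid]
                for t in range(1, L):
                    p1 = pos[t - 1] + steps[t - 1]
                    if shapely.contains_xy(poly, p1[0], p1[1]):
                        pos[t] = p1
                    else:
                        cand = _reflect_in_polygon(poly, edges, pos[t - 1].copy(), p1)
                        if shapely.contains_xy(poly, cand[0], cand[1]):
                            pos[t] = cand
                        else:  # unresolved corner case: stay in place
                            pos[t] = pos[t - 1]

        obs = pos + rng.normal(0.0, sigma_um, size=pos.shape) if sigma_um > 0 else pos
        frames = np.arange(start_frames[i], start_frames[i] + L, dtype=np.int64)
        tid = track_counter
        track_counter += 1
        loc_rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "track_id": tid,
                    "frame": frames,
                    "x_um": obs[:, 0],
                    "y_um": obs[:, 1],
                }
            )
        )
        gt_rows.append(
            {
                "track_id": tid,
                "true_state": state,
                "nanodomain_id": nd_id,
                "compartment_id": cid,
            }
        )
        trajs.append(Trajectory(track_id=tid, cell_id=cell_id, frames=frames, xy=obs))

    if not loc_rows:
        raise EmptySimulationError(
            "no trajectory survived the minimum-length filter "
            f"(min_track_length={config.min_track_length}, "
            f"mean_track_length={config.mean_track_length})"
        )
    table = pd.concat(loc_rows, ignore_index=True)
    ground_truth = pd.DataFrame(gt_rows)
    return SimulationResult(localizations=table, trajectories=trajs, ground_truth=ground_truth)


# ---------------------------------------------------------------- point fields

def uniform_point_field(
    n: int, width: float, height: float, seed: int = 0, origin: tuple = (0.0, 0.0)
) -> np.ndarray:
    """Complete-spatial-randomness control field: n uniform points in a rectangle."""
    rng = np.random.default_rng(seed)
    return np.column_stack(
        [rng.uniform(origin[0], origin[0] + width, n), rng.uniform(origin[1], origin[1] + height, n)]
    )


def planted_cluster_field(
    n_background: int,
    width: float,
    height: float,
    cluster_centres: list,
    cluster_sizes: list,
    cluster_diameter_um: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform background plus uniform-disc clusters; returns (points, labels).

    Labels: -1 for background, cluster index for planted points.  Used to test
    tessellation-based cluster detection by planted-cluster recovery.
    """
    rng = np.random.default_rng(seed)
    pts = [
        np.column_stack([rng.uniform(0, width, n_background), rng.uniform(0, height, n_background)])
    ]
    labels = [np.full(n_background, -1, dtype=np.int64)]
    r = cluster_diameter_um / 2.0
    for ci, ((cx, cy), m) in enumerate(zip(cluster_centres, cluster_sizes)):
        u = rng.uniform(0, 1, m)
        th = rng.uniform(0, 2 * np.pi, m)
        pts.append(np.column_stack([cx + r * np.sqrt(u) * np.cos(th), cy + r * np.sqrt(u) * np.sin(th)]))
        labels.append(np.full(m, ci, dtype=np.int64))
    return np.concatenate(pts), np.concatenate(labels)


# ---------------------------------------------------------------- fixture suite

FIXTURE_CONFIGS = {
    "single_state_free": dict(
        state_occupancy=(0.0, 0.0, 1.0),
        localization_sigma=0.0,
        n_molecules=600,
        seed_offset=1,
    ),
    "three_state": dict(
        n_molecules=800,
        seed_offset=2,
    ),
    "spine_rich": dict(
        n_molecules=800,
        spine_fraction=0.4,
        spine_occupancy=(0.45, 0.45, 0.10),
        seed_offset=3,
        n_spines=6,
    ),
    "immobile_mixture": dict(
        state_occupancy=(0.5, 0.0, 0.5),
        state_diffusion=(0.003, 0.03, 0.3),
        localization_sigma=0.0,
        n_molecules=800,
        seed_offset=4,
    ),
}


def write_fixture_suite(output_dir: str | Path, seed: int = 12345) -> dict:
    """Write the canonical seeded fixture datasets with ground-truth sidecars.

    Emits, per dataset: ``<name>.csv`` (localizations), ``<name>.truth.csv``,
    ``<name>.layout.json``, plus a ``manifest.json`` recording the generating
    parameters.  Deterministic: re-running with the same seed reproduces
    byte-identical files.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "datasets": {}}
    for name, spec in FIXTURE_CONFIGS.items():
        spec = dict(spec)
        n_spines = spec.pop("n_spines", 0)
        seed_offset = spec.pop("seed_offset")
        ds_seed = seed + seed_offset
        layout = build_default_layout(n_spines, seed=ds_seed)
        cfg = SimulationConfig(geometry=layout, seed=ds_seed, **spec)
        result = simulate_cell(cfg, cell_id=name)
        loc_path = outdir / f"{name}.csv"
        truth_path = outdir / f"{name}.truth.csv"
        layout_path = outdir / f"{name}.layout.json"
        spio.write_localization_table(result.localizations, loc_path)
        spio.write_ground_truth(result.ground_truth, truth_path)
        layout.to_json(layout_path, cell_id=name)
        manifest["datasets"][name] = {
            "localizations": loc_path.name,
            "ground_truth": truth_path.name,
            "layout": layout_path.name,
            "n_spines": n_spines,
            "seed": ds_seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in spec.items()
            },
            "n_tracks": int(result.ground_truth.shape[0]),
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
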