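"""Per-trajectory and per-cell mean-square-displacement (MSD) analysis.

For a 2D trajectory sampled at interval ``dt`` the time-averaged MSD at lag
``k·dt`` is the mean squared Euclidean displacement over all frame pairs
``(i, i+k)`` present in the track.  Free Brownian motion gives
``MSD(t) = a + 4·D·t``, where ``D`` is the diffusion coefficient and the
intercept ``a`` absorbs static localization error.  A trajectory is called
*immobile* when ``log10(D)`` falls at or below a fixed threshold (default
−1.6, i.e. D ≤ 0.025 μm²/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DT = 0.02  # seconds; 50 Hz acquisition
DEFAULT_D_FLOOR = 1e-5  # μm²/s; floor applied to noise-driven non-positive slopes
IMMOBILE_THRESHOLD_LOG10 = -1.6


@dataclass(frozen=True)
class Trajectory:
    """One tracked molecule: strictly increasing frame indices and (x, y) in μm."""

    track_id: object
    cell_id: object
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.int64)
        xy = np.asarray(self.xy, dtype=float)
        if frames.ndim != 1 or xy.shape != (frames.size, 2):
            raise ValueError("frames must be 1D and xy must be (n, 2)")
        if frames.size < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if not np.all(np.diff(frames) > 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")
        if not np.all(np.isfinite(xy)):
            raise ValueError(f"track {self.track_id}: non-finite coordinates")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)

    @property
    def n_points(self) -> int:
        return self.frames.size

    @property
    def span(self) -> int:
        """Number of frame intervals covered (last frame minus first)."""
        return int(self.frames[-1] - self.frames[0])


def trajectories_from_table(df: pd.DataFrame) -> list[Trajectory]:
    """Group a localization table into Trajectory objects (tracks with ≥2 points)."""
    out = []
    for (cell_id, track_id), grp in df.groupby(["cell_id", "track_id"], sort=True):
        if len(grp) < 2:
            continue
        out.append(
            Trajectory(
                track_id=track_id,
                cell_id=cell_id,
                frames=grp["frame"].to_numpy(),
                xy=grp[["x_um", "y_um"]].to_numpy(),
            )
        )
    return out


@dataclass(frozen=True)
class MSDProfile:
    """Time-averaged MSD curve: lags (frame units), lag times (s), MSD (μm²)."""

    lags: np.ndarray
    lag_times: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        if np.any(self.msd < 0):
            raise ValueError("negative MSD")
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times not strictly increasing")


def compute_msd(traj: Trajectory, max_lag: int | None = None, dt: float = DEFAULT_DT) -> MSDProfile:
    """Time-averaged MSD over all frame pairs ``(i, i+k)`` present in the track.

    Frame gaps are tolerated: every available pair at each lag contributes.
    Lags with zero pairs are omitted; ``max_lag`` beyond the track span simply
    truncates.
    """
    if max_lag is None:
        max_lag = traj.span
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    frames, xy = traj.frames, traj.xy
    lags, msds, counts = [], [], []
    for k in range(1, min(max_lag, traj.span) + 1):
        target = frames + k
        idx = np.searchsorted(frames, target)
        ok = idx < frames.size
        ok[ok] &= frames[idx[ok]] == target[ok]
        n = int(ok.sum())
        if n == 0:
            continue
        d = xy[idx[ok]] - xy[ok]
        lags.append(k)
        msds.append(float(np.mean(np.einsum("ij,ij->i", d, d))))
        counts.append(n)
    return MSDProfile(
        lags=np.array(lags, dtype=np.int64),
        lag_times=np.array(lags, dtype=float) * dt,
        msd=np.array(msds, dtype=float),
        n_pairs=np.array(counts, dtype=np.int64),
    )


@dataclass(frozen=True)
class DiffusionFit:
    """Linear MSD fit ``MSD(t) = a + 4·D·t`` over the first few lags."""

    D: float
    intercept: float
    n_points_fit: int
    floored: bool = False
    d_floor: float = DEFAULT_D_FLOOR


def fit_diffusion(
    profile: MSDProfile, n_points: int = 4, d_floor: float = DEFAULT_D_FLOOR
) -> DiffusionFit | None:
    """Ordinary least squares on the first ``n_points`` (lag time, MSD) pairs.

    D is the slope divided by 4; non-positive or sub-floor slopes are floored
    at ``d_floor`` and flagged.  Returns None (no-fit signal) when fewer than
    two lags are available.
    """
    n = min(n_points, profile.lags.size)
    if n < 2:
        return None
    t, y = profile.lag_times[:n], profile.msd[:n]
    slope, intercept = np.polyfit(t, y, 1)
    D = slope / 4.0
    floored = D < d_floor
    if floored:
        D = d_floor
    return DiffusionFit(D=float(D), intercept=float(intercept), n_points_fit=n, floored=bool(floored), d_floor=d_floor)


def classify_mobility(fit: DiffusionFit, threshold_log10: float = IMMOBILE_THRESHOLD_LOG10) -> str:
    """'immobile' iff log10(D) ≤ threshold (boundary value counts as immobile)."""
    if fit.D <= 0:
        raise ValueError("classify_mobility requires a positive (post-floor) D")
    return "immobile" if np.log10(fit.D) <= threshold_log10 else "mobile"


@dataclass
class CellMobilitySummary:
    """Per-cell mobility summary: mean MSD curve, AUC, log10-D histogram, immobile fraction."""

    cell_id: object
    mean_msd: MSDProfile | None
    auc: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    immobile_fraction: float
    n_trajectories: int
    below_min_trajectories: bool
    track_table: pd.DataFrame = field(repr=False, default=None)


DEFAULT_HIST_EDGES = np.round(np.arange(-5.0, 1.2001, 0.2), 10)


def summarize_cell(
    trajectories: list[Trajectory],
    dt: float = DEFAULT_DT,
    min_track_frames: int = 8,
    min_trajectories: int = 1000,
    auc_max_lag: int = 12,
    n_fit_points: int = 4,
    threshold_log10: float = IMMOBILE_THRESHOLD_LOG10,
    d_floor: float = DEFAULT_D_FLOOR,
    hist_edges: np.ndarray = DEFAULT_HIST_EDGES,
) -> CellMobilitySummary | None:
    """Aggregate per-trajectory MSD analysis for one cell.

    Tracks shorter than ``min_track_frames`` localizations are filtered out.
    The mean MSD curve is the lag-wise mean over tracks possessing that lag,
    reported up to ``auc_max_lag``; the AUC is the trapezoidal area under it
    over the lag window (default lags 1–12, i.e. 0.02–0.24 s at 50 Hz).
    Cells under ``min_trajectories`` are flagged, not silently dropped.
    Returns None for empty input (explicit empty-summary signal).
    """
    cell_ids = {t.cell_id for t in trajectories}
    if len(cell_ids) > 1:
        raise ValueError(f"summarize_cell got multiple cell ids: {cell_ids}")
    kept = [t for t in trajectories if t.n_points >= min_track_frames]
    if not kept:
        return None
    cell_id = kept[0].cell_id

    profiles = [compute_msd(t, max_lag=auc_max_lag, dt=dt) for t in kept]
    # lag-wise mean over tracks that possess each lag
    sums = np.zeros(auc_max_lag)
    ns = np.zeros(auc_max_lag, dtype=np.int64)
    for p in profiles:
        sums[p.lags - 1] += p.msd
        ns[p.lags - 1] += 1
    have = ns > 0
    mean_curve = None
    auc = 0.0
    if have.any():
        lags = np.nonzero(have)[0] + 1
        mean_curve = MSDProfile(
            lags=lags,
            lag_times=lags * dt,
            msd=sums[have] / ns[have],
            n_pairs=ns[have],
        )
        if lags.size >= 2:
            auc = float(np.trapezoid(mean_curve.msd, mean_curve.lag_times))

    rows = []
    for t, p in zip(kept, profiles):
        fit = fit_diffusion(p, n_points=n_fit_points, d_floor=d_floor)
        if fit is None:
            continue
        rows.append(
            {
                "track_id": t.track_id,
                "D": fit.D,
                "intercept": fit.intercept,
                "floored": fit.floored,
                "mobility": classify_mobility(fit, threshold_log10),
                "n_points": t.n_points,
            }
        )
    track_table = pd.DataFrame(rows)
    n_traj = len(track_table)
    if n_traj == 0:
        return None
    log_d = np.log10(track_table["D"].to_numpy())
    counts, _ = np.histogram(np.clip(log_d, hist_edges[0], hist_edges[-1]), bins=hist_edges)
    immobile_fraction = float((track_table["mobility"] == "immobile").mean())
    return CellMobilitySummary(
        cell_id=cell_id,
        mean_msd=mean_curve,
        auc=auc,
        hist_counts=counts,
        hist_edges=np.asarray(hist_edges),
        immobile_fraction=immobile_fraction,
        n_trajectories=n_traj,
        below_min_trajectories=n_traj < min_trajectories,
        track_table=track_table,
    )


def mean_msd_profile(trajectories: list[Trajectory], max_lag: int = 12, dt: float = DEFAULT_DT) -> MSDProfile | None:
    """Lag-wise mean MSD over a set of trajectories (tracks contribute the lags they have)."""
    sums = np.zeros(max_lag)
    ns = np.zeros(max_lag, dtype=np.int64)
    for t in trajectories:
        p = compute_msd(t, max_lag=max_lag, dt=dt)
        sums[p.lags - 1] += p.msd
        ns[p.lags - 1] += 1
    have = ns > 0
    if not have.any():
        return None
    lags = np.nonzero(have)[0] + 1
    return MSDProfile(lags=lags, lag_times=lags * dt, msd=sums[have] / ns[have], n_pairs=ns[have])


def effective_diffusion(
    trajectories: list[Trajectory],
    dt: float = DEFAULT_DT,
    min_trajectories: int = 50,
    n_fit_points: int = 4,
    max_lag: int = 12,
    d_floor: float = DEFAULT_D_FLOOR,
) -> DiffusionFit | None:
    """ROI-level effective diffusion coefficient D_eff.

    The member trajectories' MSD curves are averaged lag-wise and the linear
    MSD model is fitted to the ensemble curve.  Returns None (no-value
    signal) when the ROI holds fewer than ``min_trajectories`` tracks —
    under-populated spines/shaft segments are excluded, not estimated.
    """
    if len(trajectories) < min_trajectories:
        return None
    profile = mean_msd_profile(trajectories, max_lag=max_lag, dt=dt)
    if profile is None:
        return None
    return fit_diffusion(profile, n_points=n_fit_points, d_floor=d_floor)
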