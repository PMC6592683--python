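"""Motion-type classification and multi-state displacement-distribution inference.

Two complementary views of single-molecule kinetics:

*Moment scaling spectrum (MSS).*  For a trajectory, the ν-th displacement
moment μ_ν(kΔt) = ⟨|Δr|^ν⟩ scales as a power law in the lag; the scaling
exponents γ_ν grow linearly in ν, and the slope of γ_ν versus ν (``s_mss``)
classifies whole-trajectory motion: ≈0 immobile, between 0 and 0.5 confined,
≈0.5 free diffusion, approaching 1 directed transport.

*Three-state displacement CDF.*  Pooled single-frame displacement magnitudes
of a cell follow, under a static three-state mixture of diffusers, the model

    C(r, Δt) = 1 − f1·exp(−r²/4D1Δt) − f2·exp(−r²/4D2Δt) − f3·exp(−r²/4D3Δt)

with state occupancies f_i on the simplex and apparent diffusion coefficients
D1 < D2 < D3.  The *global fit* shares D1..D3 across all cells of a condition
while letting each cell keep its own occupancy vector, which stabilizes the
estimates when individual cells contribute modest displacement counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .trajectories import DEFAULT_DT, Trajectory

MSS_MIN_FRAMES = 20


@dataclass(frozen=True)
class MSSResult:
    track_id: object
    moment_orders: np.ndarray
    scaling_exponents: np.ndarray  # gamma_nu, gamma_0 = 0 by construction
    s_mss: float


def compute_mss(
    traj: Trajectory,
    nu_max: int = 6,
    n_lag_fit: int = 5,
    dt: float = DEFAULT_DT,
    min_frames: int = MSS_MIN_FRAMES,
) -> MSSResult | None:
    """Moment scaling spectrum slope of one trajectory.

    Requires at least ``min_frames`` localizations (default 20).  For each
    order ν in 0..nu_max, γ_ν is the log-log OLS slope of the time-averaged
    moment μ_ν over the first ``n_lag_fit`` lags; ``s_mss`` is the
    through-origin OLS slope of γ_ν against ν, clipped to [0, 1].  Returns
    None when the track is too short or a fitted lag has zero displacement
    (log undefined).
    """
    if traj.n_points < min_frames:
        return None
    frames, xy = traj.frames, traj.xy
    orders = np.arange(0, nu_max + 1)
    log_lags = []
    log_moments = []  # rows: lags, cols: orders 1..nu_max
    for k in range(1, n_lag_fit + 1):
        target = frames + k
        idx = np.searchsorted(frames, target)
        ok = idx < frames.size
        ok[ok] &= frames[idx[ok]] == target[ok]
        if not ok.any():
            continue
        d = xy[idx[ok]] - xy[ok]
        mag = np.hypot(d[:, 0], d[:, 1])
        mom = np.array([np.mean(mag**nu) for nu in orders[1:]])
        if np.any(mom <= 0):
            return None
        log_lags.append(np.log(k * dt))
        log_moments.append(np.log(mom))
    if len(log_lags) < 2:
        return None
    log_lags = np.asarray(log_lags)
    M = np.asarray(log_moments)  # (n_lags, nu_max)
    x = log_lags - log_lags.mean()
    gammas = x @ (M - M.mean(axis=0)) / (x @ x)
    gamma_full = np.concatenate([[0.0], gammas])
    # through-origin OLS of gamma vs order (gamma_0 = 0 anchors the line)
    s = float(orders @ gamma_full / (orders @ orders))
    return MSSResult(
        track_id=traj.track_id,
        moment_orders=orders,
        scaling_exponents=gamma_full,
        s_mss=float(np.clip(s, 0.0, 1.0)),
    )


def mss_table(trajectories: list[Trajectory], **kwargs) -> pd.DataFrame:
    """Per-track s_mss for all qualifying trajectories (≥20 frames)."""
    rows = []
    for t in trajectories:
        res = compute_mss(t, **kwargs)
        if res is not None:
            rows.append({"track_id": res.track_id, "cell_id": t.cell_id, "s_mss": res.s_mss})
    return pd.DataFrame(rows, columns=["track_id", "cell_id", "s_mss"])


# ------------------------------------------------------------- displacements

@dataclass(frozen=True)
class DisplacementSample:
    """Pooled single-frame displacement magnitudes of one cell (≤7 per track)."""

    cell_id: object
    displacements: np.ndarray
    n_tracks: int

    def __post_init__(self):
        if np.any(self.displacements < 0):
            raise ValueError("displacements must be non-negative")


def collect_displacements(
    trajectories: list[Trajectory],
    cell_id: object,
    max_per_track: int = 7,
    min_track_frames: int = 8,
) -> DisplacementSample:
    """First ``max_per_track`` single-frame displacement magnitudes per track.

    Only consecutive-frame pairs count; frame gaps truncate a track's
    contribution.  Capping at the first seven steps removes the long-track
    bias that plain pooling would introduce.
    """
    disps = []
    n_tracks = 0
    for t in trajectories:
        if t.cell_id != cell_id:
            raise ValueError(f"track {t.track_id} belongs to {t.cell_id}, not {cell_id}")
        if t.n_points < min_track_frames:
            continue
        consecutive = np.diff(t.frames) == 1
        stop = consecutive.size if consecutive.all() else int(np.argmin(consecutive))
        steps = t.xy[1 : stop + 1] - t.xy[:stop]
        if steps.size:
            d = np.hypot(steps[:, 0], steps[:, 1])
            disps.append(d[:max_per_track])
            n_tracks += 1
    pooled = np.concatenate(disps) if disps else np.empty(0)
    return DisplacementSample(cell_id=cell_id, displacements=pooled, n_tracks=n_tracks)


def ecdf(sample: DisplacementSample) -> tuple[np.ndarray, np.ndarray] | None:
    """Empirical CDF of the sample: sorted values and F = i/n (right-continuous)."""
    r = np.sort(sample.displacements)
    if r.size == 0:
        return None
    return r, np.arange(1, r.size + 1) / r.size


def three_state_cdf(r, dt, D, f):
    """Mixture displacement CDF: 1 − Σ f_i exp(−r²/(4 D_i Δt))."""
    r = np.asarray(r, dtype=float)
    D = np.asarray(D, dtype=float)
    f = np.asarray(f, dtype=float)
    return 1.0 - np.sum(
        f[:, None] * np.exp(-(r[None, :] ** 2) / (4.0 * D[:, None] * dt)), axis=0
    )


@dataclass
class ThreeStateModel:
    """Global three-state fit: shared D1<D2<D3 plus per-cell occupancies."""

    D: np.ndarray  # (3,) increasing
    occupancies: pd.DataFrame  # index cell_id, columns f1 f2 f3
    dt: float
    residual_norm: float
    n_starts: int
    converged: bool
    degenerate: bool
    start_costs: list = field(default_factory=list)

    def cdf(self, r, cell_id):
        f = self.occupancies.loc[cell_id].to_numpy()
        return three_state_cdf(r, self.dt, self.D, f)

    def to_json_dict(self) -> dict:
        return {
            "D_um2_per_s": [float(d) for d in self.D],
            "dt_s": self.dt,
            "occupancies": {
                str(idx): [float(v) for v in row]
                for idx, row in self.occupancies.iterrows()
            },
            "residual_norm": self.residual_norm,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


def _softmax3(a, b):
    z = np.stack([np.zeros_like(a), a, b])
    z = np.exp(z - z.max(axis=0))
    return z / z.sum(axis=0)


def _eval_grid(sample: DisplacementSample, max_points: int):
    """ECDF evaluated at jump midpoints, uniformly subsampled to ≤max_points."""
    r = np.sort(sample.displacements)
    n = r.size
    # midpoint between consecutive order statistics; F there is i/n
    mids = 0.5 * (r[:-1] + r[1:])
    F = np.arange(1, n) / n
    keep = mids > 0
    mids, F = mids[keep], F[keep]
    if mids.size > max_points:
        sel = np.linspace(0, mids.size - 1, max_points).round().astype(int)
        mids, F = mids[sel], F[sel]
    return mids, F


class FitError(RuntimeError):
    pass


def fit_three_state_global(
    samples: list[DisplacementSample],
    dt: float = DEFAULT_DT,
    n_starts: int = 10,
    seed: int | None = 0,
    max_eval_points: int = 500,
    min_displacements: int = 100,
    d_start_range: tuple = (1e-3, 1.0),
) -> ThreeStateModel:
    """Global least-squares fit of the three-state displacement-CDF model.

    Minimizes the summed squared deviation between each cell's empirical CDF
    (at its jump midpoints, ≤``max_eval_points`` per cell) and the mixture
    model, sharing D1..D3 across cells with per-cell occupancies.  The D
    ordering is enforced by a log-increment parameterization and the simplex
    constraint by a softmax transform, so the invariants hold by
    construction.  Best of ``n_starts`` seeded multistarts (log-uniform D
    initializations) wins; a fit where two D's collapse within 1% is flagged
    ``degenerate``.
    """
    if not samples:
        raise ValueError("need at least one cell sample")
    small = [s.cell_id for s in samples if s.displacements.size < min_displacements]
    if small:
        import warnings

        warnings.warn(
            f"cells below the {min_displacements}-displacement soft floor: {small}"
        )
    grids = [_eval_grid(s, max_eval_points) for s in samples]
    cell_ids = [s.cell_id for s in samples]
    n_cells = len(samples)
    rng = np.random.default_rng(seed)

    def unpack(theta):
        incs = np.exp(theta[:3])
        D = np.cumsum(incs)
        occ = _softmax3(theta[3 : 3 + n_cells], theta[3 + n_cells :]).T  # (n_cells, 3)
        return D, occ

    def residuals(theta):
        D, occ = unpack(theta)
        out = []
        for (r, F), f in zip(grids, occ):
            out.append(three_state_cdf(r, dt, D, f) - F)
        return np.concatenate(out)

    lo, hi = d_start_range
    best = None
    start_costs = []
    any_converged = False
    for s_i in range(n_starts):
        if s_i == 0:
            D0 = np.array([1e-3, 1e-2, 1e-1])  # canonical decade-spaced start
        else:
            D0 = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), 3)))
            # keep increments strictly positive
            D0 += np.arange(3) * 1e-6
        theta0 = np.concatenate(
            [np.log(np.diff(np.concatenate([[0.0], D0]))), np.zeros(2 * n_cells)]
        )
        res = least_squares(residuals, theta0, method="trf", xtol=1e-12, ftol=1e-12)
        start_costs.append(float(res.cost))
        any_converged = any_converged or res.status > 0
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not any_converged:
        raise FitError(f"no multistart converged; per-start costs: {start_costs}")
    D, occ = unpack(best.x)
    degenerate = bool(np.any(D[1:] / D[:-1] < 1.01))
    occ_df = pd.DataFrame(occ, index=cell_ids, columns=["f1", "f2", "f3"])
    # defensive renormalization (softmax already sums to 1 to machine precision)
    occ_df = occ_df.div(occ_df.sum(axis=1), axis=0)
    return ThreeStateModel(
        D=D,
        occupancies=occ_df,
        dt=dt,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_starts=n_starts,
        converged=bool(any_converged),
        degenerate=degenerate,
        start_costs=start_costs,
    )


def compare_occupancies(
    model_a: ThreeStateModel,
    model_b: ThreeStateModel,
    paired: bool = False,
    labels: tuple = ("A", "B"),
) -> pd.DataFrame:
    """Per-state comparison of per-cell occupancies between two fitted models.

    Returns one row per state with group means, the mean difference (B − A),
    its sign, and the p value from the statistics layer's test-selection rule
    (paired tests require matching cell sets).
    """
    from .stats import select_test, run_test

    rows = []
    for state in ("f1", "f2", "f3"):
        a = model_a.occupancies[state].to_numpy()
        b = model_b.occupancies[state].to_numpy()
        if paired:
            if list(model_a.occupancies.index) != list(model_b.occupancies.index):
                raise ValueError("paired comparison requires identical cell ids in order")
        diff = b.mean() - a.mean()
        desc = select_test([a, b], paired=paired)
        result = run_test([a, b], desc) if desc is not None else None
        rows.append(
            {
                "state": state,
                f"mean_{labels[0]}": a.mean(),
                f"mean_{labels[1]}": b.mean(),
                "difference": diff,
                "direction": "0" if abs(diff) < 1e-12 else ("+" if diff > 0 else "-"),
                "test": desc.name if desc is not None else "none",
                "p_value": result.p_value if result is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
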