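# sptnano

Analysis of single-particle-tracking PALM (sptPALM) recordings of membrane
proteins in neuronal dendrites: per-trajectory diffusion, motion-state
classification, multi-state displacement-distribution inference, and
Voronoï-tessellation nanodomain detection, resolved by dendritic
spine/shaft compartment. A ground-truth-labelled synthetic trajectory
generator makes every stage verifiable by parameter recovery, so the whole
pipeline can be exercised and validated without any raw microscopy data.

Intended users: quantitative microscopists and computational neurobiologists
analysing tracker output (localization tables) from live-cell
single-molecule experiments — e.g. studying how a kinase such as Fyn is
trapped in dendritic spine nanodomains.

## What it computes

**MSD and diffusion.** For each trajectory (≥ 8 frames at Δt = 20 ms) the
time-averaged mean square displacement is fitted over its first four lag
points by

    MSD(t) = a + 4·D·t

giving the apparent diffusion coefficient `D` (μm²/s) and intercept `a`.
Trajectories with `log10 D ≤ −1.6` are classified immobile; per cell the
package reports the mean MSD curve, its area under the curve (AUC,
0.02–0.24 s window), the `log10 D` histogram and the immobile fraction.
Per spine or shaft segment with ≥ 50 trajectories, an effective coefficient
`D_eff` is fitted to the ensemble-averaged MSD.

**Moment scaling spectrum (MSS).** For trajectories of ≥ 20 frames, moments
`μ_ν(kΔt) = ⟨|Δr|^ν⟩` for orders ν = 0…6 are fitted in log-log over the
first five lags; the slope `S_MSS` of the scaling exponents γ_ν versus ν
classifies motion: ≈ 0 immobile, 0–0.5 confined, ≈ 0.5 free, → 1 directed.

**Three-state displacement model.** The cumulative distribution of
single-frame displacements `r` (first seven steps of each track, pooled per
cell) is fitted with a static three-state mixture

    C(r, Δt) = 1 − f1·e^(−r²/4D1Δt) − f2·e^(−r²/4D2Δt) − f3·e^(−r²/4D3Δt)

with D1 < D2 < D3 shared across all cells of a condition (global fit) and
occupancies (f1, f2, f3) free per cell — immobile, confined and free
subpopulations.

**Nanodomains.** Pooled localizations are tessellated into Voronoï polygons;
first-rank densities `δ_i = (1+|N_i|)/(A_i + Σ_j A_j)` segment the cell
footprint (≥ 1× average field density) and, within it, nanodomains:
Voronoï-connected components with δ ≥ 2× the object's mean density and
≥ 50 detections. Domain diameter comes from principal component analysis
(`2·√2·√(λ1+λ2)`, exact for a uniform disc) and area from the merged cell
outline; domains are counted per spine.

**Statistics.** Per-cell comparisons route through a D'Agostino–Pearson
normality check: Student's/Welch's t or Mann-Whitney U for two groups,
ANOVA + Holm or Kruskal-Wallis + Dunn beyond, Kolmogorov-Smirnov for
`S_MSS` distributions.

## Worked example

```python
import numpy as np
from sptnano.geometry import build_default_layout
from sptnano.synthetic import SimulationConfig, simulate_cell
from sptnano.trajectories import summarize_cell
from sptnano.motion import collect_displacements, fit_three_state_global, mss_table
from sptnano.nanodomains import find_nanodomains

layout = build_default_layout(n_spines=4, seed=2)
config = SimulationConfig(geometry=layout, n_molecules=3000, seed=2,
                          spine_fraction=0.3, spine_occupancy=(0.45, 0.45, 0.10))
cell = simulate_cell(config, cell_id="demo")

summary = summarize_cell(cell.trajectories)
print(f"trajectories (>=8 frames): {summary.n_trajectories}")
print(f"MSD AUC (0.02-0.24 s):     {summary.auc:.4f} um^2*s")
print(f"immobile fraction:         {summary.immobile_fraction:.3f}")

mss = mss_table(cell.trajectories)
print(f"mean S_MSS (n={len(mss)} tracks >=20 frames): {mss['s_mss'].mean():.3f}")

sample = collect_displacements(cell.trajectories, "demo")
model = fit_three_state_global([sample], seed=0)
f = model.occupancies.iloc[0]
print(f"three-state fit: D = ({model.D[0]:.4f}, {model.D[1]:.4f}, {model.D[2]:.4f}) um^2/s")
print(f"state occupancies: f1={f.f1:.2f} f2={f.f2:.2f} f3={f.f3:.2f}")

points = cell.localizations[["x_um", "y_um"]].to_numpy()
_, objects, domains = find_nanodomains(points, field=(-2, -2, 12, 4))
diams = [d.diameter_nm for d in domains]
print(f"nanodomains detected: {len(domains)}, mean diameter {np.mean(diams):.0f} nm")
```

Output:

```
trajectories (>=8 frames): 1822
MSD AUC (0.02-0.24 s):     0.0099 um^2*s
immobile fraction:         0.658
mean S_MSS (n=768 tracks >=20 frames): 0.221
three-state fit: D = (0.0188, 0.0424, 0.3086) um^2/s
state occupancies: f1=0.05 f2=0.64 f3=0.31
nanodomains detected: 13, mean diameter 209 nm
```

Reading the numbers: the cell mixes trapped and free molecules, so most of
its mass sits below the mobility threshold (immobile fraction 0.66) and the
mean `S_MSS` of 0.22 lands in the confined band. The fitted state
coefficients are *apparent*: the generator's slow states (0.003 and
0.03 μm²/s) are inflated by the 25 nm localization error (σ²/Δt ≈ 0.03
μm²/s) and capped by 170 nm-disc trapping, so the slow pair blurs together
while the free state recovers the true 0.3 μm²/s. Detected nanodomain
diameters (~210 nm) slightly exceed the 170 nm trapping discs because each
localization carries that same 25 nm error.

The same pipeline runs from a shell:

```sh
sptnano run-all --seed 7 --out runs/demo        # simulate + analyse everything
sptnano metrics --input locs.csv --out runs/m   # or stage by stage on your data
```

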