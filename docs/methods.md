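# Methods

This note records the models, conventions and numerical choices behind
`sptnano`, and what its synthetic benchmarks do and do not demonstrate.

## Acquisition regime being modelled

The package targets sptPALM-style recordings: sparse photoconverted single
molecules imaged at 50 Hz (Δt = 0.02 s) for 16,000 frames, localized to a
few tens of nanometres, linked into trajectories whose length is limited by
photobleaching. Coordinates are micrometres and seconds everywhere
internally; nanometre inputs (localization error, nanodomain diameters) are
converted at the boundary.

## Synthetic generator

Each simulated molecule draws, independently:

- a **mobility state** from the occupancy vector (f1, f2, f3) — immobile,
  confined, free — with no state switching. The displacement-CDF model this
  feeds is itself a static mixture at a single lag, so generator and fitted
  model share the same structure by design; a switching regime would test a
  different (hidden-Markov) estimator that is out of scope.
- a **home compartment** (shaft or a spine), by area weight or an explicit
  spine fraction; per-compartment occupancy overrides let spines be enriched
  in trapped states.
- a **start frame** uniform over the acquisition and a **track length**
  from a geometric law (memoryless bleaching), truncated at the end of the
  acquisition. The default mean is 15 frames so that both the ≥ 8-frame
  (MSD) and ≥ 20-frame (MSS) populations are populated.

Dynamics: isotropic Gaussian steps with per-axis variance 2·D_state·Δt.
Confined molecules start uniformly inside a trapping disc (default diameter
170 nm, one per spine head plus sparse shaft discs) and reflect at its rim
by exact radial folding; all molecules reflect specularly off their
compartment polygon (iterated edge reflection; an unresolvable corner case
leaves the molecule at its last interior position). In compartments without
a disc, confined molecules diffuse freely at D2 (ground truth records
`nanodomain_id = -1`). Every reported position then receives independent
Gaussian localization error (default σ = 25 nm — the conventional precision
for this kind of recording; it is a config field). Tracks shorter than 8
localizations are discarded, mirroring the analysis threshold.

The generator emulates: multi-state mobility, nanodomain trapping,
spine/shaft geometry, bleaching-limited tracks, localization noise, uniform
photoconversion in time. It does **not** emulate: state switching within a
track, blinking-induced track splitting, drift, detection misses or false
localizations, axial (z) effects, or tracker linking errors. Passing the
recovery benchmarks therefore shows the estimators are correct for data
matching their own assumptions — not that those assumptions hold for any
particular microscope.

Defaults for the three states are D = (0.003, 0.03, 0.3) μm²/s with
occupancies (0.3, 0.3, 0.4), a representative dendritic mixture spanning
the two-decade spread seen in this kind of data.

## MSD analysis

Time-averaged MSD per trajectory over all frame pairs (i, i+k); frame gaps
contribute every available pair. The diffusion fit is OLS on the first 4
MSD points (`MSD = a + 4Dt`); 4 points balances bias against the variance
explosion of higher lags on short tracks and is a config field. Non-positive
fitted slopes are floored at D = 1e-5 μm²/s (flagged per track) so the
log10 histogram is defined.

Two estimator properties, measured by direct Monte-Carlo oracle (fixed-length
Brownian tracks, no boundaries), matter when interpreting per-track values:

- the **median** of fitted D is skewed low on short tracks (≈ −23% at 8
  frames, −10% at 15, −4% at 30; the mean is unbiased) because the high-lag
  MSD points are right-skewed with few effective degrees of freedom;
- the **intercept** is mean-unbiased but its median is slightly positive on
  short tracks (slope and intercept estimates are anti-correlated).

For this reason the diffusion-recovery benchmarks use bleaching mean 30
frames (~2000 surviving tracks), where the median skew is small relative to
the 10% recovery tolerance; the default generator keeps mean 15.

Immobile classification: `log10 D ≤ −1.6` (boundary value immobile). Cell
summaries require ≥ 1000 trajectories (under-populated cells are flagged,
not dropped). AUC: trapezoid over the mean MSD curve at lags 1–12
(0.02–0.24 s), computed on the per-cell mean curve; the alternative (mean of
per-track AUCs) is not what is implemented. The cell mean curve averages
lag-wise over tracks possessing each lag. Per-ROI `D_eff` fits the lag-wise
mean MSD of a spine or shaft segment's trajectories and requires ≥ 50
trajectories.

## Moment scaling spectrum

Orders 0–6, log-log moment fits over the first 5 lags, slope of γ_ν vs ν
through the origin (γ_0 = 0 identically), clipped to [0, 1]; applied to
tracks of ≥ 20 frames only, whole-trajectory (no transient segmentation).
Calibration on the generator: ballistic tracks give exactly 1; free
Brownian ensembles ≈ 0.46–0.50; 170 nm-disc-confined ensembles ≈ 0.12;
near-static molecules under 25 nm localization noise ≈ 0.02. A zero moment
at any fitted lag (stationary track) excludes the track (log undefined).

## Three-state displacement CDF

Per cell, the first seven single-frame displacement magnitudes per ≥ 8-frame
track (truncated at the first frame gap) are pooled — the cap removes the
overweighting of long-lived molecules. The empirical CDF is evaluated at
the midpoints of consecutive order statistics, uniformly subsampled to
≤ 500 points per cell, and fitted by unweighted least squares (a known
trade-off: CDF residuals are heteroscedastic, but unweighted fitting is
simple and recovers parameters well within tolerance).

Constraints by construction: D1 < D2 < D3 via log-increments
(D_k = Σ exp(θ_j)); per-cell occupancies on the simplex via a two-parameter
softmax. The global fit shares D across cells. Optimization:
`scipy.optimize.least_squares` (TRF), best of 10 multistarts — one
canonical decade-spaced start (0.001, 0.01, 0.1) plus 9 seeded log-uniform
draws over [1e-3, 1] μm²/s; fits where two D's agree within 1% are flagged
degenerate. Recovery at the study scale (10 cells × ~1600 tracks, σ = 0):
shared D within ~1–2%, occupancies within ~0.03 absolute.

Occupancy recovery is judged against each cell's realized per-molecule state
frequencies rather than the configured probabilities — the displacement
mixture reflects the molecules actually simulated, and at 2000 molecules
the distinction is ~1%.

## Voronoï nanodomain detection

Densities: first-rank neighbour-pooled δ_i = (1+|N_i|)/(A_i + Σ_{j∈N_i} A_j)
(bare 1/A_i available as `rank=0`). Cells are clipped to an explicit
**field of view** (default: convex hull of the points) and the global
average density is bounded localizations per field area. The field matters:
a cell footprint inside a larger, emptier field sits well above the global
average, which is what lets object segmentation recover the whole footprint
— with a threshold at the *local* mean, only ~half of uniform points would
select (site-percolation-critical, no contiguous object). Points whose true
Voronoï cell is infinite (convex-hull boundary) are flagged unbounded,
carry density 0 and are excluded from averages.

Objects: δ ≥ 1.0 × global average (configurable), Voronoï-adjacency
components, each closed with its directly adjacent below-threshold cells
(rim localizations have genuinely lower first-rank density but belong to
the footprint); < 10-member components discarded. Object density = member
count / outline area (union of member cells).

Nanodomains: within an object, δ ≥ 2.0 × object density, adjacency
components, ≥ 50 detections; membership is strictly above-threshold (no
closure — closure would let sub-threshold clusters reach the 50-detection
floor by swallowing background). Both defining thresholds are re-checked
post hoc on every domain. Diameter: PCA of member coordinates,
`2·√2·√(λ1+λ2)` in nm — the convention is pinned by calibration (it returns
exactly the true diameter for a uniformly filled disc; for an isotropic
Gaussian cluster it gives 4σ) and is recorded in output metadata. Area:
union of member Voronoï cells clipped to the object (avoids convex-hull
concavity artifacts). Per-spine counts assign each domain by centroid
containment, tie-breaking boundary cases to the lowest ROI id.

Detection performance at the benchmark scale (100-detection discs at 10×
background in a 20 μm⁻² footprint): ~93% of planted points recovered per
disc — the outermost ring is lost to first-rank smoothing across the disc
boundary, an intrinsic, roughly scale-invariant property of neighbourhood
density estimators — with zero false domains on complete-spatial-randomness
controls and zero domains from 40-detection clusters. All localizations
enter the tessellation (not one per track), so blinking recounting present
in real data is reproduced, not corrected; a one-per-track filter is a
caller-side choice. Drift correction is assumed done upstream.

## Compartments

ROIs are 2D simple polygons labelled spine/shaft/excluded; spines may carry
a `paired_shaft_id` for paired comparisons. Trajectories are assigned by
majority of localizations (threshold 0.5, configurable): the winning ROI
needs a unique maximal fraction ≥ the threshold; boundary-straddling tracks
stay unassigned rather than being split (a split-at-boundary mode was
considered and rejected as default because segment-wise metrics bias
short-track statistics); any overlap with an excluded ROI drops the track.
Compartment reports recompute the per-cell metrics on exactly the member
tracks, so they agree with the trajectory module to machine precision (this
is tested).

## Statistics

Per-cell (or per-ROI) values only — trajectories are never pooled across
cells into one test sample. Routing: D'Agostino–Pearson normality at
α = 0.05 per group (groups under 8 values are routed non-parametric, since
the test is undefined there); two normal groups → Student's t, Welch's
variant when Levene flags unequal variances, paired variants on request;
non-normal → Mann-Whitney U / Wilcoxon; > 2 groups → ANOVA with
Holm-adjusted pairwise t, or Kruskal-Wallis with Dunn's rank post hoc
(hand-implemented z tests on mean ranks with tie correction; Holm
adjustment). Distribution-shaped metrics (per-track S_MSS) use two-sample
Kolmogorov-Smirnov. Under identical normal distributions at n = 15/group
the full routed procedure rejects at 0.04–0.06 (nominal 0.05).

## Pipeline and reproducibility

One global seed fans out through `numpy.random.SeedSequence` into fixed
per-stage seeds, so enabling or disabling one stage never changes another's
randomness. Every run writes a manifest with the verbatim config echo,
per-stage output SHA-256 checksums and wall-clock times; identical config
and inputs reproduce identical checksums. Unknown config keys are rejected
by name. Floats serialize with a fixed format so CSV outputs are
byte-stable.

## Benchmark problem sizes

The validation benchmarks (`sptnano.validation`, driven by the acceptance
script and test suite) use: 100 random tracks for the MSD oracle; ~2000
surviving free tracks for diffusion recovery; ~2000-track mixtures for the
immobile fraction; 10 cells × 2600 molecules for the global three-state
fit; ≥ 400 tracks of ≥ 20 frames per MSS ensemble; 4 planted discs per
field × 3 replicates plus 100 CSR controls for nanodomains; 20 replicates
of a 600-molecule two-spine cell for compartment ordering; 1000 replicates
for the type-I calibration. The full set runs in about a minute on one CPU.

## Known limitations

- Whole-trajectory MSS only; no within-track transient-state segmentation.
- The three-state fit fixes the number of states at three; no model
  selection, no measurement-error deconvolution (apparent D's absorb
  localization noise — e.g. σ = 25 nm adds σ²/Δt ≈ 0.03 μm²/s to slow
  states).
- No drift simulation or correction; externally corrected tables are
  accepted as-is.
- 2D geometry throughout; out-of-plane spines are represented only through
  user-supplied `excluded` ROIs.
- Bootstrap confidence intervals on the shared D's are not provided.
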