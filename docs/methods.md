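# Methods

This note documents the models, estimators, numerical choices, and
limitations behind `sdpdiff`, in the order the pipeline runs.

## Trajectory model and unwrapping

Trajectories are per-molecule, time-ordered positions (nm) on a uniform time
grid (ns) in an orthorhombic periodic box.  Only orthorhombic cells are
supported: the target systems are rectangular, and triclinic minimum-image
logic would add complexity without benefit.  Species tags ("water",
"polymer") come from residue names when reading GRO/XTC (default water
residues: SOL, HOH, WAT) and are carried explicitly in the internal CSV
dialect, which is deliberately a diffable, header-row text format
(`mol_id, frame, time_ns, x/y/z_nm, bx/by/bz_nm, species`) so fixtures can
be inspected and versioned.

Unwrapping corrects each frame-to-frame displacement by the nearest periodic
image, using the box of the later frame, and accumulates the corrected
displacements.  This assumes every physical move is below half the box per
axis; a corrected displacement reaching half the box is ambiguous and raises
an error naming the molecule and frame.  For a constant box,
`wrap(unwrap(T))` reproduces the input and `unwrap` is idempotent up to
float round-off (coordinates within machine epsilon of a box face can flip
between 0 and L).  For a fluctuating (NPT) box the identity is only
approximate, because accumulated image shifts mix boxes from different
frames; all fixtures used here have constant boxes.

## Waiting/moving segmentation

A maximal run of frames is **waiting** when

(a) every position in the run lies within `displacement_radius` (default
    0.1 nm, the OH bond length) of the run's mean position, and
(b) the run's squared-displacement rate — the mean frame-to-frame squared
    displacement per unit time, `mean_k |r(k+1)−r(k)|² / dt` — is below
    `msd_rate_threshold` (default 0.35 nm² ns⁻¹).

Everything else is **moving**.  Criterion (b) deserves comment.  For free
diffusion the per-step rate equals 6D, so the default threshold is about a
tenth of bulk water's 6D ≈ 21 nm² ns⁻¹ at D_s,w = 3.5.  It is not redundant
with (a): a handful of genuinely diffusing steps occasionally stays inside a
0.1 nm ball by chance, and without (b) such runs are mislabelled as waiting
— on the two-state benchmark this artifact halves the recovered τ_w.  The
per-step MSD rate separates the two cases by roughly two orders of magnitude
(≈ 6 nm² ns⁻¹ for D = 1 moving phases versus ≈ 0.05 for 0.02 nm jitter at
0.01 ns frames).  The threshold remains the key tunable of the segmentation:
for moving-phase diffusivities below ~0.06 nm² ns⁻¹ at 0.01 ns frames it
must be lowered.

Runs are grown by a greedy forward scan.  The maximum deviation from the
running mean is tracked incrementally through an upper bound (each mean
shift adds to the bound via the triangle inequality) and re-tightened by an
exact pass only when the bound crosses the radius, keeping the scan close to
linear time without approximating the criterion at acceptance points.  A
candidate must reach `window` frames (default 4) to count as waiting; after
labelling, runs shorter than `min_segment` frames (default 3) are merged
into the preceding run's label (a leading short run takes the following
label) — a deterministic single pass that suppresses single-frame flicker.

Statistics are segment-weighted: τ_w and τ_m are means over all waiting
(resp. moving) segments pooled across molecules, each segment counting once.
The switching frequency is defined as ν = 1/(τ_w + τ_m) — cycles per unit
time — so the bookkeeping identities ν⁻¹ = τ_w + τ_m and
moving_fraction = τ_m ν hold exactly by construction; the raw count of
label switches is reported separately (`switch_count`).  When no moving
segment exists, τ_m is reported as 0 with a warning rather than NaN so the
identities stay testable.  The ensemble check (`ensemble_state_fractions`)
compares the time fraction τ_m ν against the per-frame population fraction
of moving molecules; for a stationary process these agree (ergodicity), and
on the two-state benchmark the gap is ~1e-4.

Not modelled: intermediate mobility modes such as surface diffusion along a
sorptive interface; the classifier is strictly binary.

## MSD and diffusion coefficients

MSD(Δ) averages |r(t+Δ)−r(t)|² over all molecules and **all** time origins.
Production code uses the FFT autocorrelation decomposition (O(N log N));
trajectories of ≤128 frames use the direct summed-over-origins form, which
is bit-identical to the textbook double loop and serves as the internal
cross-check of the FFT path.  Lags are limited to `max_lag_fraction`
(default 0.5) of the trajectory because long lags average few origins.

The Fickian window is the longest contiguous lag range whose local log-log
slope (central differences) lies within `slope_tol` (default 0.1) of 1.
Ballistic or confined data yield an empty window and a warning; `estimate_D`
then raises, or returns D = 0 on request for genuinely immobile systems.
D is the least-squares slope over the window divided by 6 — the 3-D
Einstein relation; the dimensional factor is a package choice.

D_μ = D / (τ_m ν) removes the waiting time from the diffusion coefficient;
ξ = D_bulk/D_μ with D_bulk defaulting to 3.5 nm² ns⁻¹ (a separate bulk
simulation value; model- and temperature-dependent, hence overridable).

A note on the two-state benchmark: with memoryless (exponential) dwells the
*ensemble* MSD is exactly linear at every lag, MSD = 6 D_moving f_m Δ,
because the expected moving time in any interval is f_m Δ; the waiting
jitter contributes only a ~1e-3 nm² offset.  Sub-linear short-lag regimes
appear for heavy-tailed dwell distributions or non-stationary starts, which
this generator deliberately does not produce.

## Percolation

Two water sites are connected when their minimum-image distance is within
`cutoff`.  The default 0.35 nm is the usual O–O hydrogen-bond heuristic
applied to oxygen (single-site) coordinates; **the cutoff is the key free
parameter of this analysis** — there is no canonical value — and results
should always be reported together with it.  Neighbour pairs come from a
periodic k-d tree; components from a union-find whose nodes carry integer
periodic-image offsets.  When a union closes a loop whose accumulated image
offset is non-zero along an axis, that cluster wraps the torus along that
axis — an exact topological spanning test under periodic boundaries,
insensitive to where the box faces are drawn (unlike "touches both faces"
rules).  A frame percolates (δ_p = 1) when any cluster spans at least one
axis; `axes="all"` requires all three.  p_p is the mean of δ_p over frames
(trapezoid rule for non-uniform spacing).

p_p is system-size dependent; no finite-size correction is applied, the
value is reported for the given cell as-is.

The synthetic lattice fixtures are site-diluted cubic lattices whose
spanning verdict is computed by an independent flood fill with
periodic-image bookkeeping (pure lattice BFS, no shared code with the
union-find); any cutoff in (spacing, √2·spacing) makes the continuum
clustering reproduce nearest-neighbour lattice connectivity exactly, which
is how the two implementations are compared on hundreds of near-threshold
configurations (simple-cubic site-percolation threshold ≈ 0.312).

## Material properties

Heat of adsorption: Q_ad = (H_p + H_wv − H_c)/n_water − H_latent with
H_wv = 4 n_water R T and H_latent = 40.68 kJ mol⁻¹, i.e. referenced to
liquid water (zero net binding gives Q_ad = −H_latent).  When per-frame
thermodynamic series are supplied, H = ⟨U⟩ + ⟨P·V⟩ with the time mean of
the instantaneous PV product — the P–V covariance is kept rather than using
⟨P⟩⟨V⟩ — and bar·nm³ converted to kJ mol⁻¹ via Avogadro's number.

Young's modulus is the least-squares slope (free intercept) of stress vs
strain over strain ≤ `linear_max_strain` (default 0.01, matching a stepwise
tensile protocol of ~0.01% increments to ~1% total strain).

Polymer–water distance d_pw is each water site's minimum-image distance to
its nearest polymer atom (all polymer atoms by default), averaged over all
waters and separately over waiting- and moving-labelled waters.  An empty
state class yields NaN for that average.

Moisture-content trends are fitted by nonlinear least squares to the four
parametric forms d_pw = (m−a)^b + c, p_p = 1/(exp(−a·m+b)+1),
Q_ad = a·exp(−b·m) + c, and E = a·(1+m)^b, each from five deterministic
data-driven starting points (log-linear or logit transforms where the form
allows), with `a` bounded below min(m) for the d_pw power law so the base
stays positive.  A constant response, or a best residual comparable to the
total signal variation, raises a fit error rather than returning a
meaningless parameter set.  Parameters are reported in the records' native
units.

## SDP model

Features: x_Q = Q_ad/(R·T) (molar convention, equivalent to per-molecule
k_BT; T defaults to 300 K and is configurable), x_E = (E/1 GPa)^½, x_p =
p_p.  The fit is unweighted OLS of ln(D_μ/D_bulk) on (1, x_Q, x_E, x_p) —
the model is stated in log form and no weighting scheme is imposed — via
statsmodels, returning weights, standard errors, R², and residuals.  A
constant feature raises a rank-deficiency error naming the feature.
Prediction works in log space, so extreme inputs cannot overflow.  The
sensitivity analysis refits every subset of {Q, E, p} (8 models including
intercept-only) and reports R² and RMSE on ln ξ⁻¹; nested OLS guarantees
the full model is maximal in-sample.

`REFERENCE_WEIGHTS` (−0.572, −3.051, −1.243, 0.466) is a published
wood-polymer fit shipped for prediction.  Its feature normalization cannot
be reconstructed independently (with x_Q ≈ 17 at Q_ad ≈ 43 kJ mol⁻¹ and
300 K, the quoted a_Q would imply vanishing ξ⁻¹), so these weights are
treated as opaque, dataset-specific constants, not transferable physics.

## Synthetic generators and what they do (not) emulate

The two-state generator uses alternating exponential dwells (the minimal
memoryless model; dwell distributions in real matrices are unknown), an
initial state drawn from the stationary occupancy, Gaussian moving steps of
variance 2·D_moving·dt per axis, and uniform-in-sphere waiting jitter of
amplitude 0.02 nm about a frozen anchor — comfortably below the 0.1 nm
classification radius so states are separable by construction.  Its
analytic coarse-grained diffusion coefficient is D_moving·τ_m/(τ_w+τ_m).
Defaults mirror the benchmark conditions: τ_w* = τ_m* = 1 ns, dt = 0.01 ns
(well below the dwell scale; dt within a fifth of the shortest mean dwell
is rejected as state aliasing), 100 ns duration, 5 nm box.  It does not
emulate polymer chemistry, hydrogen-bond directionality, sorption
isotherms, dwell-time memory, or surface diffusion — so passing tests
demonstrate estimator correctness on the idealized process, not robustness
to every feature of real MD data.

## Problem sizes and numerical tolerances in the test suite

The heavy fixtures are 200 molecules × 100 ns at 0.01 ns frames
(segmentation/ergodicity/two-state diffusion) and 500 walkers × 100 ns at
0.1 ns frames (Brownian recovery); percolation parity uses 200 random 12³
configurations per occupancy; SDP coverage uses 200 replicate fits of
60-record tables.  Bookkeeping identities are asserted to 1e-12, noiseless
OLS recovery to 1e-10, trend-fit recovery to 1e-6, finite-difference
log-derivatives to 1e-6, dwell-time recovery to 10%, diffusion recovery to
5% (Brownian) and 10% (D_μ), the ergodicity gap to 0.02.

One statistical caveat: the ±2 SE coverage check (95.45% nominal with exact
standard errors) is compared against a 95% bar from only 200 replicates,
whose observed fraction has a sampling SD of ~1.5% — three times the margin
— so that single check is expected to fluctuate across seed sets even for a
perfectly calibrated estimator; the accompanying 1000-replicate calibration
of the same estimator is statistically clean.
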