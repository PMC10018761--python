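# sdpdiff

Water diffusion in dense, sorptive, deformable polymer matrices — hydrated
biopolymers such as hemicelluloses and lignins are the motivating case — is
*intermittent*: a molecule alternates between **waiting** phases, trapped at
sorption sites, and **moving** phases of genuine Brownian relocation.
`sdpdiff` is a toolkit for quantifying this stop-and-go picture from
molecular trajectories and for linking the resulting transport coefficients
to measurable material properties through the
**sorption–deformation–percolation (SDP) model**.

It is aimed at molecular-simulation practitioners who have trajectories of
water (or another small diffusant) in a nanoporous host and want, from those
trajectories alone:

- per-frame waiting/moving labels and the switching statistics ν, τ_w, τ_m;
- the self-diffusion coefficient *D* from the Fickian regime of the MSD and
  the **microscopic diffusion coefficient** D_μ = D/(τ_m ν), the diffusivity
  of the moving phase alone;
- the **percolation probability** p_p: the time fraction during which a
  water cluster spans the periodic cell (detected topologically, by
  image-offset bookkeeping in a union-find);
- material descriptors: integral heat of adsorption Q_ad, Young's modulus
  *E*, polymer–water distance d_pw by mobility state;
- the SDP model tying them together.

## The model

With the bulk-water reference D_s,w = 3.5 nm² ns⁻¹, the apparent tortuosity
is ξ = D_s,w / D_μ and its reciprocal ξ⁻¹ (the normalized diffusion
coefficient, usually < 1) is modelled as a product of exponential factors:

    ξ⁻¹ = exp( a₀ + a_Q·x_Q + a_E·x_E + a_p·x_p )

    x_Q = Q_ad / (R T)        sorption, in thermal units
    x_E = (E / E₀)^½, E₀ = 1 GPa   deformation (persistence-length scaling)
    x_p = p_p                 percolation probability

The model is linear in the weights on the log scale, so they are fitted by
ordinary least squares of ln ξ⁻¹ on (1, x_Q, x_E, x_p), and each weight is
the log-derivative a_i = ∂ ln ξ⁻¹ / ∂x_i.  A published wood-polymer fit
(a₀ = −0.572, a_Q = −3.051, a_E = −1.243, a_p = 0.466) ships as
`sdpdiff.REFERENCE_WEIGHTS` for prediction; see the docstring caveats.

Because no reference trajectories are deposited anywhere, the package
includes a first-class synthetic-data module (`sdpdiff.synthetic`) that
generates two-state intermittent random walks, lattice percolation
configurations with an exact flood-fill spanning oracle, stress–strain and
thermodynamic tables, and SDP feature/response datasets — all with known
ground truth, which is what the test suite scores the pipeline against.

## Worked example

Generate a 50-molecule, 50 ns stop-and-go trajectory (mean dwell times
τ_w* = τ_m* = 1 ns, moving-phase D* = 1 nm² ns⁻¹), segment it, and estimate
diffusion coefficients:

```bash
$ sdpdiff synth trajectory --n 50 --duration 50 --dt 0.01 \
      --tau-w 1.0 --tau-m 1.0 --seed 7 --out traj.csv
wrote 50 molecules x 5001 frames to traj.csv

$ sdpdiff segment traj.csv --stats-out seg.json
{"nu": 0.4683063387322539, "tau_w": 1.0877882152006826, "tau_m": 1.0475661827497855,
 "moving_fraction": 0.49058188362327526, "switch_count": 2292}

$ sdpdiff diffusion traj.csv --stats seg.json --max-lag-fraction 0.1
{"D": 0.4877494648303178, "D_mu": 0.9942264097238198, "xi": 3.5203249136906796,
 "xi_inv": 0.2840646884925199, "window": [2, 500],
 "loglog_slope": 0.994306549778396, "r_squared": 0.9997472282518143}
```

Reading the numbers: the recovered dwell times (1.09 ns, 1.05 ns) match the
generating 1 ns within sampling error; the moving time fraction τ_m ν ≈ 0.49
matches the stationary value 0.5.  The measured D ≈ 0.488 nm² ns⁻¹ is the
analytic coarse-grained value D*·τ_m/(τ_w+τ_m) = 0.5, and dividing out the
moving fraction recovers the moving-phase diffusivity D_μ ≈ 0.99 ≈ D* = 1.
Against bulk water this system has tortuosity ξ ≈ 3.5, i.e. ξ⁻¹ ≈ 0.28.

Fitting SDP weights from a synthetic material table (noise σ = 0.05 on
ln ξ⁻¹) recovers the generating reference weights:

```bash
$ sdpdiff synth sdp-dataset --n 60 --noise 0.05 --seed 7 --out records.csv
$ sdpdiff sdp fit records.csv
{"a_0": -0.5906..., "a_Q": -3.0499..., "a_E": -1.2367..., "a_p": 0.4542...,
 "r_squared": 0.99999, "n_obs": 60}
```

The same operations are available as a library (`sdpdiff.segment`,
`sdpdiff.compute_msd`, `sdpdiff.cluster_frame`, `sdpdiff.sdp_fit`, ...); the
CLI is a thin wrapper.

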