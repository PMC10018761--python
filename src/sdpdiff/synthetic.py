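"""Ground-truth synthetic data for every analysis stage.

The central generator emulates the stop-and-go motion of water in a sorptive
matrix as a two-state continuous-time process: exponentially distributed
waiting and moving dwell times (the minimal memoryless model), Gaussian
displacement steps of variance 2*D_moving*dt per axis while moving, and
uniform-in-sphere jitter of amplitude ``jitter_amp`` about a fixed anchor
while waiting.  The analytic coarse-grained diffusion coefficient of this
process is D = D_moving * tau_m / (tau_w + tau_m), and the per-frame true
state sequence is retained so segmentation accuracy can be scored exactly.

Percolation fixtures live on a cubic lattice so that an exact combinatorial
spanning oracle (flood fill with periodic-image bookkeeping) exists,
independent of the production union-find; the production code still sees
plain continuum coordinates.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import GAS_CONSTANT_KJ, MaterialRecord
from .msd import D_BULK_WATER
from .sdp import DEFAULT_TEMPERATURE, SDPWeights
from .trajectory import Box, StressStrainTable, ThermoSeries, Trajectory, wrap

__all__ = [
    "TwoStateParams",
    "GroundTruth",
    "PercolationConfig",
    "gen_intermittent_trajectory",
    "gen_percolation_config",
    "gen_sdp_dataset",
    "gen_stress_strain",
    "gen_thermo_series",
    "DEFAULT_FEATURE_RANGES",
]


@dataclass
class TwoStateParams:
    """Parameters of the two-state intermittent random walk.

    tau_w, tau_m : mean exponential dwell times (ns) of the waiting and
        moving states.  ``tau_w = 0`` gives a pure Brownian walker,
        ``tau_m = 0`` (or ``tau_w = inf``) a permanently trapped one.
    d_moving : moving-phase diffusion coefficient, nm^2/ns.
    jitter_amp : waiting-phase confinement radius, nm; must stay below the
        0.1 nm classification radius so the states are cleanly separable.
    """

    tau_w: float = 1.0
    tau_m: float = 1.0
    d_moving: float = 1.0
    jitter_amp: float = 0.02
    n_molecules: int = 100
    duration: float = 100.0
    dt: float = 0.01
    box: Box = field(default_factory=lambda: Box.cubic(5.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_w < 0 or self.tau_m < 0:
            raise ValueError("dwell times must be non-negative")
        if self.d_moving <= 0 or self.duration <= 0 or self.dt <= 0:
            raise ValueError("d_moving, duration and dt must be positive")
        if not 0 < self.jitter_amp < 0.1:
            raise ValueError("jitter_amp must lie in (0, 0.1) nm")
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        finite = [t for t in (self.tau_w, self.tau_m) if 0 < t < math.inf]
        if len(finite) == 2 and self.dt >= min(finite) / 5:
            raise ValueError(
                f"dt={self.dt} ns is too coarse for dwell times "
                f"(tau_w={self.tau_w}, tau_m={self.tau_m}): state aliasing"
            )

    @property
    def p_move(self) -> float:
        """Stationary probability of the moving state."""
        if self.tau_w == 0:
            return 1.0
        if self.tau_m == 0 or math.isinf(self.tau_w):
            return 0.0
        return self.tau_m / (self.tau_w + self.tau_m)


@dataclass
class GroundTruth:
    """Oracle payload accompanying a generated trajectory."""

    states: np.ndarray                  # (n_mol, n_frames) int8; 0 wait, 1 move
    positions_unwrapped: np.ndarray     # (n_mol, n_frames, 3) nm, pre-wrap
    true_D: float                       # d_moving * p_move, nm^2/ns
    true_moving_fraction: float         # p_move
    params: TwoStateParams


def _frame_states(params: TwoStateParams, rng: np.random.Generator, times: np.ndarray) -> np.ndarray:
    """Per-frame state of one molecule (1 = moving) by sampling dwell sequences."""
    n = len(times)
    if params.tau_w == 0:
        return np.ones(n, dtype=np.int8)
    if params.tau_m == 0 or math.isinf(params.tau_w):
        return np.zeros(n, dtype=np.int8)
    start_moving = rng.random() < params.p_move
    # draw comfortably more dwells than needed, extend in the rare shortfall
    mean_cycle = params.tau_w + params.tau_m
    est = max(8, int(2 * params.duration / mean_cycle) + 8)
    boundaries = []
    total = 0.0
    state = start_moving
    while total <= params.duration:
        block_w = rng.exponential(params.tau_w, size=est)
        block_m = rng.exponential(params.tau_m, size=est)
        for k in range(est):
            dwell = block_m[k] if state else block_w[k]
            total += dwell
            boundaries.append(total)
            state = not state
            if total > params.duration:
                break
    boundaries = np.asarray(boundaries)
    idx = np.searchsorted(boundaries, times, side="right")
    states = (idx % 2 == 0) == start_moving
    return states.astype(np.int8)


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    vec = rng.normal(size=(n, 3))
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return vec / norm * r[:, None]


def gen_intermittent_trajectory(
    params: TwoStateParams,
) -> tuple[Trajectory, GroundTruth]:
    """Generate a wrapped two-state trajectory plus its ground truth.

    While moving, the anchor path takes Gaussian steps of variance
    2*d_moving*dt per axis; while waiting, the observed position is the
    anchor plus independent uniform-in-sphere jitter, so waiting positions
    stay within ``jitter_amp`` of a fixed point.  Deterministic per seed.
    """
    n_frames = int(round(params.duration / params.dt)) + 1
    times = np.arange(n_frames) * params.dt
    rng = np.random.default_rng(params.seed)
    L = params.box.lengths
    n_mol = params.n_molecules
    states = np.empty((n_mol, n_frames), dtype=np.int8)
    positions = np.empty((n_mol, n_frames, 3))
    sigma = math.sqrt(2.0 * params.d_moving * params.dt)
    for mol in range(n_mol):
        s = _frame_states(params, rng, times)
        states[mol] = s
        x0 = rng.random(3) * L
        steps = rng.normal(scale=sigma, size=(n_frames, 3))
        steps[0] = 0.0
        steps[s == 0] = 0.0               # anchor is frozen while waiting
        base = x0 + np.cumsum(steps, axis=0)
        jitter = _uniform_in_sphere(rng, n_frames, params.jitter_amp)
        jitter[s == 1] = 0.0
        positions[mol] = base + jitter
    truth = GroundTruth(
        states=states,
        positions_unwrapped=positions.copy(),
        true_D=params.d_moving * params.p_move,
        true_moving_fraction=params.p_move,
        params=params,
    )
    traj = Trajectory(
        times=times,
        positions=positions,
        box=np.broadcast_to(L, (n_frames, 3)).copy(),
        species=np.repeat("water", n_mol).astype(object),
    )
    traj = wrap(traj)
    return traj, truth


# ---------------------------------------------------------------------------
# percolation fixtures with an independent flood-fill oracle
# ---------------------------------------------------------------------------

@dataclass
class PercolationConfig:
    positions: np.ndarray       # (n_occupied, 3) nm
    box: Box
    spans: np.ndarray           # (3,) bool — oracle verdict per axis
    occupied: np.ndarray        # (L, L, L) bool lattice
    spacing: float
    lattice_size: int

    @property
    def delta_p_any(self) -> int:
        return int(self.spans.any())

    @property
    def delta_p_all(self) -> int:
        return int(self.spans.all())


def _flood_fill_spans(occupied: np.ndarray) -> np.ndarray:
    """Spanning verdict per axis by BFS with periodic-image bookkeeping.

    Each occupied site is visited with an integer image vector; reaching a
    site already visited in this component under a different image means the
    component wraps the torus along the axes where the images differ.
    """
    L = occupied.shape[0]
    spans = np.zeros(3, dtype=bool)
    seen_global = np.zeros(occupied.shape, dtype=bool)
    sites = np.argwhere(occupied)
    for sx, sy, sz in sites:
        if seen_global[sx, sy, sz]:
            continue
        images: dict[tuple[int, int, int], tuple[int, int, int]] = {}
        queue = deque([((int(sx), int(sy), int(sz)), (0, 0, 0))])
        while queue:
            site, img = queue.popleft()
            if site in images:
                prev = images[site]
                for ax in range(3):
                    if img[ax] != prev[ax]:
                        spans[ax] = True
                continue
            images[site] = img
            seen_global[site] = True
            x, y, z = site
            for ax, step in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
                coords = [x, y, z]
                coords[ax] += step
                shift = 0
                if coords[ax] < 0:
                    coords[ax] += L
                    shift = -1
                elif coords[ax] >= L:
                    coords[ax] -= L
                    shift = 1
                nxt = (coords[0], coords[1], coords[2])
                if occupied[nxt]:
                    nimg = list(img)
                    nimg[ax] += shift
                    queue.append((nxt, tuple(nimg)))
    return spans


def gen_percolation_config(
    lattice_size: int = 12,
    occupancy: float = 0.31,
    spacing: float = 0.25,
    seed: int = 0,
) -> PercolationConfig:
    """Random site-diluted cubic lattice mapped to continuum coordinates.

    Sites sit at cell centers, ``spacing`` apart, in a periodic box of edge
    ``lattice_size * spacing``.  The spanning verdict is computed by the
    lattice flood-fill oracle (nearest-neighbour connectivity), which the
    production continuum clustering should reproduce with any cutoff in
    (spacing, spacing*sqrt(2)).
    """
    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    occupied = rng.random((lattice_size,) * 3) < occupancy
    coords = np.argwhere(occupied)
    positions = (coords + 0.5) * spacing
    spans = _flood_fill_spans(occupied)
    return PercolationConfig(
        positions=positions.astype(float),
        box=Box.cubic(lattice_size * spacing),
        spans=spans,
        occupied=occupied,
        spacing=spacing,
        lattice_size=lattice_size,
    )


# ---------------------------------------------------------------------------
# SDP feature/response tables
# ---------------------------------------------------------------------------

#: feature sampling ranges spanning the regimes the model targets:
#: Q_ad in thermal units up to the strong-sorption scale (~43 kJ/mol at 300 K
#: is x_Q ~ 17), moduli 1-8 GPa, and the full percolation range.
DEFAULT_FEATURE_RANGES = {
    "x_Q": (2.0, 18.0),
    "x_E": (1.0, 2.8),
    "x_p": (0.0, 1.0),
}


def gen_sdp_dataset(
    weights: SDPWeights,
    n: int = 60,
    feature_ranges: dict | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    T: float = DEFAULT_TEMPERATURE,
    D_bulk: float = D_BULK_WATER,
) -> pd.DataFrame:
    """Material records sampled from the SDP model with known weights.

    Features are uniform in the stated ranges; ln xi_inv gets i.i.d. Gaussian
    noise of ``noise_sigma``.  The returned frame carries the implied
    physical columns (Q_ad, E, p_p, D_mu) consumed by the fitting code plus
    the noise-free truth columns (prefixed ``true_``).
    """
    if n < 5:
        raise ValueError("need at least 5 records")
    ranges = dict(DEFAULT_FEATURE_RANGES)
    if feature_ranges:
        ranges.update(feature_ranges)
    rng = np.random.default_rng(seed)
    x_Q = rng.uniform(*ranges["x_Q"], size=n)
    x_E = rng.uniform(*ranges["x_E"], size=n)
    x_p = rng.uniform(*ranges["x_p"], size=n)
    ln_clean = weights.a_0 + weights.a_Q * x_Q + weights.a_E * x_E + weights.a_p * x_p
    ln_obs = ln_clean + rng.normal(scale=noise_sigma, size=n) if noise_sigma > 0 else ln_clean.copy()
    df = pd.DataFrame(
        {
            "label": [f"synthetic-{k:03d}" for k in range(n)],
            "m": rng.uniform(0.0, 0.3, size=n),
            "Q_ad": x_Q * GAS_CONSTANT_KJ * T,
            "E": x_E**2,
            "p_p": x_p,
            "D_mu": np.exp(ln_obs) * D_bulk,
            "true_ln_xi_inv": ln_clean,
            "true_xi_inv": np.exp(ln_clean),
        }
    )
    return df


def gen_stress_strain(
    E_true: float,
    max_strain: float = 0.01,
    step: float = 1e-4,
    noise: float = 0.0,
    seed: int = 0,
) -> StressStrainTable:
    """Linear-elastic stress-strain table: stress = E_true * strain + noise (GPa).

    Default grid mimics a stepwise tensile protocol: 0.01% strain increments
    up to 1% total (101 rows including the unstrained state).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(round(max_strain / step))
    strain = np.arange(n_steps + 1) * step
    rng = np.random.default_rng(seed)
    stress = E_true * strain
    if noise > 0:
        stress = stress + rng.normal(scale=noise, size=len(strain))
    return StressStrainTable(strain=strain, stress=stress)


def gen_thermo_series(
    n: int,
    U_mean: float,
    P_mean: float = 1.0,
    V_mean: float = 125.0,
    T: float = DEFAULT_TEMPERATURE,
    U_std: float = 0.0,
    seed: int = 0,
) -> ThermoSeries:
    """Per-frame thermodynamic series with a prescribed mean enthalpy.

    Pressure and volume fluctuate mildly but independently around their
    means, so <P V> = P_mean * V_mean holds in expectation.
    """
    rng = np.random.default_rng(seed)
    U = np.full(n, U_mean) + (rng.normal(scale=U_std, size=n) if U_std > 0 else 0.0)
    P = np.full(n, P_mean)
    V = np.full(n, V_mean)
    return ThermoSeries(U=U, P=P, V=V, T=np.full(n, T))


def truth_to_record(
    label: str, m: float, Q_ad: float, E: float, p_p: float, D_mu: float
) -> MaterialRecord:
    """Convenience constructor used by the CLI fixtures."""
    return MaterialRecord(label=label, m=m, Q_ad=Q_ad, E=E, p_p=p_p, D_mu=D_mu)
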