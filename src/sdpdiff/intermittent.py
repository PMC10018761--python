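"""Waiting/moving segmentation of intermittent molecular motion.

Water in a dense sorptive matrix moves in a stop-and-go fashion: it is
trapped ("waiting") at sorption sites and occasionally relocates ("moving").
A run of frames is classified as waiting when (a) every position in the run
stays within ``displacement_radius`` of the run's mean position — the default
0.1 nm is the OH bond length — and (b) the rate of change of the squared
displacement within the run, measured as the mean frame-to-frame squared
displacement per unit time (an MSD rate, ~6D for free diffusion), stays
below ``msd_rate_threshold``.  Everything else is moving.  Criterion (b)
matters because a handful of genuinely diffusing steps can by chance stay
inside a 0.1 nm ball while still moving at full per-step speed; their MSD
rate exposes them.

From the resulting alternating segments we report the mean waiting time
tau_w, mean moving time tau_m (segment-weighted: each segment counts once,
pooled over molecules), the switching frequency nu = 1/(tau_w + tau_m), and
the moving time fraction tau_m * nu.  These satisfy the bookkeeping identity
t_tot = tau_w*nu*t_tot + tau_m*nu*t_tot by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "WAITING",
    "MOVING",
    "SegmentationParams",
    "Segment",
    "SegmentationResult",
    "EnsembleFractions",
    "SegmentationError",
    "segment",
    "ensemble_state_fractions",
]

WAITING = 0
MOVING = 1


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentationParams:
    """Tunable thresholds for the waiting/moving classification.

    displacement_radius : nm — confinement radius of a waiting run (default
        0.1 nm, the OH bond length).
    msd_rate_threshold : nm^2/ns — upper bound on the run's mean per-frame
        squared-displacement rate, mean_k |r(k+1) - r(k)|^2 / dt.  For free
        diffusion this rate is 6D, so the default 0.35 (a tenth of the 6D of
        bulk water) rejects runs whose steps proceed at diffusive speed while
        comfortably accepting sub-0.1 nm confinement jitter.
    window : frames — minimum length of a waiting run.
    min_segment : frames — runs shorter than this are merged into the
        neighbouring label (a leading short run takes the following label).
    """

    displacement_radius: float = 0.1
    msd_rate_threshold: float = 0.35
    window: int = 4
    min_segment: int = 3

    def __post_init__(self) -> None:
        if self.displacement_radius <= 0:
            raise SegmentationError("displacement_radius must be positive")
        if self.window < 2:
            raise SegmentationError("window must be at least 2 frames")
        if self.min_segment < 1:
            raise SegmentationError("min_segment must be at least 1 frame")


@dataclass(frozen=True)
class Segment:
    mol: int            # row index into the trajectory
    start: int          # first frame (inclusive)
    end: int            # last frame (exclusive)
    label: int          # WAITING or MOVING

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    labels: np.ndarray                  # (n_molecules, n_frames) int8
    segments: list[Segment]
    nu: float                           # switching frequency, 1/ns
    tau_w: float                        # mean waiting time, ns
    tau_m: float                        # mean moving time, ns
    moving_fraction: float              # tau_m * nu
    switch_count: int                   # raw label switches over all molecules
    dt: float                           # frame spacing, ns
    params: SegmentationParams = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def waiting_fraction(self) -> float:
        return 1.0 - self.moving_fraction


def _grow_and_label(P, times, labels, radius, rate_thr, window, n):
    """Greedy forward scan: grow maximal confined runs, label them waiting.

    Candidate runs are grown frame by frame while every member stays within
    ``radius`` of the running mean.  An upper bound on the maximum deviation
    is maintained incrementally (mean shifts are accumulated via the triangle
    inequality) and re-tightened by an exact numpy pass only when it crosses
    the radius, which keeps the scan close to linear time.
    """
    pos_arr = P
    P = P.tolist()
    i = 0
    while i <= n - window:
        x0, y0, z0 = P[i]
        sx, sy, sz = x0, y0, z0
        cnt = 1
        mx, my, mz = x0, y0, z0
        bound = 0.0
        j = i + 1
        while j < n:
            x, y, z = P[j]
            sx += x; sy += y; sz += z
            cnt += 1
            nmx = sx / cnt; nmy = sy / cnt; nmz = sz / cnt
            ddx = nmx - mx; ddy = nmy - my; ddz = nmz - mz
            shift = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            dx = x - nmx; dy = y - nmy; dz = z - nmz
            dj = math.sqrt(dx * dx + dy * dy + dz * dz)
            b = bound + shift
            if dj > b:
                b = dj
            if b >= radius:
                seg = pos_arr[i : j + 1]
                mean = seg.mean(axis=0)
                b = float(np.sqrt(((seg - mean) ** 2).sum(axis=1)).max())
                if b >= radius:
                    # frame j breaks the run; undo its contribution and stop
                    break
            bound = b
            mx, my, mz = nmx, nmy, nmz
            j += 1
        run_len = j - i
        if run_len >= window:
            dur = times[j - 1] - times[i]
            # MSD rate of the run: mean frame-to-frame squared displacement
            # per unit time (~6D when the run is secretly diffusing)
            steps = np.diff(pos_arr[i:j], axis=0)
            rate = float((steps * steps).sum()) / dur if dur > 0 else 0.0
            if rate < rate_thr:
                labels[i:j] = WAITING
            i = j
        else:
            i += 1


def _run_length_encode(labels: np.ndarray) -> list[list[int]]:
    """[[label, length], ...] in order."""
    runs = []
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            runs.append([int(labels[start]), k - start])
            start = k
    return runs


def _merge_short_runs(labels: np.ndarray, min_segment: int) -> np.ndarray:
    """Merge runs shorter than min_segment into the preceding run's label.

    A leading short run (no preceding segment) is folded into the following
    one instead.  Deterministic single forward pass.
    """
    runs = _run_length_encode(labels)
    out: list[list[int]] = []
    pending = 0
    for lab, ln in runs:
        if ln < min_segment:
            if out:
                out[-1][1] += ln
            else:
                pending += ln
            continue
        ln += pending
        pending = 0
        if out and out[-1][0] == lab:
            out[-1][1] += ln
        else:
            out.append([lab, ln])
    if pending:
        if out:
            out[-1][1] += pending
        else:  # trajectory shorter than min_segment everywhere: keep as-is
            return labels
    merged = np.empty_like(labels)
    k = 0
    for lab, ln in out:
        merged[k : k + ln] = lab
        k += ln
    return merged


def segment(traj: Trajectory, params: SegmentationParams | None = None) -> SegmentationResult:
    """Classify every molecule's frames into waiting/moving segments.

    The trajectory must be unwrapped (periodic jumps would register as
    spurious moves).  Returns per-frame labels, the segment list, and the
    pooled switching statistics.
    """
    if params is None:
        params = SegmentationParams()
    n_mol, n_frames = traj.n_molecules, traj.n_frames
    if n_frames < params.window:
        raise SegmentationError(
            f"trajectory has {n_frames} frames, fewer than window={params.window}"
        )
    if not np.all(np.isfinite(traj.positions)):
        raise SegmentationError("positions contain non-finite values")

    labels = np.full((n_mol, n_frames), MOVING, dtype=np.int8)
    times = traj.times.tolist()
    for m in range(n_mol):
        _grow_and_label(
            traj.positions[m], times, labels[m],
            params.displacement_radius, params.msd_rate_threshold,
            params.window, n_frames,
        )
        labels[m] = _merge_short_runs(labels[m], params.min_segment)

    dt = traj.dt if n_frames > 1 else 0.0
    segments: list[Segment] = []
    switch_count = 0
    wait_time = move_time = 0.0
    n_wait = n_move = 0
    for m in range(n_mol):
        start = 0
        row = labels[m]
        for k in range(1, n_frames + 1):
            if k == n_frames or row[k] != row[start]:
                seg = Segment(mol=m, start=start, end=k, label=int(row[start]))
                segments.append(seg)
                dur = seg.n_frames * dt
                if seg.label == WAITING:
                    wait_time += dur
                    n_wait += 1
                else:
                    move_time += dur
                    n_move += 1
                if k < n_frames:
                    switch_count += 1
                start = k

    tau_w = wait_time / n_wait if n_wait else 0.0
    if n_move:
        tau_m = move_time / n_move
    else:
        tau_m = 0.0
        warnings.warn(
            "no moving segments found; tau_m reported as 0", stacklevel=2
        )
    cycle = tau_w + tau_m
    nu = 1.0 / cycle if cycle > 0 else 0.0
    moving_fraction = tau_m * nu
    return SegmentationResult(
        labels=labels,
        segments=segments,
        nu=nu,
        tau_w=tau_w,
        tau_m=tau_m,
        moving_fraction=moving_fraction,
        switch_count=switch_count,
        dt=dt,
        params=params,
    )


@dataclass
class EnsembleFractions:
    """Per-frame population fractions plus the ergodicity comparison."""

    waiting: np.ndarray           # (n_frames,) fraction of molecules waiting
    moving: np.ndarray            # (n_frames,) fraction of molecules moving
    mean_moving: float            # time average of the moving population fraction
    time_fraction_moving: float   # tau_m * nu from the segmentation

    @property
    def ergodicity_gap(self) -> float:
        """|ensemble moving fraction - time moving fraction|; small when the
        process is stationary and the trajectory long."""
        return abs(self.mean_moving - self.time_fraction_moving)


def ensemble_state_fractions(seg: SegmentationResult) -> EnsembleFractions:
    """Fraction of molecules in each state per frame, with the ergodicity check.

    The time fraction of the moving phase (tau_m * nu, a single-molecule
    statistic) should agree with the ensemble fraction of moving molecules
    when the dynamics are stationary — the ergodicity assumption used to
    interpret the moving fraction as a population fraction.
    """
    moving = (seg.labels == MOVING).mean(axis=0)
    return EnsembleFractions(
        waiting=1.0 - moving,
        moving=moving,
        mean_moving=float(moving.mean()),
        time_fraction_moving=seg.moving_fraction,
    )
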