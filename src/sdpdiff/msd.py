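"""Mean-squared displacement, Fickian-regime detection, and diffusion coefficients.

MSD(lag) is averaged over every molecule and every time origin.  The diffusion
coefficient follows the 3-D Einstein relation D = slope/6 over the detected
Fickian (linear) window.  The microscopic diffusion coefficient D_mu = D / f_m
removes the waiting phases using the moving time fraction f_m = tau_m * nu,
and the apparent tortuosity is xi = D_bulk / D_mu with the bulk-water
reference D_bulk = 3.5 nm^2/ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "D_BULK_WATER",
    "MSDCurve",
    "FickianWindow",
    "DiffusionResult",
    "FickianRegimeError",
    "compute_msd",
    "detect_fickian",
    "estimate_D",
    "microscopic_D",
    "tortuosity",
    "estimate_diffusion",
]

#: bulk-water self-diffusion reference, nm^2/ns (model/temperature dependent)
D_BULK_WATER = 3.5

_DIRECT_MAX_FRAMES = 128


class FickianRegimeError(RuntimeError):
    pass


@dataclass
class MSDCurve:
    """Ensemble/time-origin averaged MSD: lags (ns), msd (nm^2), counts per lag."""

    lags: np.ndarray
    msd: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.counts = np.asarray(self.counts)

    @property
    def n_lags(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class FickianWindow:
    """Contiguous lag-index range [start, stop) where MSD grows linearly."""

    start: int
    stop: int

    @property
    def empty(self) -> bool:
        return self.stop <= self.start

    @property
    def n_lags(self) -> int:
        return max(0, self.stop - self.start)


@dataclass
class DiffusionResult:
    D: float                       # nm^2/ns
    window: FickianWindow
    loglog_slope: float            # mean local slope inside the window
    r_squared: float               # linear-fit quality on MSD vs lag
    D_mu: float | None = None      # nm^2/ns
    xi: float | None = None
    xi_inv: float | None = None
    D_bulk_ref: float = D_BULK_WATER


def _msd_direct(pos: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Plain summed-over-origins MSD; reference path for short trajectories."""
    n_mol, n_frames, _ = pos.shape
    msd = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    counts[0] = n_mol * n_frames
    for k in range(1, max_lag + 1):
        d = pos[:, k:, :] - pos[:, : n_frames - k, :]
        sq = (d * d).sum(axis=-1)
        counts[k] = sq.size
        msd[k] = np.sum(sq) / counts[k]
    return msd, counts


def _msd_fft(pos: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """FFT autocorrelation form of the origin-averaged MSD (O(N log N))."""
    n_mol, n_frames, _ = pos.shape
    X = pos.transpose(0, 2, 1).reshape(n_mol * 3, n_frames)
    F = np.fft.rfft(X, n=2 * n_frames, axis=1)
    acf = np.fft.irfft(F * np.conj(F), axis=1)[:, :n_frames]
    D2 = X * X
    c = np.cumsum(D2, axis=1)
    total = c[:, -1][:, None]
    k = np.arange(n_frames)
    # S1(k) = sum_{t<n-k} x_t^2 + sum_{t>=k} x_t^2
    lead = np.where(k > 0, np.take_along_axis(np.pad(c, ((0, 0), (1, 0))), (n_frames - k)[None, :], axis=1), total)
    tail = total - np.take_along_axis(np.pad(c, ((0, 0), (1, 0))), k[None, :], axis=1)
    S1 = lead + tail
    per_series = (S1 - 2.0 * acf) / (n_frames - k)[None, :]
    msd = per_series.reshape(n_mol, 3, n_frames).sum(axis=1).mean(axis=0)
    msd = msd[: max_lag + 1]
    msd[0] = 0.0
    counts = n_mol * (n_frames - np.arange(max_lag + 1))
    return msd, counts


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.5) -> MSDCurve:
    """MSD(lag) averaged over all molecules and all time origins.

    ``max_lag_fraction`` limits the largest lag to that fraction of the
    trajectory length; large lags are poorly averaged (few origins).
    Requires an unwrapped trajectory.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    n_frames = traj.n_frames
    if n_frames < 2:
        raise ValueError("MSD requires at least 2 frames")
    max_lag = max(1, int(np.floor((n_frames - 1) * max_lag_fraction)))
    pos = traj.positions
    if n_frames <= _DIRECT_MAX_FRAMES:
        msd, counts = _msd_direct(pos, max_lag)
    else:
        msd, counts = _msd_fft(pos, max_lag)
        msd = np.maximum(msd, 0.0)   # clip FFT round-off at tiny values
    lags = traj.dt * np.arange(max_lag + 1) if traj.dt > 0 else np.arange(max_lag + 1, dtype=float)
    return MSDCurve(lags=lags, msd=msd, counts=counts)


def detect_fickian(msd: MSDCurve, slope_tol: float = 0.1) -> FickianWindow:
    """Longest contiguous lag window with log-log slope within 1 +/- slope_tol.

    Local slopes are central differences of log(MSD) vs log(lag) at interior
    lags (lag 0 excluded).  Returns an empty window, with a warning, when no
    lag satisfies the criterion (e.g. purely ballistic motion, slope 2).
    """
    if msd.n_lags < 10:
        raise ValueError("Fickian detection requires at least 10 lags")
    lags = msd.lags[1:]
    vals = msd.msd[1:]
    ok = vals > 0
    slopes = np.full(len(vals), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        lv = np.where(ok, np.log(np.where(ok, vals, 1.0)), np.nan)
        ll = np.log(lags)
        slopes[1:-1] = (lv[2:] - lv[:-2]) / (ll[2:] - ll[:-2])
    good = np.abs(slopes - 1.0) <= slope_tol
    good &= np.isfinite(slopes)
    # longest run of True
    best_start = best_len = 0
    run_start = None
    for i, g in enumerate(np.append(good, False)):
        if g and run_start is None:
            run_start = i
        elif not g and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if best_len == 0:
        warnings.warn("no Fickian regime detected; returning empty window", stacklevel=2)
        return FickianWindow(0, 0)
    # shift by 1: slopes index i corresponds to msd index i+1
    return FickianWindow(best_start + 1, best_start + best_len + 1)


def estimate_D(
    msd: MSDCurve, window: FickianWindow, *, zero_if_empty: bool = False
) -> tuple[float, float]:
    """Least-squares slope of MSD vs lag over the window, divided by 6 (3-D).

    Returns (D, r_squared).  An empty window raises unless ``zero_if_empty``
    (then D = 0 is returned, for genuinely immobile systems).
    """
    if window.empty:
        if zero_if_empty:
            return 0.0, 1.0
        raise FickianRegimeError("no Fickian regime: cannot estimate D")
    x = msd.lags[window.start : window.stop]
    y = msd.msd[window.start : window.stop]
    if len(x) < 2:
        slope = y[0] / x[0]
        return float(slope) / 6.0, 1.0
    A = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(res[0]) if len(res) else float(((y - A @ [slope, intercept]) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope) / 6.0, r2


def microscopic_D(D: float, moving_fraction: float) -> float:
    """D_mu = D / (tau_m * nu): diffusion coefficient of the moving phase alone."""
    if not 0 < moving_fraction <= 1:
        raise ValueError(
            f"no moving phase: moving_fraction must lie in (0, 1], got {moving_fraction}"
        )
    return D / moving_fraction


def tortuosity(D_mu: float, D_bulk: float = D_BULK_WATER) -> tuple[float, float]:
    """Apparent tortuosity xi = D_bulk / D_mu and its reciprocal.

    xi_inv = D_mu / D_bulk is the normalized (bulk-referenced) diffusion
    coefficient; it is below 1 whenever confinement slows the moving phase.
    """
    if D_mu <= 0 or D_bulk <= 0:
        raise ValueError("D_mu and D_bulk must be positive")
    xi = D_bulk / D_mu
    return xi, 1.0 / xi


def estimate_diffusion(
    traj: Trajectory,
    moving_fraction: float | None = None,
    *,
    D_bulk: float = D_BULK_WATER,
    max_lag_fraction: float = 0.5,
    slope_tol: float = 0.1,
    zero_if_empty: bool = False,
) -> DiffusionResult:
    """Full pipeline: MSD -> Fickian window -> D (-> D_mu, xi when f_m given)."""
    curve = compute_msd(traj, max_lag_fraction=max_lag_fraction)
    window = detect_fickian(curve, slope_tol=slope_tol)
    D, r2 = estimate_D(curve, window, zero_if_empty=zero_if_empty)
    slope = np.nan
    if not window.empty:
        x = curve.lags[window.start : window.stop]
        y = curve.msd[window.start : window.stop]
        pos_ok = (x > 0) & (y > 0)
        if pos_ok.sum() >= 2:
            slope = float(np.polyfit(np.log(x[pos_ok]), np.log(y[pos_ok]), 1)[0])
    result = DiffusionResult(
        D=D, window=window, loglog_slope=slope, r_squared=r2, D_bulk_ref=D_bulk
    )
    if moving_fraction is not None and D > 0:
        result.D_mu = microscopic_D(D, moving_fraction)
        result.xi, result.xi_inv = tortuosity(result.D_mu, D_bulk)
    return result
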