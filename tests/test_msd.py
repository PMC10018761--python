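"""MSD estimation, Fickian-window detection, and diffusion coefficients."""

import numpy as np
import pytest

import sdpdiff as s
from sdpdiff.msd import (
    D_BULK_WATER,
    FickianRegimeError,
    FickianWindow,
    MSDCurve,
    _msd_direct,
    _msd_fft,
    compute_msd,
    detect_fickian,
    estimate_D,
    microscopic_D,
    tortuosity,
)
from sdpdiff.trajectory import Trajectory


def make_traj(pos, dt=0.1, box=1000.0):
    pos = np.asarray(pos, dtype=float)
    return Trajectory(times=np.arange(pos.shape[1]) * dt, positions=pos, box=[box] * 3)


def msd_double_loop_oracle(pos, max_lag):
    """Literal definition: average |r(t+lag) - r(t)|^2 over molecules and origins."""
    n_mol, n_frames, _ = pos.shape
    msd = np.zeros(max_lag + 1)
    for k in range(1, max_lag + 1):
        sq = []
        for m in range(n_mol):
            for t in range(n_frames - k):
                d = pos[m, t + k] - pos[m, t]
                sq.append((d * d).sum())
        msd[k] = np.sum(np.array(sq)) / len(sq)
    return msd


class TestComputeMsd:
    def test_stationary_is_zero(self):
        curve = compute_msd(make_traj(np.ones((3, 20, 3))), max_lag_fraction=1.0)
        np.testing.assert_array_equal(curve.msd, 0.0)

    def test_ballistic_closed_form(self):
        # r = v t with v = 1 nm/ns along x: MSD(lag) = lag^2 exactly
        t = np.arange(50) * 0.1
        pos = np.zeros((2, 50, 3))
        pos[:, :, 0] = t
        curve = compute_msd(make_traj(pos), max_lag_fraction=1.0)
        np.testing.assert_allclose(curve.msd, curve.lags**2, atol=1e-12)

    def test_matches_double_loop_oracle_exactly(self, rng):
        pos = rng.random((3, 5, 3))
        curve = compute_msd(make_traj(pos), max_lag_fraction=1.0)
        oracle = msd_double_loop_oracle(pos, 4)
        np.testing.assert_array_equal(curve.msd, oracle)

    def test_fft_path_equals_direct_path(self, rng):
        pos = np.cumsum(rng.normal(size=(2, 300, 3)), axis=1)
        msd_f, counts_f = _msd_fft(pos, 150)
        msd_d, counts_d = _msd_direct(pos, 150)
        np.testing.assert_allclose(msd_f, msd_d, rtol=1e-9, atol=1e-9)
        np.testing.assert_array_equal(counts_f, counts_d)

    def test_linearity_over_walker_pools(self, rng):
        a = np.cumsum(rng.normal(size=(2, 40, 3)), axis=1)
        b = np.cumsum(rng.normal(size=(3, 40, 3)), axis=1)
        msd_a = compute_msd(make_traj(a), 1.0).msd
        msd_b = compute_msd(make_traj(b), 1.0).msd
        msd_ab = compute_msd(make_traj(np.concatenate([a, b])), 1.0).msd
        np.testing.assert_allclose(msd_ab, (2 * msd_a + 3 * msd_b) / 5, rtol=1e-12)

    def test_invariant_under_translation_and_box_change(self, rng):
        pos = np.cumsum(rng.normal(size=(2, 60, 3)), axis=1)
        base = compute_msd(make_traj(pos), 1.0).msd
        shifted = compute_msd(make_traj(pos + 123.4), 1.0).msd
        other_box = compute_msd(
            Trajectory(times=np.arange(60) * 0.1, positions=pos, box=[7.0] * 3), 1.0
        ).msd
        np.testing.assert_allclose(shifted, base, rtol=1e-9, atol=1e-9)
        np.testing.assert_array_equal(other_box, base)

    def test_counts_non_increasing_and_msd_zero_at_origin(self, brownian_msd):
        assert brownian_msd.msd[0] == 0.0
        assert (np.diff(brownian_msd.counts) <= 0).all()
        assert (brownian_msd.msd >= 0).all()

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            compute_msd(make_traj(np.zeros((1, 1, 3))))


class TestFickianWindow:
    def test_brownian_window_covers_most_lags(self, brownian_msd):
        win = detect_fickian(brownian_msd)
        lags_beyond_first_decade = np.sum(brownian_msd.lags > 10 * brownian_msd.lags[1])
        assert win.n_lags >= 0.8 * lags_beyond_first_decade

    def test_ballistic_has_no_fickian_regime(self):
        t = np.arange(60) * 0.1
        pos = np.zeros((1, 60, 3))
        pos[:, :, 0] = t
        curve = compute_msd(make_traj(pos), max_lag_fraction=1.0)
        with pytest.warns(UserWarning, match="no Fickian regime"):
            win = detect_fickian(curve)
        assert win.empty

    def test_two_state_msd_is_linear_at_all_lags(self, two_state_msd, two_state_seg):
        # a stationary two-state process with memoryless dwells has an exactly
        # linear ensemble MSD, 6 * D_moving * f_m * lag, at every lag: the
        # waiting jitter plateau (~1e-3 nm^2) is negligible against it
        win = detect_fickian(two_state_msd)
        assert not win.empty
        assert win.n_lags >= 0.8 * (two_state_msd.n_lags - 1)
        D, _ = estimate_D(two_state_msd, win)
        assert D == pytest.approx(1.0 * two_state_seg.moving_fraction, rel=0.1)

    def test_requires_ten_lags(self):
        curve = MSDCurve(lags=np.arange(5.0), msd=np.arange(5.0), counts=np.ones(5))
        with pytest.raises(ValueError):
            detect_fickian(curve)


class TestDiffusionCoefficients:
    def test_exact_line_gives_unit_D(self):
        lags = np.linspace(0, 10, 50)
        curve = MSDCurve(lags=lags, msd=6 * lags, counts=np.ones(50))
        D, r2 = estimate_D(curve, FickianWindow(1, 50))
        assert D == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_empty_window_raises_or_returns_zero(self):
        curve = MSDCurve(lags=np.arange(10.0), msd=np.zeros(10), counts=np.ones(10))
        with pytest.raises(FickianRegimeError, match="no Fickian regime"):
            estimate_D(curve, FickianWindow(0, 0))
        assert estimate_D(curve, FickianWindow(0, 0), zero_if_empty=True)[0] == 0.0

    def test_brownian_recovery(self, brownian_msd):
        win = detect_fickian(brownian_msd)
        D, _ = estimate_D(brownian_msd, win)
        assert D == pytest.approx(1.0, rel=0.05)

    def test_microscopic_D(self):
        assert microscopic_D(0.5, 0.25) == 2.0
        assert microscopic_D(0.7, 1.0) == 0.7  # full mobility: D_mu = D
        with pytest.raises(ValueError, match="no moving phase"):
            microscopic_D(0.5, 0.0)

    def test_tortuosity(self):
        xi, xi_inv = tortuosity(3.5, 3.5)
        assert xi == 1.0 and xi_inv == 1.0
        xi, xi_inv = tortuosity(0.35)
        assert xi == pytest.approx(10.0)
        assert xi * xi_inv == pytest.approx(1.0)
        with pytest.raises(ValueError):
            tortuosity(0.0)

    def test_full_pipeline_on_two_state(self, two_state, two_state_seg):
        traj, _ = two_state
        res = s.estimate_diffusion(
            traj, two_state_seg.moving_fraction, max_lag_fraction=0.1
        )
        assert res.D_mu >= res.D
        assert 0 < res.xi_inv < 1  # slower than bulk water
        assert res.D_bulk_ref == D_BULK_WATER
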