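"""Acquisition model: phase cycles, bSSFP steady state, trajectories,
forward k-space synthesis."""

import numpy as np
import pytest

from naear import (
    SequenceParams,
    bssfp_signal,
    build_phantom,
    make_phase_cycles,
    make_trajectory,
    sample_kspace,
)
from naear.phantom import B0Params, PhantomSpec
from naear.nufft import nufft_forward


def bloch_steady_state(m0, t1, t2, offres, params, increment_deg, n_tr=800):
    """Independent oracle: iterate the Bloch rotations to steady state."""
    a = np.deg2rad(params.flip)
    rx = np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
    )
    tr, te = params.tr * 1e-3, params.te * 1e-3
    th = 2 * np.pi * offres * tr - np.deg2rad(increment_deg)
    e1, e2 = np.exp(-tr / (t1 * 1e-3)), np.exp(-tr / (t2 * 1e-3))
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    relax = np.diag([e2, e2, e1])
    recover = np.array([0.0, 0.0, m0 * (1 - e1)])
    m = np.array([0.0, 0.0, m0])
    for _ in range(n_tr):
        m = rot @ (relax @ (rx @ m)) + recover
    m = rx @ m
    th_w = np.arctan2(np.sin(th), np.cos(th))
    return (m[0] + 1j * m[1]) * np.exp(1j * th_w * te / tr) * np.exp(
        -te / (t2 * 1e-3)
    )


class TestPhaseCycles:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (5, [0.0, 72.0, 144.0, 216.0, 288.0]),
            (1, [0.0]),
            (4, [0.0, 90.0, 180.0, 270.0]),
        ],
    )
    def test_uniform_increments(self, n, expected):
        assert list(make_phase_cycles(n).increments) == expected

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            make_phase_cycles(0)


class TestBssfpSignal:
    params = SequenceParams()

    def test_zero_magnetisation_gives_zero_signal(self):
        assert bssfp_signal(0.0, 60.0, 55.0, 30.0, self.params, 72.0) == 0.0

    def test_periodic_in_offres_with_period_one_over_tr(self):
        period = 1.0 / (self.params.tr * 1e-3)
        for f in (-40.0, 0.0, 25.0, 90.0):
            a = bssfp_signal(1.0, 60.0, 55.0, f, self.params, 72.0)
            b = bssfp_signal(1.0, 60.0, 55.0, f + period, self.params, 72.0)
            assert abs(a - b) < 1e-9 * max(abs(a), 1.0)

    @pytest.mark.parametrize("increment", [0.0, 72.0, 144.0])
    def test_matches_bloch_iteration_at_band_and_passband(self, increment):
        """Closed-form magnitudes agree with a brute-force Bloch run to
        steady state within 1% at the band centre and in the passband."""
        tr_s = self.params.tr * 1e-3
        f_band = (np.pi + np.deg2rad(increment)) / (2 * np.pi * tr_s)
        f_pass = np.deg2rad(increment) / (2 * np.pi * tr_s)
        for f in (f_band, f_pass):
            closed = bssfp_signal(1.0, 60.0, 55.0, f, self.params, increment)
            oracle = bloch_steady_state(1.0, 60.0, 55.0, f, self.params, increment)
            assert abs(abs(closed) - abs(oracle)) <= 0.01 * abs(oracle)

    def test_band_minima_displaced_by_increment_over_360_tr(self):
        """argmin over a dense off-resonance grid shifts by (dphi/360)/TR Hz
        between consecutive phase cycles."""
        tr_s = self.params.tr * 1e-3
        freqs = np.linspace(0.0, 2.0 / tr_s, 4001)
        cycles = make_phase_cycles(5)
        minima = []
        for inc in cycles.increments:
            mags = np.abs(bssfp_signal(1.0, 60.0, 55.0, freqs, self.params, inc))
            minima.append(freqs[np.argmin(mags)])
        expected_shift = (72.0 / 360.0) / tr_s
        period = 1.0 / tr_s
        df = freqs[1] - freqs[0]
        for a, b in zip(minima, minima[1:]):
            shift = (b - a) % period
            assert abs(shift - expected_shift) <= 2 * df

    def test_nonpositive_relaxation_rejected(self):
        with pytest.raises(ValueError):
            bssfp_signal(1.0, -1.0, 55.0, 0.0, self.params, 0.0)


class TestTrajectories:
    def test_cartesian_enumerates_full_grid(self):
        params = SequenceParams(fov=240.0, resolution=2.0)
        traj = make_trajectory(params, "cartesian")
        assert traj.coords.shape[0] == 120**3
        assert len(np.unique(traj.coords[:, 0])) == 120

    @pytest.mark.parametrize("kind", ["cartesian", "radial", "cones"])
    def test_nyquist_bound_and_weight_positivity(self, small_params, kind):
        kw = {} if kind == "cartesian" else dict(n_readouts=200, samples_per_readout=24)
        traj = make_trajectory(small_params, kind, **kw)
        kmax = 1.0 / (2.0 * small_params.resolution)
        assert np.all(np.abs(traj.coords) <= kmax + 1e-12)
        assert np.all(traj.density_weights > 0)
        assert np.all(traj.timestamps >= 0)
        assert np.all(traj.timestamps <= small_params.readout_duration)

    @pytest.mark.parametrize("kind", ["radial", "cones"])
    def test_point_response_is_centre_peaked(self, small_params, kind):
        """Adjoint of uniform k-space data (a point source at the origin)
        must peak at the grid centre after density compensation."""
        from naear.nufft import nufft_adjoint

        traj = make_trajectory(
            small_params, kind, n_readouts=400, samples_per_readout=32
        )
        n = small_params.grid_size
        psf = np.abs(
            nufft_adjoint(
                np.ones(traj.coords.shape[0]),
                traj.coords,
                traj.density_weights,
                (n, n, n),
                small_params.resolution,
            )
        )
        assert np.unravel_index(np.argmax(psf), psf.shape) == (n // 2, n // 2, n // 2)
        # energy concentrates: centre value dominates the median background
        assert psf.max() > 20 * np.median(psf)

    def test_unsupported_kind_rejected(self, small_params):
        with pytest.raises(ValueError):
            make_trajectory(small_params, "spiral-galaxy")

    def test_time_per_cycle_is_readouts_times_tr(self, small_params):
        traj = make_trajectory(
            small_params, "cones", n_readouts=600, samples_per_readout=24
        )
        expected = traj.n_readouts * small_params.tr * 1e-3 / 60.0
        assert traj.time_per_cycle_min(small_params) == pytest.approx(expected)


class TestSampleKspace:
    def _uniform_phantom(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            voxel_size=2.0,
            ear_offset=16.0,
            b0_params=B0Params(amplitude_hz=0.0, boundary_amplitude_hz=0.0),
        )
        return build_phantom(spec)

    def test_cartesian_offres_free_equals_dft(self, small_params, small_cartesian):
        """With zero off-resonance and t=0 sampling the forward model is a
        plain discrete Fourier transform of the steady-state image."""
        ph = self._uniform_phantom()
        cycles = make_phase_cycles(2)
        ks = sample_kspace(ph, small_cartesian, small_params, cycles, noise_sd=0.0)
        sig = bssfp_signal(
            ph.concentration_map, ph.t1_map, ph.t2_map, ph.offres_map,
            small_params, cycles.increments[0],
        )
        expected = nufft_forward(sig, small_cartesian.coords, ph.spec.voxel_size)
        assert np.abs(ks.samples[0] - expected).max() <= 1e-10 * np.abs(expected).max()

    def test_same_seed_reproduces_samples(self, small_params, small_cones):
        ph = self._uniform_phantom()
        cycles = make_phase_cycles(3)
        a = sample_kspace(ph, small_cones, small_params, cycles, noise_sd=0.05, seed=9)
        b = sample_kspace(ph, small_cones, small_params, cycles, noise_sd=0.05, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_linear_in_m0(self, small_params, small_cones):
        ph = self._uniform_phantom()
        cycles = make_phase_cycles(2)
        a = sample_kspace(ph, small_cones, small_params, cycles, noise_sd=0.0)
        ph2 = self._uniform_phantom()
        ph2.concentration_map = 2.0 * ph2.concentration_map
        b = sample_kspace(ph2, small_cones, small_params, cycles, noise_sd=0.0)
        assert np.abs(b.samples - 2.0 * a.samples).max() <= 1e-9 * np.abs(
            b.samples
        ).max()

    def test_conjugate_symmetry_for_real_offres_free_image(self):
        """k-space of a real image is Hermitian: data(-k) = conj(data(k))."""
        rng = np.random.default_rng(4)
        img = rng.random((16, 16, 16))
        coords = rng.uniform(-0.2, 0.2, size=(500, 3))
        coords = np.concatenate([coords, -coords])
        s = nufft_forward(img, coords, 2.0)
        assert np.abs(s[500:] - np.conj(s[:500])).max() <= 1e-4 * np.abs(s).max()

    def test_trajectory_beyond_phantom_nyquist_rejected(self, small_params):
        spec = PhantomSpec(grid_shape=(24, 24, 24), voxel_size=4.0, ear_offset=20.0,
                           hydrops_fraction=(0.2, 0.2))
        ph = build_phantom(spec)
        traj = make_trajectory(
            SequenceParams(fov=96.0, resolution=2.0), "radial",
            n_readouts=50, samples_per_readout=16,
        )
        with pytest.raises(ValueError, match="Nyquist"):
            sample_kspace(ph, traj, small_params, make_phase_cycles(1))
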