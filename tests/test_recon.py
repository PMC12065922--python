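import numpy as np
import pytest
from scipy import signal

from paitwin.forward import ChannelData, Projector, SensorArray
from paitwin.recon import (Beamformer, MultispectralImage, ProcessingConfig,
                           bandpass_filter, das_reconstruct, energy_correct,
                           envelope, frame_average, reconstruct)


def _cd(samples, dt=0.025, wavelengths=None):
    samples = np.asarray(samples, dtype=float)
    if wavelengths is None:
        wavelengths = 800.0 + 10 * np.arange(samples.shape[0])
    return ChannelData(samples=samples, time_step=dt, wavelengths=wavelengths)


class TestEnergyCorrect:
    def test_unit_energies_identity(self):
        cd = _cd(np.random.default_rng(0).random((3, 4, 64)))
        out = energy_correct(cd, [1.0, 1.0, 1.0])
        assert np.array_equal(out.samples, cd.samples)

    def test_energy_two_halves_that_wavelength(self):
        cd = _cd(np.ones((2, 1, 8)))
        out = energy_correct(cd, [1.0, 2.0])
        assert np.all(out.samples[0] == 1.0)
        assert np.all(out.samples[1] == 0.5)

    def test_laser_spectrum_cancels_for_flat_absorber(self):
        # a flat absorber measured through a coloured laser spectrum
        energies = np.array([1.0, 0.7, 1.3, 0.9])
        flat = np.ones((4, 2, 16)) * energies[:, None, None]
        out = energy_correct(_cd(flat), energies)
        ratios = out.samples.mean(axis=(1, 2))
        assert np.allclose(ratios, ratios[0])

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            energy_correct(_cd(np.ones((1, 1, 8))), [0.0])


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(2048) * 0.025  # 40 MHz sampling
        tone = np.sin(2 * np.pi * 4.0 * t)
        out = bandpass_filter(_cd(tone[None, None, :]), 1.0, 7.0)
        amp = np.abs(signal.hilbert(out.samples[0, 0]))[512:1536]
        assert amp.mean() == pytest.approx(1.0, rel=0.01)

    def test_dc_removed(self):
        out = bandpass_filter(_cd(np.full((1, 1, 1024), 3.0)), 1.0, 7.0)
        assert np.abs(out.samples[0, 0, 100:-100]).max() < 1e-3

    def test_white_noise_variance_matches_response_integral(self):
        rng = np.random.default_rng(3)
        noise = rng.standard_normal((1, 8, 16384))
        out = bandpass_filter(_cd(noise), 1.0, 7.0)
        # oracle: filtfilt applies |H|^2, so output variance = mean |H|^4
        sos = signal.butter(4, [1.0, 7.0], btype="bandpass", fs=40.0,
                            output="sos")
        w, h = signal.sosfreqz(sos, worN=4096, fs=40.0)
        expected = np.mean(np.abs(h) ** 4)
        got = out.samples.var()
        assert got == pytest.approx(expected, rel=0.05)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_cd(np.zeros((1, 1, 64))), 7.0, 1.0)


class TestFrameAverage:
    def test_identical_frames_unchanged(self):
        f = _cd(np.random.default_rng(1).random((2, 3, 32)))
        out = frame_average([f, f, f, f])
        assert np.allclose(out.samples, f.samples)

    def test_noise_reduced_by_sqrt_n(self):
        rng = np.random.default_rng(2)
        frames = [_cd(rng.standard_normal((1, 1, 200_000)))
                  for _ in range(4)]
        out = frame_average(frames)
        assert out.samples.std() == pytest.approx(0.5, rel=0.02)

    def test_opposite_frames_cancel(self):
        a = _cd(np.random.default_rng(3).random((1, 2, 16)))
        b = _cd(-a.samples)
        assert np.all(frame_average([a, b]).samples == 0)


class TestDas:
    def _point_setup(self, iz=70, ix=20):
        from .test_forward import _homogeneous_phantom
        ph = _homogeneous_phantom(0.0, 0.0, nz=128, nx=64, spacing=0.2)
        array = SensorArray(n_elements=128)
        p0 = np.zeros(ph.shape)
        p0[iz, ix] = 1.0
        proj = Projector(ph, array, sos=1.5, apply_attenuation=False)
        cd = _cd(proj.project(p0)[None], dt=proj.dt, wavelengths=[800.0])
        return ph, array, cd

    def test_point_source_localized_within_one_voxel(self):
        ph, array, cd = self._point_setup(iz=70, ix=20)
        img = das_reconstruct(cd, array, ph.shape, ph.spacing, 1.5)
        env = envelope(img[0])
        peak = np.unravel_index(np.argmax(env), env.shape)
        assert abs(peak[0] - 70) <= 1 and abs(peak[1] - 20) <= 1

    def test_zero_channels_zero_image(self, small_array):
        cd = _cd(np.zeros((1, small_array.n_elements, 512)))
        img = das_reconstruct(cd, small_array, (64, 32), 0.2, 1.5)
        assert np.all(img == 0)

    def test_linearity(self):
        ph, array, cd1 = self._point_setup(iz=60, ix=30)
        _, _, cd2 = self._point_setup(iz=90, ix=40)
        both = _cd(cd1.samples + cd2.samples, dt=cd1.time_step,
                   wavelengths=[800.0])
        r1 = das_reconstruct(cd1, array, ph.shape, ph.spacing, 1.5)
        r2 = das_reconstruct(cd2, array, ph.shape, ph.spacing, 1.5)
        rb = das_reconstruct(both, array, ph.shape, ph.spacing, 1.5)
        assert np.allclose(rb, r1 + r2, atol=1e-9 * np.abs(rb).max())

    def test_amplitude_linear_in_p0(self):
        # end-to-end: envelope peak scales with the absorber's p0
        ph, array, cd = self._point_setup()
        img1 = envelope(das_reconstruct(cd, array, ph.shape, ph.spacing, 1.5))
        cd5 = _cd(5 * cd.samples, dt=cd.time_step, wavelengths=[800.0])
        img5 = envelope(das_reconstruct(cd5, array, ph.shape, ph.spacing, 1.5))
        assert img5.max() == pytest.approx(5 * img1.max(), rel=1e-9)

    def test_point_spread_consistent_with_bandwidth(self):
        from .test_forward import _homogeneous_phantom
        # fine grid so the point-spread width is not sampling-limited
        ph = _homogeneous_phantom(0.0, 0.0, nz=256, nx=64, spacing=0.05)
        array = SensorArray(n_elements=128)
        p0 = np.zeros(ph.shape)
        p0[160, 32] = 1.0
        proj = Projector(ph, array, sos=1.5, apply_attenuation=False)
        cd = _cd(proj.project(p0)[None], dt=proj.dt, wavelengths=[800.0])
        env = envelope(das_reconstruct(cd, array, ph.shape, ph.spacing, 1.5))[0]
        line = env[:, 32]
        half = line.max() / 2
        fwhm_mm = np.sum(line >= half) * ph.spacing
        # axial resolution ~ sos / (2 * bandwidth); assert within x2
        expected = 1.5 / (2 * array.center_frequency
                          * array.fractional_bandwidth)
        assert expected / 2 < fwhm_mm < expected * 2


class TestEnvelope:
    def test_pure_tone_constant(self):
        n = 256
        line = np.sin(2 * np.pi * 16 * np.arange(n) / n)  # integer cycles
        env = envelope(np.tile(line[:, None], (1, 4)))
        assert np.allclose(env[8:-8], 1.0, atol=0.02)

    def test_zeros(self):
        assert np.all(envelope(np.zeros((16, 4))) == 0)

    def test_sign_symmetric(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((64, 8))
        assert np.allclose(envelope(x), envelope(-x))

    def test_dominates_rectified_signal(self):
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.standard_normal((128, 3)), axis=0)
        x -= x.mean(axis=0)
        assert np.all(envelope(x) >= np.abs(x) - 1e-9)

    def test_nonfinite_rejected(self):
        bad = np.zeros((8, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            envelope(bad)


def test_reconstruct_produces_nonnegative_msi(node_phantom, small_array):
    proj = Projector(node_phantom, small_array)
    traces = np.stack([proj.project(node_phantom.mua[k])
                       for k in range(len(node_phantom.wavelengths))])
    cd = ChannelData(traces, proj.dt, node_phantom.wavelengths)
    msi = reconstruct(cd, small_array, node_phantom.shape,
                      node_phantom.spacing, ProcessingConfig(), sos=proj.sos)
    assert isinstance(msi, MultispectralImage)
    assert np.all(msi.pixels >= 0)
    assert msi.pixels.shape[0] == len(node_phantom.wavelengths)
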