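"""Device twin: light transport, pressure generation, acoustic detection.

Full photon Monte Carlo and wave-equation solvers are deliberately replaced
by desk-scale substitutes that preserve the mechanisms this package studies
(wavelength-dependent fluence decay, i.e. spectral coloring; weak signals
from low-blood-volume nodes; additive detector noise):

* fluence: a collimated-beam effective-attenuation model.  Each image column
  is attenuated by exp(-integral mu_eff dz) with

      mu_eff = sqrt(mua * (mua + 3 * mus'))

  which reduces exactly to Beer-Lambert when mus' = 0 and to the diffusion
  -theory effective attenuation sqrt(3 * mua * mus') in the scattering
  -dominated limit.  A small voxel Monte Carlo random walk is provided as an
  independent cross-check.

* acoustics: every voxel radiates a band-limited pulse (Gaussian-modulated
  cosine at the array centre frequency) that reaches each arc element after
  distance/sos with 1/r geometric decay; contributions superpose linearly.
  Tissue acoustic attenuation enters as a per-voxel exponential amplitude
  loss using the attenuation averaged over the overlying column.

* noise: i.i.d. additive Gaussian noise on the time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .phantoms import TissuePhantom

__all__ = [
    "IlluminationConfig",
    "FluenceField",
    "SensorArray",
    "ChannelData",
    "Projector",
    "compute_fluence",
    "monte_carlo_fluence",
    "initial_pressure",
    "forward_project",
    "add_gaussian_noise",
]


@dataclass(frozen=True)
class IlluminationConfig:
    """Collimated surface illumination entering along the depth axis.

    ``beam_center``/``beam_width`` are lateral positions in mm; a width of
    ``None`` illuminates the full lateral extent with a flat profile.
    ``surface_fluence`` is the incident normalization (1 per pulse).
    """

    beam_center: float | None = None
    beam_width: float | None = None
    surface_fluence: float = 1.0
    edge_sigma: float = 0.5  # mm, Gaussian roll-off outside the flat top

    def __post_init__(self):
        if self.beam_width is not None and self.beam_width <= 0:
            raise ValueError("beam width must be positive")
        if self.surface_fluence <= 0:
            raise ValueError("surface fluence must be positive")


@dataclass
class FluenceField:
    """Relative fluence (dimensionless) on the phantom grid."""

    values: np.ndarray
    wavelength: float
    spacing: float


@dataclass(frozen=True)
class SensorArray:
    """Arc-shaped 1D detector array in the imaging plane.

    The arc centre (geometric focus) sits at depth ``focus_depth`` on the
    lateral midline; elements span ``angular_span`` degrees symmetrically
    about the upward normal, at ``radius`` mm from the focus, above the
    tissue.  The device modelled has 256 elements at 4 MHz centre frequency.
    """

    n_elements: int = 256
    radius: float = 40.0          # mm
    angular_span: float = 125.0   # degrees
    focus_depth: float = 10.0     # mm
    center_frequency: float = 4.0  # MHz
    fractional_bandwidth: float = 1.0
    sampling_rate: float = 40.0   # MHz

    def __post_init__(self):
        if self.n_elements < 1:
            raise ValueError("need at least one element")
        band_top = self.center_frequency * (1 + self.fractional_bandwidth / 2)
        if self.sampling_rate <= 2 * band_top:
            raise ValueError("sampling rate must exceed twice the upper band edge")

    def element_positions(self, lateral_extent: float) -> np.ndarray:
        """(n_elements, 2) array of (z, x) positions in mm."""
        half = np.radians(self.angular_span) / 2
        ang = np.linspace(-half, half, self.n_elements)
        cx = lateral_extent / 2
        z = self.focus_depth - self.radius * np.cos(ang)
        x = cx + self.radius * np.sin(ang)
        return np.column_stack([z, x])

    def pulse_kernel(self) -> tuple[np.ndarray, int]:
        """Band-limited element impulse response and its centre index."""
        dt = 1.0 / self.sampling_rate
        bw = self.fractional_bandwidth
        # Gaussian envelope sigma from the -6 dB fractional bandwidth
        sigma_f = bw * self.center_frequency / (2 * np.sqrt(2 * np.log(2)))
        sigma_t = 1.0 / (2 * np.pi * sigma_f)
        half_n = int(np.ceil(4 * sigma_t / dt))
        t = (np.arange(-half_n, half_n + 1)) * dt
        kernel = np.cos(2 * np.pi * self.center_frequency * t) * np.exp(
            -0.5 * (t / sigma_t) ** 2
        )
        return kernel, half_n


@dataclass
class ChannelData:
    """Detected pressure time series, (n_wavelengths, n_elements, n_time)."""

    samples: np.ndarray
    time_step: float  # us
    wavelengths: np.ndarray

    def __post_init__(self):
        self.samples = np.atleast_3d(np.asarray(self.samples))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("channel data contains non-finite samples")

    @property
    def n_time(self) -> int:
        return self.samples.shape[-1]

    def copy(self) -> "ChannelData":
        return ChannelData(self.samples.copy(), self.time_step,
                          self.wavelengths.copy())


# ---------------------------------------------------------------------------
# fluence
# ---------------------------------------------------------------------------

def _beam_profile(illum: IlluminationConfig, nx: int, spacing: float) -> np.ndarray:
    if illum.beam_width is None:
        return np.full(nx, illum.surface_fluence)
    x = (np.arange(nx) + 0.5) * spacing
    center = illum.beam_center if illum.beam_center is not None else nx * spacing / 2
    half = illum.beam_width / 2
    d = np.abs(x - center) - half
    profile = np.where(d <= 0, 1.0, np.exp(-0.5 * (d / illum.edge_sigma) ** 2))
    return illum.surface_fluence * profile


def compute_fluence(phantom: TissuePhantom, illum: IlluminationConfig | None,
                    wavelength: float) -> FluenceField:
    """Relative fluence for one wavelength under collimated illumination.

    Evaluated at voxel centres: the column above a voxel contributes its full
    attenuation, the voxel itself half of its own.
    """
    illum = illum or IlluminationConfig()
    k = phantom.wavelength_index(wavelength)
    mua = phantom.mua[k]
    mus = phantom.mus_reduced[k]
    mu_eff = np.sqrt(mua * (mua + 3.0 * mus))
    dz = phantom.spacing
    # optical depth from the surface to each voxel centre
    tau = np.cumsum(mu_eff, axis=0) * dz - 0.5 * mu_eff * dz
    field = _beam_profile(illum, phantom.shape[1], dz)[None, :] * np.exp(-tau)
    return FluenceField(values=field, wavelength=wavelength, spacing=dz)


def monte_carlo_fluence(phantom: TissuePhantom, wavelength: float,
                        n_photons: int = 50_000, rng_seed=0) -> FluenceField:
    """Voxel Monte Carlo fluence estimate (independent cross-check).

    Photons enter at the top surface travelling along +z, random-walk with
    isotropic scattering at rate mus' (similarity approximation) and lose
    weight continuously to absorption; the track-length estimator gives the
    fluence.  Intended for small grids and qualitative comparison only.
    """
    rng = np.random.default_rng(rng_seed)
    k = phantom.wavelength_index(wavelength)
    mua = phantom.mua[k]
    mus = phantom.mus_reduced[k]
    nz, nx = phantom.shape
    dz = phantom.spacing
    deposit = np.zeros((nz, nx))
    step = dz  # substep length (one voxel)

    x = rng.uniform(0, nx * dz, n_photons)
    z = np.full(n_photons, 0.5 * dz)
    theta = np.zeros(n_photons)  # direction angle from +z axis
    w = np.ones(n_photons)
    max_steps = 6 * max(nz, nx)
    for _ in range(max_steps):
        alive = w > 1e-4
        alive &= (z >= 0) & (z < nz * dz) & (x >= 0) & (x < nx * dz)
        if not alive.any():
            break
        iz = (z[alive] / dz).astype(np.intp)
        ix = (x[alive] / dz).astype(np.intp)
        np.add.at(deposit, (iz, ix), w[alive])
        w[alive] *= np.exp(-mua[iz, ix] * step)
        scatter = rng.random(iz.size) < 1.0 - np.exp(-mus[iz, ix] * step)
        new_theta = rng.uniform(0, 2 * np.pi, iz.size)
        th = theta[alive]
        th[scatter] = new_theta[scatter]
        theta[alive] = th
        z[alive] += step * np.cos(th)
        x[alive] += step * np.sin(th)
        w[~alive] = 0.0
    # normalize: incident photons per column = n_photons / nx
    field = deposit / (n_photons / nx)
    return FluenceField(values=field, wavelength=wavelength, spacing=dz)


# ---------------------------------------------------------------------------
# initial pressure and acoustic projection
# ---------------------------------------------------------------------------

def initial_pressure(phantom: TissuePhantom, fluence: FluenceField,
                     wavelength: float) -> np.ndarray:
    """Initial pressure p0 = Gruneisen * mua * fluence (arbitrary units)."""
    k = phantom.wavelength_index(wavelength)
    if fluence.values.shape != phantom.shape:
        raise ValueError("fluence grid does not match phantom shape")
    return phantom.gruneisen * phantom.mua[k] * fluence.values


class Projector:
    """Cached voxel-to-element geometry for repeated forward projections.

    Precomputes element distances, delays and the column-averaged acoustic
    attenuation factors for one (grid, array, sos) combination so that
    per-wavelength projections reduce to a weighted histogram plus one FFT
    convolution per acquisition.
    """

    def __init__(self, phantom: TissuePhantom, array: SensorArray,
                 sos: float | None = None, apply_attenuation: bool = True):
        if sos is None:
            sos = float(np.median(phantom.sos))
        if sos <= 0:
            raise ValueError("speed of sound must be positive")
        self.array = array
        self.sos = sos
        nz, nx = phantom.shape
        dz = phantom.spacing
        zc = (np.arange(nz) + 0.5) * dz
        xc = (np.arange(nx) + 0.5) * dz
        Z, X = np.meshgrid(zc, xc, indexing="ij")
        pos = array.element_positions(nx * dz)  # (n_el, 2)
        dzs = Z.ravel()[:, None] - pos[:, 0][None, :]
        dxs = X.ravel()[:, None] - pos[:, 1][None, :]
        self.r = np.sqrt(dzs ** 2 + dxs ** 2).astype(np.float32)  # (nvox, n_el)
        dt = 1.0 / array.sampling_rate
        self.dt = dt
        delays = self.r / sos / dt  # fractional sample index
        kernel, half_n = array.pulse_kernel()
        self.kernel = kernel
        self.n_time = int(np.ceil(delays.max())) + 2 * half_n + 2
        self.idx0 = np.floor(delays).astype(np.int64)
        self.frac = (delays - self.idx0).astype(np.float32)
        rmin = dz  # avoid the 1/r singularity at co-located voxel/element
        self.inv_r = (1.0 / np.maximum(self.r, rmin)).astype(np.float32)
        if apply_attenuation:
            # attenuation (dB/MHz/cm) averaged over the column above each voxel
            att = phantom.attenuation
            col_mean = np.cumsum(att, axis=0) / (np.arange(nz)[:, None] + 1)
            db = (col_mean.ravel()[:, None] * array.center_frequency
                  * self.r / 10.0)  # r in mm -> cm
            self.att_factor = (10.0 ** (-db / 20.0)).astype(np.float32)
        else:
            self.att_factor = None

    def project(self, p0: np.ndarray) -> np.ndarray:
        """(n_elements, n_time) channel data for one initial-pressure grid."""
        amp = p0.ravel().astype(np.float32)[:, None] * self.inv_r
        if self.att_factor is not None:
            amp = amp * self.att_factor
        n_el = self.r.shape[1]
        traces = np.zeros((n_el, self.n_time + 1), dtype=np.float64)
        for e in range(n_el):
            i0 = self.idx0[:, e]
            f = self.frac[:, e]
            a = amp[:, e]
            traces[e] += np.bincount(i0, weights=a * (1 - f),
                                     minlength=self.n_time + 1)[: self.n_time + 1]
            traces[e] += np.bincount(i0 + 1, weights=a * f,
                                     minlength=self.n_time + 1)[: self.n_time + 1]
        traces = traces[:, : self.n_time]
        half_n = (len(self.kernel) - 1) // 2
        out = signal.fftconvolve(traces, self.kernel[None, :], mode="full")
        return out[:, half_n: half_n + self.n_time]


def forward_project(p0: np.ndarray, array: SensorArray,
                    phantom: TissuePhantom, sos: float | None = None,
                    wavelength: float | None = None,
                    projector: Projector | None = None,
                    apply_attenuation: bool = True) -> ChannelData:
    """Project one initial-pressure grid onto the detector array.

    Pass a prebuilt :class:`Projector` to amortize geometry across
    wavelengths and repeated phantoms of identical shape.
    """
    proj = projector or Projector(phantom, array, sos=sos,
                                  apply_attenuation=apply_attenuation)
    samples = proj.project(np.asarray(p0, dtype=float))
    wl = np.asarray([wavelength if wavelength is not None else np.nan])
    return ChannelData(samples=samples[None, :, :], time_step=proj.dt,
                       wavelengths=wl)


def add_gaussian_noise(cd: ChannelData, sigma: float, rng_seed=0) -> ChannelData:
    """Additive i.i.d. Gaussian detector noise, seed-deterministic."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    out = cd.copy()
    if sigma > 0:
        rng = np.random.default_rng(rng_seed) if not isinstance(
            rng_seed, np.random.Generator
        ) else rng_seed
        out.samples = out.samples + rng.normal(0.0, sigma, size=out.samples.shape)
    return out
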