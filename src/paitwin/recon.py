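"""Channel-data processing chain: energy correction, bandpass filtering,
frame averaging, delay-and-sum beamforming and Hilbert envelope detection.

The chain mirrors the clinical device pipeline: per-wavelength laser-energy
correction, zero-phase bandpass, a four-frame average, delay-and-sum (DAS)
with linear delay interpolation and uniform element weights, then the
analytic-signal magnitude along each depth line.  Reconstruction uses a
homogeneous speed of sound (by default the one used for projection; a
mismatched value can be passed for realism studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .forward import ChannelData, SensorArray

__all__ = [
    "ProcessingConfig",
    "MultispectralImage",
    "Beamformer",
    "energy_correct",
    "bandpass_filter",
    "frame_average",
    "das_reconstruct",
    "envelope",
    "reconstruct",
]


@dataclass(frozen=True)
class ProcessingConfig:
    """Settings of the image-formation chain."""

    band: tuple[float, float] = (1.0, 7.0)  # MHz
    frames_to_average: int = 4
    energies: dict = field(default_factory=dict)  # wavelength -> pulse energy
    sos: float | None = None  # mm/us; None = reuse the projection value
    filter_order: int = 4

    def __post_init__(self):
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.frames_to_average < 1:
            raise ValueError("need at least one frame")


@dataclass
class MultispectralImage:
    """Non-negative envelope image stack, (n_wavelengths, depth, lateral)."""

    pixels: np.ndarray
    spacing: float
    wavelengths: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (n_wavelengths, depth, lateral)")
        if self.pixels.shape[0] != self.wavelengths.size:
            raise ValueError("wavelength axis mismatch")

    def at(self, wavelength: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.wavelengths, wavelength))[0]
        if idx.size == 0:
            raise ValueError(f"wavelength {wavelength} nm not acquired")
        return self.pixels[int(idx[0])]


def energy_correct(cd: ChannelData, energies) -> ChannelData:
    """Divide each wavelength's samples by its pulse energy.

    ``energies`` maps wavelength (nm) to a positive per-pulse energy, or is a
    sequence aligned with ``cd.wavelengths``.
    """
    if isinstance(energies, dict):
        e = np.array([energies[w] for w in cd.wavelengths], dtype=float)
    else:
        e = np.asarray(energies, dtype=float)
    if e.shape != cd.wavelengths.shape:
        raise ValueError("one energy per wavelength required")
    if np.any(e <= 0):
        raise ValueError("pulse energies must be positive")
    out = cd.copy()
    out.samples = out.samples / e[:, None, None]
    return out


def bandpass_filter(cd: ChannelData, low: float, high: float,
                    order: int = 4) -> ChannelData:
    """Zero-phase Butterworth bandpass (edges in MHz) along the time axis."""
    nyq = 0.5 / cd.time_step
    if not 0 < low < high < nyq:
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / cd.time_step,
                        output="sos")
    out = cd.copy()
    out.samples = signal.sosfiltfilt(sos, out.samples, axis=-1)
    return out


def frame_average(frames: list[ChannelData]) -> ChannelData:
    """Element-wise mean over repeated acquisition frames."""
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    shape = frames[0].samples.shape
    for f in frames[1:]:
        if f.samples.shape != shape:
            raise ValueError("all frames must share one shape")
    out = frames[0].copy()
    out.samples = np.mean([f.samples for f in frames], axis=0)
    return out


class Beamformer:
    """Cached delay-and-sum geometry for a fixed grid/array/sos.

    Pixel values are the uniform-weight sum over elements of the channel
    sample at the geometric delay ``|element - pixel| / sos`` with linear
    interpolation; delays beyond the recorded time axis contribute zero
    (counted in ``n_out_of_range``).
    """

    def __init__(self, array: SensorArray, grid_shape: tuple[int, int],
                 spacing: float, sos: float, n_time: int, time_step: float):
        nz, nx = grid_shape
        zc = (np.arange(nz) + 0.5) * spacing
        xc = (np.arange(nx) + 0.5) * spacing
        Z, X = np.meshgrid(zc, xc, indexing="ij")
        pos = array.element_positions(nx * spacing)
        r = np.sqrt((Z.ravel()[:, None] - pos[:, 0]) ** 2
                    + (X.ravel()[:, None] - pos[:, 1]) ** 2)
        delays = r / sos / time_step
        self.grid_shape = grid_shape
        self.n_time = n_time
        valid = delays < n_time - 1
        self.n_out_of_range = int((~valid).sum())
        d = np.where(valid, delays, 0.0)
        self.idx0 = np.floor(d).astype(np.int64)
        self.frac = (d - self.idx0).astype(np.float32)
        self.valid = valid

    def apply(self, traces: np.ndarray) -> np.ndarray:
        """Beamform one (n_elements, n_time) array to the image grid."""
        n_el = traces.shape[0]
        el = np.arange(n_el)[None, :]
        s0 = traces[el, self.idx0]
        s1 = traces[el, self.idx0 + 1]
        vals = (s0 * (1.0 - self.frac) + s1 * self.frac) * self.valid
        return vals.sum(axis=1).reshape(self.grid_shape)


def das_reconstruct(cd: ChannelData, array: SensorArray,
                    grid_shape: tuple[int, int], spacing: float,
                    sos: float, beamformer: Beamformer | None = None) -> np.ndarray:
    """Delay-and-sum beamforming, one signed image per wavelength.

    Returns an array (n_wavelengths, depth, lateral).  Pass a prebuilt
    :class:`Beamformer` to amortize the delay tables.
    """
    bf = beamformer or Beamformer(array, grid_shape, spacing, sos,
                                  cd.n_time, cd.time_step)
    if bf.n_time != cd.n_time:
        raise ValueError("beamformer was built for a different time axis")
    return np.stack([bf.apply(cd.samples[k]) for k in range(cd.samples.shape[0])])


def envelope(image: np.ndarray) -> np.ndarray:
    """Analytic-signal magnitude along each depth line.

    Accepts (depth, lateral) or (n_wavelengths, depth, lateral) arrays; the
    Hilbert transform runs along the depth axis.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    axis = img.ndim - 2
    return np.abs(signal.hilbert(img, axis=axis))


def reconstruct(cd: ChannelData, array: SensorArray,
                grid_shape: tuple[int, int], spacing: float,
                config: ProcessingConfig | None = None,
                sos: float | None = None,
                beamformer: Beamformer | None = None) -> MultispectralImage:
    """Beamform + envelope-detect processed channel data into an MSI."""
    cfg = config or ProcessingConfig()
    c = sos if sos is not None else cfg.sos
    if c is None:
        raise ValueError("a reconstruction speed of sound is required")
    signed = das_reconstruct(cd, array, grid_shape, spacing, c, beamformer)
    return MultispectralImage(pixels=envelope(signed), spacing=spacing,
                              wavelengths=cd.wavelengths)
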