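"""Linear spectral unmixing of hemoglobin and derived functional maps.

Per pixel, the measured multispectral amplitudes over the unmixing band
(700–850 nm by default, five acquisition wavelengths) are decomposed onto
the whole-blood Hb and HbO2 endmember spectra by non-negative least squares
(concentrations are physical); sO2 = HbO2 / (Hb + HbO2) and tHb = Hb + HbO2
follow.  No fluence correction is applied before unmixing, so the spectral
-coloring bias of the measurement chain is reproduced, not removed.

For two endmembers the NNLS solution is computed in closed form: take the
unconstrained least-squares solution if it is feasible, otherwise the best
single-endmember fit — vectorised over all pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recon import MultispectralImage
from .spectra import ChromophoreSpectra, default_spectra

__all__ = [
    "UnmixResult",
    "select_unmix_wavelengths",
    "endmember_matrix",
    "linear_unmix",
    "so2_map",
    "water_proxy",
]


@dataclass
class UnmixResult:
    """Hb / HbO2 concentration maps (arbitrary units) and residuals."""

    hb: np.ndarray
    hbo2: np.ndarray
    residual: np.ndarray
    wavelengths_used: np.ndarray
    spacing: float = 1.0

    @property
    def thb(self) -> np.ndarray:
        return self.hb + self.hbo2

    @property
    def so2(self) -> np.ndarray:
        """Raw saturation ratio; NaN where tHb = 0.  See :func:`so2_map`."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.thb > 0, self.hbo2 / self.thb, np.nan)


def select_unmix_wavelengths(wavelengths, low: float = 700.0,
                             high: float = 850.0) -> np.ndarray:
    """Acquisition wavelengths inside the closed unmixing band, in order."""
    wl = np.asarray(getattr(wavelengths, "wavelengths", wavelengths), dtype=float)
    subset = wl[(wl >= low) & (wl <= high)]
    if subset.size < 2:
        raise ValueError(
            f"need at least 2 acquisition wavelengths in [{low}, {high}] nm, "
            f"found {subset.size}"
        )
    return subset


def endmember_matrix(spectra: ChromophoreSpectra, subset) -> np.ndarray:
    """(n_wavelengths, 2) matrix of [Hb, HbO2] whole-blood absorption."""
    subset = np.asarray(subset, dtype=float)
    E = np.column_stack([
        spectra.absorption("hb", subset),
        spectra.absorption("hbo2", subset),
    ])
    if np.linalg.matrix_rank(E) < 2:
        raise ValueError("endmember matrix is rank deficient over this band")
    return E


def _nnls_two(E: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised non-negative least squares for two endmembers.

    ``S`` is (n_wavelengths, n_pixels).  Returns coefficients (2, n_pixels)
    and per-pixel residual norms.
    """
    G = E.T @ E
    b = E.T @ S  # (2, npix)
    c_free = np.linalg.solve(G, b)  # unconstrained solution
    # single-endmember fallbacks, clamped at zero
    c1 = np.maximum(b[0] / G[0, 0], 0.0)
    c2 = np.maximum(b[1] / G[1, 1], 0.0)

    def resid2(c):  # squared residual per pixel for coefficient matrix (2, npix)
        fit = E @ c
        return np.sum((S - fit) ** 2, axis=0)

    sol = np.where(np.all(c_free >= 0, axis=0, keepdims=True), c_free, np.nan)
    alt1 = np.vstack([c1, np.zeros_like(c1)])
    alt2 = np.vstack([np.zeros_like(c2), c2])
    r1 = resid2(alt1)
    r2 = resid2(alt2)
    boundary = np.where(r1 <= r2, alt1, alt2)
    coeffs = np.where(np.isnan(sol), boundary, sol)
    return coeffs, np.sqrt(resid2(coeffs))


def linear_unmix(msi: MultispectralImage,
                 spectra: ChromophoreSpectra | None = None,
                 subset=None, nonnegative: bool = True) -> UnmixResult:
    """Unmix an envelope image stack into Hb and HbO2 maps.

    With ``nonnegative=False`` the plain least-squares solution is returned
    (useful as an oracle; concentrations may then be negative).
    """
    spectra = spectra or default_spectra()
    if subset is None:
        subset = select_unmix_wavelengths(msi.wavelengths)
    subset = np.asarray(subset, dtype=float)
    if subset.size < 2:
        raise ValueError("need at least as many wavelengths as endmembers (2)")
    E = endmember_matrix(spectra, subset)
    stack = np.stack([msi.at(w) for w in subset])  # (nwl, nz, nx)
    shape = stack.shape[1:]
    S = stack.reshape(subset.size, -1)
    if nonnegative:
        coeffs, resid = _nnls_two(E, S)
    else:
        coeffs, res, *_ = np.linalg.lstsq(E, S, rcond=None)
        resid = np.sqrt(np.sum((S - E @ coeffs) ** 2, axis=0))
    return UnmixResult(
        hb=coeffs[0].reshape(shape),
        hbo2=coeffs[1].reshape(shape),
        residual=resid.reshape(shape),
        wavelengths_used=subset,
        spacing=msi.spacing,
    )


def so2_map(u: UnmixResult, thb_threshold: float | None = None) -> np.ma.MaskedArray:
    """Oxygen saturation map, masked where tHb falls below a threshold.

    The default threshold is 1 % of the 99th-percentile tHb, which
    suppresses undefined ratios in signal-free background.
    """
    thb = u.thb
    if thb_threshold is None:
        thb_threshold = 0.01 * np.percentile(thb, 99)
    if thb_threshold < 0:
        raise ValueError("tHb threshold must be >= 0")
    defined = thb > max(thb_threshold, 0.0) if thb_threshold > 0 else thb > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(defined, u.hbo2 / np.where(defined, thb, 1.0), 0.0)
    return np.ma.MaskedArray(ratio, mask=~defined)


def water_proxy(msi: MultispectralImage, roi_mask: np.ndarray,
                wavelength: float = 1000.0) -> float:
    """Mean envelope amplitude over an ROI at one (acquired) wavelength.

    At and above ~1000 nm water dominates soft-tissue absorption, so this
    statistic tracks ROI water content.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    img = msi.at(wavelength)
    if roi_mask.shape != img.shape:
        raise ValueError("ROI mask does not match image shape")
    return float(img[roi_mask].mean())
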