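"""Chromophore absorption spectra of the near-infrared tissue absorbers.

The package ships one literature-derived table (``data/chromophores.csv``)
with the absorption coefficient, per mm, of whole blood (fully deoxygenated
and fully oxygenated), pure water, soft fat and cutaneous melanin over
660–1100 nm.  Spectra are evaluated by linear interpolation inside the
tabulated support; extrapolation is refused because the NIR spectra of
hemoglobin and water change qualitatively outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["ChromophoreSpectra", "CHROMOPHORES", "default_spectra"]

#: Chromophore column names in tabulation order.
CHROMOPHORES = ("hb", "hbo2", "water", "fat", "melanin")


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Tabulated absorption spectra (per mm) with linear interpolation.

    Parameters
    ----------
    wavelengths
        Strictly increasing tabulation wavelengths in nm.
    values
        Mapping chromophore name -> array of absorption coefficients
        (per mm) aligned with ``wavelengths``.
    """

    wavelengths: np.ndarray
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be a strictly increasing 1D array")
        object.__setattr__(self, "wavelengths", wl)
        vals = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for name, arr in vals.items():
            if arr.shape != wl.shape:
                raise ValueError(f"spectrum {name!r} does not match wavelength grid")
        object.__setattr__(self, "values", vals)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def absorption(self, chromophore: str, wavelength) -> np.ndarray | float:
        """Absorption coefficient (per mm) at ``wavelength`` (nm).

        Raises
        ------
        KeyError
            For an unknown chromophore.
        ValueError
            For wavelengths outside the tabulated support (no extrapolation).
        """
        if chromophore not in self.values:
            raise KeyError(f"unknown chromophore {chromophore!r}")
        wl = np.asarray(wavelength, dtype=float)
        lo, hi = self.support
        if np.any(wl < lo) or np.any(wl > hi):
            raise ValueError(
                f"wavelength {wavelength} nm outside tabulated range [{lo}, {hi}] nm"
            )
        out = np.interp(wl, self.wavelengths, self.values[chromophore])
        return float(out) if np.isscalar(wavelength) else out

    def blood_absorption(self, so2, wavelength):
        """Whole-blood absorption at oxygen saturation ``so2`` (per mm)."""
        so2 = np.asarray(so2, dtype=float)
        mua = so2 * self.absorption("hbo2", wavelength) + (1.0 - so2) * self.absorption(
            "hb", wavelength
        )
        return float(mua) if mua.ndim == 0 else mua

    def isosbestic_wavelength(self, step: float = 0.1) -> float:
        """Wavelength (nm) where Hb and HbO2 absorb equally, by dense scan."""
        lo, hi = self.support
        grid = np.linspace(lo, hi, int(round((hi - lo) / step)) + 1)
        diff = self.absorption("hb", grid) - self.absorption("hbo2", grid)
        sign = np.sign(diff)
        crossings = np.nonzero(np.diff(sign) != 0)[0]
        if crossings.size == 0:
            raise ValueError("no isosbestic point inside the tabulated range")
        i = crossings[0]
        # linear root between the bracketing grid points
        x0, x1, y0, y1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
        return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def default_spectra() -> ChromophoreSpectra:
    """Load the embedded chromophore table."""
    import pandas as pd

    path = resources.files("paitwin.data") / "chromophores.csv"
    raw = pd.read_csv(str(path), comment="#")
    return ChromophoreSpectra(
        wavelengths=raw["wavelength_nm"].to_numpy(),
        values={c: raw[c].to_numpy() for c in CHROMOPHORES},
    )
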