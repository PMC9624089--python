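"""Spectral radiometry: photon flux (PPFD/PAR) and red:far-red ratios.

Irradiance spectra are the physical description of the two light
treatments contrasted by the experiment: an unshaded treatment with a
high red:far-red (R:FR) ratio and a shaded treatment in which far-red
enrichment lowers the ratio, mimicking a canopy.  This module converts
energy spectra (W m^-2 nm^-1) into photon units and computes the two
summary statistics the design is controlled on: PAR (photosynthetically
active radiation, the photon flux integrated over 400-700 nm) and the
R:FR ratio (red band 660-670 nm over far-red band 725-735 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# CODATA exact values
AVOGADRO = 6.02214076e23  # mol^-1
PLANCK = 6.62607015e-34  # J s
LIGHT_SPEED = 2.99792458e8  # m s^-1

RED_BAND = (660.0, 670.0)
FAR_RED_BAND = (725.0, 735.0)
PAR_BAND = (400.0, 700.0)


@dataclass(frozen=True)
class SpectrumTable:
    """An irradiance spectrum on a strictly increasing wavelength grid.

    Attributes
    ----------
    wavelength : ndarray
        Wavelengths in nm, strictly increasing.
    irradiance : ndarray
        Spectral irradiance in W m^-2 nm^-1, non-negative.
    """

    wavelength: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        if wl.ndim != 1 or wl.shape != irr.shape:
            raise ValueError("wavelength and irradiance must be 1-D and equal length")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(irr < 0):
            raise ValueError("irradiance must be non-negative")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "irradiance", irr)

    @classmethod
    def from_csv(cls, path) -> "SpectrumTable":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["irradiance_W_m2_nm"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelength, "irradiance_W_m2_nm": self.irradiance}
        ).to_csv(path, index=False)


def _band_slice(spectrum: SpectrumTable, band: tuple[float, float]):
    lo, hi = band
    wl = spectrum.wavelength
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"band [{lo}, {hi}] nm outside spectrum grid [{wl[0]}, {wl[-1]}] nm")
    mask = (wl >= lo) & (wl <= hi)  # endpoints inclusive
    return wl[mask], spectrum.irradiance[mask]


def ppfd(spectrum: SpectrumTable, band: tuple[float, float] = PAR_BAND) -> float:
    """Photon flux in a wavelength band, in µmol m^-2 s^-1.

    The per-wavelength photon flux is ``Irr * lambda / (N_A * h * c)``
    (irradiance divided by the energy of one mole of photons at that
    wavelength), integrated over the band by the trapezoid rule so the
    result is stable under grid refinement.  With the default band this
    is PAR.
    """
    wl, irr = _band_slice(spectrum, band)
    if wl.size < 2:
        raise ValueError("band contains fewer than 2 grid points")
    # lambda in metres; flux density in mol m^-2 s^-1 nm^-1
    flux = irr * (wl * 1e-9) / (AVOGADRO * PLANCK * LIGHT_SPEED)
    return float(np.trapezoid(flux, wl) * 1e6)


def par(spectrum: SpectrumTable) -> float:
    """PAR: photon flux integrated over 400-700 nm (µmol m^-2 s^-1)."""
    return ppfd(spectrum, PAR_BAND)


def band_energy(spectrum: SpectrumTable, band: tuple[float, float], literal_sum: bool = False) -> float:
    """Integrated irradiance over a band (W m^-2).

    By default the grid values are integrated by the trapezoid rule;
    ``literal_sum=True`` instead adds up the sampled irradiances without
    the grid-step weight, the convention of summing spectrometer bins
    directly (grid-resolution dependent).
    """
    wl, irr = _band_slice(spectrum, band)
    if literal_sum:
        return float(irr.sum())
    if wl.size < 2:
        raise ValueError("band contains fewer than 2 grid points")
    return float(np.trapezoid(irr, wl))


def r_fr_ratio(spectrum: SpectrumTable, literal_sum: bool = False) -> float:
    """Red:far-red ratio: irradiance summed over 660-670 nm / 725-735 nm.

    Low values (≈0.3) signal canopy shade; open sky is high (≈7 under
    the red-LED treatment modelled here).  Scale-invariant: multiplying
    the spectrum by a positive constant leaves the ratio unchanged.
    """
    red = band_energy(spectrum, RED_BAND, literal_sum=literal_sum)
    far_red = band_energy(spectrum, FAR_RED_BAND, literal_sum=literal_sum)
    if far_red <= 0:
        raise ValueError("far-red band (725-735 nm) has zero energy; ratio undefined")
    return red / far_red
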