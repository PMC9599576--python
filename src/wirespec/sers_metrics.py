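"""Quality metrics for SERS substrates: band areas, relative standard
deviation of band areas along a scan, and the analyte-normalized
enhancement factor."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_core import SpectrumSet, WavenumberGrid

__all__ = ["BandWindow", "band_area", "band_areas", "rsd", "enhancement_factor"]


@dataclass(frozen=True)
class BandWindow:
    """Closed integration window ``center +- halfwidth`` in cm^-1."""

    center: float
    halfwidth: float

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")

    @property
    def lo(self) -> float:
        return self.center - self.halfwidth

    @property
    def hi(self) -> float:
        return self.center + self.halfwidth


def band_area(
    spectrum: np.ndarray, grid: WavenumberGrid, window: BandWindow
) -> float:
    """Trapezoidal integral of intensity over the band window.

    Integrates over grid points with ``lo <= nu <= hi``; the window must
    contain at least two grid points.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if spectrum.shape != (len(grid),):
        raise ValueError("spectrum length does not match grid")
    mask = (grid.values >= window.lo) & (grid.values <= window.hi)
    if mask.sum() < 2:
        raise ValueError(
            f"window [{window.lo}, {window.hi}] covers fewer than 2 grid points"
        )
    return float(np.trapezoid(spectrum[mask], grid.values[mask]))


def band_areas(spectra: SpectrumSet, window: BandWindow) -> np.ndarray:
    """Band area per spectrum of a set."""
    return np.array(
        [band_area(row, spectra.grid, window) for row in spectra.intensities]
    )


def rsd(values) -> float:
    """Relative standard deviation in percent: ``100 * sd / mean`` with
    the sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least two values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean is zero; RSD undefined")
    return float(100.0 * values.std(ddof=1) / mean)


def enhancement_factor(
    i_sers: float, c_sers: float, i_ref: float, c_ref: float
) -> float:
    """Concentration-normalized SERS enhancement factor
    ``(i_sers / c_sers) / (i_ref / c_ref)``."""
    for name, v in (
        ("i_sers", i_sers),
        ("c_sers", c_sers),
        ("i_ref", i_ref),
        ("c_ref", c_ref),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (i_sers / c_sers) / (i_ref / c_ref)
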