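"""One-dimensional spectra and their on-disk representation.

A :class:`Spectrum1D` is the common currency of the FTIR, WAXS-profile and CD
stages: a sampled signal on a strictly monotonic axis (wavenumber in cm^-1,
wavelength in nm, or scattering vector q in 1/Angstrom) with an axis-kind tag.
Spectra are stored internally with an ascending axis; descending input (the
native ordering of most FTIR instruments) is flipped on construction and the
original orientation recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Spectrum1D", "read_spectrum", "write_spectrum"]

#: recognised axis kinds and their conventional units
AXIS_UNITS = {
    "wavenumber": "cm^-1",
    "wavelength": "nm",
    "q": "1/A",
}


@dataclass
class Spectrum1D:
    """A sampled 1D signal with axis metadata.

    Parameters
    ----------
    x : array_like
        Axis values, strictly monotonic.  Stored ascending.
    y : array_like
        Intensities (absorbance, ellipticity or counts), finite.
    kind : str
        One of ``"wavenumber"``, ``"wavelength"``, ``"q"``.
    """

    x: np.ndarray
    y: np.ndarray
    kind: str = "wavenumber"
    descending_input: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or self.x.size != self.y.size:
            raise ValueError("x and y must be 1D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if self.kind not in AXIS_UNITS:
            raise ValueError(f"unknown axis kind {self.kind!r}")
        dx = np.diff(self.x)
        if np.all(dx < 0):
            self.x = self.x[::-1].copy()
            self.y = self.y[::-1].copy()
            self.descending_input = True
        elif not np.all(dx > 0):
            raise ValueError("axis must be strictly monotonic")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("intensities must be finite")

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return self.x.size

    @property
    def spacing(self) -> float:
        """Mean grid step (exact for uniform grids)."""
        return float((self.x[-1] - self.x[0]) / (self.n - 1))

    @property
    def is_uniform(self) -> bool:
        dx = np.diff(self.x)
        return bool(np.allclose(dx, dx[0], rtol=1e-8, atol=1e-10))

    def require_uniform(self, what: str = "this operation") -> None:
        if not self.is_uniform:
            raise ValueError(f"{what} requires a uniformly spaced axis")

    # -- manipulation -----------------------------------------------------
    def crop(self, lo: float, hi: float) -> "Spectrum1D":
        """Restrict to axis values in ``[lo, hi]`` (inclusive)."""
        lo, hi = sorted((lo, hi))
        sel = (self.x >= lo - 1e-12) & (self.x <= hi + 1e-12)
        if sel.sum() < 2:
            raise ValueError(f"crop window [{lo}, {hi}] keeps fewer than 2 points")
        return Spectrum1D(self.x[sel], self.y[sel], self.kind)

    def interp_at(self, x0: float) -> float:
        """Linear interpolation of the intensity at ``x0``."""
        if not (self.x[0] - 1e-12 <= x0 <= self.x[-1] + 1e-12):
            raise ValueError(f"{x0} outside axis range [{self.x[0]}, {self.x[-1]}]")
        return float(np.interp(x0, self.x, self.y))

    def integral(self) -> float:
        """Trapezoidal integral of intensity over the axis."""
        return float(np.trapezoid(self.y, self.x))

    def copy_with(self, y: np.ndarray) -> "Spectrum1D":
        return Spectrum1D(self.x.copy(), np.asarray(y, dtype=float), self.kind)


def read_spectrum(path: str | Path, kind: str = "wavenumber") -> Spectrum1D:
    """Read a two-column delimited text spectrum (``#`` comments allowed)."""
    arr = np.loadtxt(path, comments="#", delimiter=None)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return Spectrum1D(arr[:, 0], arr[:, 1], kind)


def write_spectrum(spec: Spectrum1D, path: str | Path, header: str = "") -> None:
    """Write a spectrum as two-column text with a commented header."""
    unit = AXIS_UNITS[spec.kind]
    head = f"{spec.kind} ({unit})\tintensity"
    if header:
        head = header.rstrip("\n") + "\n" + head
    np.savetxt(path, np.column_stack([spec.x, spec.y]), header=head, fmt="%.10g")
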