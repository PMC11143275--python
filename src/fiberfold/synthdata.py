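"""Synthetic data generators with bundled ground truth.

Every input stream the analysis stages consume can be generated here with a
known construction, so recovery can be tested without measured data:

* amide I absorbance spectra as sums of mixed Gaussian/Lorentzian bands over
  an anchor-line baseline,
* oriented fiber-diffraction detector images (Bragg arcs at stated d-spacings
  over a diffuse halo, flat-detector geometry, optional Poisson statistics),
* per-residue chemical-shift tables drawn around random-coil values with
  class-dependent secondary-shift offsets,
* CD spectra as convex combinations of the packaged basis curves,
* steric-zipper C-alpha lattices at a stated inter-sheet distance.

Each generator returns its product together with a :class:`SynthTruth`
carrying the generator name, exact parameters and seed; rerunning with the
same arguments reproduces the output bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ftir
from .cd import CDBasis, canonical_basis
from .nmr import RandomCoilTable, ShiftRecord, load_random_coil_table
from .seqstruct import SequenceRecord, ZipperStructure
from .spectrum import Spectrum1D
from .waxs import DetectorGeometry, DetectorImage, q_from_d, twotheta_from_d

__all__ = [
    "SynthTruth",
    "NoiseModel",
    "SynthReflection",
    "CLASS_SHIFT_OFFSETS",
    "synth_amide_spectrum",
    "synth_fiber_image",
    "bragg_share",
    "synth_shift_table",
    "synth_cd_spectrum",
    "synth_zipper_structure",
]

#: class-dependent secondary-shift offsets (ppm) used for synthesis; signs
#: follow the standard convention (CA/C' downfield in helices, CB inverted)
CLASS_SHIFT_OFFSETS = {
    "helix": {"CA": 3.0, "CB": -1.0, "C": 2.0},
    "sheet": {"CA": -2.0, "CB": 2.0, "C": -2.0},
    "coil": {"CA": 0.0, "CB": 0.0, "C": 0.0},
}


@dataclass
class SynthTruth:
    """Generator provenance: name, exact parameters and seed."""

    generator: str
    parameters: dict
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"generator": self.generator, "seed": self.seed,
                           "parameters": self.parameters},
                          indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        obj = json.loads(Path(path).read_text())
        return cls(obj["generator"], obj["parameters"], obj["seed"])


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, optional Poisson counting statistics (images
    only) and a slow baseline drift of the given amplitude."""

    sigma: float = 0.0
    poisson: bool = False
    drift_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.drift_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")


# ---------------------------------------------------------------------------
# FTIR
# ---------------------------------------------------------------------------

def synth_amide_spectrum(bands, grid=(1560.0, 1760.0, 1.0),
                         baseline: list[tuple[float, float]] | None = None,
                         noise: NoiseModel | None = None,
                         seed: int = 0) -> tuple[Spectrum1D, SynthTruth]:
    """Sum of component bands plus an anchor-line baseline plus noise.

    ``grid`` is (start, stop, step) or an explicit axis array (ascending or
    descending; the orientation is recorded).  ``baseline`` is a list of
    (wavenumber, absorbance) anchor points joined by straight lines.  Truth
    records the exact band table and the structure fractions it implies.
    """
    noise = noise or NoiseModel()
    if isinstance(grid, tuple) and len(grid) == 3:
        start, stop, step = grid
        x = np.arange(start, stop + 0.5 * abs(step), step)
    else:
        x = np.asarray(grid, dtype=float)
    descending = bool(x[0] > x[-1])
    xa = x[::-1] if descending else x
    bands = [b if isinstance(b, ftir.Band) else ftir.Band(**b) for b in bands]
    for b in bands:
        if not xa[0] <= b.center <= xa[-1]:
            raise ValueError(f"band at {b.center} cm^-1 lies outside the grid "
                             f"[{xa[0]}, {xa[-1]}]")
    y = np.zeros_like(xa)
    for b in bands:
        y += ftir.band_profile(xa, b.center, b.fwhh, b.area, b.gauss_frac)
    if baseline:
        pts = sorted(baseline)
        bx = np.array([p[0] for p in pts])
        by = np.array([p[1] for p in pts])
        y += np.interp(xa, bx, by)
    rng = np.random.default_rng(seed)
    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * math.pi)
        y += noise.drift_amplitude * np.cos(
            math.pi * (xa - xa[0]) / (xa[-1] - xa[0]) + phase)
    if noise.sigma > 0:
        y += rng.normal(0.0, noise.sigma, size=xa.size)
    spec = Spectrum1D(x if not descending else xa[::-1],
                      y if not descending else y[::-1], kind="wavenumber")
    fractions = ftir.structure_fractions(bands).as_dict() \
        if all(1590 <= b.center <= 1710 for b in bands) else None
    truth = SynthTruth("synth_amide_spectrum", {
        "bands": [{"center": b.center, "fwhh": b.fwhh, "area": b.area,
                   "gauss_frac": b.gauss_frac, "height": b.height} for b in bands],
        "baseline": baseline or [],
        "noise": {"sigma": noise.sigma, "drift": noise.drift_amplitude},
        "descending": descending,
        "fractions": fractions,
    }, seed)
    return spec, truth


# ---------------------------------------------------------------------------
# WAXS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthReflection:
    """A reflection to deposit: spacing d (Angstrom), peak amplitude
    (counts at the ring center), radial FWHM in q (Angstrom^-1), arc class
    and arc FWHM (degrees, ignored for isotropic)."""

    d: float
    amplitude: float
    fwhm_q: float = 0.05
    arc: str = "isotropic"
    arc_fwhm_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.arc not in ("meridional", "equatorial", "isotropic"):
            raise ValueError(f"unknown arc class {self.arc!r}")
        if self.d <= 0 or self.amplitude < 0 or self.fwhm_q <= 0:
            raise ValueError("d, amplitude and fwhm_q must be positive")


def _arc_factor(chi_deg: np.ndarray, arc: str, fwhm_deg: float) -> np.ndarray:
    """Azimuthal modulation, normalized to mean 1 over the full circle so the
    azimuthal average of the image reproduces the radial model."""
    if arc == "isotropic":
        return np.ones_like(chi_deg)
    center = 0.0 if arc == "meridional" else 90.0
    # folded angular distance to the arc center (arcs repeat every 180 deg)
    delta = np.abs(np.mod(chi_deg - center + 90.0, 180.0) - 90.0)
    prof = np.exp(-4.0 * math.log(2.0) * (delta / fwhm_deg) ** 2)
    # analytic mean over azimuth of the folded Gaussian
    mean = prof_mean = float(np.mean(
        np.exp(-4.0 * math.log(2.0) *
               (np.abs(np.mod(np.linspace(0, 360, 1441)[:-1] - center + 90.0, 180.0)
                       - 90.0) / fwhm_deg) ** 2)))
    return prof / mean


def synth_fiber_image(reflections, geometry: DetectorGeometry,
                      shape: tuple[int, int] = (256, 256),
                      halo: dict | None = None,
                      noise: NoiseModel | None = None,
                      seed: int = 0) -> tuple[DetectorImage, SynthTruth]:
    """Deposit Bragg arcs over a diffuse halo on a flat detector.

    ``halo`` is ``{"center_d": A, "fwhm_q": A^-1, "amplitude": counts,
    "offset": counts}`` (wide Gaussian in q plus a constant).  With
    ``noise.poisson`` the image is drawn pixel-wise from a Poisson law around
    the noiseless intensity, giving non-negative integer counts.
    """
    noise = noise or NoiseModel()
    refl = [r if isinstance(r, SynthReflection) else SynthReflection(**r)
            for r in reflections]
    for r in refl:
        if geometry.wavelength / (2.0 * r.d) >= 1.0:
            raise ValueError(f"unphysical d = {r.d} at lambda = "
                             f"{geometry.wavelength} (sin theta >= 1)")
    rmax_px = math.hypot(max(geometry.beam_center[0], shape[0] - geometry.beam_center[0]),
                         max(geometry.beam_center[1], shape[1] - geometry.beam_center[1]))
    for r in refl:
        if geometry.radius_px(r.d) > rmax_px:
            raise ValueError(f"reflection d = {r.d} falls outside a "
                             f"{shape[0]}x{shape[1]} detector")
    qmap = geometry.pixel_q(shape)
    chimap = geometry.pixel_azimuth_deg(shape)
    img = np.zeros(shape, dtype=float)
    for r in refl:
        q0 = q_from_d(r.d)
        radial = np.exp(-4.0 * math.log(2.0) * ((qmap - q0) / r.fwhm_q) ** 2)
        img += r.amplitude * radial * _arc_factor(chimap, r.arc, r.arc_fwhm_deg)
    halo = halo or {}
    if halo:
        q_h = q_from_d(halo.get("center_d", 4.5))
        fw = halo.get("fwhm_q", 1.0)
        img += halo.get("amplitude", 0.0) * np.exp(
            -4.0 * math.log(2.0) * ((qmap - q_h) / fw) ** 2)
        img += halo.get("offset", 0.0)
    rng = np.random.default_rng(seed)
    if noise.poisson:
        img = rng.poisson(img).astype(float)
    if noise.sigma > 0:
        img = np.clip(img + rng.normal(0.0, noise.sigma, size=img.shape), 0.0, None)
    truth = SynthTruth("synth_fiber_image", {
        "reflections": [{"d": r.d, "amplitude": r.amplitude, "fwhm_q": r.fwhm_q,
                         "arc": r.arc, "arc_fwhm_deg": r.arc_fwhm_deg,
                         "q": q_from_d(r.d),
                         "twotheta_deg": twotheta_from_d(r.d, geometry.wavelength)}
                        for r in refl],
        "halo": halo,
        "shape": list(shape),
        "geometry": {"wavelength": geometry.wavelength,
                     "distance_mm": geometry.distance_mm,
                     "pixel_um": geometry.pixel_um,
                     "beam_center": list(geometry.beam_center),
                     "fiber_axis": geometry.fiber_axis},
        "noise": {"sigma": noise.sigma, "poisson": noise.poisson},
    }, seed)
    return DetectorImage(img), truth


def bragg_share(truth: SynthTruth, d_range: tuple[float, float] = (3.0, 12.0)) -> float:
    """Analytic Bragg share (percent) of a :func:`synth_fiber_image`
    construction over a d window: the reflections' integrated area in the
    azimuthally averaged q profile versus reflections + halo + offset."""
    from scipy.special import erf
    p = truth.parameters
    q1, q2 = q_from_d(d_range[1]), q_from_d(d_range[0])

    def _gauss_area(amp, center, fwhm):
        s = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return amp * s * math.sqrt(2.0 * math.pi) * 0.5 * (
            erf((q2 - center) / (s * math.sqrt(2))) -
            erf((q1 - center) / (s * math.sqrt(2))))

    peaks = sum(_gauss_area(r["amplitude"], r["q"], r["fwhm_q"])
                for r in p["reflections"])
    halo = p.get("halo") or {}
    bg = 0.0
    if halo:
        bg += _gauss_area(halo.get("amplitude", 0.0),
                          q_from_d(halo.get("center_d", 4.5)),
                          halo.get("fwhm_q", 1.0))
        bg += halo.get("offset", 0.0) * (q2 - q1)
    return 100.0 * peaks / (peaks + bg)


# ---------------------------------------------------------------------------
# NMR
# ---------------------------------------------------------------------------

def synth_shift_table(sequence: SequenceRecord, labels: list[str],
                      sigma: float = 0.0, seed: int = 0,
                      table: RandomCoilTable | None = None,
                      ) -> tuple[list[ShiftRecord], SynthTruth]:
    """Draw CA/CB/C' shifts around random-coil values plus the class
    offsets of :data:`CLASS_SHIFT_OFFSETS`, with Gaussian scatter ``sigma``
    (ppm).  Labels are per residue, in {helix, sheet, coil}."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if len(labels) != len(sequence):
        raise ValueError("one label per residue required")
    bad = set(labels) - set(CLASS_SHIFT_OFFSETS)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    table = table or load_random_coil_table()
    rng = np.random.default_rng(seed)
    records = []
    for i, (aa, label) in enumerate(zip(sequence.sequence, labels)):
        idx = sequence.first_residue + i
        atoms = ("CA", "C") if aa == "G" else ("CA", "CB", "C")
        for atom in atoms:
            rc = table.shift(aa, atom)  # raises for missing reference entries
            delta = CLASS_SHIFT_OFFSETS[label][atom]
            val = rc + delta + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            records.append(ShiftRecord(index=idx, residue=aa, atom=atom,
                                       shift_ppm=val, scheme="DSS"))
    truth = SynthTruth("synth_shift_table", {
        "sequence": sequence.sequence,
        "first_residue": sequence.first_residue,
        "labels": list(labels),
        "sigma": sigma,
        "offsets": CLASS_SHIFT_OFFSETS,
    }, seed)
    return records, truth


# ---------------------------------------------------------------------------
# CD
# ---------------------------------------------------------------------------

def synth_cd_spectrum(fractions: tuple[float, float, float],
                      basis: CDBasis | None = None, sigma: float = 0.0,
                      seed: int = 0) -> tuple[Spectrum1D, SynthTruth]:
    """Convex combination f_alpha * B_alpha + f_beta * B_beta + f_coil *
    B_coil plus Gaussian noise on the basis grid."""
    fa, fb, fc = fractions
    if min(fa, fb, fc) < 0:
        raise ValueError("fractions must be non-negative")
    if abs(fa + fb + fc - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    basis = basis or canonical_basis()
    y = fa * basis.alpha + fb * basis.beta + fc * basis.coil
    rng = np.random.default_rng(seed)
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=y.size)
    spec = Spectrum1D(basis.wavelengths, y, kind="wavelength")
    truth = SynthTruth("synth_cd_spectrum", {
        "fractions": {"alpha": fa, "beta": fb, "coil": fc},
        "sigma": sigma,
    }, seed)
    return spec, truth


# ---------------------------------------------------------------------------
# steric zipper
# ---------------------------------------------------------------------------

def synth_zipper_structure(n_strands: int = 4, distance: float = 9.5,
                           strand_length: int = 6, strand_spacing: float = 4.8,
                           ca_spacing: float = 3.8, jitter: float = 0.0,
                           rotation: np.ndarray | None = None,
                           translation: np.ndarray | None = None,
                           seed: int = 0) -> tuple[ZipperStructure, SynthTruth]:
    """Two flat C-alpha sheet lattices separated by ``distance`` Angstrom
    along their common normal.

    Each sheet is an ``n_strands x strand_length`` grid (inter-strand spacing
    4.8 A, C-alpha spacing 3.8 A by default).  ``jitter`` adds Gaussian
    coordinate noise of that standard deviation; an optional rigid motion
    (rotation matrix + translation) is applied to the whole assembly.
    """
    if distance <= 0:
        raise ValueError("inter-sheet distance must be > 0")
    if n_strands < 2:
        raise ValueError("need at least 2 strands per sheet")
    xs = np.arange(strand_length) * ca_spacing
    ys = np.arange(n_strands) * strand_spacing
    gx, gy = np.meshgrid(xs, ys)
    flat = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    sheet1 = flat.copy()
    sheet2 = flat + np.array([0.0, 0.0, distance])
    rng = np.random.default_rng(seed)
    if jitter > 0:
        sheet1 = sheet1 + rng.normal(0.0, jitter, sheet1.shape)
        sheet2 = sheet2 + rng.normal(0.0, jitter, sheet2.shape)
    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        sheet1 = sheet1 @ rotation.T
        sheet2 = sheet2 @ rotation.T
    if translation is not None:
        sheet1 = sheet1 + translation
        sheet2 = sheet2 + translation
    truth = SynthTruth("synth_zipper_structure", {
        "n_strands": n_strands, "distance": distance,
        "strand_length": strand_length, "strand_spacing": strand_spacing,
        "ca_spacing": ca_spacing, "jitter": jitter,
        "rigid_motion": rotation is not None or translation is not None,
    }, seed)
    return ZipperStructure({"A": sheet1, "B": sheet2}), truth
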