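"""Wide-angle X-ray fiber diffraction reduction.

Oriented protein fibers scatter into a pattern of Bragg arcs (the
nanocrystalline fraction) superimposed on a diffuse halo (short-range order).
This module reduces a flat-detector 2D pattern to:

* an azimuthally averaged radial profile I(q), q = 4 pi sin(theta) / lambda,
* fitted reflections (pseudo-Voigt peaks over a smooth background) carrying
  d-spacing, 2theta and FWHM,
* Scherrer crystallite sizes  L = Ks * lambda / (beta * cos theta),
* the crystallinity index  Xc = 100 * sum(I) / (sum(I) + sum(B))  of summed
  Bragg versus diffuse-background intensity, and
* an orientation class per reflection (meridional / equatorial / isotropic)
  from the azimuthal intensity distribution in the reflection's radius band.

Geometry is a flat, untilted detector: a reflection of spacing d lands at
radius r = D * tan(2 theta) with sin(theta) = lambda / (2 d).  The fiber axis
is image-vertical by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .spectrum import Spectrum1D

__all__ = [
    "DetectorGeometry",
    "DetectorImage",
    "RadialProfile",
    "Reflection",
    "ScherrerParams",
    "CrystallinityResult",
    "ReflectionModel",
    "ReflectionFitResult",
    "q_from_d",
    "d_from_q",
    "d_from_twotheta",
    "twotheta_from_d",
    "azimuthal_average",
    "subtract_background_profile",
    "fit_reflections",
    "scherrer_size",
    "crystallinity_index",
    "azimuthal_class",
]


# ---------------------------------------------------------------------------
# Bragg conversions
# ---------------------------------------------------------------------------

def q_from_d(d: float | np.ndarray) -> float | np.ndarray:
    """q = 2 pi / d (Angstrom^-1)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be > 0")
    out = 2.0 * math.pi / d
    return float(out) if out.ndim == 0 else out


def d_from_q(q: float | np.ndarray) -> float | np.ndarray:
    """d = 2 pi / q (Angstrom)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    out = 2.0 * math.pi / q
    return float(out) if out.ndim == 0 else out


def d_from_twotheta(twotheta_deg: float, wavelength: float) -> float:
    """Bragg's law: d = lambda / (2 sin(theta))."""
    if not 0.0 < twotheta_deg < 180.0:
        raise ValueError("2theta must lie in (0, 180) degrees")
    return wavelength / (2.0 * math.sin(math.radians(twotheta_deg) / 2.0))


def twotheta_from_d(d: float, wavelength: float) -> float:
    """Inverse Bragg relation, in degrees."""
    s = wavelength / (2.0 * d)
    if s >= 1.0:
        raise ValueError(f"d = {d} unreachable at lambda = {wavelength} (sin theta >= 1)")
    return math.degrees(2.0 * math.asin(s))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry.

    wavelength in Angstrom (0.9996 synchrotron or 1.5418 Cu K-alpha),
    distance in mm, pixel size in micrometers, beam center in pixel
    coordinates (row, col), fiber axis along image rows ("vertical") or
    columns ("horizontal").
    """

    wavelength: float
    distance_mm: float
    pixel_um: float
    beam_center: tuple[float, float]
    fiber_axis: str = "vertical"

    def __post_init__(self) -> None:
        if min(self.wavelength, self.distance_mm, self.pixel_um) <= 0:
            raise ValueError("wavelength, distance and pixel size must be > 0")
        if self.fiber_axis not in ("vertical", "horizontal"):
            raise ValueError("fiber_axis must be 'vertical' or 'horizontal'")

    def radius_mm(self, d: float) -> float:
        """Ring radius r = D tan(2 theta) for spacing d (Angstrom)."""
        tt = math.radians(twotheta_from_d(d, self.wavelength))
        if tt >= math.pi / 2:
            raise ValueError(f"2theta >= 90 deg for d = {d}; off a flat detector")
        return self.distance_mm * math.tan(tt)

    def radius_px(self, d: float) -> float:
        return self.radius_mm(d) / (self.pixel_um * 1e-3)

    def pixel_q(self, shape: tuple[int, int]) -> np.ndarray:
        """Map each pixel to q (Angstrom^-1)."""
        rows = np.arange(shape[0])[:, None] - self.beam_center[0]
        cols = np.arange(shape[1])[None, :] - self.beam_center[1]
        r_mm = np.hypot(rows, cols) * (self.pixel_um * 1e-3)
        theta = 0.5 * np.arctan2(r_mm, self.distance_mm)
        return 4.0 * math.pi * np.sin(theta) / self.wavelength

    def pixel_azimuth_deg(self, shape: tuple[int, int]) -> np.ndarray:
        """Azimuth of each pixel, degrees in [0, 360), 0 at the fiber axis.

        With the default vertical fiber axis, 0 deg points toward smaller row
        indices (image "up"); azimuth increases counter-clockwise.
        """
        rows = np.arange(shape[0])[:, None] - self.beam_center[0]
        cols = np.arange(shape[1])[None, :] - self.beam_center[1]
        # image up = -rows; angle measured from up
        chi = np.degrees(np.arctan2(cols, -rows * np.ones_like(cols)))
        if self.fiber_axis == "horizontal":
            chi = chi - 90.0
        return np.mod(chi, 360.0)


@dataclass
class DetectorImage:
    """2D counts with an optional validity mask (True = usable pixel)."""

    counts: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity on a q grid (strictly increasing)."""

    q: np.ndarray
    intensity: np.ndarray
    counts_per_bin: np.ndarray | None = None
    empty_bins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")

    def as_spectrum(self) -> Spectrum1D:
        return Spectrum1D(self.q, self.intensity, kind="q")


@dataclass(frozen=True)
class Reflection:
    """A fitted Bragg reflection."""

    d: float                      # Angstrom
    twotheta: float               # degrees
    fwhm_twotheta: float          # radians in 2theta
    intensity: float              # integrated peak area (counts * A^-1 in q)
    azimuthal: str = "unknown"    # meridional | equatorial | isotropic

    def __post_init__(self) -> None:
        if self.fwhm_twotheta <= 0:
            raise ValueError("FWHM must be > 0")


@dataclass(frozen=True)
class ScherrerParams:
    shape_factor: float = 0.9
    instrumental_fwhm: float = 0.0  # radians in 2theta
    correction: str = "gaussian"    # or "linear"

    def __post_init__(self) -> None:
        if self.shape_factor <= 0:
            raise ValueError("shape factor must be > 0")
        if self.correction not in ("gaussian", "linear"):
            raise ValueError("correction must be 'gaussian' or 'linear'")


@dataclass(frozen=True)
class CrystallinityResult:
    bragg_intensity: float
    background_intensity: float
    xc_percent: float | None  # None when both sums vanish (undefined)


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

def azimuthal_average(image: DetectorImage, geometry: DetectorGeometry,
                      q_grid: np.ndarray | int | None = None) -> RadialProfile:
    """Azimuthal mean intensity per q bin.

    ``q_grid`` may be an explicit array of bin centers (uniform), a bin
    count, or None (defaults to 2x the half-diagonal in pixels).  Bins with
    no unmasked pixel are flagged, not zero-filled.
    """
    qmap = geometry.pixel_q(image.shape)
    qm = qmap[image.mask]
    vals = image.counts[image.mask]
    if qm.size == 0:
        raise ValueError("all pixels are masked")
    if q_grid is None or isinstance(q_grid, int):
        nbins = q_grid if isinstance(q_grid, int) else max(image.shape)
        edges = np.linspace(0.0, qm.max() * (1 + 1e-9), nbins + 1)
    else:
        centers = np.asarray(q_grid, dtype=float)
        if np.any(np.diff(centers) <= 0):
            raise ValueError("q grid must be strictly increasing")
        mid = 0.5 * (centers[1:] + centers[:-1])
        edges = np.concatenate([[centers[0] - (mid[0] - centers[0])], mid,
                                [centers[-1] + (centers[-1] - mid[-1])]])
    idx = np.digitize(qm, edges) - 1
    nbins = len(edges) - 1
    inside = (idx >= 0) & (idx < nbins)
    sums = np.bincount(idx[inside], weights=vals[inside], minlength=nbins)
    npix = np.bincount(idx[inside], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(npix > 0, sums / np.maximum(npix, 1), np.nan)
    centers = 0.5 * (edges[1:] + edges[:-1])
    empty = npix == 0
    keep = ~empty
    return RadialProfile(q=centers[keep], intensity=mean[keep],
                         counts_per_bin=npix[keep],
                         empty_bins=centers[empty])


def subtract_background_profile(profile: RadialProfile,
                                background: RadialProfile) -> tuple[RadialProfile, int]:
    """Pointwise background subtraction; negative bins clipped to zero.

    Returns the corrected profile and the number of clipped bins.
    """
    if profile.q.shape != background.q.shape or not np.allclose(profile.q, background.q):
        raise ValueError("profile and background must share the same q grid")
    diff = profile.intensity - background.intensity
    clipped = int(np.sum(diff < 0))
    return RadialProfile(profile.q, np.clip(diff, 0.0, None),
                         counts_per_bin=profile.counts_per_bin), clipped


# ---------------------------------------------------------------------------
# reflection fitting (model / results)
# ---------------------------------------------------------------------------

def _pseudo_voigt(q, center, fwhm, area, eta):
    """Area-normalised pseudo-Voigt: eta Lorentzian + (1-eta) Gaussian."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    g = area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * ((q - center) / sigma) ** 2)
    hw = fwhm / 2.0
    lor = area / math.pi * hw / ((q - center) ** 2 + hw ** 2)
    return (1.0 - eta) * g + eta * lor


class ReflectionModel:
    """Pseudo-Voigt peaks over a smooth background, fitted to I(q).

    The background is either a low-order polynomial (``background="poly"``,
    default degree 2) or a single wide Gaussian halo (``background="halo"``).
    Peak positions may be supplied as initial q guesses or found
    automatically with a prominence-based peak search.
    """

    def __init__(self, profile: RadialProfile, n_peaks: int | None = None, *,
                 init_q: list[float] | None = None, background: str = "halo",
                 poly_degree: int = 2, d_range: tuple[float, float] = (3.0, 12.0)):
        self.profile = profile
        qlo, qhi = q_from_d(d_range[1]), q_from_d(d_range[0])
        sel = (profile.q >= qlo) & (profile.q <= qhi)
        if sel.sum() < 10:
            raise ValueError("profile does not cover the requested d range")
        self.q = profile.q[sel]
        self.i = profile.intensity[sel]
        self.background = background
        self.poly_degree = poly_degree
        if init_q is None:
            init_q = self._auto_peaks(n_peaks)
        self.init_q = sorted(init_q)

    def _auto_peaks(self, n_peaks: int | None) -> list[float]:
        y = self.i
        if y.size >= 15:
            y = savgol_filter(y, 11 if y.size > 11 else (y.size // 2) * 2 - 1, 2)
        rng = float(y.max() - y.min())
        # peaks broader than a quarter of the window are background, not Bragg
        idx, props = find_peaks(y, prominence=0.02 * rng,
                                width=(None, 0.25 * y.size))
        if idx.size == 0:
            return []
        order = np.argsort(props["prominences"])[::-1]
        if n_peaks is not None:
            order = order[:n_peaks]
        return [float(self.q[i]) for i in idx[order]]

    def _make_params(self) -> lmfit.Parameters:
        p = lmfit.Parameters()
        span = self.q[-1] - self.q[0]
        scale = max(float(self.i.max()), 1e-12)
        for k, q0 in enumerate(self.init_q):
            p.add(f"c{k}", value=q0, min=q0 - 0.06 * span, max=q0 + 0.06 * span)
            p.add(f"w{k}", value=0.03 * span, min=2.0 * np.min(np.diff(self.q)),
                  max=0.5 * span)
            amp0 = max(float(np.interp(q0, self.q, self.i)) * 0.03 * span, 1e-9)
            p.add(f"a{k}", value=amp0, min=0.0)
            p.add(f"e{k}", value=0.3, min=0.0, max=1.0)
        if self.background == "halo":
            p.add("h_amp", value=0.5 * scale, min=0.0)
            p.add("h_c", value=float(self.q[np.argmax(self.i)]),
                  min=self.q[0] - span, max=self.q[-1] + span)
            p.add("h_w", value=span, min=0.3 * span, max=10.0 * span)
            p.add("h_off", value=float(self.i.min()), min=0.0)
        else:
            for j in range(self.poly_degree + 1):
                p.add(f"b{j}", value=float(self.i.min()) if j == 0 else 0.0)
        return p

    def _background_curve(self, p, q):
        if self.background == "halo":
            sig = p["h_w"].value / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            return p["h_off"].value + p["h_amp"].value * \
                np.exp(-0.5 * ((q - p["h_c"].value) / sig) ** 2)
        qc = (q - q.mean()) / (q.max() - q.min())
        return sum(p[f"b{j}"].value * qc ** j for j in range(self.poly_degree + 1))

    def _peaks_curve(self, p, q):
        out = np.zeros_like(q)
        for k in range(len(self.init_q)):
            out += _pseudo_voigt(q, p[f"c{k}"].value, p[f"w{k}"].value,
                                 p[f"a{k}"].value, p[f"e{k}"].value)
        return out

    def _residual(self, p):
        return self.i - self._peaks_curve(p, self.q) - self._background_curve(p, self.q)

    def fit(self, wavelength: float) -> "ReflectionFitResult":
        params = self._make_params()
        out = lmfit.minimize(self._residual, params, method="least_squares")
        if not out.success:
            warnings.warn("reflection fit did not converge; best-so-far returned",
                          stacklevel=2)
        p = out.params
        reflections = []
        for k in range(len(self.init_q)):
            qc, wq, area = p[f"c{k}"].value, p[f"w{k}"].value, p[f"a{k}"].value
            d = d_from_q(qc)
            tt = twotheta_from_d(d, wavelength)
            theta = math.radians(tt) / 2.0
            # local Jacobian d(2theta)/dq = lambda / (2 pi cos theta)
            fwhm_tt = wq * wavelength / (2.0 * math.pi * math.cos(theta))
            reflections.append(Reflection(d=d, twotheta=tt, fwhm_twotheta=fwhm_tt,
                                          intensity=area))
        reflections.sort(key=lambda r: r.d, reverse=True)
        return ReflectionFitResult(model=self, reflections=reflections,
                                   params=p, converged=bool(out.success),
                                   wavelength=wavelength)


@dataclass
class ReflectionFitResult:
    """Fitted reflections plus the peak/background decomposition."""

    model: ReflectionModel
    reflections: list[Reflection]
    params: lmfit.Parameters
    converged: bool
    wavelength: float

    def background_curve(self, q: np.ndarray | None = None) -> np.ndarray:
        q = self.model.q if q is None else np.asarray(q, float)
        return self.model._background_curve(self.params, q)

    def peaks_curve(self, q: np.ndarray | None = None) -> np.ndarray:
        q = self.model.q if q is None else np.asarray(q, float)
        return self.model._peaks_curve(self.params, q)

    def crystallinity(self) -> CrystallinityResult:
        """Crystallinity index over the fitted q window."""
        q = self.model.q
        si = float(np.trapezoid(self.peaks_curve(q), q))
        sb = float(np.trapezoid(self.background_curve(q), q))
        return crystallinity_index(si, sb)

    def summary(self) -> str:
        lines = ["Fiber diffraction reflection fit",
                 "=" * 56,
                 f"{'d (A)':>8} {'2theta':>8} {'FWHM(2t) rad':>13} "
                 f"{'area':>10}  class",
                 "-" * 56]
        for r in self.reflections:
            lines.append(f"{r.d:8.3f} {r.twotheta:8.3f} {r.fwhm_twotheta:13.5f} "
                         f"{r.intensity:10.4g}  {r.azimuthal}")
        xc = self.crystallinity()
        xc_s = "undefined" if xc.xc_percent is None else f"{xc.xc_percent:.1f}%"
        lines += ["-" * 56,
                  f"crystallinity index Xc = {xc_s}   converged: {self.converged}"]
        return "\n".join(lines)


def fit_reflections(profile: RadialProfile, wavelength: float,
                    n_peaks: int | None = None, *, init_d: list[float] | None = None,
                    background: str = "halo",
                    d_range: tuple[float, float] = (3.0, 12.0)) -> ReflectionFitResult:
    """Functional wrapper around :class:`ReflectionModel`."""
    init_q = None if init_d is None else [q_from_d(d) for d in init_d]
    return ReflectionModel(profile, n_peaks, init_q=init_q, background=background,
                           d_range=d_range).fit(wavelength)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def scherrer_size(reflection: Reflection, geometry: DetectorGeometry,
                  params: ScherrerParams | None = None) -> float:
    """Scherrer crystallite size L = Ks lambda / (beta cos theta), with the
    instrumental broadening removed in quadrature (or linearly)."""
    params = params or ScherrerParams()
    beta = reflection.fwhm_twotheta
    bi = params.instrumental_fwhm
    if beta <= bi:
        raise ValueError("peak FWHM does not exceed instrumental broadening")
    beta_c = math.sqrt(beta ** 2 - bi ** 2) if params.correction == "gaussian" \
        else beta - bi
    theta = math.radians(reflection.twotheta) / 2.0
    return params.shape_factor * geometry.wavelength / (beta_c * math.cos(theta))


def crystallinity_index(bragg: float, background: float) -> CrystallinityResult:
    """Xc = 100 * sum(I) / (sum(I) + sum(B))."""
    if bragg < 0 or background < 0:
        raise ValueError("intensity sums must be non-negative")
    if bragg == 0.0 and background == 0.0:
        return CrystallinityResult(0.0, 0.0, None)
    return CrystallinityResult(bragg, background,
                               100.0 * bragg / (bragg + background))


def azimuthal_class(image: DetectorImage, geometry: DetectorGeometry,
                    reflection: Reflection, *, band_frac: float = 0.05,
                    axis_tol_deg: float = 30.0, iso_variation: float = 0.2,
                    n_bins: int = 72) -> tuple[str, float | None]:
    """Classify a reflection's azimuthal intensity distribution.

    The annulus at the reflection radius (relative half-width ``band_frac``)
    is folded to half-period azimuth (arcs appear twice per turn by Friedel
    symmetry).  Class is ``meridional`` if the folded maximum lies within
    ``axis_tol_deg`` of the fiber axis, ``equatorial`` if within the same
    tolerance of the perpendicular; distributions whose azimuthal variation
    stays below ``iso_variation`` of the mean are ``isotropic``.  Returns the
    class and the arc FWHM in degrees (None for isotropic).
    """
    r_px = geometry.radius_px(reflection.d)
    rows = np.arange(image.shape[0])[:, None] - geometry.beam_center[0]
    cols = np.arange(image.shape[1])[None, :] - geometry.beam_center[1]
    r = np.hypot(rows, cols * np.ones_like(rows))
    half = max(band_frac * r_px, 1.5)
    sel = (np.abs(r - r_px) <= half) & image.mask
    if not sel.any():
        raise ValueError("reflection radius band lies outside the image")
    chi = geometry.pixel_azimuth_deg(image.shape)[sel]
    vals = image.counts[sel]
    chi_f = np.mod(chi, 180.0)  # fold Friedel pairs
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    idx = np.digitize(chi_f, edges) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    npix = np.bincount(idx, minlength=n_bins)
    ok = npix > 0
    prof = np.where(ok, sums / np.maximum(npix, 1), np.nan)
    prof = prof[ok]
    centers = (0.5 * (edges[1:] + edges[:-1]))[ok]
    mean = float(np.nanmean(prof))
    variation = float(np.nanmax(prof) - np.nanmin(prof))
    if mean > 0 and variation < iso_variation * mean:
        return "isotropic", None
    peak_chi = float(centers[int(np.nanargmax(prof))])
    # distance to axis (0/180) and to equator (90) on the folded circle
    dist_axis = min(peak_chi, 180.0 - peak_chi)
    dist_eq = abs(peak_chi - 90.0)
    # arc FWHM: width at half of (max - min) around the peak, on the folded axis
    base = float(np.nanmin(prof))
    half_h = base + 0.5 * (float(np.nanmax(prof)) - base)
    shift = np.argmax(prof)
    rolled = np.roll(prof, len(prof) // 2 - shift)
    above = rolled >= half_h
    fwhm = float(np.sum(above)) * (180.0 / n_bins)
    if dist_axis <= axis_tol_deg:
        return "meridional", fwhm
    if dist_eq <= axis_tol_deg:
        return "equatorial", fwhm
    return "isotropic", None
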