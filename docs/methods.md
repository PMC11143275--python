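# Methods

This note records the models, parameter choices and numerical decisions
behind each analysis stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Amide I band model

A component band is a convex mix of an area-normalized Gaussian and
Lorentzian of common full width at half height (FWHH):

    B(ν; c, w, A, f) = A · [ f·G(ν; c, w) + (1−f)·L(ν; c, w) ]

with center c (cm⁻¹), FWHH w > 0, area A ≥ 0 and Gaussian fraction
f ∈ [0, 1]. The fit minimizes

    SSR(absorbance) + w₂ · SSR(second derivative),   w₂ = 300 by default,

where the model's second derivative is obtained by applying the *identical*
Savitzky–Golay filter (21 points, cubic, edge handling by polynomial fit on
the terminal window) used on the data, so filter distortion cancels between
the two. No baseline is fitted; spectra are baseline-corrected beforehand by
subtracting the piecewise-linear interpolant through the spectrum's values
at fixed anchor wavenumbers (1800, 1740, 1720, 1580 cm⁻¹ for absorbance
work; 1710 and 1580 cm⁻¹ in the deconvolution protocol).

Defaults: seven bands initialized at 1696, 1682, 1660, 1650, 1632, 1624 and
1615 cm⁻¹ (three in the low-wavenumber β-sheet region), centers constrained
to ±6 cm⁻¹, FWHH to 4–60 cm⁻¹, areas non-negative, Gaussian fractions fixed
during the fit. Initial areas default to an equal share of the observed
integral — starting far off-scale sends the optimizer into secondary
minima. The optimizer (trust-region least squares via lmfit) runs with very
tight termination (ftol = xtol = gtol = 10⁻¹⁵): the objective has long,
nearly flat valleys in which overlapping bands trade area, and looser
criteria stall mid-valley with percent-level area errors even on noiseless
data.

**Identifiability caveat.** Band *areas* of overlapping components are only
well determined when the model can represent the data essentially exactly.
Smooth perturbations at the 10⁻⁵ level of the peak absorbance (noise,
residual baseline, lineshape mismatch) move the global minimum far along
the flat valleys, changing individual areas by tens of percent while class
*fractions* degrade much more slowly. This is an intrinsic property of
multi-band amide I fitting, not of this implementation; recovery tests are
therefore stated on noiseless constructions, and the degradation with noise
is monotone on average. Published analyses face the same degeneracy and
resolve it with operator-chosen constraints.

Structure fractions are class area shares: β-sheet 1610–1641 cm⁻¹ plus the
anti-parallel companion range 1690–1700 cm⁻¹ (reported separately as the
anti-parallel share), α-helix 1648–1657 cm⁻¹, everything else in 1642–1686
cm⁻¹ "other". The α range is nested inside "other"; α takes precedence
because broad irregular/turn bands are weak in second-derivative spectra
while the 1650 cm⁻¹ band is sharp. Centers outside all ranges count as
"other" with a warning.

## Fourier self-deconvolution (FSD)

Band narrowing divides out an assumed Lorentzian lineshape in the Fourier
domain. With t the conjugate variable of wavenumber, the interferogram is
multiplied by

    D(t) = exp(π γ |t|) · exp(−(π g t)² / (4 ln 2)),

which maps a Lorentzian band of FWHH γ exactly onto a Gaussian of FWHH g
with its area preserved; the resolution enhancement factor is K = γ/g
(default 20/13.33 = 1.5). The linear trend through the spectrum's endpoints
is removed before the FFT and restored afterwards, so the implicit
periodicity does not create edge ringing. If the exponential weight would
overflow on the given grid the call is rejected and the maximal safe γ
reported. The inverse operation (re-convolution) caps the inverse-filter
gain at 100: Fourier components suppressed below 1 % by the apodization
carry only rounding noise, and amplifying them without bound makes the
round-trip error grow linearly with the allowed gain (at gain 100 the
round-trip RMS error is ~3·10⁻⁴ of the spectrum range).

## β-sheet organizational index

Pipeline: FSD (γ = 20, g = 13.33) → two-point baseline subtraction (1710,
1580 cm⁻¹) → fit of 8 Gaussian bands at 1695, 1684, 1672, 1660, 1650, 1640,
1630, 1624 cm⁻¹ → index = height(1695 band) / height(1624 band). The eight
centers are *fixed* by default (configurable): with movable centers the
post-FSD decomposition is not identifiable — neighbouring bands ~6 cm⁻¹
apart trade area freely along flat valleys, which biases the height ratio
by ~10 % in the worst constructions, whereas fixed centers make the Gaussian
design matrix linearly independent and recovery accurate to ±0.015
(noiseless) and ±0.05 (2 % noise). When the 1624-band height falls below
2 % of the tallest fitted band the index is reported as undefined (NaN)
rather than as a ratio of noise amplitudes.

## WAXS reduction

Geometry is a flat, untilted detector: a spacing d diffracts at
sin θ = λ/2d and lands at radius r = D·tan 2θ; per pixel,
q = 4π sin θ/λ with θ = ½·arctan(r/D). Azimuthal averaging takes the mean
of unmasked pixel counts per q bin; empty bins are flagged, never
zero-filled, and the binning conserves total unmasked intensity exactly
(bin mean × bin count sums to the pixel total). Reflections are pseudo-Voigt
peaks over either a wide-Gaussian halo plus constant (default) or a
low-order polynomial; automatic peak seeding uses a prominence filter that
rejects candidates wider than a quarter of the analysis window (those are
background, not Bragg). Peak widths are converted from q to 2θ via the local
Jacobian d(2θ)/dq = λ/(2π cos θ).

Crystallinity X_c = 100·ΣI/(ΣI+ΣB) integrates the fitted peak and
background curves over the analysis window (default d ∈ [3, 12] Å); it is
invariant under uniform intensity rescaling. Scherrer sizes use
L = K_s λ/(β cos θ) with shape factor K_s = 0.9 (conventional for unknown
crystallite habit) and optional instrumental-broadening correction in
quadrature (Gaussian) or linear, selectable.

Orientation classes are read from the azimuthal intensity in the
reflection's radius band, folded to a half turn (Friedel symmetry):
meridional if the folded maximum lies within ±30° of the fiber axis
(image-vertical by convention), equatorial within ±30° of the
perpendicular, isotropic if the azimuthal variation stays below 20 % of the
mean; thresholds configurable. The arc FWHM is measured at half of the
(max − min) modulation.

## Chemical-shift classification

Carbon shifts on the TMS scale are converted to DSS by adding 2.67 ppm
(idempotent, exactly invertible). Secondary shifts Δδ = δ_obs − δ_rc use a
packaged random-coil table (DSS-referenced, complete over Cα/Cβ/C′ for the
20 standard residues; the asset is a swappable TSV). Votes: Cα and C′ call
helix for Δδ > τ and sheet for Δδ < −τ; Cβ uses the inverted convention;
|Δδ| ≤ τ is coil; τ = 0.7 ppm by default, a conventional chemical-shift-
index-style cutoff. The class is the strict majority of available votes;
ties and missing majorities are "ambiguous". Raising τ can only move calls
toward coil, never coil toward helix/sheet. ¹⁵N shifts are parsed and
stored but excluded from voting (poorly resolved in fiber samples).
Multiple conformers of one residue type are classified separately via an
optional conformer label.

## Sequence hotspots and zipper geometry

Hydropathy is the sliding-window mean of the Kyte–Doolittle scale,
min–max normalized over the scale extremes (poly-Ile = 1, poly-Arg = 0);
edge residues are computed on truncated windows and flagged. Steric-zipper
hotspots are hexapeptide windows with Rosetta-scale energy ≤ −23 kcal/mol
(inclusive), merged when overlapping or directly adjacent; aggregation
hotspots are maximal runs of ≥ 5 consecutive residues at ≥ 5 % propensity
(both configurable — the cutoffs are nominal since the upstream tools'
outputs are parsed, not recomputed). The consensus is the interval
intersection of the two evidence streams, annotated with mean hydropathy
and residue-count overlap against a helix annotation; the packaged CT
annotation fixes helix N4 at residues 51–80 (the peptide-verified region)
and carries nominal boundaries for the other four helices.

The inter-sheet distance of a steric zipper is defined by least-squares
plane fits (SVD) to each sheet's Cα atoms: the distance is the mean over
both unit normals of |(centroid₂ − centroid₁)·n̂|, which is exactly
invariant under rigid motions and sheet-label permutation, and degrades
gracefully (error below the jitter amplitude) under coordinate noise.
Collinear "sheets" are rejected.

Peptide masses sum residue masses plus water, with terminal-modification
deltas of +42.0367 Da (average; +42.0106 monoisotopic) for N-acetylation
and −0.9848 Da (−0.98402) for C-amidation; a disulfide-linked homodimer
weighs 2M − 2.016 Da (loss of two hydrogens).

## CD unmixing

The packaged basis consists of smooth sums of Gaussian bands constructed to
the canonical far-UV signatures: the α curve has equal minima at 208 and
222 nm and a positive band at 193 nm, the β curve a single minimum at
217 nm with a positive band at 196 nm, the coil curve a deep minimum at
198 nm; amplitudes mirror typical mean-residue-ellipticity proportions.
This three-component estimator is a deliberately simple surrogate for
reference-set deconvolution and is labelled as such. Fractions are obtained
by non-negative least squares with the sum-to-one constraint built into the
solve as a heavily weighted extra row, then renormalized exactly. Building
the constraint in (rather than renormalizing a free NNLS solution) removes
most of the clipping bias that appears on noisy spectra whenever a true
fraction is near zero. Because canonical α and β curves are strongly
correlated (cosine ≈ 0.88 on this grid), per-spectrum fraction scatter at
5 % noise is of order 0.03–0.07; ensemble means over ~20 spectra recover
the truth to better than ±0.02. Unmixing is exact on noiseless convex
combinations, and a synthetic α→β titration yields strictly monotone
estimated β fractions.

## Synthetic data

The generators produce: amide spectra as exact band sums plus optional
anchor-line baselines, cosine drift and Gaussian noise; detector images by
depositing radial Gaussian profiles in q with azimuthal arc modulation
(normalized to mean 1 over the circle so azimuthal averaging reproduces the
radial model), a wide-Gaussian halo, and optional Poisson statistics;
shift tables around random-coil values with class offsets of
(Cα +3, Cβ −1, C′ +2) ppm for helix and (−2, +2, −2) for sheet — generator
constants recorded in the truth file, consistent in sign with standard
secondary-shift conventions; CD spectra as convex basis combinations; and
zipper lattices as two flat Cα grids (3.8 Å along strands, 4.8 Å between
strands) at a stated separation. Every generator is bit-reproducible from
(parameters, seed) and serializes its ground truth alongside the data.

What the generators do *not* emulate: water-vapor interference and ATR
penetration-depth effects in FTIR; detector tilt, polarization/absorption
corrections and texture in WAXS; peak overlap and assignment ambiguity in
NMR; concentration/path-length calibration in CD. Passing recovery tests
therefore demonstrates correctness of the analysis chain under its stated
model, not robustness to every artifact of measured data.

Noise defaults are nominal (the protocols this package follows do not
characterize their noise levels) and configurable everywhere. The bundled
end-to-end demonstration uses a noiseless amide spectrum — see the
identifiability caveat above — Poisson-noisy diffraction images, 0.2 ppm
shift scatter and mild CD noise.

## Problem sizes

Default test and demonstration sizes: 201-point spectra (1 cm⁻¹ grid),
512×512 (tests) or 384×384 (bundle) detector frames, 100-residue shift
tables, 71-point CD grids. These sizes keep the full recovery suite to
well under a minute per modality while leaving every estimator's behaviour
unchanged at larger inputs.
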