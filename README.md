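# fiberfold

Quantitative solid-state structural analysis of silk-like protein fibers.

Spider silk proteins (spidroins) convert from a largely α-helical soluble
state into β-sheet-rich fibers. Establishing that conversion quantitatively
requires several solid-state modalities read side by side: infrared
spectroscopy of the amide I band, wide-angle X-ray fiber diffraction,
solid-state NMR chemical shifts, sequence-level fibrillation predictors and
circular dichroism of designed peptides. `fiberfold` implements the complete
analysis chain for all five modalities, together with synthetic-data
generators that produce every input stream with known ground truth, so each
stage is testable end to end without measured data.

## What it computes

**FTIR (amide I, 1600–1700 cm⁻¹).** Straight-line baseline subtraction
through fixed anchors; Savitzky–Golay second derivatives (21-point window);
a simultaneous least-squares fit of mixed Gaussian/Lorentzian component
bands to the spectrum *and* its second derivative (derivative residual
weighted ×300); secondary-structure fractions from relative band areas
(β-sheet 1610–1641 and 1690–1700 cm⁻¹, α-helix 1648–1657 cm⁻¹, other
1642–1686 cm⁻¹); Fourier self-deconvolution (Lorentzian FWHH γ = 20 cm⁻¹
divided out, Gaussian apodization FWHH g = 13.33 cm⁻¹, resolution
enhancement K = γ/g = 1.5); and the β-sheet organizational index — the
height ratio of the ~1695 and ~1624 cm⁻¹ β-sheet bands after an 8-band fit,
which separates anti-parallel (0.2–0.3) from parallel (≤ 0.05) sheet
packing.

**WAXS.** Flat-detector azimuthal averaging (r = D·tan 2θ,
q = 4π sin θ/λ); pseudo-Voigt reflection fitting over a diffuse halo;
d-spacings via Bragg's law; crystallinity index
X_c = 100·ΣI/(ΣI + ΣB) from the fitted Bragg vs background areas; Scherrer
crystallite sizes L = K_s·λ/(β cos θ); and per-reflection orientation
classes (meridional/equatorial/isotropic) from the azimuthal intensity in
the reflection's radius band.

**NMR.** TMS↔DSS referencing (carbon scales differ by 2.67 ppm); secondary
shifts Δδ = δ_obs − δ_rc against a packaged random-coil table; helix/sheet/
coil calls by a majority vote over Cα/Cβ/C′ (Cα, C′ positive Δδ → helix;
Cβ inverted; threshold τ = 0.7 ppm), with support for multiple conformers
of one residue type.

**Sequence.** Normalized Kyte–Doolittle hydropathy profiles; fibrillation
hotspots from steric-zipper energies (threshold ≤ −23 kcal/mol, inclusive)
and aggregation propensity runs; their interval-intersection consensus
annotated with helix overlaps; inter-sheet distances of zipper structures by
least-squares plane fits; peptide masses with acetyl/amide termini and
disulfide-linked dimers.

**CD.** Savitzky–Golay smoothing (7-point window), minima detection, and
three-component fraction unmixing by sum-constrained non-negative least
squares against packaged α/β/coil basis curves (α minima at 208/222 nm,
β minimum at 217 nm).

A configuration-driven pipeline (`fiberfold.report`) runs any subset of the
stages and assembles a deterministic JSON report with descriptive
cross-modality consistency flags.

## Worked example

Generate a complete synthetic bundle (a β-rich fiber-like state across all
five modalities) and run the pipeline on it:

```sh
fiberfold synth bundle --outdir demo --seed 1
fiberfold run --config demo/pipeline.yaml --base-dir demo
```

The report (abridged) prints:

```json
{
  "consistency": {
    "ftir_nmr_beta": true,
    "parallel_sheet_prevalence": true,
    "waxs_hotspot_intersheet": true
  },
  "sections": {
    "ftir": {
      "fractions": {"beta": 0.48, "alpha": 0.37, "other": 0.15},
      "organizational_index": 0.095
    },
    "waxs": {
      "reflections": [{"d": 9.75, "azimuthal_class": "equatorial"},
                      {"d": 4.59, "azimuthal_class": "meridional"},
                      {"d": 3.88, "azimuthal_class": "isotropic"}],
      "crystallinity_percent": 11.8
    },
    "nmr": {"class_counts": {"sheet": 61, "helix": 25, "coil": 10}},
    "seq": {"consensus_hotspots": [{"start": 56, "end": 74,
                                    "helix_overlap": {"N4": 19}}],
            "intersheet_distance": 9.8},
    "cd": {"fractions": {"alpha": 0.15, "beta": 0.70, "coil": 0.15},
           "minima_nm": [219.0]}
  }
}
```

Reading it: the amide I decomposition finds 48% β-sheet with an
organizational index ≈ 0.1 (parallel-sheet prevalence); the diffraction
pattern shows the amyloid-like ~9.75 Å inter-sheet and 4.59 Å inter-strand
spacings; most residues carry β-sheet chemical shifts; the sequence evidence
places the fibrillation hotspot inside the annotated helix 4 (residues
51–80); and the CD spectrum unmixes to a β-dominated state with a single
minimum at 219 nm. The three consistency flags record that the modalities
agree. All numbers match the generator ground truth bundled next to each
input file (`*.truth.json`).

The same stages are available from Python, e.g.

```python
from fiberfold import ftir, synthdata

spec, truth = synthdata.synth_amide_spectrum(
    [ftir.Band(1650, 22, 0.6), ftir.Band(1624, 18, 0.4)])
fit = ftir.fit_band_model(spec)
print(fit.summary())
```

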