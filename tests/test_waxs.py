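import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fiberfold import synthdata, waxs
from fiberfold.synthdata import NoiseModel, SynthReflection


class TestBraggConversions:
    def test_q_two_pi_gives_unit_d(self):
        assert waxs.d_from_q(2.0 * math.pi) == pytest.approx(1.0)

    def test_cu_kalpha_twotheta_for_4p4(self):
        tt = waxs.twotheta_from_d(4.4, 1.5418)
        assert tt == pytest.approx(20.18, abs=0.01)
        assert waxs.d_from_twotheta(tt, 1.5418) == pytest.approx(4.4, rel=1e-12)

    @pytest.mark.parametrize("d", [3.74, 5.1, 9.67])
    def test_q_d_round_trip(self, d):
        assert waxs.d_from_q(waxs.q_from_d(d)) == pytest.approx(d, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            waxs.d_from_q(-1.0)
        with pytest.raises(ValueError):
            waxs.twotheta_from_d(0.5, 1.5418)  # sin(theta) > 1


class TestAzimuthalAverage:
    def test_uniform_image_gives_constant_profile(self, synchrotron_geometry):
        img = waxs.DetectorImage(np.full((128, 128), 4.0))
        geom = waxs.DetectorGeometry(0.9996, 76.3, 102.0, (64.0, 64.0))
        prof = waxs.azimuthal_average(img, geom, 50)
        np.testing.assert_allclose(prof.intensity, 4.0)

    def test_single_ring_maximum_at_2pi_over_d(self, synchrotron_geometry):
        img, _ = synthdata.synth_fiber_image(
            [SynthReflection(4.4, 100.0, 0.05)], synchrotron_geometry, shape=(512, 512))
        prof = waxs.azimuthal_average(img, synchrotron_geometry)
        qmax = prof.q[np.argmax(prof.intensity)]
        dq = np.median(np.diff(prof.q))
        assert abs(qmax - 2.0 * math.pi / 4.4) <= dq

    def test_two_rings_resolved_and_ordered(self, synchrotron_geometry):
        img, _ = synthdata.synth_fiber_image(
            [SynthReflection(9.75, 80.0, 0.05), SynthReflection(4.59, 100.0, 0.05)],
            synchrotron_geometry, shape=(512, 512))
        prof = waxs.azimuthal_average(img, synchrotron_geometry)
        from scipy.signal import find_peaks
        idx, _ = find_peaks(prof.intensity, prominence=10.0)
        qs = prof.q[idx]
        assert len(qs) == 2
        assert qs[0] == pytest.approx(waxs.q_from_d(9.75), abs=0.01)
        assert qs[1] == pytest.approx(waxs.q_from_d(4.59), abs=0.01)

    def test_masked_bins_flagged_not_zero_filled(self, synchrotron_geometry):
        img = waxs.DetectorImage(np.ones((64, 64)),
                                 mask=np.zeros((64, 64), dtype=bool))
        img.mask[:16, :16] = True
        geom = waxs.DetectorGeometry(0.9996, 76.3, 102.0, (32.0, 32.0))
        prof = waxs.azimuthal_average(img, geom, 40)
        assert prof.empty_bins is not None and prof.empty_bins.size > 0
        assert np.all(np.isfinite(prof.intensity))

    @given(st.integers(0, 10_000))
    def test_total_intensity_conserved(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(32, 80)), int(rng.integers(32, 80)))
        counts = rng.uniform(0, 100, shape)
        mask = rng.random(shape) > 0.1
        img = waxs.DetectorImage(counts, mask=mask)
        geom = waxs.DetectorGeometry(0.9996, 76.3, 102.0,
                                     (shape[0] / 2.0, shape[1] / 2.0))
        prof = waxs.azimuthal_average(img, geom, int(rng.integers(10, 60)))
        total = counts[mask].sum()
        binned = float(np.sum(prof.intensity * prof.counts_per_bin))
        assert binned == pytest.approx(total, rel=1e-6)


class TestBackgroundSubtraction:
    def test_profile_minus_itself_is_zero(self):
        prof = waxs.RadialProfile(np.linspace(0.5, 2.0, 50), np.random.default_rng(0).uniform(1, 5, 50))
        out, clipped = waxs.subtract_background_profile(prof, prof)
        np.testing.assert_allclose(out.intensity, 0.0)
        assert clipped == 0

    def test_excess_background_clipped_and_counted(self):
        q = np.linspace(0.5, 2.0, 10)
        a = waxs.RadialProfile(q, np.full(10, 2.0))
        b = waxs.RadialProfile(q, np.array([1.0] * 5 + [3.0] * 5))
        out, clipped = waxs.subtract_background_profile(a, b)
        assert clipped == 5
        assert np.all(out.intensity >= 0)

    def test_grid_mismatch_rejected(self):
        a = waxs.RadialProfile(np.linspace(0.5, 2.0, 10), np.ones(10))
        b = waxs.RadialProfile(np.linspace(0.5, 2.1, 10), np.ones(10))
        with pytest.raises(ValueError, match="grid"):
            waxs.subtract_background_profile(a, b)

    def test_halo_subtraction_recovers_peak_area(self, synchrotron_geometry):
        halo = {"center_d": 4.8, "fwhm_q": 1.1, "amplitude": 60.0, "offset": 3.0}
        sig, truth = synthdata.synth_fiber_image(
            [SynthReflection(4.59, 100.0, 0.08)], synchrotron_geometry,
            shape=(384, 384), halo=halo)
        bg, _ = synthdata.synth_fiber_image([], synchrotron_geometry,
                                            shape=(384, 384), halo=halo)
        p_sig = waxs.azimuthal_average(sig, synchrotron_geometry, 400)
        p_bg = waxs.azimuthal_average(bg, synchrotron_geometry, 400)
        corrected, _ = waxs.subtract_background_profile(p_sig, p_bg)
        area = np.trapezoid(corrected.intensity, corrected.q)
        # analytic peak area: amplitude * fwhm_q * sqrt(pi / (4 ln 2))
        expect = 100.0 * 0.08 * math.sqrt(math.pi / (4 * math.log(2)))
        assert area == pytest.approx(expect, rel=0.05)


class TestReflectionFit:
    def test_single_peak_d_within_half_percent(self, synchrotron_geometry):
        img, _ = synthdata.synth_fiber_image(
            [SynthReflection(4.59, 100.0, 0.08)], synchrotron_geometry,
            shape=(512, 512), halo={"center_d": 4.8, "fwhm_q": 1.2, "amplitude": 50.0, "offset": 3.0})
        prof = waxs.azimuthal_average(img, synchrotron_geometry)
        fit = waxs.fit_reflections(prof, synchrotron_geometry.wavelength, init_d=[4.59])
        assert fit.reflections[0].d == pytest.approx(4.59, rel=0.005)

    def test_pure_halo_yields_no_reflections(self, synchrotron_geometry):
        img, _ = synthdata.synth_fiber_image(
            [], synchrotron_geometry, shape=(384, 384),
            halo={"center_d": 4.8, "fwhm_q": 1.5, "amplitude": 50.0, "offset": 3.0})
        prof = waxs.azimuthal_average(img, synchrotron_geometry)
        fit = waxs.fit_reflections(prof, synchrotron_geometry.wavelength)
        assert fit.reflections == []

    def test_ct_like_triplet_recovered(self, synchrotron_geometry):
        img, _ = synthdata.synth_fiber_image(
            [SynthReflection(9.75, 60.0, 0.06), SynthReflection(4.59, 100.0, 0.08),
             SynthReflection(3.88, 50.0, 0.08)], synchrotron_geometry,
            shape=(512, 512), halo={"center_d": 4.8, "fwhm_q": 1.2, "amplitude": 100.0, "offset": 5.0})
        prof = waxs.azimuthal_average(img, synchrotron_geometry)
        fit = waxs.fit_reflections(prof, synchrotron_geometry.wavelength,
                                   init_d=[9.75, 4.59, 3.88])
        ds = [r.d for r in fit.reflections]
        assert ds == sorted(ds, reverse=True)
        for got, want in zip(ds, (9.75, 4.59, 3.88)):
            assert got == pytest.approx(want, rel=0.005)

    def test_d_invariant_across_geometries(self, synchrotron_geometry, cuka_geometry):
        """The same lattice spacing must be recovered from patterns recorded
        at 76.3 mm (synchrotron) and 110.8 mm (Cu K-alpha) geometries."""
        ds = {}
        for geom in (synchrotron_geometry, cuka_geometry):
            img, _ = synthdata.synth_fiber_image(
                [SynthReflection(4.59, 100.0, 0.08)], geom, shape=(512, 512),
                halo={"center_d": 4.8, "fwhm_q": 1.2, "amplitude": 40.0, "offset": 2.0})
            prof = waxs.azimuthal_average(img, geom)
            fit = waxs.fit_reflections(prof, geom.wavelength, init_d=[4.59])
            ds[geom.wavelength] = fit.reflections[0].d
        assert ds[0.9996] == pytest.approx(ds[1.5418], rel=0.005)


class TestScherrer:
    def test_closed_form_example(self):
        # lambda 1.5418, beta 0.0349 rad, 2theta 20.18 deg, Ks 0.9 -> 40.4 A
        refl = waxs.Reflection(d=4.4, twotheta=20.18, fwhm_twotheta=0.0349,
                               intensity=1.0)
        geom = waxs.DetectorGeometry(1.5418, 110.8, 102.0, (0.0, 0.0))
        L = waxs.scherrer_size(refl, geom)
        assert L == pytest.approx(40.4, abs=0.1)

    def test_doubling_width_halves_size(self):
        geom = waxs.DetectorGeometry(1.5418, 110.8, 102.0, (0.0, 0.0))
        r1 = waxs.Reflection(4.4, 20.18, 0.02, 1.0)
        r2 = waxs.Reflection(4.4, 20.18, 0.04, 1.0)
        assert waxs.scherrer_size(r1, geom) == pytest.approx(
            2.0 * waxs.scherrer_size(r2, geom), rel=1e-12)

    def test_monotone_in_width_and_wavelength(self):
        geom_a = waxs.DetectorGeometry(1.0, 100.0, 100.0, (0.0, 0.0))
        geom_b = waxs.DetectorGeometry(1.5, 100.0, 100.0, (0.0, 0.0))
        widths = [0.01, 0.02, 0.04, 0.08]
        sizes = [waxs.scherrer_size(waxs.Reflection(4.4, 20.0, w, 1.0), geom_a)
                 for w in widths]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert waxs.scherrer_size(waxs.Reflection(4.4, 20.0, 0.02, 1.0), geom_b) > \
            waxs.scherrer_size(waxs.Reflection(4.4, 20.0, 0.02, 1.0), geom_a)

    def test_width_below_instrumental_broadening_rejected(self):
        geom = waxs.DetectorGeometry(1.5418, 110.8, 102.0, (0.0, 0.0))
        refl = waxs.Reflection(4.4, 20.18, 0.01, 1.0)
        with pytest.raises(ValueError, match="instrumental"):
            waxs.scherrer_size(refl, geom, waxs.ScherrerParams(instrumental_fwhm=0.02))

    @pytest.mark.parametrize("L_true", [23.0, 40.0, 50.0])
    def test_forward_model_invert_round_trip(self, L_true, synchrotron_geometry):
        geom = synchrotron_geometry
        d = 4.59
        theta = math.radians(waxs.twotheta_from_d(d, geom.wavelength)) / 2.0
        beta = 0.9 * geom.wavelength / (L_true * math.cos(theta))
        fwhm_q = beta * 2.0 * math.pi * math.cos(theta) / geom.wavelength
        img, _ = synthdata.synth_fiber_image(
            [SynthReflection(d, 100.0, fwhm_q)], geom, shape=(512, 512),
            halo={"center_d": 4.8, "fwhm_q": 1.2, "amplitude": 30.0, "offset": 2.0})
        prof = waxs.azimuthal_average(img, geom)
        fit = waxs.fit_reflections(prof, geom.wavelength, init_d=[d])
        L = waxs.scherrer_size(fit.reflections[0], geom)
        assert L == pytest.approx(L_true, rel=0.10)


class TestCrystallinity:
    def test_eq_ratio(self):
        res = waxs.crystallinity_index(21.0, 79.0)
        assert res.xc_percent == pytest.approx(21.0)

    def test_boundaries(self):
        assert waxs.crystallinity_index(0.0, 5.0).xc_percent == 0.0
        assert waxs.crystallinity_index(5.0, 0.0).xc_percent == 100.0
        assert waxs.crystallinity_index(0.0, 0.0).xc_percent is None

    def test_invariant_under_uniform_rescaling(self, synchrotron_geometry):
        img, _ = synthdata.synth_fiber_image(
            [SynthReflection(4.59, 100.0, 0.08)], synchrotron_geometry,
            shape=(384, 384), halo={"center_d": 4.8, "fwhm_q": 1.2, "amplitude": 60.0, "offset": 3.0})
        prof = waxs.azimuthal_average(img, synchrotron_geometry)
        xc1 = waxs.fit_reflections(prof, 0.9996, init_d=[4.59]).crystallinity().xc_percent
        prof2 = waxs.RadialProfile(prof.q, prof.intensity * 7.5)
        xc2 = waxs.fit_reflections(prof2, 0.9996, init_d=[4.59]).crystallinity().xc_percent
        assert xc1 == pytest.approx(xc2, abs=0.2)

    @pytest.mark.parametrize("target", [13.0, 21.0])
    def test_constructed_bragg_share_recovered_within_2points(
            self, target, synchrotron_geometry):
        refl = [SynthReflection(9.75, 60.0, 0.06), SynthReflection(4.59, 100.0, 0.08),
                SynthReflection(3.88, 50.0, 0.08)]
        halo = {"center_d": 4.8, "fwhm_q": 1.1, "amplitude": 100.0, "offset": 5.0}
        # scale the halo so the analytic Bragg share equals the target
        _, truth = synthdata.synth_fiber_image(refl, synchrotron_geometry,
                                               shape=(64, 64), halo=halo)
        share0 = synthdata.bragg_share(truth)
        scale = (share0 / target) * (100.0 - target) / (100.0 - share0)
        halo = {**halo, "amplitude": halo["amplitude"] * scale,
                "offset": halo["offset"] * scale}
        img, truth = synthdata.synth_fiber_image(refl, synchrotron_geometry,
                                                 shape=(512, 512), halo=halo)
        assert synthdata.bragg_share(truth) == pytest.approx(target, abs=1e-9)
        prof = waxs.azimuthal_average(img, synchrotron_geometry)
        fit = waxs.fit_reflections(prof, 0.9996, init_d=[9.75, 4.59, 3.88])
        assert fit.crystallinity().xc_percent == pytest.approx(target, abs=2.0)


class TestAzimuthalClass:
    @pytest.mark.parametrize("arc,expected", [
        ("meridional", "meridional"),
        ("equatorial", "equatorial"),
        ("isotropic", "isotropic"),
    ])
    def test_arc_classes_recovered(self, arc, expected, synchrotron_geometry):
        img, _ = synthdata.synth_fiber_image(
            [SynthReflection(4.59, 100.0, 0.08, arc, 30.0)],
            synchrotron_geometry, shape=(512, 512),
            halo={"amplitude": 0.0, "offset": 1.0})
        refl = waxs.Reflection(4.59, waxs.twotheta_from_d(4.59, 0.9996), 0.01, 1.0)
        cls, _ = waxs.azimuthal_class(img, synchrotron_geometry, refl)
        assert cls == expected

    def test_equatorial_arc_width_recovered(self, synchrotron_geometry):
        img, _ = synthdata.synth_fiber_image(
            [SynthReflection(4.59, 100.0, 0.08, "equatorial", 25.0)],
            synchrotron_geometry, shape=(512, 512),
            halo={"amplitude": 0.0, "offset": 1.0})
        refl = waxs.Reflection(4.59, waxs.twotheta_from_d(4.59, 0.9996), 0.01, 1.0)
        cls, fwhm = waxs.azimuthal_class(img, synchrotron_geometry, refl)
        assert cls == "equatorial"
        assert fwhm == pytest.approx(25.0, abs=3.0)

    def test_radius_band_outside_image_rejected(self, synchrotron_geometry):
        img = waxs.DetectorImage(np.ones((64, 64)))
        geom = waxs.DetectorGeometry(0.9996, 76.3, 102.0, (32.0, 32.0))
        refl = waxs.Reflection(3.0, waxs.twotheta_from_d(3.0, 0.9996), 0.01, 1.0)
        with pytest.raises(ValueError, match="outside"):
            waxs.azimuthal_class(img, geom, refl)
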