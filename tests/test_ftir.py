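"""Amide-I preprocessing, mixture fitting, AICc averaging, peak widths."""

import numpy as np
import pytest

from nanospring import ftir, synth
from nanospring.ftir import FWHM_TO_SD, GaussianComponent, IRSpectrum, MixtureFit


def gaussian_spectrum(center=1650.0, fwhm=20.0, height=1.0, slope=0.0, offset=0.0):
    wn = np.arange(1590.0, 1726.0)
    sd = fwhm / FWHM_TO_SD
    ab = height * np.exp(-0.5 * ((wn - center) / sd) ** 2) + offset + slope * (
        wn - wn[0]
    )
    return IRSpectrum(wn, ab)


class TestPreprocess:
    def test_unit_norm_over_region(self):
        (out,) = ftir.preprocess_spectra([gaussian_spectrum()])
        assert np.linalg.norm(out.absorbance) == pytest.approx(1.0, abs=1e-12)

    def test_straight_line_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            ftir.preprocess_spectra([gaussian_spectrum(height=0.0, slope=0.01, offset=1.0)])

    def test_baseline_removed_from_known_mixture(self):
        clean = gaussian_spectrum()
        dirty = gaussian_spectrum(slope=3e-3, offset=0.4)
        (out_clean,) = ftir.preprocess_spectra([clean])
        (out_dirty,) = ftir.preprocess_spectra([dirty])
        r = np.corrcoef(out_clean.absorbance, out_dirty.absorbance)[0, 1]
        assert r > 0.999

    def test_idempotent(self):
        (once,) = ftir.preprocess_spectra([gaussian_spectrum(slope=1e-3)])
        (twice,) = ftir.preprocess_spectra([once])
        assert np.allclose(once.absorbance, twice.absorbance, atol=1e-9)

    def test_region_not_covered_rejected(self):
        s = IRSpectrum(np.arange(1620.0, 1700.0), np.ones(80))
        with pytest.raises(ValueError, match="cover"):
            ftir.preprocess_spectra([s])


class TestMedian:
    def test_identical_replicates_unchanged(self):
        s = gaussian_spectrum()
        med = ftir.median_spectrum([s, s, s])
        assert np.array_equal(med.absorbance, s.absorbance)

    def test_single_spike_rejected_by_median(self):
        rng = np.random.default_rng(1)
        reps = []
        for _ in range(9):
            s = gaussian_spectrum()
            s.absorbance = s.absorbance + rng.normal(0, 1e-3, len(s.absorbance))
            reps.append(s)
        reps[4].absorbance[60] += 10.0  # corrupted channel in one replicate
        med = ftir.median_spectrum(reps)
        clean = gaussian_spectrum()
        assert abs(med.absorbance[60] - clean.absorbance[60]) < 5e-3

    def test_mismatched_grids_rejected(self):
        s1 = gaussian_spectrum()
        s2 = IRSpectrum(s1.wavenumber_cm1[:-1], s1.absorbance[:-1])
        with pytest.raises(ValueError, match="grid"):
            ftir.median_spectrum([s1, s2])


class TestMixtureFit:
    def test_noiseless_single_gaussian_recovered(self):
        (pre,) = ftir.preprocess_spectra([gaussian_spectrum(1650.0, 20.0)])
        fit = ftir.fit_gaussian_mixture(pre, 1, seed=3)
        (comp,) = fit.components
        assert comp.center_cm1 == pytest.approx(1650.0, abs=1e-4 * 1650)
        assert comp.fwhm_cm1 == pytest.approx(20.0, rel=1e-4)

    def test_deterministic_for_fixed_seed(self):
        (pre,) = ftir.preprocess_spectra([gaussian_spectrum()])
        f1 = ftir.fit_gaussian_mixture(pre, 2, seed=7)
        f2 = ftir.fit_gaussian_mixture(pre, 2, seed=7)
        assert f1.rss == f2.rss
        assert all(
            a.center_cm1 == b.center_cm1 for a, b in zip(f1.components, f2.components)
        )

    def test_under_determined_k_rejected(self):
        s = IRSpectrum(np.arange(1600.0, 1630.0), np.ones(30) + np.arange(30) * 0.01)
        with pytest.raises(ValueError, match="under-determined"):
            ftir.fit_gaussian_mixture(s, 13)

    def test_area_fractions_sum_to_one(self):
        (pre,) = ftir.preprocess_spectra([gaussian_spectrum()])
        fit = ftir.fit_gaussian_mixture(pre, 3, seed=5)
        assert sum(c.area_fraction for c in fit.components) == pytest.approx(1.0)


def dummy_fit(k, aicc):
    comps = [
        GaussianComponent(1620.0 + 10 * i, 15.0, 1.0, area_fraction=1.0 / k)
        for i in range(k)
    ]
    return MixtureFit(comps, rss=1.0, n_points=100, aicc=aicc, best_of_starts=0)


class TestSelection:
    def test_single_fit_gets_weight_one(self):
        sel = ftir.select_component_count([dummy_fit(4, -100.0)])
        assert sel.records[0][2] == 1.0
        assert sel.weighted_mean_k == 4.0
        assert sel.weighted_sd_k == 0.0

    def test_equal_aicc_splits_evenly(self):
        sel = ftir.select_component_count([dummy_fit(3, -50.0), dummy_fit(5, -50.0)])
        weights = [r[2] for r in sel.records]
        assert weights == pytest.approx([0.5, 0.5])
        assert sel.weighted_mean_k == pytest.approx(4.0)

    def test_hand_computed_delta_two(self):
        """dAICc = {0, 2} gives Akaike weights {0.7311, 0.2689}."""
        sel = ftir.select_component_count([dummy_fit(3, 10.0), dummy_fit(4, 12.0)])
        weights = [r[2] for r in sel.records]
        assert weights[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-4)
        assert weights == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_weights_invariant_to_constant_shift(self):
        base = [dummy_fit(2, -20.0), dummy_fit(3, -26.0), dummy_fit(4, -24.0)]
        shifted = [dummy_fit(f.k, f.aicc + 123.4) for f in base]
        w1 = [r[2] for r in ftir.select_component_count(base).records]
        w2 = [r[2] for r in ftir.select_component_count(shifted).records]
        assert w1 == pytest.approx(w2, abs=1e-12)
        assert sum(w1) == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_k_rejected(self):
        with pytest.raises(ValueError):
            ftir.select_component_count([dummy_fit(3, 0.0), dummy_fit(3, 1.0)])

    def test_aicc_guard_on_small_n(self):
        s = IRSpectrum(np.arange(1600.0, 1716.0), np.ones(116))
        with pytest.raises(ValueError, match="AICc"):
            ftir._aicc(1.0, 10, 10)


def width_fit(widths, centers=None):
    k = len(widths)
    centers = centers or [1620.0 + 15 * i for i in range(k)]
    comps = [
        GaussianComponent(c, w, 1.0, area_fraction=1.0 / k)
        for c, w in zip(centers, widths)
    ]
    return MixtureFit(comps, rss=0.1, n_points=116, aicc=0.0, best_of_starts=0)


class TestPeakWidth:
    def test_identical_widths_give_null_result(self):
        models = {
            f"c{i}": width_fit([12.0, 12.0, 12.0], [1630.0, 1645.0, 1665.0])
            for i in range(4)
        }
        report = ftir.peak_width_analysis(models)
        assert report.p_value > 0.9

    def test_broad_target_peak_detected(self):
        models = {
            f"c{i}": width_fit([12.0, 30.0, 12.0], [1625.0, 1645.0, 1670.0])
            for i in range(4)
        }
        report = ftir.peak_width_analysis(models)
        assert report.p_value < 0.05
        assert report.mean_fwhm_cm1 == pytest.approx(30.0)
        assert report.mean_fwhm_cm1 > np.mean(report.other_widths_fwhm)

    def test_sub_percent_component_excluded(self):
        comps = [
            GaussianComponent(1630.0, 12.0, 1.0, area_fraction=0.595),
            GaussianComponent(1645.0, 20.0, 1.0, area_fraction=0.40),
            GaussianComponent(1700.0, 5.0, 0.01, area_fraction=0.005),
        ]
        fit = MixtureFit(comps, rss=0.1, n_points=116, aicc=0.0, best_of_starts=0)
        report = ftir.peak_width_analysis({"a": fit, "b": fit})
        assert 5.0 not in report.other_widths_fwhm

    def test_replicate_without_target_component_excluded_with_warning(self):
        good = width_fit([12.0, 20.0], [1640.0, 1660.0])
        bad = width_fit([12.0, 20.0], [1610.0, 1700.0])
        with pytest.warns(UserWarning, match="excluded"):
            report = ftir.peak_width_analysis({"a": good, "b": good, "c": bad})
        assert report.excluded_replicates == ["c"]

    def test_single_replicate_omits_test_with_reason(self):
        report = ftir.peak_width_analysis({"a": width_fit([12.0, 20.0], [1640.0, 1660.0])})
        assert report.p_value is None
        assert "omitted" in report.reason


class TestEndToEnd:
    def test_component_count_recovered_on_synthetic_plate(self, amide_plate):
        """Carrier-averaged AICc-weighted component count lands on the
        generating three-component mixture."""
        spectra, _ = amide_plate
        carrier = "carrier_0"
        group = [s for s in spectra if s.carrier_id == carrier]
        med = ftir.median_spectrum(ftir.preprocess_spectra(group))
        fits = [ftir.fit_gaussian_mixture(med, k, seed=100 + k) for k in range(1, 8)]
        sel = ftir.select_component_count(fits)
        assert 2.5 <= sel.weighted_mean_k <= 3.5

    def test_noiseless_roundtrip_recovers_components(self):
        spectra, truth = synth.gen_amide1_spectra(
            noise_sd=0.0, n_wells=1, n_carriers=1, seed=0
        )
        (pre,) = ftir.preprocess_spectra(spectra)
        fit = ftir.fit_gaussian_mixture(pre, 3, seed=11)
        centers = sorted(c.center_cm1 for c in fit.components)
        assert centers == pytest.approx(sorted(truth["center_cm1"]), rel=1e-3)
        widths = [c.fwhm_cm1 for c in fit.components]
        assert sorted(widths) == pytest.approx(sorted(truth["fwhm_cm1"]), rel=1e-3)
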