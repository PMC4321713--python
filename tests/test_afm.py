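"""AFM trace parsing, baseline correction, fingerprint detection, fitting."""

import numpy as np
import pytest

from nanospring import afm, synth
from nanospring.wlc import WLCParams, wlc_extension, wlc_force


def make_wlc_trace(lp=0.37, lc=94.0, contact=0.0, fmax=250.0, spacing=0.25, tail=50.0):
    """Noiseless single-branch WLC trace ending in a rupture to baseline."""
    p = WLCParams(lp, lc)
    x_rup = wlc_extension(p, fmax)
    d = np.arange(0.0, contact + x_rup + tail, spacing)
    f = np.zeros_like(d)
    ext = d - contact
    sel = (ext > 0) & (ext <= x_rup)
    f[sel] = wlc_force(p, ext[sel])
    return afm.ForceDistanceTrace("synthetic", d, f)


class TestIO:
    def test_round_trip_with_metadata(self, tmp_path):
        trace = afm.ForceDistanceTrace(
            "t1", np.arange(1000.0), np.ones(1000), pulling_speed_nm_s=800.0
        )
        afm.write_trace(trace, tmp_path / "t1.tsv")
        (loaded,) = afm.read_traces(tmp_path / "t1.tsv")
        assert len(loaded) == 1000
        assert loaded.pulling_speed_nm_s == 800.0
        assert loaded.trace_id == "t1"

    def test_malformed_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1.0\t2.0\n3.0\t4.0\t5.0\n")
        with pytest.raises(afm.TraceParseError, match="bad.tsv:2"):
            afm.read_traces(path)

    def test_non_numeric_row_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1.0\t2.0\nx\ty\n")
        with pytest.raises(afm.TraceParseError, match="non-numeric"):
            afm.read_traces(path)

    def test_unequal_column_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            afm.ForceDistanceTrace("t", np.arange(5.0), np.arange(4.0))


class TestBaseline:
    def test_offset_removed_from_tail(self):
        trace = make_wlc_trace()
        shifted = afm.ForceDistanceTrace(
            trace.trace_id, trace.distance_nm, trace.force_pN + 10.0
        )
        corrected = afm.correct_baseline(shifted)
        tail = corrected.force_pN[-50:]
        assert abs(np.median(tail)) < 1e-9

    def test_idempotent_on_zeroed_trace(self):
        trace = make_wlc_trace()
        once = afm.correct_baseline(trace)
        twice = afm.correct_baseline(once)
        assert np.allclose(once.force_pN, twice.force_pN, atol=1e-9)
        assert np.allclose(once.distance_nm, twice.distance_nm, atol=0.51)

    def test_contact_point_recovered(self):
        trace = make_wlc_trace(contact=13.0)
        corrected = afm.correct_baseline(trace)
        # the generating trace has its contact at 13 nm; after correction
        # the origin should sit there
        shift = trace.distance_nm[0] - corrected.distance_nm[0]
        assert shift == pytest.approx(13.0, abs=0.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            afm.correct_baseline(
                afm.ForceDistanceTrace("t", np.arange(10.0), np.zeros(10))
            )

    def test_no_baseline_segment_rejected(self):
        # force keeps rising to the very end: no detached tail
        d = np.linspace(0, 80, 400)
        f = wlc_force(WLCParams(0.4, 100.0), d)
        with pytest.raises(afm.BaselineError):
            afm.correct_baseline(afm.ForceDistanceTrace("t", d, f))


class TestContourLengthTransform:
    def test_exact_on_points_from_single_wlc(self):
        p = WLCParams(0.4, 100.0)
        d = np.linspace(30, 90, 100)
        trace = afm.ForceDistanceTrace("t", d, wlc_force(p, d))
        lc, _ = contour = afm.contour_length_transform(trace, 0.4)
        assert np.allclose(lc, 100.0, atol=1e-6)

    def test_two_branch_trace_gives_bimodal_density(self):
        p1, p2 = WLCParams(0.4, 90.0), WLCParams(0.4, 98.0)
        d1 = np.linspace(40, wlc_extension(p1, 200.0), 150)
        d2 = np.linspace(d1[-1], wlc_extension(p2, 200.0), 150)
        d = np.concatenate([d1, d2])
        f = np.concatenate([wlc_force(p1, d1), wlc_force(p2, d2)])
        lc, _ = afm.contour_length_transform(
            afm.ForceDistanceTrace("t", d, f), 0.4
        )
        modes = np.sort(np.unique(np.round(lc)))
        assert 90.0 in modes and 98.0 in modes
        assert lc.min() == pytest.approx(90.0, abs=0.5)
        assert lc.max() == pytest.approx(98.0, abs=0.5)

    def test_all_points_below_threshold_gives_empty_transform(self):
        trace = afm.ForceDistanceTrace(
            "t", np.linspace(0, 50, 100), np.full(100, 2.0)
        )
        lc, (counts, edges) = afm.contour_length_transform(trace, 0.4)
        assert len(lc) == 0 and len(counts) == 0


class TestDetector:
    def test_specific_double_rupture_detected(self):
        traces, truth = synth.gen_fd_traces(
            n_traces=1, specific_fraction=1.0, noise_sd_pN=3.0, seed=42
        )
        corrected = afm.correct_baseline(traces[0])
        event = afm.detect_specific_event(corrected, persistence_length_nm=0.37)
        assert event.specific
        assert event.delta_Lc_nm == pytest.approx(8.0, abs=2.0)

    def test_single_rupture_rejected(self):
        trace = make_wlc_trace()
        corrected = afm.correct_baseline(trace)
        event = afm.detect_specific_event(corrected, persistence_length_nm=0.37)
        assert not event.specific
        assert event.reason == "single peak"

    def test_wide_separation_rejected(self):
        traces, _ = synth.gen_fd_traces(
            n_traces=1,
            specific_fraction=1.0,
            separation_nm=16.0,
            noise_sd_pN=3.0,
            seed=42,
        )
        corrected = afm.correct_baseline(traces[0])
        event = afm.detect_specific_event(corrected, persistence_length_nm=0.37)
        assert not event.specific
        assert event.reason == "separation outside window"
        assert event.delta_Lc_nm == pytest.approx(16.0, abs=2.5)

    def test_flag_accuracy_on_seeded_cohort(self, afm_cohort):
        """Specific/non-specific calls match generator truth >= 99%."""
        traces, truth = afm_cohort
        correct = 0
        for trace, (_, row) in zip(traces, truth.iterrows()):
            corrected = afm.correct_baseline(trace)
            event = afm.detect_specific_event(corrected, persistence_length_nm=0.4)
            correct += event.specific == row["specific"]
        assert correct >= 99


class TestAnalyzeTrace:
    def test_noiseless_specific_trace_recovered_exactly(self):
        traces, truth = synth.gen_fd_traces(
            n_traces=1,
            specific_fraction=1.0,
            noise_sd_pN=0.0,
            baseline_offset_range_pN=(0.0, 0.0),
            seed=3,
        )
        corrected = afm.correct_baseline(traces[0])
        event = afm.detect_specific_event(corrected, persistence_length_nm=0.37)
        fit = afm.analyze_trace(corrected, event)
        row = truth.iloc[0]
        assert fit.params.contour_length_nm == pytest.approx(row["lc_nm"], rel=1e-3)
        assert fit.params.persistence_length_nm == pytest.approx(row["lp_nm"], rel=1e-3)

    def test_noisy_trace_within_population_tolerances(self):
        traces, truth = synth.gen_fd_traces(
            n_traces=1, specific_fraction=1.0, noise_sd_pN=5.0, seed=8
        )
        corrected = afm.correct_baseline(traces[0])
        event = afm.detect_specific_event(corrected, persistence_length_nm=0.37)
        fit = afm.analyze_trace(corrected, event)
        row = truth.iloc[0]
        assert fit.params.contour_length_nm == pytest.approx(row["lc_nm"], rel=0.05)
        assert fit.params.persistence_length_nm == pytest.approx(
            row["lp_nm"], rel=0.30
        )

    def test_non_specific_event_rejected(self):
        trace = make_wlc_trace()
        event = afm.StretchEvent(specific=False, reason="single peak")
        with pytest.raises(ValueError, match="rejected"):
            afm.analyze_trace(trace, event)


class TestPopulation:
    def test_hand_arithmetic(self):
        from nanospring.wlc import WLCFit

        fits = [
            WLCFit(WLCParams(lp, 90.0), {}, 0.0, 10) for lp in (0.2, 0.4, 0.6)
        ]
        pop = afm.summarize_population(fits)
        assert pop.persistence_mean_nm == pytest.approx(0.4)
        assert pop.persistence_sd_nm == pytest.approx(0.16330, abs=1e-4)

    def test_single_fit_has_zero_sd(self):
        from nanospring.wlc import WLCFit

        pop = afm.summarize_population([WLCFit(WLCParams(0.4, 90.0), {}, 0.0, 10)])
        assert pop.contour_sd_nm == 0.0

    def test_histogram_counts_sum_to_accepted(self, afm_cohort):
        traces, truth = afm_cohort
        fits = []
        for trace in traces[:30]:
            corrected = afm.correct_baseline(trace)
            event = afm.detect_specific_event(corrected, persistence_length_nm=0.4)
            if event.specific:
                fits.append(afm.analyze_trace(corrected, event))
        pop = afm.summarize_population(fits)
        assert pop.lc_hist_counts.sum() == pop.n_accepted == len(fits)
        assert pop.lp_hist_counts.sum() == pop.n_accepted

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            afm.summarize_population([])
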