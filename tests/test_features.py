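import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpmkl.features import (
    PEAK_FEATURES,
    PEAK_TO_PEAK_FEATURES,
    SIGNAL_FEATURES,
    FeatureSchema,
    PeakMeasurement,
    PeakWindowTable,
    area_features,
    build_feature_table,
    detect_peak,
    feature_category,
    peak_features,
    peak_to_peak_features,
    recenter_windows,
    spectral_features,
    zero_crossing_features,
)
from erpmkl.preprocessing import EpochWindow, SubjectErp
from erpmkl.synthetic import ComponentSpec, erp_template, template_time_grid

FS = 256.0
P300_WINDOW = EpochWindow(-200.0, 800.0, FS)


def _times():
    return P300_WINDOW.times_ms()


class TestDetectPeak:
    def test_unique_maximum(self):
        t = _times()
        wave = np.zeros_like(t)
        idx = int(np.argmin(np.abs(t - 310.0)))
        wave[idx] = 7.5
        pm = detect_peak(wave, (250.0, 450.0), P300_WINDOW)
        assert pm.amplitude_uV == 7.5
        assert pm.latency_ms == pytest.approx(t[idx])

    def test_sign_symmetry(self):
        comps = [ComponentSpec("N", -1, 180.0, 0.0, 6.0, 0.0, 20.0)]
        wave = erp_template(comps, (-200.0, 800.0), FS)
        pm = detect_peak(wave, (120.0, 240.0), P300_WINDOW)
        assert pm.amplitude_uV < 0
        assert abs(pm.latency_ms - 180.0) <= 1000.0 / FS

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        t = _times()
        for _ in range(20):
            wave = rng.normal(size=t.size)
            pm = detect_peak(wave, (100.0, 600.0), P300_WINDOW)
            in_win = np.flatnonzero((t >= 100.0) & (t <= 600.0))
            best = max(in_win, key=lambda i: (abs(wave[i]), -i))
            assert pm.index == best
            assert pm.amplitude_uV == wave[best]

    def test_tie_broken_earliest(self):
        wave = np.zeros(P300_WINDOW.n_samples)
        t = _times()
        ia = int(np.argmin(np.abs(t - 300.0)))
        ib = int(np.argmin(np.abs(t - 400.0)))
        wave[ia] = -3.0
        wave[ib] = 3.0
        pm = detect_peak(wave, (250.0, 450.0), P300_WINDOW)
        assert pm.index == ia

    def test_window_outside_epoch_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            detect_peak(np.zeros(P300_WINDOW.n_samples), (700.0, 900.0), P300_WINDOW)


class TestPeakFeatures:
    def test_ratio_closed_form(self):
        t = _times()
        wave = 0.05 * t  # linear ramp
        pm = PeakMeasurement(amplitude_uV=10.0, latency_ms=300.0, index=100)
        feats = peak_features(pm, wave, (250.0, 350.0), P300_WINDOW)
        assert feats["ratio"] == pytest.approx(30.0)
        assert feats["abs_ratio"] == pytest.approx(30.0)
        assert feats["amplitude"] == 10.0
        assert feats["abs_amplitude"] == 10.0
        assert feats["latency"] == 300.0

    def test_monotone_window_no_alternations(self):
        t = _times()
        wave = 0.01 * t
        pm = detect_peak(wave, (300.0, 500.0), P300_WINDOW)
        feats = peak_features(pm, wave, (300.0, 500.0), P300_WINDOW)
        assert feats["slope_sign_alternations"] == 0
        # ramp slope recovered exactly: |dv|/dt constant
        assert feats["avg_abs_slope"] == pytest.approx(0.01)

    def test_sinusoid_one_period_two_alternations(self):
        t = _times()
        wave = np.sin(2 * np.pi * (t - 300.0) / 200.0)  # one period in [300, 500]
        pm = detect_peak(wave, (300.0, 500.0), P300_WINDOW)
        feats = peak_features(pm, wave, (300.0, 500.0), P300_WINDOW)
        # oracle: count sign changes of the sampled first difference
        mask = (t >= 300.0) & (t <= 500.0)
        signs = np.sign(np.diff(wave[mask]))
        signs = signs[signs != 0]
        expected = int(np.sum(signs[1:] != signs[:-1]))
        assert expected == 2
        assert feats["slope_sign_alternations"] == expected

    def test_zero_amplitude_ratio_policy(self, caplog):
        pm = PeakMeasurement(amplitude_uV=0.0, latency_ms=300.0, index=100)
        with caplog.at_level("WARNING"):
            feats = peak_features(
                pm, np.zeros(P300_WINDOW.n_samples), (250.0, 350.0), P300_WINDOW
            )
        assert feats["ratio"] == 0.0 and feats["abs_ratio"] == 0.0
        assert "ratio" in caplog.text


class TestPeakToPeak:
    def test_worked_example(self):
        a = PeakMeasurement(-5.0, 100.0, 10)
        b = PeakMeasurement(10.0, 300.0, 60)
        feats = peak_to_peak_features(a, b)
        assert feats["pp_abs_amplitude_diff"] == pytest.approx(15.0)
        assert feats["pp_latency_diff"] == pytest.approx(200.0)
        assert feats["pp_slope"] == pytest.approx(0.075)

    def test_identical_amplitudes(self):
        a = PeakMeasurement(4.0, 100.0, 10)
        b = PeakMeasurement(4.0, 250.0, 40)
        feats = peak_to_peak_features(a, b)
        assert feats["pp_abs_amplitude_diff"] == 0.0
        assert feats["pp_slope"] == 0.0
        assert feats["pp_latency_diff"] == 150.0

    @given(
        st.floats(-50, 50),
        st.floats(-50, 50),
        st.floats(0, 400),
        st.floats(1, 300),
    )
    def test_formula_recomputed(self, amp_a, amp_b, lat_a, dlat):
        a = PeakMeasurement(amp_a, lat_a, 0)
        b = PeakMeasurement(amp_b, lat_a + dlat, 1)
        feats = peak_to_peak_features(a, b)
        assert feats["pp_abs_amplitude_diff"] == abs(amp_b - amp_a)
        assert feats["pp_latency_diff"] == b.latency_ms - a.latency_ms
        assert feats["pp_slope"] == (amp_b - amp_a) / (b.latency_ms - a.latency_ms)

    def test_equal_latencies_error(self):
        a = PeakMeasurement(1.0, 100.0, 10)
        b = PeakMeasurement(2.0, 100.0, 10)
        with pytest.raises(ValueError, match="latency"):
            peak_to_peak_features(a, b)


class TestAreaFeatures:
    def test_constant_one_second(self):
        v = np.ones(256)
        feats = area_features(v, dt_s=1 / 256)
        assert feats["positive_area"] == pytest.approx(1.0)
        assert feats["negative_area"] == 0.0
        assert feats["total_area"] == pytest.approx(1.0)
        assert feats["abs_total_area"] == pytest.approx(1.0)

    def test_odd_symmetric(self):
        t = np.linspace(-1, 1, 501)
        v = t**3
        feats = area_features(v, dt_s=0.004)
        assert feats["total_area"] == pytest.approx(0.0, abs=1e-12)
        assert feats["abs_total_area"] == pytest.approx(2 * feats["positive_area"])

    @given(st.integers(0, 1000))
    @settings(max_examples=25)
    def test_identity(self, seed):
        v = np.random.default_rng(seed).normal(size=64)
        feats = area_features(v, dt_s=1 / 256)
        assert feats["abs_total_area"] == pytest.approx(
            feats["positive_area"] - feats["negative_area"]
        )
        assert feats["total_area"] == pytest.approx(
            feats["positive_area"] + feats["negative_area"]
        )


class TestZeroCrossing:
    def test_strictly_positive_span(self):
        v = np.ones(100)
        feats = zero_crossing_features(v, 10, 80, dt_s=1 / 256)
        assert feats == {"zero_crossing": 0.0, "zero_cross_density": 0.0}

    def test_sinusoid_two_periods(self):
        # exactly two periods of a cosine between the first and last peak
        # (both ends on maxima); span length avoids zero-valued samples
        n = 257
        i0, i1 = 20, 219
        v = np.zeros(n)
        idx = np.arange(i0, i1 + 1)
        v[idx] = np.cos(2 * np.pi * 2 * (idx - i0) / (i1 - i0))
        span = v[i0 : i1 + 1]
        expected = int(np.sum(span[:-1] * span[1:] < 0))
        feats = zero_crossing_features(v, i0, i1, dt_s=1 / 256)
        assert feats["zero_crossing"] == expected
        assert expected == 4

    def test_single_flip(self):
        v = np.concatenate([np.ones(50), -np.ones(50)])
        feats = zero_crossing_features(v, 0, 99, dt_s=1 / 256)
        assert feats["zero_crossing"] == 1.0
        span_s = 99 / 256
        assert feats["zero_cross_density"] == pytest.approx(1 / span_s)


class TestSpectralFeatures:
    def test_pure_tone_mode(self):
        t = np.arange(257) / FS
        v = np.sin(2 * np.pi * 10 * t)
        feats = spectral_features(v, FS)
        df = FS / 257
        assert abs(feats["mode_frequency"] - 10.0) <= df

    def test_single_bin_concentration(self):
        # one exact DFT bin -> mode = median = mean = that bin
        n = 256
        t = np.arange(n) / FS
        f_bin = 8 * FS / n
        v = np.sin(2 * np.pi * f_bin * t)
        feats = spectral_features(v, FS)
        assert feats["mode_frequency"] == pytest.approx(f_bin)
        assert feats["median_frequency"] == pytest.approx(f_bin)
        assert feats["mean_frequency"] == pytest.approx(f_bin, rel=1e-3)

    def test_two_tone_mean(self):
        n = 256
        t = np.arange(n) / FS
        v = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 15 * t)
        feats = spectral_features(v, FS)
        assert feats["mean_frequency"] == pytest.approx(10.0, abs=FS / n)

    def test_all_zero_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            feats = spectral_features(np.zeros(64), FS)
        assert feats == {
            "mode_frequency": 0.0,
            "median_frequency": 0.0,
            "mean_frequency": 0.0,
        }
        assert "zero" in caplog.text

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            spectral_features(np.ones(4), FS)


class TestFeatureSchema:
    def test_printed_totals(self):
        schema = FeatureSchema()
        assert schema.n_columns() == 726
        assert schema.n_columns("auditory_p300") == 282
        assert schema.n_columns("visual_p300") == 282
        assert schema.n_columns("mmn") == 162
        assert len(schema.columns()) == 726

    def test_counts_against_independent_formula(self):
        # oracle: 2 classes x 3 channels x (7P + 3(P-1) + 10)
        schema = FeatureSchema()
        for paradigm, P in [("auditory_p300", 4), ("visual_p300", 4), ("mmn", 2)]:
            expected = 2 * 3 * (
                len(PEAK_FEATURES) * P
                + len(PEAK_TO_PEAK_FEATURES) * (P - 1)
                + len(SIGNAL_FEATURES)
            )
            assert schema.n_columns(paradigm) == expected

    def test_restricted_schema(self):
        schema = FeatureSchema().restrict(("mmn",))
        assert schema.n_columns() == 162

    def test_generic_peak_count(self):
        schema = FeatureSchema(
            paradigms=("auditory_p300",),
            stimulus_classes={"auditory_p300": ("target",)},
            channels=("Cz",),
            peaks={"auditory_p300": ("a", "b", "c")},
        )
        assert schema.n_columns() == 7 * 3 + 3 * 2 + 10

    def test_category_mapping(self):
        assert feature_category("mmn.x.Fz.mmn_peak1.latency") == "latency_amplitude"
        assert feature_category("mmn.x.Fz.signal.rms") == "morphological"
        assert feature_category("mmn.x.Fz.signal.mode_frequency") == "frequency"
        schema = FeatureSchema()
        cats = {c: feature_category(c) for c in schema.columns()}
        assert set(cats.values()) == {
            "latency_amplitude",
            "morphological",
            "frequency",
        }


class TestRecenterWindows:
    def test_windows_shift_onto_grand_average_peaks(self):
        comps = [
            ComponentSpec("N100", -1, 120.0, 0.0, 5.0, 0.0, 15.0),
            ComponentSpec("P200", 1, 185.0, 0.0, 6.0, 0.0, 12.0),
            ComponentSpec("N200", -1, 270.0, 0.0, 4.0, 0.0, 15.0),
            ComponentSpec("P300", 1, 420.0, 0.0, 10.0, 0.0, 40.0),
        ]
        grand = erp_template(comps, (-200.0, 800.0), FS)
        table = recenter_windows(
            PeakWindowTable(),
            grand,
            "auditory_p300",
            ("N100", "P200", "N200", "P300"),
            P300_WINDOW,
        )
        step = 1000.0 / FS
        for pk, comp in zip(("N100", "P200", "N200", "P300"), comps):
            lo, hi = table.get("auditory_p300", pk)
            assert lo <= comp.mean_latency_ms <= hi
            mid = (lo + hi) / 2
            assert abs(mid - comp.mean_latency_ms) <= step
        # other paradigms untouched
        assert table.get("mmn", "mmn_peak1") == PeakWindowTable().get("mmn", "mmn_peak1")


class TestBuildFeatureTable:
    def test_default_schema_totals(self, tiny_feature_table):
        X = tiny_feature_table.X
        assert X.shape[1] == 726
        by_paradigm = {
            p: sum(c.startswith(p + ".") for c in X.columns)
            for p in ("auditory_p300", "visual_p300", "mmn")
        }
        assert by_paradigm == {"auditory_p300": 282, "visual_p300": 282, "mmn": 162}
        assert not X.isna().any().any()

    def test_subject_order_invariance(self, tiny_cohort):
        a = build_feature_table(tiny_cohort)
        b = build_feature_table(list(reversed(tiny_cohort)))
        assert list(a.X.columns) == list(b.X.columns)
        for sid in a.X.index:
            assert np.array_equal(a.X.loc[sid].to_numpy(), b.X.loc[sid].to_numpy())

    def test_missing_waveform_names_subject(self, tiny_cohort):
        erp = tiny_cohort[0]
        broken = SubjectErp(
            subject_id="broken01",
            group=erp.group,
            fs_hz=erp.fs_hz,
            windows=dict(erp.windows),
            waveforms={
                k: v
                for k, v in erp.waveforms.items()
                if k != ("mmn", "duration_deviant", "Pz")
            },
        )
        with pytest.raises(KeyError, match="broken01"):
            build_feature_table([broken])

    def test_template_peaks_recovered(self):
        # deterministic Gaussian bumps: detected amplitude/latency must land
        # within one sample of the analytic component parameters
        # components spaced so that a neighbour's tail never dominates the
        # overlapping part of another peak's search window
        comps = {
            "N100": ComponentSpec("N100", -1, 110.0, 0.0, 5.0, 0.0, 15.0),
            "P200": ComponentSpec("P200", 1, 185.0, 0.0, 6.0, 0.0, 15.0),
            "N200": ComponentSpec("N200", -1, 265.0, 0.0, 4.0, 0.0, 15.0),
            "P300": ComponentSpec("P300", 1, 400.0, 0.0, 10.0, 0.0, 40.0),
        }
        wave = erp_template(list(comps.values()), (-200.0, 800.0), FS)
        table = PeakWindowTable()
        step = 1000.0 / FS
        for pk, comp in comps.items():
            pm = detect_peak(wave, table.get("auditory_p300", pk), P300_WINDOW)
            assert abs(pm.latency_ms - comp.mean_latency_ms) <= step
            assert abs(pm.amplitude_uV) == pytest.approx(
                comp.mean_amplitude_uV, rel=0.05
            )
            assert np.sign(pm.amplitude_uV) == comp.polarity
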