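import numpy as np
import pytest

from tubeheart import aps as ap
from tubeheart import synthgen as sg
from tubeheart.core import DataError, VoltageTrace

from conftest import make_linear_ap
from oracles import group_peaks, peak_scan


def render_voltage(preset, seed, **overrides):
    spec = sg.preset_spec(preset, seed=seed, **overrides)
    gt = sg.make_beat_schedule(spec)
    return gt, sg.render_voltage_trace(gt, spec)


class TestRestingPotential:
    def test_flat_trace(self):
        t = np.arange(5000) / 5000.0
        trace = VoltageTrace(t=t, v=np.full(5000, -40.0), rate=5000.0)
        assert ap.resting_potential(trace) == -40.0

    def test_synthetic_within_half_mv(self):
        _, trace = render_voltage("wt_young", 1, rest_vm_mv=-42.0, noise_sd=1.0)
        assert ap.resting_potential(trace) == pytest.approx(-42.0, abs=0.5)

    def test_wt_estimates_in_physiological_range(self):
        # wildtype resting potentials fall in the -50..-35 mV range
        for seed in range(5):
            _, trace = render_voltage("wt_young", seed)
            assert -50.0 <= ap.resting_potential(trace) <= -35.0

    def test_no_baseline_raises(self):
        t = np.arange(3000) / 5000.0
        v = -40.0 + 30.0 * np.sin(2 * np.pi * 50 * t)  # never settles
        with pytest.raises(DataError):
            ap.resting_potential(VoltageTrace(t=t, v=v, rate=5000.0),
                                 min_baseline_s=1.0)


class TestDetectEvents:
    def test_programmed_singles(self):
        gt, trace = render_voltage("wt_young", 2, noise_sd=0.0,
                                   ead_prob=0.0, burst_prob=0.0)
        table = ap.detect_events(trace)
        assert len(table) == len(gt.ap_events)
        assert table.df["n_peaks"].eq(1).all()
        assert (table.df["cls"] == "single").all()

    def test_eight_peak_burst_grouped_as_one_event(self):
        gt, trace = render_voltage(
            "kcnq_like", 0, duration_s=4.0, noise_sd=0.0, burst_prob=1.0,
            di_dist=(3.0, 0.0), si_dist=(0.3, 0.0),
            peaks_per_burst_dist=(8.0, 0.0))
        table = ap.detect_events(trace, ap.EventParams(group_ms=300.0))
        assert len(table) == 1
        assert int(table.df["n_peaks"].iloc[0]) == 8
        assert table.df["cls"].iloc[0] == "burst"

    def test_flat_trace_no_events(self):
        t = np.arange(10000) / 5000.0
        table = ap.detect_events(VoltageTrace(t=t, v=np.full(10000, -40.0),
                                              rate=5000.0))
        assert len(table) == 0

    def test_oracle_peak_totals(self):
        # event count and per-event peak counts equal a naive scan's totals
        gt, trace = render_voltage("sei_like", 7, noise_sd=0.0)
        table = ap.detect_events(trace)
        rest = table.resting_vm
        idx = peak_scan(trace.v, rest, 10.0)
        groups = group_peaks(idx, trace.rate, 0.300)
        assert len(table) == len(groups)
        assert table.df["n_peaks"].tolist() == [len(g) for g in groups]

    def test_amplitude_matches_programmed(self):
        gt, trace = render_voltage("wt_young", 3, noise_sd=0.0,
                                   rest_vm_mv=-40.0, amp_mv=50.0,
                                   ead_prob=0.0, burst_prob=0.0)
        table = ap.detect_events(trace)
        assert np.allclose(table.df["max_amplitude_mv"], 50.0, atol=0.2)

    def test_event_duration_matches_schedule(self):
        gt, trace = render_voltage("wt_young", 4, noise_sd=0.0)
        table = ap.detect_events(trace)
        truth = np.array([e.event_duration for e in gt.ap_events]) * 1000
        assert np.allclose(table.df["duration_ms"], truth, atol=2.0)


class TestAPD:
    def test_linear_ap_closed_form(self):
        trace = make_linear_ap(rest=-40.0, peak=10.0, repol_s=0.100, rate=2000.0)
        table = ap.detect_events(trace)
        assert len(table) == 1
        row = table.df.iloc[0]
        dt_ms = 1000.0 / trace.rate
        assert row["apd10_ms"] == pytest.approx(10.0, abs=dt_ms)
        assert row["apd50_ms"] == pytest.approx(50.0, abs=dt_ms)
        assert row["apd90_ms"] == pytest.approx(90.0, abs=dt_ms)

    @pytest.mark.parametrize("rate", [2000.0, 5000.0, 10000.0])
    def test_linear_ap_any_rate(self, rate):
        trace = make_linear_ap(rate=rate)
        row = ap.detect_events(trace).df.iloc[0]
        dt_ms = 1000.0 / rate
        for x, expect in ((10, 10.0), (50, 50.0), (90, 90.0)):
            assert row[f"apd{x}_ms"] == pytest.approx(expect, abs=dt_ms)

    def test_exponential_repolarization(self):
        # v = rest + amp * exp(-t/tau) after an instantaneous upstroke:
        # APD50 crosses at tau*ln2 past the peak
        rest, amp, tau, rate = -40.0, 50.0, 0.030, 10000.0
        n = int(2.0 * rate)
        t = np.arange(n) / rate
        v = np.full(n, rest)
        t0 = 1.0
        decay = t >= t0
        v[decay] = rest + amp * np.exp(-(t[decay] - t0) / tau)
        trace = VoltageTrace(t=t, v=v, rate=rate)
        row = ap.detect_events(trace).df.iloc[0]
        onset_to_peak = t0 - row["onset"]
        expected = (tau * np.log(2.0) + onset_to_peak) * 1000.0
        assert row["apd50_ms"] == pytest.approx(expected, abs=1000.0 / rate)

    def test_apd_ordering(self):
        for seed in range(3):
            _, trace = render_voltage("wt_young", seed)
            singles = ap.detect_events(trace).singles.dropna()
            assert (singles["apd10_ms"] <= singles["apd50_ms"]).all()
            assert (singles["apd50_ms"] <= singles["apd90_ms"]).all()

    def test_non_single_events_have_no_apd(self):
        gt, trace = render_voltage("kcnq_like", 1, noise_sd=0.0)
        df = ap.detect_events(trace).df
        bursts = df[df["cls"] == "burst"]
        assert len(bursts) > 0
        assert bursts[["apd10_ms", "apd50_ms", "apd90_ms"]].isna().all().all()

    def test_peak_reference_option(self):
        trace = make_linear_ap(rate=5000.0)
        row = ap.detect_events(
            trace, ap.EventParams(apd_reference="peak")).df.iloc[0]
        # peak-referenced APDs exclude the (instantaneous) upstroke offset
        assert row["apd50_ms"] == pytest.approx(50.0, abs=0.4)


class TestClassification:
    def test_programmed_ead_labels(self):
        gt, trace = render_voltage("sei_like", 9, noise_sd=0.0)
        table = ap.detect_events(trace)
        truth = [e.cls for e in gt.ap_events]
        assert table.df["cls"].tolist() == truth

    def test_offset_invariance(self):
        gt, trace = render_voltage("sei_like", 10, noise_sd=0.0)
        shifted = VoltageTrace(t=trace.t, v=trace.v + 25.0, rate=trace.rate)
        a = ap.detect_events(trace).df
        b = ap.detect_events(shifted).df
        assert a["cls"].tolist() == b["cls"].tolist()
        assert np.allclose(a["max_amplitude_mv"], b["max_amplitude_mv"],
                           atol=1e-6)

    def test_classify_unit_rules(self):
        # direct rule checks on constructed peak descriptions
        assert ap.classify_event(np.array([10.0]), np.array([1.0]),
                                 valley_v=0.0, rest=-40.0) == "single"
        assert ap.classify_event(np.array([10.0, -5.0]), np.array([1.0, 1.05]),
                                 valley_v=-10.0, rest=-40.0) == "ead_double"
        assert ap.classify_event(np.array([10.0, 9.0]), np.array([1.0, 1.1]),
                                 valley_v=-39.0, rest=-40.0) == "burst"
        assert ap.classify_event(np.array([10.0, 8.0, 9.0]),
                                 np.array([1.0, 1.1, 1.2]),
                                 valley_v=-39.0, rest=-40.0) == "burst"


class TestRecordSummary:
    def test_identical_events_mean_equals_single(self):
        gt, trace = render_voltage("wt_young", 2, noise_sd=0.0,
                                   di_dist=(0.65, 0.0), si_dist=(0.25, 0.0),
                                   ead_prob=0.0, burst_prob=0.0)
        table = ap.detect_events(trace)
        df = ap.record_summary({"fly1": table})
        assert df["mean_peaks_per_burst"].iloc[0] == 1.0
        assert df["mean_event_duration_ms"].iloc[0] == pytest.approx(
            table.df["duration_ms"].iloc[0], abs=0.5)

    def test_cohort_ordering_peaks_per_burst(self):
        import warnings

        def cohort_mean(preset, seeds):
            tables = {}
            for s in seeds:
                _, trace = render_voltage(preset, s)
                tables[f"f{s}"] = ap.detect_events(trace)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                return ap.record_summary(tables)["mean_peaks_per_burst"].mean()

        assert cohort_mean("kcnq_like", range(5)) > cohort_mean("wt_young",
                                                                range(5))

    def test_below_minimum_warning(self):
        gt, trace = render_voltage("wt_young", 2, duration_s=8.0,
                                   noise_sd=0.0, ead_prob=0.0, burst_prob=0.0)
        table = ap.detect_events(trace)
        assert 0 < len(table.singles) < 20
        with pytest.warns(UserWarning, match="single-peak"):
            df = ap.record_summary({"fly1": table}, window_s=30.0)
        assert np.isfinite(df["mean_apd50_ms"].iloc[0])

    def test_short_window_warning(self):
        _, trace = render_voltage("wt_young", 2, noise_sd=0.0)
        table = ap.detect_events(trace)
        with pytest.warns(UserWarning, match="window"):
            ap.record_summary({"fly1": table}, window_s=10.0)
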