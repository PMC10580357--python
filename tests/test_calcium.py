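"""ΔF/F, transient detection and summary statistics."""

import numpy as np
import pytest

from neurocalnet import (
    MetricSeries,
    TraceMatrix,
    compute_dff,
    detect_transients,
    normalize_to_baseline,
    transient_stats,
)
from neurocalnet import synthetic as syn
from neurocalnet.synthetic import CalciumSimConfig, calcium_kernel, gen_calcium_traces

from conftest import detection_scores

FS = 30.0


def planted_trace(times, amps, duration=120.0, f0=100.0, noise=0.0, seed=0):
    """Raw trace with kernels planted at given times (fraction amplitudes)."""
    t = np.arange(0, duration, 1.0 / FS)
    dff = np.zeros_like(t)
    for t0, a in zip(times, amps):
        dff += a * calcium_kernel(t - t0, 0.05, 0.5)
    x = f0 * (1.0 + dff)
    if noise:
        x = x + f0 * np.random.default_rng(seed).normal(0, noise, t.size)
    return TraceMatrix(values=x[None, :], frame_rate=FS)


class TestComputeDff:
    def test_constant_trace_zero_dff(self):
        tm = TraceMatrix(values=np.full((2, 300), 50.0), frame_rate=FS)
        dff = compute_dff(tm)
        np.testing.assert_allclose(dff.dff, 0.0, atol=1e-12)
        np.testing.assert_allclose(dff.baseline_f0, 50.0)

    def test_step_with_locked_baseline_gives_50pct(self):
        # a brief step to 150 on a 100 baseline; the running 20th
        # percentile stays at 100, so peak ΔF/F is exactly 50%
        x = np.full(3000, 100.0)
        x[1500:1510] = 150.0
        dff = compute_dff(TraceMatrix(values=x[None, :], frame_rate=FS))
        assert dff.dff.max() == pytest.approx(50.0, abs=1e-9)

    def test_planted_amplitude_recovered_noiseless(self):
        tm = planted_trace(np.arange(10, 110, 10.0), [0.25] * 10)
        dff = compute_dff(tm)
        events = detect_transients(dff)
        assert len(events) == 10
        for ev in events:
            assert ev.amplitude == pytest.approx(25.0, rel=0.05)

    def test_nonpositive_baseline_names_neuron(self):
        x = np.vstack([np.full(300, 10.0), np.full(300, -5.0)])
        tm = TraceMatrix(values=x, frame_rate=FS)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="roi001"):
                compute_dff(tm)


class TestDetectTransients:
    def test_zero_trace_no_events(self):
        dff = compute_dff(TraceMatrix(values=np.full((1, 600), 80.0),
                                      frame_rate=FS))
        assert detect_transients(dff) == []

    def test_single_5sigma_event_found_with_accurate_onset(self):
        # one planted kernel at 5x noise SD; >=95% of seeded runs must
        # find exactly one event with onset within 3 frames
        hits = 0
        for s in range(20):
            tm = planted_trace([60.0], [0.25], noise=0.05, seed=s)
            events = detect_transients(compute_dff(tm))
            if len(events) == 1 and abs(events[0].onset_frame / FS - 60.0) <= 3 / FS:
                hits += 1
        assert hits >= 19

    def test_two_separated_events_found(self):
        tm = planted_trace([50.0, 52.0], [0.25, 0.25])
        events = detect_transients(compute_dff(tm))
        assert len(events) == 2

    def test_gain_invariance(self):
        tm = planted_trace(np.arange(10, 110, 7.0), [0.25] * 15, noise=0.05,
                           seed=3)
        ev1 = detect_transients(compute_dff(tm))
        tm2 = TraceMatrix(values=tm.values * 7.3, frame_rate=FS)
        ev2 = detect_transients(compute_dff(tm2))
        assert [(e.onset_frame, e.peak_frame) for e in ev1] == [
            (e.onset_frame, e.peak_frame) for e in ev2
        ]
        for a, b in zip(ev1, ev2):
            assert a.amplitude == pytest.approx(b.amplitude, rel=1e-9)

    def test_shape_check_discards_symmetric_bump(self):
        # a Gaussian bump (rise == decay) is not a calcium transient
        t = np.arange(0, 60, 1.0 / FS)
        bump = 0.4 * np.exp(-((t - 30.0) ** 2) / (2 * 0.3**2))
        tm = TraceMatrix(values=(100 * (1 + bump))[None, :], frame_rate=FS)
        with_check = detect_transients(compute_dff(tm), shape_check=True)
        without = detect_transients(compute_dff(tm), shape_check=False)
        assert len(without) == 1 and not without[0].shape_ok
        assert with_check == []

    def test_detector_roc_at_default_snr(self, default_population):
        traces, truth = default_population
        events = detect_transients(compute_dff(traces))
        recall, precision = detection_scores(events, truth, FS)
        assert recall >= 0.9
        assert precision >= 0.9


class TestTransientStats:
    def test_frequency_arithmetic(self):
        from neurocalnet.calcium import TransientEvent

        events = [
            TransientEvent(neuron=0, onset_frame=i * 100, peak_frame=i * 100 + 4,
                           amplitude=20.0, rise_time=0.13, decay_time=0.3)
            for i in range(10)
        ]
        df = transient_stats(events, n_neurons=2, duration=300.0)
        assert df.loc[0, "frequency_per_min"] == pytest.approx(2.0)
        assert df.loc[1, "frequency_per_min"] == 0.0
        assert np.isnan(df.loc[1, "mean_amplitude_pct"])
        assert bool(df.loc[1, "silent"])

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            transient_stats([], 1, -5.0)

    def test_frequency_recovers_planted_rate(self):
        # counting mode (shape QC off: the waveform filter trades a known
        # count deficit for purity); the 20-seed mean must sit within two
        # standard errors of the planted Poisson rate
        est = []
        for s in range(20):
            tm, gt = gen_calcium_traces(CalciumSimConfig(seed=s))
            events = detect_transients(compute_dff(tm), shape_check=False)
            df = transient_stats(events, tm.n_neurons, tm.duration)
            est.append(df.frequency_per_min.mean())
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 2.0) <= 2 * se


class TestNormalizeToBaseline:
    def test_simple_ratio(self):
        s = MetricSeries({"pre": 4.0, "d7": 6.0})
        out = normalize_to_baseline(s)
        assert out.values == {"pre": 1.0, "d7": 1.5}

    def test_flat_series_all_ones(self):
        s = MetricSeries({tp: 3.3 for tp in ("pre", "d1", "d7", "d28")})
        out = normalize_to_baseline(s)
        assert all(v == pytest.approx(1.0) for v in out.values.values())

    def test_missing_or_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_baseline(MetricSeries({"d7": 2.0}))
        with pytest.raises(ValueError):
            normalize_to_baseline(MetricSeries({"pre": 0.0, "d7": 2.0}))

    def test_scaled_amplitude_recovered(self):
        # amplitude scaled x0.8 at d7 relative to baseline sessions
        amps = {}
        for label, scale, seed in (("pre", 1.0, 21), ("d7", 0.8, 22)):
            cfg = CalciumSimConfig(seed=seed,
                                   amplitude_mean=0.25 * scale)
            tm, _ = gen_calcium_traces(cfg)
            ev = detect_transients(compute_dff(tm))
            df = transient_stats(ev, tm.n_neurons, tm.duration)
            amps[label] = float(df.mean_amplitude_pct.mean())
        out = normalize_to_baseline(MetricSeries(amps))
        assert out.values["d7"] == pytest.approx(0.8, abs=0.1)
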