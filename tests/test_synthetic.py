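"""Generator contracts: silent limits, coupling structure, determinism."""

import numpy as np
import pytest

from neurocalnet import synthetic as syn
from neurocalnet.synthetic import (
    CalciumSimConfig,
    RampProtocol,
    RoiLayout,
    SpikeTemplate,
    gen_ap_sweep,
    gen_calcium_movie,
    gen_calcium_traces,
    gen_psc_trace,
    gen_updown_session,
)


class TestCalciumTraces:
    def test_silent_limit_is_flat_baseline(self):
        cfg = CalciumSimConfig(event_rate=0.0, noise_sd=0.0, n_neurons=3,
                               duration=30.0, seed=0)
        tm, gt = gen_calcium_traces(cfg)
        assert np.allclose(tm.values, cfg.baseline_f)
        assert all(t.size == 0 for t in gt.spike_times)

    def test_full_coupling_gives_unit_correlation(self):
        cfg = CalciumSimConfig(shared_drive_weight=1.0, noise_sd=0.0,
                               n_neurons=5, duration=120.0, seed=1)
        tm, _ = gen_calcium_traces(cfg)
        r = np.corrcoef(tm.values)
        assert np.allclose(r, 1.0, atol=1e-12)

    def test_uncoupled_mean_correlation_near_zero(self):
        # average over seeds so sparse-event fluctuations cancel
        vals = []
        for s in range(20):
            cfg = CalciumSimConfig(shared_drive_weight=0.0, n_neurons=10,
                                   duration=120.0, seed=s)
            tm, _ = gen_calcium_traces(cfg)
            r = np.corrcoef(tm.values)
            vals.append(r[np.triu_indices(10, 1)].mean())
        assert abs(np.mean(vals)) < 0.01

    def test_correlation_monotone_in_coupling(self):
        means = []
        for w in (0.0, 0.3, 0.6, 1.0):
            per_seed = []
            for s in range(10):
                cfg = CalciumSimConfig(shared_drive_weight=w, seed=400 + s,
                                       n_neurons=10, duration=120.0)
                tm, _ = gen_calcium_traces(cfg)
                r = np.corrcoef(tm.values)
                per_seed.append(r[np.triu_indices(10, 1)].mean())
            means.append(np.mean(per_seed))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_rendered_amplitude_matches_draw_noiseless(self):
        # kernel sampled at 30 Hz loses <1% of peak to grid discretization
        cfg = CalciumSimConfig(noise_sd=0.0, n_neurons=1, event_rate=0.5,
                               duration=300.0, seed=5)
        tm, gt = gen_calcium_traces(cfg)
        dff = tm.values[0] / cfg.baseline_f - 1.0
        for t0, a in zip(gt.spike_times[0], gt.event_amplitudes[0]):
            if t0 > 295:
                continue
            lo = int(t0 * 30)
            peak = dff[lo : lo + 20].max()
            assert peak == pytest.approx(a, rel=0.01)

    def test_seed_determinism_bit_identical(self):
        cfg = CalciumSimConfig(seed=9, n_neurons=4, duration=20.0)
        a, _ = gen_calcium_traces(cfg)
        b, _ = gen_calcium_traces(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CalciumSimConfig(kernel_rise=0.5, kernel_decay=0.1)
        with pytest.raises(ValueError):
            CalciumSimConfig(shared_drive_weight=1.5)
        with pytest.raises(ValueError):
            CalciumSimConfig(noise_sd=float("nan"))

    def test_coupling_matrix_invariants(self):
        cfg = CalciumSimConfig(shared_drive_weight=(0.1, 0.5, 0.9), n_neurons=3,
                               duration=10.0, seed=0)
        _, gt = gen_calcium_traces(cfg)
        m = gt.coupling_matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)


class TestCalciumMovie:
    def test_single_constant_roi_exact(self):
        cfg = CalciumSimConfig(event_rate=0.0, noise_sd=0.0, n_neurons=1,
                               duration=2.0, seed=0)
        tm, _ = gen_calcium_traces(cfg)
        layout = RoiLayout(frame_shape=(64, 64), n_rois=1, radius=5,
                           pixel_noise_sd=0.0)
        mov, gt = gen_calcium_movie(tm, layout)
        mask = gt.roi_masks[0]
        np.testing.assert_allclose(mov.data[:, mask].mean(axis=1), tm.values[0])

    def test_independent_rois_uncorrelated(self):
        vals = []
        for s in range(20):
            cfg = CalciumSimConfig(n_neurons=2, duration=60.0, seed=s)
            tm, _ = gen_calcium_traces(cfg)
            layout = RoiLayout(frame_shape=(64, 64), n_rois=2, radius=5)
            mov, gt = gen_calcium_movie(tm, layout, seed=s)
            t0 = mov.data[:, gt.roi_masks[0]].mean(axis=1)
            t1 = mov.data[:, gt.roi_masks[1]].mean(axis=1)
            vals.append(np.corrcoef(t0, t1)[0, 1])
        assert abs(np.mean(vals)) < 0.05

    def test_default_layout_25_disjoint_rois(self):
        cfg = CalciumSimConfig(duration=2.0, seed=0)
        tm, _ = gen_calcium_traces(cfg)
        mov, gt = gen_calcium_movie(tm, RoiLayout())
        assert len(gt.roi_masks) == 25
        assert np.max(np.sum(gt.roi_masks, axis=0)) == 1  # disjoint

    def test_overlapping_layout_rejected(self):
        cfg = CalciumSimConfig(n_neurons=25, duration=2.0, seed=0)
        tm, _ = gen_calcium_traces(cfg)
        layout = RoiLayout(frame_shape=(32, 32), n_rois=25, radius=5)
        with pytest.raises(ValueError):
            gen_calcium_movie(tm, layout)


class TestPscGenerator:
    def test_zero_rate_flat(self):
        sw, gt = gen_psc_trace(rate=0.0, amp_mean=20.0, duration=5.0,
                               noise_sd=0.0, seed=0)
        assert gt.psc_times.size == 0
        assert np.allclose(sw.signal, sw.signal[0])

    def test_poisson_mean_count(self):
        counts = [
            gen_psc_trace(rate=2.0, amp_mean=20.0, duration=100.0, seed=s)[1]
            .psc_times.size
            for s in range(50)
        ]
        # Poisson(200): SE of the 50-seed mean is 2
        assert np.mean(counts) == pytest.approx(200.0, abs=6.0)

    def test_polarity_sign_convention(self):
        swe, _ = gen_psc_trace(2.0, 20.0, "EPSC", 10.0, 0.0, seed=1)
        swi, _ = gen_psc_trace(2.0, 20.0, "IPSC", 10.0, 0.0, seed=1)
        base_e = np.median(swe.signal)
        base_i = np.median(swi.signal)
        assert swe.signal.min() < base_e - 1  # inward deflections
        assert swi.signal.max() > base_i + 1  # outward deflections
        np.testing.assert_allclose(swe.signal - base_e, -(swi.signal - base_i),
                                   atol=1e-9)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            gen_psc_trace(rate=1.0, amp_mean=-5.0)


class TestApGenerator:
    def test_gaussian_template_fwhm_closed_form(self):
        t = SpikeTemplate(kind="gaussian", height_mv=80.0, sigma_ms=0.5)
        truth = t.truth_features()
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 0.5
        # measured from the dV/dt crossing, so slightly narrower than the
        # full FWHM; agreement within one 10-kHz sample
        assert truth["half_width"] == pytest.approx(fwhm, abs=0.1)

    def test_rect_template_area_closed_form(self):
        t = SpikeTemplate(kind="rect", height_mv=60.0, width_ms=1.5)
        truth = t.truth_features()
        assert truth["area"] == pytest.approx(60.0 * 1.5)
        assert truth["amplitude"] == pytest.approx(60.0)

    def test_no_template_zero_spikes(self):
        sw, feats = gen_ap_sweep(n_spikes=0)
        assert feats.spike_count == 0

    def test_template_wider_than_sweep_rejected(self):
        proto = RampProtocol(pre_s=0.01, hyper_s=0.01, ramp_s=0.01)
        with pytest.raises(ValueError):
            gen_ap_sweep(proto, SpikeTemplate(sigma_ms=100.0))


class TestUpDownGenerator:
    def test_threshold_below_range_all_positive(self):
        # effectively infinite slope, threshold below the bottom filament
        with pytest.warns(UserWarning):
            sess = gen_updown_session(0.01, slope_log10=1e-6, seed=0)
        assert all(sess.responses)

    def test_threshold_above_range_all_negative(self):
        with pytest.warns(UserWarning):
            sess = gen_updown_session(3.0, slope_log10=1e-6, seed=0)
        assert not any(sess.responses)

    def test_steep_psychometric_alternates_at_boundary(self):
        # threshold between 0.4 and 0.6 g: after convergence the staircase
        # oscillates across that boundary
        sess = gen_updown_session(0.49, slope_log10=1e-6, seed=3, n_trials=12)
        forces = sess.forces[2:]
        assert set(forces) <= {0.4, 0.6}

    def test_determinism(self):
        a = gen_updown_session(0.6, seed=11)
        b = gen_updown_session(0.6, seed=11)
        assert a.forces == b.forces and a.responses == b.responses
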