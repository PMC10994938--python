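"""Motion traces, phantom rendering, localisation, and the tracking chain."""

import numpy as np
import pytest

from mrisr.image import GrayImage
from mrisr.tracking_sim import (ChainTiming, LostTargetError, MLCSpec,
                                MotionTrace, PhantomSpec, estimate_latency,
                                experiment_suite, gen_breathing_trace,
                                gen_sinusoid_trace, geometric_error,
                                latency_corrected_error, mlc_respond,
                                render_frame, run_chain, template_match)


def delayed_copy(trace: MotionTrace, tau: float) -> MotionTrace:
    """Pure-delay aperture: same samples, timestamps shifted later."""
    return MotionTrace(trace.t + tau, trace.x.copy())


class TestSinusoidTrace:
    def test_closed_form_value(self):
        tr = gen_sinusoid_trace(10.0, 0.25, 2.0, 100.0)
        i = np.argmin(np.abs(tr.t - 1.0))
        assert tr.x[i] == pytest.approx(10 * np.sin(np.pi / 2))

    def test_zero_mean_over_integer_periods(self):
        tr = gen_sinusoid_trace(5.0, 0.5, 8.0, 64.0)
        assert abs(tr.x.mean()) < 1e-9

    def test_rms_is_amplitude_over_sqrt2(self):
        tr = gen_sinusoid_trace(7.0, 0.25, 8.0, 64.0)
        assert np.sqrt(np.mean(tr.x ** 2)) == pytest.approx(7 / np.sqrt(2),
                                                            rel=1e-6)

    def test_undersampling_rejected(self):
        with pytest.raises(ValueError):
            gen_sinusoid_trace(10, 2.0, 10, 3.0)


class TestBreathingTrace:
    def test_seed_determinism(self):
        a = gen_breathing_trace(seed=3, duration=20, rate=10)
        b = gen_breathing_trace(seed=3, duration=20, rate=10)
        assert np.array_equal(a.x, b.x)

    def test_degenerates_to_sinusoid(self):
        br = gen_breathing_trace(seed=1, duration=16, rate=20,
                                 period_jitter=0.0, amplitude_jitter=0.0,
                                 drift=0.0)
        sin = gen_sinusoid_trace(10.0, 1 / 4.0, 16, 20)
        assert np.allclose(br.x, sin.x, atol=1e-9)

    def test_spectrum_peak_near_breathing_frequency(self):
        tr = gen_breathing_trace(seed=8, duration=120, rate=10)
        x = tr.x - tr.x.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), 0.1)
        # ignore sub-0.1 Hz drift band when locating the respiratory peak
        band = freqs > 0.1
        fpeak = freqs[band][np.argmax(spec[band])]
        assert fpeak == pytest.approx(0.25, rel=0.1)


class TestRenderFrame:
    def test_centered_disc_centroid(self):
        spec = PhantomSpec()
        f = render_frame(spec, 0.0, 64)
        w = f.pixels - spec.background
        rows, cols = np.indices(f.shape)
        cy = (w * rows).sum() / w.sum()
        cx = (w * cols).sum() / w.sum()
        assert cy == pytest.approx(31.5, abs=0.05)
        assert cx == pytest.approx(31.5, abs=0.05)

    def test_displacement_moves_centroid_exactly(self):
        spec = PhantomSpec()
        f0 = render_frame(spec, 0.0, 64)
        f2 = render_frame(spec, 2 * 6.25, 64)  # two LR pixels in mm
        _, cols = np.indices(f0.shape)

        def cx(f):
            w = f.pixels - spec.background
            return (w * cols).sum() / w.sum()

        assert cx(f2) - cx(f0) == pytest.approx(2.0, abs=0.01)

    def test_disc_area_matches_analytic(self):
        spec = PhantomSpec()
        f = render_frame(spec, 0.0, 256)
        spacing = 400 / 256
        half = (spec.target_intensity + spec.background) / 2
        area = (f.pixels > half).sum()
        assert area == pytest.approx(np.pi * 30 ** 2 / spacing ** 2, rel=0.02)

    def test_out_of_field_rejected(self):
        with pytest.raises(ValueError):
            render_frame(PhantomSpec(), 180.0, 64)


class TestTemplateMatch:
    @pytest.fixture
    def scene(self):
        spec = PhantomSpec()
        frame = render_frame(spec, 0.0, 64)
        half = int(np.ceil(30 / 6.25)) + 4
        c = 32
        template = GrayImage(
            frame.pixels[c - half:c + half, c - half:c + half], frame.spacing)
        ref = (float(c - half), float(c - half))
        return spec, template, ref

    def test_reference_position_gives_zero_displacement(self, scene):
        spec, template, ref = scene
        frame = render_frame(spec, 0.0, 64)
        d = template_match(frame, template, ref)
        assert np.abs(d).max() < 1e-9

    def test_integer_shift_in_mm(self, scene):
        spec, template, ref = scene
        frame = render_frame(spec, 3 * 6.25, 64)
        d = template_match(frame, template, ref, subpixel=False)
        assert d[1] == pytest.approx(3 * 6.25)
        assert d[0] == pytest.approx(0.0)

    def test_subpixel_shift_recovered(self, scene):
        spec, template, ref = scene
        frame = render_frame(spec, 0.5 * 6.25, 64)  # half an LR pixel
        d = template_match(frame, template, ref, subpixel=True)
        assert d[1] == pytest.approx(0.5 * 6.25, abs=0.2 * 6.25)

    def test_lost_target_below_threshold(self, scene):
        spec, template, ref = scene
        blank = GrayImage(np.full((64, 64), spec.background), template.spacing)
        with pytest.raises(LostTargetError):
            template_match(blank, template, ref)


class TestMLCRespond:
    def test_saturated_step(self):
        spec = MLCSpec(max_leaf_velocity=25.0)
        assert mlc_respond(10.0, 0.0, spec, 0.1) == pytest.approx(2.5)

    def test_exact_arrival_within_reach(self):
        spec = MLCSpec(max_leaf_velocity=25.0)
        assert mlc_respond(1.0, 0.0, spec, 0.1) == 1.0

    def test_slow_ramp_zero_steady_state_lag(self):
        spec = MLCSpec(max_leaf_velocity=25.0)
        dt = 0.01
        state = 0.0
        lags = []
        for i in range(1000):
            cmd = 10.0 * (i * dt)  # 10 mm/s < 25 mm/s
            state = mlc_respond(cmd, state, spec, dt)
            lags.append(cmd - state)
        assert abs(lags[-1]) < 1e-9


class TestEstimateLatency:
    def test_zero_for_identical_traces(self):
        tr = gen_sinusoid_trace(10, 0.25, 30, 3.6)
        assert estimate_latency(tr, tr) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_delay_recovered(self):
        tr = gen_sinusoid_trace(10, 0.25, 60, 3.6)
        ap = delayed_copy(tr, 0.350)
        assert estimate_latency(tr, ap) == pytest.approx(0.350, abs=0.005)

    def test_noisy_delay_recovered_within_20ms(self):
        tr = gen_sinusoid_trace(10, 0.25, 60, 3.6)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ap = MotionTrace(tr.t + 0.350,
                             tr.x + 0.5 * rng.standard_normal(len(tr.x)))
            errs.append(abs(estimate_latency(tr, ap) - 0.350))
        assert max(errs) <= 0.02

    def test_unbiased_across_delays_and_frequencies(self):
        for f in (0.1, 0.25):
            tr = gen_sinusoid_trace(10, f, 80, 3.6)
            for tau in (0.1, 0.35, 0.5):
                ap = delayed_copy(tr, tau)
                assert estimate_latency(tr, ap) == pytest.approx(tau, abs=0.005)

    def test_non_sinusoidal_target_rejected(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 30, 1 / 3.6)
        tr = MotionTrace(t, rng.standard_normal(len(t)))
        with pytest.raises(ValueError):
            estimate_latency(tr, tr)


class TestGeometricError:
    def test_identical_traces_zero(self):
        tr = gen_sinusoid_trace(10, 0.25, 10, 10)
        assert geometric_error(tr, tr) == 0.0

    def test_constant_offset(self):
        tr = gen_sinusoid_trace(10, 0.25, 10, 10)
        ap = MotionTrace(tr.t, tr.x + 2.0)
        assert geometric_error(tr, ap) == pytest.approx(2.0)

    def test_delayed_sinusoid_closed_form(self):
        A, f, tau = 10.0, 0.25, 0.3
        tr = gen_sinusoid_trace(A, f, 80, 100.0)
        ap = delayed_copy(tr, tau)
        expected = A * np.sqrt(2) * abs(np.sin(np.pi * f * tau))
        assert geometric_error(tr, ap) == pytest.approx(expected, rel=0.01)

    def test_no_overlap_rejected(self):
        tr = gen_sinusoid_trace(10, 0.25, 5, 10)
        ap = MotionTrace(tr.t + 100.0, tr.x)
        with pytest.raises(ValueError):
            geometric_error(tr, ap)


class TestLatencyCorrectedError:
    def test_exact_cancellation_for_pure_delay(self):
        tr = gen_sinusoid_trace(10, 0.25, 60, 3.6)
        ap = delayed_copy(tr, 0.35)
        assert latency_corrected_error(tr, ap, 0.35) < 1e-6

    def test_noise_floor_recovered(self):
        tr = gen_sinusoid_trace(10, 0.25, 120, 50.0)
        rng = np.random.default_rng(2)
        noise = 0.4 * rng.standard_normal(len(tr.x))
        ap = MotionTrace(tr.t + 0.35, tr.x + noise)
        corrected = latency_corrected_error(tr, ap, 0.35)
        assert corrected == pytest.approx(np.sqrt(np.mean(noise ** 2)),
                                          rel=0.10)

    def test_correction_never_worse_for_pure_delay(self):
        tr = gen_sinusoid_trace(10, 0.25, 60, 3.6)
        ap = delayed_copy(tr, 0.35)
        assert (latency_corrected_error(tr, ap, 0.35)
                <= geometric_error(tr, ap))


class TestRunChain:
    def test_identity_chain(self):
        tr = gen_sinusoid_trace(10, 0.25, 20, 20)
        tgt, ap = run_chain(tr, PhantomSpec(), ChainTiming(frame_period=0.0),
                            MLCSpec(max_leaf_velocity=1e9),
                            localiser=lambda x: x)
        assert geometric_error(tgt, ap) < 1e-9

    def test_injected_stage_delay_recovered(self):
        tr = gen_sinusoid_trace(10, 0.25, 40, 20)
        timing = ChainTiming(frame_period=0.0, recon_delay=0.2,
                             tracking_delay=0.15)
        tgt, ap = run_chain(tr, PhantomSpec(), timing,
                            MLCSpec(max_leaf_velocity=1e9),
                            localiser=lambda x: x)
        assert estimate_latency(tgt, ap) == pytest.approx(0.35, abs=0.01)

    def test_frame_period_contributes_half_period(self):
        tr = gen_sinusoid_trace(10, 0.25, 40, 4.0)
        timing = ChainTiming(frame_period=0.25, recon_delay=0.225)
        tgt, ap = run_chain(tr, PhantomSpec(), timing,
                            MLCSpec(max_leaf_velocity=1e9),
                            localiser=lambda x: x)
        assert estimate_latency(tgt, ap) == pytest.approx(0.35, abs=0.01)

    @pytest.mark.parametrize("sr_method,step", [("none", 400 / 64),
                                                ("bicubic", 400 / 256)])
    def test_measured_displacement_quantisation_follows_grid(self, sr_method,
                                                             step):
        """Without sub-pixel refinement, measured displacements come in
        multiples of the tracking-grid pixel size: fov/64 without
        up-sampling, fov/256 with 4x up-sampling."""
        from mrisr.kspace_ops import kspace_downsample
        from mrisr.sr_core import upsample_bicubic
        from mrisr.tracking_sim import _prepare_tracking

        spec = PhantomSpec()
        sr = (None if sr_method == "none"
              else (lambda im: upsample_bicubic(im, 4)))
        process, template, ref_pos = _prepare_tracking(spec, sr)
        for disp in (3.7, -8.2, 14.9):
            frame = process(disp, None)
            d = template_match(frame, template, ref_pos, subpixel=False)
            assert (d[1] / step) == pytest.approx(round(d[1] / step))
            assert abs(d[1] - disp) <= step  # within one tracking pixel

    def test_hr_acquisition_inflates_latency(self):
        # acquiring natively at 256x256 takes ~(256/64)^2 longer per frame
        tr = gen_sinusoid_trace(10, 0.1, 60, 4.0)
        slow = ChainTiming(frame_period=0.25 * (256 / 64))
        tgt, ap = run_chain(tr, PhantomSpec(), slow,
                            MLCSpec(max_leaf_velocity=1e9),
                            localiser=lambda x: x)
        lat_slow = estimate_latency(tgt, ap)
        fast = ChainTiming(frame_period=0.25)
        tgt, ap = run_chain(tr, PhantomSpec(), fast,
                            MLCSpec(max_leaf_velocity=1e9),
                            localiser=lambda x: x)
        lat_fast = estimate_latency(tgt, ap)
        assert lat_slow > 3 * lat_fast


class TestExperimentSuite:
    def test_bookkeeping_three_repeats_per_method(self):
        table, reports = experiment_suite({"none": "none"}, n_repeats=3,
                                          seed=0, sin_duration=15.0,
                                          breathing_duration=20.0)
        assert len(reports) == 1
        r = reports[0]
        assert r.n_repeats == 3
        assert len(r.latencies) == len(r.rmses) == len(r.rmses_corrected) == 3
        assert set(table.columns) >= {"method", "latency_s", "rmse_mm",
                                      "rmse_corrected_mm"}

    def test_estimated_latency_is_causal(self):
        table, _ = experiment_suite({"none": "none", "bicubic": "bicubic"},
                                    n_repeats=1, seed=4, sin_duration=15.0,
                                    breathing_duration=20.0)
        assert (table["latency_s"] >= 0).all()
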