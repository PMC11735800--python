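"""Background correction, ratio normalization, antiparallel validation, QC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scgmp import synthio, traceproc
from scgmp.protocol import ANP, StimulusEvent
from scgmp.traceproc import (
    QCStatus,
    RatioTrace,
    TraceSet,
    background_correct,
    compute_ratio,
    max_event_peak,
    normalize_baseline,
    process_traceset,
    qc_trace,
    validate_antiparallel,
)


def make_traceset(cfp, yfp, protocol=(), frame_period=5.0, background="bg"):
    return TraceSet(
        frame_period=frame_period,
        cfp=dict(cfp),
        yfp=dict(yfp),
        background_roi=background,
        protocol=list(protocol),
    )


class TestBackgroundCorrect:
    def test_zero_background_leaves_traces_unchanged(self):
        n = 10
        ts = make_traceset(
            {"a": np.full(n, 50.0), "bg": np.zeros(n)},
            {"a": np.full(n, 40.0), "bg": np.zeros(n)},
        )
        out = background_correct(ts)
        np.testing.assert_allclose(out.cfp["a"], 50.0)
        np.testing.assert_allclose(out.yfp["a"], 40.0)

    def test_constant_offset_removed(self):
        n = 10
        ts = make_traceset(
            {"a": np.full(n, 50.0 + 7.0), "bg": np.full(n, 7.0)},
            {"a": np.full(n, 40.0 + 7.0), "bg": np.full(n, 7.0)},
        )
        out = background_correct(ts)
        np.testing.assert_allclose(out.cfp["a"], 50.0)
        np.testing.assert_allclose(out.yfp["a"], 40.0)

    def test_recovers_generator_truth_offsets(self, noiseless_bundle):
        cfg = synthio.TraceDatasetConfig(n_cells=16, noise_sd=0.0)
        out = background_correct(noiseless_bundle.traces)
        roi = noiseless_bundle.traces.rois[0]
        # noiseless channels start at CFP0/YFP0 after offset removal; the
        # only residual is the background ROI's own noise in the scalar mean
        assert out.cfp[roi][0] == pytest.approx(cfg.cfp0, rel=1e-3)
        assert out.yfp[roi][0] == pytest.approx(cfg.yfp0, rel=1e-3)

    def test_background_brighter_than_cells_rejected(self):
        n = 10
        ts = make_traceset(
            {"a": np.full(n, 5.0), "bg": np.full(n, 50.0)},
            {"a": np.full(n, 5.0), "bg": np.full(n, 50.0)},
        )
        with pytest.raises(ValueError, match="background"):
            background_correct(ts)


class TestComputeRatio:
    def test_equal_channels_give_unit_ratio(self):
        n = 8
        ts = make_traceset(
            {"a": np.full(n, 3.0), "bg": np.zeros(n)},
            {"a": np.full(n, 3.0), "bg": np.zeros(n)},
        )
        np.testing.assert_allclose(compute_ratio(ts)["a"], 1.0)

    def test_single_frame_arithmetic(self):
        cfp = np.ones(5)
        yfp = np.ones(5)
        cfp[2] = 1.1
        yfp[2] = 0.9
        ts = make_traceset(
            {"a": cfp, "bg": np.zeros(5)}, {"a": yfp, "bg": np.zeros(5)}
        )
        r = compute_ratio(ts)["a"]
        assert r[2] == pytest.approx(11.0 / 9.0)

    def test_nonpositive_yfp_flagged(self):
        yfp = np.ones(5)
        yfp[3] = 0.0
        ts = make_traceset(
            {"a": np.ones(5), "bg": np.zeros(5)}, {"a": yfp, "bg": np.zeros(5)}
        )
        r = compute_ratio(ts)["a"]
        assert np.all(np.isnan(r))
        rt = normalize_baseline(r, (0, 3), roi="a")
        assert rt.qc_status is QCStatus.REJECT_BASELINE

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(0)
        cfp = 100 + rng.random(20)
        yfp = 90 + rng.random(20)
        ts1 = make_traceset(
            {"a": cfp, "bg": np.zeros(20)}, {"a": yfp, "bg": np.zeros(20)}
        )
        ts2 = make_traceset(
            {"a": gain * cfp, "bg": np.zeros(20)},
            {"a": gain * yfp, "bg": np.zeros(20)},
        )
        np.testing.assert_allclose(
            compute_ratio(ts1)["a"], compute_ratio(ts2)["a"], rtol=1e-9
        )


class TestNormalizeBaseline:
    def test_constant_series(self):
        rt = normalize_baseline(np.full(30, 2.5), (0, 10))
        np.testing.assert_allclose(rt.r, 1.0)
        assert rt.baseline_noise_sd == 0.0

    def test_baseline_mean_is_one_exactly(self, rng):
        r = 1.25 + 0.05 * rng.standard_normal(60)
        rt = normalize_baseline(r, (0, 25))
        assert np.mean(rt.r[0:25]) == pytest.approx(1.0, abs=1e-12)

    def test_plateau_matches_sensor_closed_form(self, noiseless_bundle):
        ts = background_correct(noiseless_bundle.traces)
        ratios = compute_ratio(ts)
        model = synthio.SensorModel()
        for roi in ts.rois:
            prof = noiseless_bundle.truth[roi]
            if prof.true_class != "ANP_PREF":
                continue
            rt = normalize_baseline(ratios[roi], (0, 25), roi=roi)
            ev = ts.protocol[0]  # ANP 50 nM
            plateau = rt.r[ev.end_frame - 1]
            c_end = synthio.simulate_cgmp_course(
                ts.protocol, prof, len(rt.r), ts.frame_period
            )[ev.end_frame - 1]
            expected = synthio.sensor_ratio(c_end, model) / model.r0
            assert plateau == pytest.approx(expected, rel=1e-3)
            break

    def test_baseline_overlapping_stimulus_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            normalize_baseline(
                np.ones(60), (0, 40), protocol=[StimulusEvent(ANP, 50, 30, 35)]
            )


class TestAntiparallel:
    def test_noiseless_response_valid_with_corr_near_minus_one(self, noiseless_bundle):
        ts = background_correct(noiseless_bundle.traces)
        roi = next(
            r for r in ts.rois if noiseless_bundle.truth[r].true_class == "ANP_PREF"
        )
        ok, score = validate_antiparallel(ts, roi, ts.protocol[0])
        assert ok
        assert score == pytest.approx(-1.0, abs=0.02)

    def test_common_mode_drift_invalid(self):
        # both channels rising (focus drift): positively correlated residuals
        n = 60
        t = np.arange(n, dtype=float)
        rise = 1.0 + 0.01 * np.sin(t / 3.0) + 0.005 * t
        ts = make_traceset(
            {"a": 100 * rise, "bg": np.zeros(n)},
            {"a": 90 * rise, "bg": np.zeros(n)},
            protocol=[StimulusEvent(ANP, 50, 20, 40)],
        )
        ok, score = validate_antiparallel(ts, "a", ts.protocol[0])
        assert not ok
        assert score > 0

    def test_pure_noise_windows_rarely_validate(self):
        # Monte Carlo under the generator's own noise model
        cfg = synthio.TraceDatasetConfig(
            n_cells=60,
            proportions={"ANP_PREF": 0, "ANP_CNP": 0, "CNP_PREF": 0, "NONRESPONDER": 1.0},
        )
        bundle = synthio.generate_trace_dataset(cfg, seed=21)
        ts = background_correct(bundle.traces)
        total = valid = 0
        for roi in ts.rois:
            for ev in ts.protocol:
                ok, _ = validate_antiparallel(ts, roi, ev)
                total += 1
                valid += ok
        assert total == 300
        assert valid / total <= 0.05

    def test_window_too_short_rejected(self, noiseless_bundle):
        ts = background_correct(noiseless_bundle.traces)
        with pytest.raises(ValueError, match="short"):
            validate_antiparallel(
                ts, ts.rois[0], StimulusEvent(ANP, 50, 287, 288), tail=1
            )


def planted_noise_trace(peak_over_noise, noise_sd=0.01, n=90, seed=0):
    """Normalized trace with exact baseline noise SD and a planted peak."""
    rng = np.random.default_rng(seed)
    r = np.ones(n)
    b = rng.standard_normal(25)
    b = (b - b.mean()) / b.std()  # exact zero mean, unit (population) SD
    r[:25] = 1.0 + noise_sd * b
    r[45] = 1.0 + peak_over_noise * noise_sd
    return RatioTrace("x", r, (0, 25), noise_sd)


class TestQC:
    EVENTS = [StimulusEvent(ANP, 50, 40, 50)]

    def test_peak_below_twice_noise_rejected(self):
        rt = planted_noise_trace(1.9)
        assert qc_trace(rt, self.EVENTS) is QCStatus.REJECT_LOW_SIGNAL

    def test_strong_peak_passes(self):
        rt = planted_noise_trace(10.0)
        assert qc_trace(rt, self.EVENTS) is QCStatus.PASS

    def test_boundary_is_exactly_two(self):
        assert qc_trace(planted_noise_trace(2.0), self.EVENTS) is QCStatus.PASS
        assert (
            qc_trace(planted_noise_trace(1.999999), self.EVENTS)
            is QCStatus.REJECT_LOW_SIGNAL
        )

    def test_zero_noise_any_positive_peak_passes(self):
        r = np.ones(90)
        r[45] = 1.0 + 1e-4
        rt = RatioTrace("x", r, (0, 25), 0.0)
        assert qc_trace(rt, self.EVENTS) is QCStatus.PASS

    def test_erratic_baseline_rejected(self):
        rng = np.random.default_rng(3)
        rt = planted_noise_trace(10.0)
        # violent random-walk movement on the late quiet frames
        rt.r[75:] = 1.0 + np.cumsum(rng.choice([-0.08, 0.08], size=15))
        assert qc_trace(rt, self.EVENTS) is QCStatus.REJECT_BASELINE

    def test_qc_monotone_in_peak_amplitude(self):
        statuses = [
            qc_trace(planted_noise_trace(k), self.EVENTS)
            for k in (0.5, 1.0, 1.5, 2.0, 3.0, 5.0)
        ]
        passed = [s is not QCStatus.REJECT_LOW_SIGNAL for s in statuses]
        # once passing, higher amplitude never reverts to low-signal
        assert passed == sorted(passed)


class TestProcessTraceset:
    def test_responders_pass_and_nonresponders_low_signal(self, noisy_bundle):
        rts = process_traceset(noisy_bundle.traces)
        n_resp = n_pass = 0
        for roi, rt in rts.items():
            cls = noisy_bundle.truth[roi].true_class
            if cls != "NONRESPONDER":
                n_resp += 1
                n_pass += rt.qc_status is QCStatus.PASS
        assert n_pass / n_resp >= 0.95

    def test_gain_invariance_end_to_end(self, noiseless_bundle):
        ts = noiseless_bundle.traces
        scaled = TraceSet(
            frame_period=ts.frame_period,
            cfp={k: 3.0 * v for k, v in ts.cfp.items()},
            yfp={k: 3.0 * v for k, v in ts.yfp.items()},
            background_roi=ts.background_roi,
            protocol=ts.protocol,
        )
        a = process_traceset(ts)
        b = process_traceset(scaled)
        for roi in a:
            np.testing.assert_allclose(a[roi].r, b[roi].r, rtol=1e-9)
            assert a[roi].qc_status == b[roi].qc_status
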