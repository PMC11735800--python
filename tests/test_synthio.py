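"""Synthetic generators: sensor law, kinetics, channel construction, plants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scgmp import synthio
from scgmp.protocol import ANP, CNP, NO, StimulusEvent
from scgmp.synthio import (
    BoundaryPlan,
    CellProfile,
    ImageConfig,
    PlantedCell,
    PlantedGene,
    SensorModel,
    TraceDatasetConfig,
    sensor_ratio,
)


class TestSensorRatio:
    def test_baseline_and_half_activation_and_saturation(self):
        m = SensorModel()
        assert sensor_ratio(0.0, m) == m.r0
        # half-activation at the EC50 by definition of the Hill law
        assert sensor_ratio(500.0, m) == pytest.approx(
            m.r0 * (1 + m.delta_rmax / 2), rel=1e-12
        )
        assert sensor_ratio(1e6, m) == pytest.approx(
            m.r0 * (1 + m.delta_rmax), rel=1e-3
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            sensor_ratio(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e6))
    def test_monotone_nondecreasing(self, c):
        m = SensorModel()
        assert sensor_ratio(c + 1.0, m) >= sensor_ratio(c, m)


class TestCgmpCourse:
    def test_nonresponder_all_zero(self):
        prof = synthio.DEFAULT_CLASS_PROFILES["NONRESPONDER"]
        course = synthio.simulate_cgmp_course(
            [StimulusEvent(ANP, 50, 5, 10)], prof, 30
        )
        assert np.all(course == 0)

    def test_rectangular_pulse_limit(self):
        prof = CellProfile("ANP_PREF", amp={ANP: 700.0}, rise_tau=0.0, decay_tau=0.0)
        course = synthio.simulate_cgmp_course(
            [StimulusEvent(ANP, 50, 5, 10)], prof, 20
        )
        expected = np.zeros(20)
        expected[5:10] = 700.0
        np.testing.assert_allclose(course, expected)

    def test_equal_amplitude_doses_give_equal_plateaus(self):
        # the sensor saturates in cGMP, so equal evoked amplitudes at the two
        # matched doses produce equal plateau heights
        prof = CellProfile(
            "ANP_PREF", amp={ANP: 900.0}, rise_tau=2.0, decay_tau=1e-9
        )
        events = [StimulusEvent(ANP, 50, 10, 30), StimulusEvent(ANP, 250, 60, 80)]
        course = synthio.simulate_cgmp_course(events, prof, 100, frame_period=5.0)
        assert course[29] == pytest.approx(course[79], rel=1e-6)

    def test_event_outside_series_rejected(self):
        prof = synthio.DEFAULT_CLASS_PROFILES["ANP_PREF"]
        with pytest.raises(ValueError):
            synthio.simulate_cgmp_course(
                [StimulusEvent(ANP, 50, 5, 40)], prof, 30
            )


class TestRenderTrace:
    def _quiet_profile(self, **kw):
        defaults = dict(
            amp={ANP: 1000.0},
            rise_tau=0.0,
            decay_tau=0.0,
            bleach_tau=float("inf"),
            noise_sd=0.0,
        )
        defaults.update(kw)
        return CellProfile("ANP_PREF", **defaults)

    def test_constant_channels_at_zero_cgmp(self):
        prof = self._quiet_profile()
        cfp, yfp = synthio.render_trace(np.zeros(50), prof, cfp0=800, yfp0=600)
        np.testing.assert_allclose(cfp, 800.0)
        np.testing.assert_allclose(yfp, 600.0)

    def test_antiparallel_on_step(self):
        prof = self._quiet_profile()
        course = np.zeros(40)
        course[20:] = 5e5  # saturating
        cfp, yfp = synthio.render_trace(course, prof)
        assert cfp[21] > cfp[19] and yfp[21] < yfp[19]
        dc = np.diff(cfp)
        dy = np.diff(yfp)
        moving = np.abs(dc) > 1e-12
        assert np.all(np.sign(dc[moving]) == -np.sign(dy[moving]))

    def test_ratio_fidelity_noiseless_unbleached(self):
        model = SensorModel()
        prof = self._quiet_profile()
        course = np.linspace(0, 2000, 60)
        cfp, yfp = synthio.render_trace(course, prof, model, cfp0=1000, yfp0=500)
        expected = sensor_ratio(course, model) * 1000 / 500 / model.r0
        np.testing.assert_allclose(cfp / yfp, expected, rtol=1e-12)

    def test_common_bleach_cancels_in_ratio(self):
        model = SensorModel()
        course = np.linspace(0, 2000, 60)
        bleached = self._quiet_profile(bleach_tau=300.0)
        clean = self._quiet_profile()
        cb, yb = synthio.render_trace(course, bleached, model)
        cc, yc = synthio.render_trace(course, clean, model)
        np.testing.assert_allclose(cb / yb, cc / yc, rtol=1e-12)

    def test_seed_determinism(self):
        prof = self._quiet_profile(noise_sd=0.02)
        course = np.zeros(100)
        a = synthio.render_trace(course, prof, seed=42)
        b = synthio.render_trace(course, prof, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestTraceDataset:
    def test_single_class_proportions(self):
        cfg = TraceDatasetConfig(
            n_cells=10,
            proportions={"ANP_PREF": 1.0, "ANP_CNP": 0, "CNP_PREF": 0, "NONRESPONDER": 0},
        )
        bundle = synthio.generate_trace_dataset(cfg, seed=0)
        assert all(p.true_class == "ANP_PREF" for p in bundle.truth.values())

    def test_exact_split_counts(self):
        cfg = TraceDatasetConfig(n_cells=300)
        bundle = synthio.generate_trace_dataset(cfg, seed=0)
        from collections import Counter

        counts = Counter(p.true_class for p in bundle.truth.values())
        assert counts == {c: 75 for c in synthio.CLASS_LABELS}

    def test_bitwise_determinism(self):
        cfg = TraceDatasetConfig(n_cells=12)
        a = synthio.generate_trace_dataset(cfg, seed=9)
        b = synthio.generate_trace_dataset(cfg, seed=9)
        for roi in a.traces.cfp:
            np.testing.assert_array_equal(a.traces.cfp[roi], b.traces.cfp[roi])
            np.testing.assert_array_equal(a.traces.yfp[roi], b.traces.yfp[roi])

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            TraceDatasetConfig(
                proportions={"ANP_PREF": 0.6, "ANP_CNP": 0.6, "CNP_PREF": 0, "NONRESPONDER": 0}
            )

    def test_background_roi_present(self):
        cfg = TraceDatasetConfig(n_cells=4)
        bundle = synthio.generate_trace_dataset(cfg, seed=0)
        assert bundle.traces.background_roi in bundle.traces.cfp
        assert "background" not in bundle.traces.rois


class TestGriddedImages:
    def test_identity_perturbation_landmarks_equal(self, noiseless_bundle):
        cfg = ImageConfig()
        img = synthio.generate_gridded_images(noiseless_bundle, cfg, seed=1)
        np.testing.assert_allclose(img.landmarks_ref, img.landmarks_if)

    def test_round_cells_have_round_masks(self):
        from scgmp.mapcorr import roundness

        cfg = TraceDatasetConfig(
            n_cells=4,
            proportions={"ANP_PREF": 1.0, "ANP_CNP": 0, "CNP_PREF": 0, "NONRESPONDER": 0},
        )
        bundle = synthio.generate_trace_dataset(cfg, seed=2)
        # force elongation 1 (circles)
        from dataclasses import replace

        bundle.truth = {r: replace(p, elongation=1.0) for r, p in bundle.truth.items()}
        img = synthio.generate_gridded_images(bundle, ImageConfig(), seed=2)
        for label_id in img.roi_for_label:
            assert roundness(img.masks == label_id) == pytest.approx(1.0, abs=0.02)

    def test_masks_nonoverlapping_and_labeled(self, gridded_images):
        img = gridded_images
        labels = set(np.unique(img.masks)) - {0}
        assert labels == set(img.roi_for_label)

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(ValueError):
            ImageConfig(n_landmarks=2)


class TestCountMatrix:
    def test_planted_cells_exact(self):
        from scgmp.scqc import CountMatrix

        plan = BoundaryPlan(
            cells=(PlantedCell(299, 5000), PlantedCell(300, 5000),
                   PlantedCell(400, 5000, mito_pct=20.0))
        )
        res = synthio.generate_count_matrix(800, 40, plan, seed=4)
        m = CountMatrix(res.counts, res.gene_ids, res.cell_ids, res.mito)
        det = dict(zip(m.cell_ids, m.detected_genes_per_cell()))
        tot = dict(zip(m.cell_ids, m.total_counts_per_cell()))
        mito = dict(zip(m.cell_ids, m.mito_pct_per_cell()))
        assert det["planted_cell_0"] == 299 and det["planted_cell_1"] == 300
        assert tot["planted_cell_0"] == 5000
        assert mito["planted_cell_2"] == pytest.approx(20.0)

    def test_metadata_matches_brute_force_recount(self):
        plan = BoundaryPlan(cells=(PlantedCell(50, 400, 10.0),), genes=(PlantedGene(7),))
        res = synthio.generate_count_matrix(200, 30, plan, seed=5)
        dense = np.asarray(res.counts.todense())
        # brute-force detected-gene recount per planted column
        j = res.cell_ids.index("planted_cell_0")
        assert int(np.sum(dense[:, j] > 0)) == 50
        assert int(dense[:, j].sum()) == 400
        gi = res.gene_ids.index("planted_gene_0")
        assert int(np.sum(dense[gi] > 0)) == 7

    def test_reproducible_for_fixed_seed(self):
        a = synthio.generate_count_matrix(100, 20, seed=6)
        b = synthio.generate_count_matrix(100, 20, seed=6)
        assert (a.counts != b.counts).nnz == 0
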