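"""Synthetic generator: temporal design, masks, and signal structure."""

from __future__ import annotations

import numpy as np
import pytest

import somatobci as sb
from somatobci.hrf import convolve_boxcar
from somatobci.synthgen import (
    ConfigError,
    centered_affine,
    make_masks,
    response_weights,
)

from conftest import TINY_GRID, tiny_generator


class TestMakeDesign:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_balanced_classes(self, seed):
        ev = sb.make_design(sb.DesignSpec(), seed)
        counts = ev.class_counts()
        assert counts["foot"] == counts["hand"] == 9

    def test_training_run_timing_sums_to_340_volumes(self):
        spec = sb.DesignSpec()
        ev = sb.make_design(spec, seed=5)
        last = ev.frame.iloc[-1]
        used_rests = np.diff(ev.frame.onset) - spec.trial_duration
        total = (
            spec.lead_in
            + 18 * spec.trial_duration
            + used_rests.sum()
            + (sum(spec.rest_multiset()) - used_rests.sum())  # last trial's rest
            + spec.trailing_rest
        )
        assert total == pytest.approx(680.0)
        assert spec.n_volumes(2.0) == 340
        # last trial's GLM window must fit inside the run
        assert last.onset + 28.0 <= 680.0 - 2.0

    def test_rests_drawn_without_replacement(self):
        spec = sb.DesignSpec()
        ev = sb.make_design(spec, seed=3)
        rests = np.diff(ev.frame.onset) - spec.trial_duration
        observed = sorted(rests)
        expected = sorted(spec.rest_multiset())[:-1]  # last rest unobserved
        # the 17 observed gaps are a sub-multiset of {6x16, 6x18, 6x20}
        for r in set(observed):
            assert observed.count(r) <= expected.count(r) + 1

    def test_zero_trials_gives_empty_table(self):
        ev = sb.make_design(sb.DesignSpec(n_trials_per_class=0), seed=0)
        assert len(ev) == 0

    def test_wrong_multiset_size_rejected(self):
        spec = sb.DesignSpec(rest_durations=(16.0, 18.0))
        with pytest.raises(ConfigError, match="multiset"):
            sb.make_design(spec, seed=0)

    def test_deterministic_given_seed(self):
        a = sb.make_design(sb.DesignSpec(), 11).frame
        b = sb.make_design(sb.DesignSpec(), 11).frame
        assert a.equals(b)

    def test_answer_design_is_single_class(self):
        ev = sb.make_design(sb.DesignSpec(), 0, run_kind="answer",
                            answer_class="hand")
        assert len(ev) == 5
        assert set(ev.frame.condition) == {"hand"}


class TestMasks:
    def test_nested_and_disjoint_on_default_grid(self):
        layout = sb.SomatotopicLayout()
        h = sb.make_masks(
            (40, 40, 20), centered_affine((40, 40, 20)),
            range(10, 100, 10), layout,
        )
        counts = [h.voxel_count("S1", lev) for lev in h.levels("S1")]
        assert counts == sorted(counts, reverse=True)
        assert not np.any(h.select(["S1"], 10) & h.select(["S2"], 10))

    def test_lowest_s2_mask_exceeds_500_voxels(self):
        h = sb.make_masks(
            (40, 40, 20), centered_affine((40, 40, 20)),
            range(10, 100, 10), sb.SomatotopicLayout(),
        )
        assert h.voxel_count("S2", 10) > 500

    def test_layout_requires_foot_right_of_hand(self):
        with pytest.raises(ConfigError):
            sb.SomatotopicLayout(foot_centroid_x=-10, hand_centroid_x=10)


class TestSimulateRun:
    def _noiseless(self, amplitude, seed=0):
        layout = sb.SomatotopicLayout.for_grid(TINY_GRID)
        affine = centered_affine(TINY_GRID)
        h = sb.make_masks(TINY_GRID, affine, [10, 80], layout)
        noise = sb.NoiseModel(sigma=0.0, drift_amplitude=0.0)
        run = sb.simulate_run(
            sb.DesignSpec(), layout, sb.HrfModel(), noise, h,
            amplitude, seed=seed,
        )
        return run, layout

    def test_noiseless_foot_voxel_equals_scaled_regressor(self):
        run, layout = self._noiseless(amplitude=2.0)
        coords = run.voxel_coords
        centroid = np.array([
            layout.foot_centroid_x, layout.s1_core_y, layout.s1_core_z,
        ])
        vox = int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))
        foot_events = run.events.frame.query("condition == 'foot'")
        expected = convolve_boxcar(
            run.volume_times,
            foot_events.onset.to_numpy(),
            foot_events.duration.to_numpy(),
            sb.HrfModel(),
        )
        foot_w, _ = response_weights(layout, run.grid_shape, run.affine)
        residual = run.data[vox] - 100.0 - 2.0 * foot_w[vox] * expected
        # only cross-talk from hand blocks remains (selectivity complement)
        hand_events = run.events.frame.query("condition == 'hand'")
        hand_reg = convolve_boxcar(
            run.volume_times,
            hand_events.onset.to_numpy(),
            hand_events.duration.to_numpy(),
            sb.HrfModel(),
        )
        np.testing.assert_allclose(
            residual,
            2.0 * (1 - layout.s1_selectivity) * foot_w[vox]
            / layout.s1_selectivity * hand_reg
            if layout.s1_selectivity < 1
            else 0.0,
            atol=1e-4,
        )

    def test_block_contrast_scales_linearly_with_amplitude(self):
        contrasts = []
        for amplitude in (1.0, 2.0, 4.0):
            run, layout = self._noiseless(amplitude)
            coords = run.voxel_coords
            centroid = np.array([
                layout.foot_centroid_x, layout.s1_core_y, layout.s1_core_z,
            ])
            vox = int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))
            df = run.events.frame
            tr = run.meta.tr
            means = {}
            for cond in ("foot", "hand"):
                idx = []
                for ev in df[df.condition == cond].itertuples():
                    start = int(ev.onset / tr)
                    idx.extend(range(start + 2, start + 9))  # plateau-ish
                means[cond] = run.data[vox, idx].mean()
            contrasts.append(means["foot"] - means["hand"])
        assert contrasts[0] > 0
        ratios = np.array(contrasts) / contrasts[0]
        np.testing.assert_allclose(ratios, [1.0, 2.0, 4.0], rtol=1e-3)

    def test_same_seed_bit_identical(self):
        gen = tiny_generator(1.0, n_training_runs=2)
        a = sb.simulate_subject(gen, seed=4)
        b = sb.simulate_subject(gen, seed=4)
        for ra, rb in zip(a.all_runs, b.all_runs):
            np.testing.assert_array_equal(ra.data, rb.data)
            assert ra.events.frame.equals(rb.events.frame)


class TestSimulateSubject:
    def test_session_structure(self):
        gen = tiny_generator(1.0, n_training_runs=6, n_answer_runs=2)
        session = sb.simulate_subject(gen, seed=0)
        assert len(session.training_runs) == 6
        assert len(session.answer_runs) == 2
        shapes = {r.grid_shape for r in session.all_runs}
        assert shapes == {TINY_GRID}
        assert session.training_runs[0].meta.n_volumes == 340
        assert session.answer_runs[0].meta.n_volumes == 96

    def test_ground_truth_records_centroids(self):
        session = sb.simulate_subject(tiny_generator(1.0), seed=0)
        gt = session.ground_truth
        assert gt["foot_centroid_x"] > gt["hand_centroid_x"]
        assert len(gt["foot_cluster"]) > 0 and len(gt["hand_cluster"]) > 0
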