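"""Phantom generation and simulated observers."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from radrobust.core import dice
from radrobust.phantom import (
    ObserverModel,
    PhantomSpec,
    StudyConfig,
    generate_phantom,
    generate_study,
    simulate_manual_mask,
    simulate_semiauto_mask,
    smooth_mask,
)


class TestGeneratePhantom:
    def test_noise_free_homogeneous_interior(self):
        spec = PhantomSpec(noise_sd=0.0, spiculation_count=0, edge_blur_fwhm=0.0, seed=1)
        vol, mask = generate_phantom(spec)
        interior = vol.data[mask.data]
        assert np.all(interior == spec.core_intensity)

    def test_determinism(self):
        spec = PhantomSpec(seed=11)
        v1, m1 = generate_phantom(spec)
        v2, m2 = generate_phantom(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(m1.data, m2.data)

    def test_sphere_volume_close_to_analytic(self):
        spec = PhantomSpec(grid_shape=(30, 30, 30), spacing=(1.0, 1.0, 1.0),
                           lesion_radius=10.0, spiculation_count=0, noise_sd=0.0,
                           seed=0)
        _, mask = generate_phantom(spec)
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        assert mask.volume_mm3() == pytest.approx(analytic, rel=0.15)

    def test_lesion_must_fit_grid(self):
        spec = PhantomSpec(grid_shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0),
                           lesion_radius=8.0)
        with pytest.raises(ValueError, match="does not fit"):
            generate_phantom(spec)

    def test_mask_single_component(self, small_phantom):
        _, _, truth = small_phantom
        _, n = ndimage.label(truth.data, structure=np.ones((3, 3, 3), bool))
        assert n == 1


class TestSimulateManualMask:
    def test_zero_noise_equals_smoothed_truth(self, small_phantom):
        _, _, truth = small_phantom
        model = ObserverModel(kind="manual", boundary_jitter_sd=0.0,
                              smoothing_fwhm=3.0, systematic_bias=0.0, seed=0)
        out = simulate_manual_mask(truth, model)
        expected = smooth_mask(truth.data, 3.0, truth.spacing)
        assert np.array_equal(out.data, expected)

    def test_positive_bias_grows_volume(self, small_phantom):
        _, _, truth = small_phantom
        model = ObserverModel(kind="manual", boundary_jitter_sd=0.0,
                              smoothing_fwhm=3.0, systematic_bias=2.0, seed=0)
        out = simulate_manual_mask(truth, model)
        assert out.n_voxels > truth.n_voxels

    def test_determinism_and_overlap(self, small_phantom):
        _, _, truth = small_phantom
        model = ObserverModel(kind="manual", seed=5)
        a = simulate_manual_mask(truth, model)
        b = simulate_manual_mask(truth, model)
        assert np.array_equal(a.data, b.data)
        assert 0.0 < dice(truth, a) <= 1.0

    def test_pairwise_dice_decreases_with_jitter(self, small_phantom):
        """Monte-Carlo monotonicity: more jitter, less inter-observer overlap."""
        _, _, truth = small_phantom

        def mean_pairwise(jitter, rep):
            masks = [
                simulate_manual_mask(
                    truth, ObserverModel(kind="manual", boundary_jitter_sd=jitter,
                                         seed=rep * 100 + i))
                for i in range(5)
            ]
            return np.mean([dice(a, b) for a, b in itertools.combinations(masks, 2)])

        low = np.mean([mean_pairwise(0.4, r) for r in range(10)])
        high = np.mean([mean_pairwise(2.0, r) for r in range(10)])
        assert high < low

    def test_wrong_kind_rejected(self, small_phantom):
        _, _, truth = small_phantom
        with pytest.raises(ValueError):
            simulate_manual_mask(truth, ObserverModel(kind="semiauto"))


class TestSimulateSemiautoMask:
    def test_high_contrast_lesion_recovered(self, clean_phantom):
        _, volume, truth = clean_phantom
        model = ObserverModel(kind="semiauto", boundary_jitter_sd=0.0,
                              smoothing_fwhm=0.0, seed=3)
        out = simulate_semiauto_mask(volume, truth, model)
        assert dice(out, truth) >= 0.95

    def test_runs_vary_less_than_manual_observers(self, small_phantom):
        """Run-to-run GrowCut variation < manual inter-observer variation."""
        _, volume, truth = small_phantom
        semi_dice, manual_dice = [], []
        for rep in range(10):
            s1 = simulate_semiauto_mask(
                volume, truth,
                ObserverModel(kind="semiauto", seed=rep * 2))
            s2 = simulate_semiauto_mask(
                volume, truth,
                ObserverModel(kind="semiauto", seed=rep * 2 + 1))
            semi_dice.append(dice(s1, s2))
            m1 = simulate_manual_mask(
                truth, ObserverModel(kind="manual", boundary_jitter_sd=0.6,
                                     seed=rep * 2))
            m2 = simulate_manual_mask(
                truth, ObserverModel(kind="manual", boundary_jitter_sd=0.6,
                                     seed=rep * 2 + 1))
            manual_dice.append(dice(m1, m2))
        assert np.mean(semi_dice) > np.mean(manual_dice)

    def test_fully_seeded_automaton_returns_truth(self, clean_phantom):
        """Seeding every voxel (truth fg, rest bg) fixes the automaton."""
        from radrobust import growcut

        _, volume, truth = clean_phantom
        seeds = np.where(truth.data, 1, 2).astype(np.int32)
        res = growcut.segment(volume.data, seeds, margin_voxels=2, max_iters=10)
        assert res.converged
        out = growcut.postprocess(res.labels, spacing=truth.spacing)
        assert np.array_equal(out.data, truth.data)

    def test_determinism(self, small_phantom):
        _, volume, truth = small_phantom
        model = ObserverModel(kind="semiauto", seed=9)
        a = simulate_semiauto_mask(volume, truth, model)
        b = simulate_semiauto_mask(volume, truth, model)
        assert np.array_equal(a.data, b.data)


class TestGenerateStudy:
    def test_default_design_counts(self):
        cfg = StudyConfig()
        assert cfg.n_masks_per_tumor == 11

    def test_small_study_structure(self):
        cfg = StudyConfig(n_tumors=2, master_seed=3)
        ds = generate_study(cfg)
        assert len(ds.tumors) == 2
        for case in ds.tumors:
            assert len(case.segmentations) == 11
            groups = [r.group for r in case.segmentations]
            assert groups.count("manual") == 5
            assert groups.count("semiauto") == 6
            for rec in case.segmentations:
                comp, n = ndimage.label(rec.mask.data, np.ones((3, 3, 3), bool))
                assert n == 1  # every observer mask is one component

    def test_study_determinism(self):
        cfg = StudyConfig(n_tumors=1, master_seed=17)
        a = generate_study(cfg)
        b = generate_study(cfg)
        for ca, cb in zip(a.tumors, b.tumors):
            assert np.array_equal(ca.volume.data, cb.volume.data)
            for ra, rb in zip(ca.segmentations, cb.segmentations):
                assert np.array_equal(ra.mask.data, rb.mask.data)
                assert ra.seed == rb.seed

    def test_semiauto_masks_agree_more_than_manual(self):
        """The configured ordering of observer variability, per tumor."""
        cfg = StudyConfig(n_tumors=2, master_seed=23)
        ds = generate_study(cfg)
        for case in ds.tumors:
            by_group = {"manual": [], "semiauto": []}
            for rec in case.segmentations:
                by_group[rec.group].append(rec.mask)
            means = {
                g: np.mean([dice(a, b) for a, b in itertools.combinations(ms, 2)])
                for g, ms in by_group.items()
            }
            assert means["semiauto"] > means["manual"]
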