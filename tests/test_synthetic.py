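"""Synthetic study generator: planted structure and its recoverability."""

import numpy as np
import pytest

from recallseg.connectivity import compute_scene_fc, vectorize_lower_triangle
from recallseg.labels import binarize_labels, score_all_scenes
from recallseg.rpca import rpca_decompose
from recallseg.segmentation import DurationBounds, consensus_scenes
from recallseg.synthetic import (
    StoryConfig,
    SyntheticConfig,
    generate_annotator_proposals,
    generate_study,
    generate_true_scenes,
)
from recallseg.timing import scenes_to_tr_windows


class TestTrueScenes:
    def test_partition_and_range_624s_8(self, rng):
        scenes = generate_true_scenes(rng, 624.0, 8, [f"q{i}" for i in range(25)])
        assert len(scenes) == 8
        assert scenes[0].onset_s == 0.0
        assert scenes[-1].offset_s == 624.0
        for s in scenes:
            assert 45.0 <= s.duration_s <= 120.0
        for a, b in zip(scenes, scenes[1:]):
            assert a.offset_s == b.onset_s
        # every question in exactly one scene, >= 1 per scene
        all_q = [q for s in scenes for q in s.question_ids]
        assert len(all_q) == len(set(all_q)) == 25
        assert all(len(s.question_ids) >= 1 for s in scenes)

    def test_single_scene(self, rng):
        scenes = generate_true_scenes(rng, 60.0, 1, ["q0"])
        assert (scenes[0].onset_s, scenes[0].offset_s) == (0.0, 60.0)

    def test_infeasible_combination(self, rng):
        with pytest.raises(ValueError, match="cannot sum"):
            generate_true_scenes(rng, 200.0, 10, [f"q{i}" for i in range(10)])


class TestAnnotatorProposals:
    def cfg(self, **kw):
        return SyntheticConfig(**{"n_annotators": 5, "seed": 0, **kw})

    def test_no_noise_annotators_identical_and_consensus_exact(self, rng):
        cfg = self.cfg(boundary_jitter_sd_s=0.0, split_merge_prob=0.0)
        truth = generate_true_scenes(rng, 500.0, 6, [f"q{i}" for i in range(12)])
        segs = generate_annotator_proposals(rng, truth, cfg)
        for seg in segs:
            for p, t in zip(seg.proposals, truth):
                assert (p.onset_s, p.offset_s) == (t.onset_s, t.offset_s)
                assert p.question_ids == t.question_ids
        scenes = consensus_scenes(segs, DurationBounds(), validate=False)
        assert [(s.onset_s, s.offset_s) for s in scenes] == [
            (t.onset_s, t.offset_s) for t in truth
        ]

    def test_jitter_averages_out(self):
        """Monte Carlo: consensus boundary error stays below
        3 * jitter_sd / sqrt(n_annotators) on average (scaled-down: 50 seeds)."""
        sd = 3.0
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cfg = self.cfg(boundary_jitter_sd_s=sd)
            truth = generate_true_scenes(rng, 500.0, 6, [f"q{i}" for i in range(12)])
            segs = generate_annotator_proposals(rng, truth, cfg)
            scenes = consensus_scenes(segs, DurationBounds(), validate=False)
            true_bounds = np.array([t.offset_s for t in truth[:-1]])
            got_bounds = np.array([s.offset_s for s in scenes[:-1]])
            errs.append(np.abs(got_bounds - true_bounds).mean())
        assert np.mean(errs) <= 3 * sd / np.sqrt(5)

    def test_proposals_always_contiguous(self, rng):
        cfg = self.cfg(boundary_jitter_sd_s=5.0, split_merge_prob=0.3)
        truth = generate_true_scenes(rng, 600.0, 7, [f"q{i}" for i in range(14)])
        for seg in generate_annotator_proposals(rng, truth, cfg):
            assert seg.proposals[0].onset_s == 0.0
            assert seg.proposals[-1].offset_s == 600.0
            for a, b in zip(seg.proposals, seg.proposals[1:]):
                assert a.offset_s == b.onset_s

    def test_merging_annotator_bridges_groups(self, rng):
        """A merged proposal carries both scenes' questions, so transitive
        question-sharing fuses the two groups into one consensus scene."""
        cfg = self.cfg(boundary_jitter_sd_s=0.0)
        truth = generate_true_scenes(rng, 400.0, 4, [f"q{i}" for i in range(8)])
        segs = generate_annotator_proposals(rng, truth, cfg)
        merged_cfg = self.cfg(boundary_jitter_sd_s=0.0, split_merge_prob=1.0, n_annotators=1)
        merger = generate_annotator_proposals(rng, truth, merged_cfg, story_name="m")
        scenes = consensus_scenes(segs + merger, DurationBounds(), validate=False)
        assert len(scenes) == 1  # one chain through the all-merging annotator
        scenes_without = consensus_scenes(segs, DurationBounds(), validate=False)
        assert len(scenes_without) == 4


class TestTimeSeries:
    def test_no_sparse_yields_smaller_idiosyncratic_part(self):
        """Calibration: without planted sparse perturbations the robust-PCA
        sparse component carries only FC sampling noise, so its share of the
        stacked matrix is well below that of a run with dense perturbations."""

        def sparse_share(density):
            cfg = SyntheticConfig(
                stories=(StoryConfig("s", 400.0, 4, 8),),
                subjects_per_story=12,
                n_rois=10,
                effect_size=0.0,
                sparse_density=density,
                sparse_magnitude=1.2,
                seed=0,
            )
            study = generate_study(cfg)
            wins = scenes_to_tr_windows(
                study.truth.scenes["s"], cfg.timing_for(cfg.stories[0])
            )
            z = np.stack(
                [
                    vectorize_lower_triangle(compute_scene_fc(ts, wins[0], 0).matrix)
                    for ts in study.timeseries["s"]
                ]
            )
            res = rpca_decompose(z)
            return np.linalg.norm(res.sparse) / np.linalg.norm(z)

        assert sparse_share(0.0) < 0.5 * sparse_share(0.15)

    def test_noiseless_single_factor_saturates_fc(self, rng):
        cfg = SyntheticConfig(
            stories=(StoryConfig("s", 120.0, 1, 2),),
            subjects_per_story=1,
            n_rois=4,
            planted_rank=1,
            scene_pattern_var=0.0,
            sparse_density=0.0,
            noise_sd=0.0,
            seed=1,
        )
        study = generate_study(cfg)
        wins = scenes_to_tr_windows(study.truth.scenes["s"], cfg.timing_for(cfg.stories[0]))
        fc = compute_scene_fc(study.timeseries["s"][0], wins[0], 0).matrix
        assert np.allclose(np.abs(fc), 1.0, atol=1e-8)

    def test_default_scale_sample_count(self):
        cfg = SyntheticConfig()
        per_story = [s.n_scenes * cfg.subjects_per_story for s in cfg.stories]
        assert per_story == [360, 450, 360, 270]
        assert sum(per_story) == 1440


class TestRecallCoupling:
    def test_low_fraction_near_target(self, small_study, small_config):
        rows = []
        for story in small_config.stories:
            scores = score_all_scenes(
                small_study.records,
                small_study.truth.scenes[story.name],
                small_study.subjects_for(story.name),
            )
            rows.append(scores.ravel())
        labs = binarize_labels(np.concatenate(rows))
        assert abs((1 - labs.mean()) - 0.25) <= 0.03

    def test_effect_links_labels_to_expression(self, small_study, small_config):
        """Higher planted expression must mean higher scene scores."""
        for story in small_config.stories:
            scores = score_all_scenes(
                small_study.records,
                small_study.truth.scenes[story.name],
                small_study.subjects_for(story.name),
            )
            expr = small_study.truth.expressions[story.name]
            r = np.corrcoef(np.log(expr).ravel(), scores.ravel())[0, 1]
            assert r > 0.5


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = SyntheticConfig(
            stories=(StoryConfig("s", 300.0, 3, 6),),
            subjects_per_story=4,
            n_rois=6,
            seed=9,
        )
        a, b = generate_study(cfg), generate_study(cfg)
        assert np.array_equal(a.timeseries["s"][0].data, b.timeseries["s"][0].data)
        assert [r.score for r in a.records] == [r.score for r in b.records]
        assert [
            (p.onset_s, p.offset_s)
            for seg in a.annotations["s"]
            for p in seg.proposals
        ] == [
            (p.onset_s, p.offset_s)
            for seg in b.annotations["s"]
            for p in seg.proposals
        ]
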