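"""Consensus scene segmentation: validation, matching, averaging, repair."""

import itertools

import numpy as np
import pytest

from recallseg.segmentation import (
    AnnotatorSegmentation,
    ConsensusScene,
    DurationBounds,
    SceneProposal,
    SegmentationError,
    build_consensus_scenes,
    consensus_scenes,
    match_proposals,
    repair_continuity,
    validate_annotator_segmentation,
)


def seg(annotator, windows, duration=None, questions=None):
    """Build an AnnotatorSegmentation from (onset, offset) pairs."""
    if questions is None:
        questions = [{f"q{i}"} for i in range(len(windows))]
    props = tuple(
        SceneProposal(annotator, on, off, frozenset(qs))
        for (on, off), qs in zip(windows, questions)
    )
    return AnnotatorSegmentation(
        annotator, props, duration if duration is not None else windows[-1][1]
    )


class TestValidation:
    @pytest.mark.parametrize(
        "windows, expect_valid, reason_substr",
        [
            # too-short scene fails the 45 s floor
            ([(0, 30), (30, 90)], [False, True], "duration < 45"),
            # in-range, contiguous: all pass
            ([(0, 60), (60, 150)], [True, True], None),
            # 5 s gap exceeds the 0.5 s tolerance
            ([(0, 60), (65, 120)], [False, False], "gap"),
            # 200 s scene exceeds the 120 s ceiling
            ([(0, 200)], [False], "duration > 120"),
        ],
    )
    def test_duration_and_continuity(self, windows, expect_valid, reason_substr):
        report = validate_annotator_segmentation(seg("a", windows), DurationBounds())
        assert [c.valid for c in report.checks] == expect_valid
        if reason_substr is not None:
            all_reasons = "; ".join(r for c in report.checks for r in c.reasons)
            assert reason_substr in all_reasons

    def test_gap_location_reported(self):
        report = validate_annotator_segmentation(seg("a", [(0, 60), (65, 120)]))
        assert report.gap_locations == (60,)

    def test_overlap_location_reported(self):
        report = validate_annotator_segmentation(seg("a", [(0, 60), (55, 120)]))
        assert report.overlap_locations == (55,)

    def test_empty_proposals_is_structured_error(self):
        with pytest.raises(SegmentationError, match="empty"):
            AnnotatorSegmentation("a", (), 100.0)

    def test_unsorted_input_sorted_with_warning(self):
        p1 = SceneProposal("a", 60, 120, frozenset({"q2"}))
        p2 = SceneProposal("a", 0, 60, frozenset({"q1"}))
        with pytest.warns(UserWarning, match="not sorted"):
            s = AnnotatorSegmentation("a", (p1, p2), 120.0)
        assert [p.onset_s for p in s.proposals] == [0, 60]


class TestMatching:
    def test_shared_question_links_two(self):
        a = seg("A", [(0, 60)], 60, [{"q1", "q2"}])
        b = seg("B", [(5, 58)], 58, [{"q2", "q3"}])
        supported, unsupported = match_proposals([a, b])
        assert len(supported) == 1 and len(supported[0]) == 2
        assert not unsupported

    def test_disjoint_questions_unsupported(self):
        a = seg("A", [(0, 60)], 60, [{"q1"}])
        b = seg("B", [(0, 60)], 60, [{"q7"}])
        supported, unsupported = match_proposals([a, b])
        assert not supported
        assert len(unsupported) == 2

    def test_transitive_sharing_groups_three(self):
        a = seg("A", [(0, 60)], 60, [{"q1"}])
        b = seg("B", [(0, 60)], 60, [{"q1", "q2"}])
        c = seg("C", [(0, 60)], 60, [{"q2"}])
        supported, _ = match_proposals([a, b, c])
        assert len(supported) == 1 and len(supported[0]) == 3

    def test_duplicate_annotator_rejected(self):
        a = seg("A", [(0, 60)], 60, [{"q1"}])
        with pytest.raises(SegmentationError, match="duplicate"):
            match_proposals([a, a])

    def test_matches_brute_force_components(self, rng):
        """Oracle: grouping equals connected components of the explicit graph
        over all cross-annotator question-sharing pairs."""
        for trial in range(20):
            n_annot = int(rng.integers(2, 6))
            n_scenes = int(rng.integers(1, 7))
            segs = []
            for a in range(n_annot):
                questions = [
                    set(
                        f"q{j}"
                        for j in rng.choice(12, size=rng.integers(1, 4), replace=False)
                    )
                    for _ in range(n_scenes)
                ]
                windows = [(60.0 * i, 60.0 * (i + 1)) for i in range(n_scenes)]
                segs.append(seg(f"a{a}", windows, 60.0 * n_scenes, questions))
            proposals = [p for s in segs for p in s.proposals]
            # brute force: enumerate all pairs, then union into components
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(range(len(proposals)))
            for i, j in itertools.combinations(range(len(proposals)), 2):
                if (
                    proposals[i].annotator_id != proposals[j].annotator_id
                    and proposals[i].question_ids & proposals[j].question_ids
                ):
                    g.add_edge(i, j)
            expected = {
                frozenset((proposals[i].annotator_id, proposals[i].onset_s) for i in comp)
                for comp in nx.connected_components(g)
            }
            supported, unsupported = match_proposals(segs)
            got = {
                frozenset((p.annotator_id, p.onset_s) for p in grp)
                for grp in supported + unsupported
            }
            assert got == expected


class TestConsensus:
    def test_boundaries_are_means(self):
        a = seg("A", [(100, 160)], 160, [{"q1"}])
        b = seg("B", [(110, 170)], 170, [{"q1"}])
        supported, _ = match_proposals([a, b])
        scenes = build_consensus_scenes(supported, DurationBounds(), 170)
        assert scenes[0].onset_s == pytest.approx(105)
        assert scenes[0].offset_s == pytest.approx(165)

    def test_single_annotator_group_excluded(self):
        a = seg("A", [(0, 60)], 60, [{"q1"}])
        b = seg("B", [(0, 60)], 60, [{"q9"}])
        supported, unsupported = match_proposals([a, b])
        assert supported == []
        with pytest.raises(SegmentationError, match="no consensus"):
            build_consensus_scenes(supported, DurationBounds(), 60)

    def test_identical_proposals_average_to_themselves(self):
        segs = [seg(f"A{i}", [(50, 120)], 120, [{"q1"}]) for i in range(5)]
        supported, _ = match_proposals(segs)
        scenes = build_consensus_scenes(supported, DurationBounds(), 120)
        assert (scenes[0].onset_s, scenes[0].offset_s) == (50, 120)
        assert len(scenes[0].supporting_annotators) == 5

    def test_out_of_bounds_scene_flagged_not_dropped(self):
        segs = [seg(f"A{i}", [(0, 30)], 30, [{"q1"}]) for i in range(2)]
        supported, _ = match_proposals(segs)
        scenes = build_consensus_scenes(supported, DurationBounds(), 30)
        assert len(scenes) == 1 and scenes[0].duration_flag


class TestRepair:
    def scene(self, t, on, off):
        return ConsensusScene(t, on, off, frozenset({"A", "B"}), frozenset({"q"}))

    def test_gap_repaired_to_midpoint(self):
        out = repair_continuity([self.scene(0, 0, 58), self.scene(1, 62, 120)], 120)
        assert (out[0].offset_s, out[1].onset_s) == (60, 60)

    def test_overlap_repaired_to_midpoint(self):
        # midpoint of prev offset 60 and next onset 55, computed by hand
        out = repair_continuity([self.scene(0, 0, 60), self.scene(1, 55, 120)], 120)
        assert out[0].offset_s == pytest.approx(57.5)
        assert out[1].onset_s == pytest.approx(57.5)

    def test_contiguous_input_unchanged(self):
        scenes = [self.scene(0, 0, 60), self.scene(1, 60, 120)]
        out = repair_continuity(scenes, 120)
        assert [(s.onset_s, s.offset_s) for s in out] == [(0, 60), (60, 120)]

    def test_order_inversion_rejected(self):
        # midpoint after scene 1 (16) falls before the midpoint before it (55)
        scenes = [self.scene(0, 0, 100), self.scene(1, 10, 20), self.scene(2, 12, 112)]
        with pytest.raises(SegmentationError, match="invert"):
            repair_continuity(scenes, 112)


class TestPipelineProperties:
    def make_segs(self, rng, n_annot=4, n_scenes=5, duration=300.0):
        bounds = np.linspace(0, duration, n_scenes + 1)
        segs = []
        for a in range(n_annot):
            jit = np.concatenate([[0], rng.uniform(-2, 2, n_scenes - 1), [0]])
            b = bounds + jit
            windows = [(b[i], b[i + 1]) for i in range(n_scenes)]
            questions = [{f"q{i}a", f"q{i}b"} for i in range(n_scenes)]
            segs.append(seg(f"a{a}", windows, duration, questions))
        return segs

    def test_exact_partition(self, rng):
        segs = self.make_segs(rng)
        scenes = consensus_scenes(segs, DurationBounds(30, 120), validate=False)
        assert scenes[0].onset_s == 0
        assert scenes[-1].offset_s == 300.0
        total = sum(s.duration_s for s in scenes)
        assert total == pytest.approx(300.0, abs=1e-9)
        for prev, nxt in zip(scenes, scenes[1:]):
            assert prev.offset_s == nxt.onset_s

    def test_min_support_enforced(self, rng):
        segs = self.make_segs(rng)
        for s in consensus_scenes(segs, DurationBounds(30, 120), validate=False):
            assert len(s.supporting_annotators) >= 2

    def test_annotator_order_invariance(self, rng):
        segs = self.make_segs(rng)
        ref = consensus_scenes(segs, DurationBounds(30, 120), validate=False)
        for perm in itertools.permutations(range(len(segs))):
            out = consensus_scenes(
                [segs[i] for i in perm], DurationBounds(30, 120), validate=False
            )
            assert [(s.onset_s, s.offset_s, s.question_ids) for s in out] == [
                (s.onset_s, s.offset_s, s.question_ids) for s in ref
            ]
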