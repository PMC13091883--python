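"""Consensus scene segmentation from multiple annotators' proposals.

Several annotators (in the motivating studies, large language models reading a
narrative transcript together with its recall questions) each propose a
contiguous segmentation of the narrative into scenes, every scene carrying the
recall-question identifiers anchored to it.  Proposals from distinct annotators
that share at least one recall question are taken to describe the same
underlying scene; groups supported by at least ``min_support`` annotators
become consensus scenes whose onset/offset are the arithmetic means of the
member proposals'.  Averaged boundaries are then repaired to an exact partition
of ``[0, narrative_duration_s]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "SceneProposal",
    "AnnotatorSegmentation",
    "ConsensusScene",
    "DurationBounds",
    "ProposalCheck",
    "ValidationReport",
    "SegmentationError",
    "validate_annotator_segmentation",
    "match_proposals",
    "build_consensus_scenes",
    "repair_continuity",
    "consensus_scenes",
]


class SegmentationError(ValueError):
    """Raised for structurally invalid segmentations or empty consensus."""


@dataclass(frozen=True)
class SceneProposal:
    """One annotator's scene window with its anchored recall questions."""

    annotator_id: str
    onset_s: float
    offset_s: float
    question_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise SegmentationError(
                f"proposal ({self.onset_s}, {self.offset_s}) by "
                f"{self.annotator_id!r}: offset must exceed onset"
            )
        if self.onset_s < 0:
            raise SegmentationError(f"negative onset {self.onset_s}")
        if not self.question_ids:
            raise SegmentationError("proposal must carry at least one question id")
        object.__setattr__(self, "question_ids", frozenset(self.question_ids))

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class AnnotatorSegmentation:
    """A full, ordered scene segmentation of one narrative by one annotator."""

    annotator_id: str
    proposals: tuple[SceneProposal, ...]
    narrative_duration_s: float

    def __post_init__(self) -> None:
        if not self.proposals:
            raise SegmentationError(
                f"annotator {self.annotator_id!r}: empty proposal list"
            )
        props = tuple(self.proposals)
        if any(p.onset_s > q.onset_s for p, q in zip(props, props[1:])):
            warnings.warn(
                f"annotator {self.annotator_id!r}: proposals not sorted by onset; "
                "sorting internally",
                stacklevel=2,
            )
            props = tuple(sorted(props, key=lambda p: (p.onset_s, p.offset_s)))
        object.__setattr__(self, "proposals", props)


@dataclass(frozen=True)
class DurationBounds:
    """Admissible scene duration range and boundary-continuity tolerance."""

    min_s: float = 45.0
    max_s: float = 120.0
    epsilon_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_s < self.max_s:
            raise ValueError(f"require 0 < min_s < max_s, got {self.min_s}, {self.max_s}")
        if self.epsilon_s < 0:
            raise ValueError("epsilon_s must be >= 0")


@dataclass(frozen=True)
class ConsensusScene:
    """A merged scene supported by >= min_support annotators."""

    index_t: int
    onset_s: float
    offset_s: float
    supporting_annotators: frozenset[str]
    question_ids: frozenset[str]
    duration_flag: bool = False

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class ProposalCheck:
    proposal: SceneProposal
    valid: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class ValidationReport:
    annotator_id: str
    checks: tuple[ProposalCheck, ...]
    gap_locations: tuple[float, ...] = ()
    overlap_locations: tuple[float, ...] = ()

    @property
    def all_valid(self) -> bool:
        return all(c.valid for c in self.checks)


def validate_annotator_segmentation(
    seg: AnnotatorSegmentation, bounds: DurationBounds = DurationBounds()
) -> ValidationReport:
    """Check every proposal's duration and the segmentation's continuity.

    A proposal passes iff its duration lies in ``[min_s, max_s]`` and it is
    contiguous (within ``epsilon_s``) with its neighbours, the narrative start,
    and the narrative end.  Gap and overlap positions are reported.
    """
    props = seg.proposals
    reasons: list[list[str]] = [[] for _ in props]
    gaps: list[float] = []
    overlaps: list[float] = []
    eps = bounds.epsilon_s

    for i, p in enumerate(props):
        if p.duration_s < bounds.min_s:
            reasons[i].append(f"duration < {bounds.min_s:g}")
        elif p.duration_s > bounds.max_s:
            reasons[i].append(f"duration > {bounds.max_s:g}")

    if abs(props[0].onset_s) > eps:
        reasons[0].append(f"first onset {props[0].onset_s:g} != 0")
    if abs(props[-1].offset_s - seg.narrative_duration_s) > eps:
        reasons[-1].append(
            f"last offset {props[-1].offset_s:g} != narrative end "
            f"{seg.narrative_duration_s:g}"
        )
    for i in range(len(props) - 1):
        delta = props[i + 1].onset_s - props[i].offset_s
        if delta > eps:
            gaps.append(props[i].offset_s)
            reasons[i].append(f"gap of {delta:g} s after offset {props[i].offset_s:g}")
            reasons[i + 1].append(f"gap of {delta:g} s before onset {props[i + 1].onset_s:g}")
        elif delta < -eps:
            overlaps.append(props[i + 1].onset_s)
            reasons[i].append(f"overlap of {-delta:g} s at {props[i + 1].onset_s:g}")
            reasons[i + 1].append(f"overlap of {-delta:g} s at {props[i + 1].onset_s:g}")

    checks = tuple(
        ProposalCheck(p, valid=not r, reasons=tuple(r)) for p, r in zip(props, reasons)
    )
    return ValidationReport(seg.annotator_id, checks, tuple(gaps), tuple(overlaps))


def match_proposals(
    segmentations: list[AnnotatorSegmentation], min_support: int = 2
) -> tuple[list[list[SceneProposal]], list[list[SceneProposal]]]:
    """Group proposals across annotators by shared recall questions.

    Proposals from distinct annotators with intersecting question sets are
    linked; groups are the connected components of that graph (so sharing is
    transitive).  Returns ``(supported, unsupported)`` where a group is
    supported iff it contains proposals from >= ``min_support`` distinct
    annotators.
    """
    ids = [s.annotator_id for s in segmentations]
    if len(set(ids)) != len(ids):
        raise SegmentationError(f"duplicate annotator ids in {ids}")
    if len(segmentations) < 2:
        raise SegmentationError("need at least two annotators for consensus")

    proposals = [p for seg in segmentations for p in seg.proposals]
    parent = list(range(len(proposals)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # question -> first proposal index seen carrying it; linking through the
    # shared question is equivalent to linking all pairs, component-wise
    by_question: dict[str, list[int]] = {}
    for i, p in enumerate(proposals):
        for q in p.question_ids:
            by_question.setdefault(q, []).append(i)
    for idxs in by_question.values():
        cross = {proposals[i].annotator_id for i in idxs}
        if len(cross) >= 2:
            for j in idxs[1:]:
                union(idxs[0], j)

    groups: dict[int, list[SceneProposal]] = {}
    for i, p in enumerate(proposals):
        groups.setdefault(find(i), []).append(p)

    def group_key(g: list[SceneProposal]) -> tuple:
        return (
            min(p.onset_s for p in g),
            min(p.offset_s for p in g),
            min(min(p.question_ids) for p in g),
        )

    supported, unsupported = [], []
    for g in sorted(groups.values(), key=group_key):
        g_sorted = sorted(g, key=lambda p: (p.annotator_id, p.onset_s))
        n_annot = len({p.annotator_id for p in g})
        (supported if n_annot >= min_support else unsupported).append(g_sorted)
    return supported, unsupported


def build_consensus_scenes(
    groups: list[list[SceneProposal]],
    bounds: DurationBounds,
    narrative_duration_s: float,
) -> list[ConsensusScene]:
    """Average each supported group's onsets/offsets into one consensus scene.

    Scenes are sorted by (onset, offset, smallest question id) and indexed from
    0; scenes whose averaged duration falls outside ``bounds`` are flagged, not
    dropped (dropping would break continuity).
    """
    if not groups:
        raise SegmentationError("no consensus: zero supported groups")
    def _mean(values: list[float]) -> float:
        # exact for unanimous proposals (sum/n can lose the last bit)
        if all(v == values[0] for v in values):
            return values[0]
        return math.fsum(values) / len(values)

    raw = []
    for g in groups:
        onset = _mean([p.onset_s for p in g])
        offset = _mean([p.offset_s for p in g])
        raw.append(
            (
                onset,
                offset,
                frozenset(p.annotator_id for p in g),
                frozenset().union(*(p.question_ids for p in g)),
            )
        )
    raw.sort(key=lambda s: (s[0], s[1], min(s[3])))
    return [
        ConsensusScene(
            index_t=t,
            onset_s=onset,
            offset_s=offset,
            supporting_annotators=supp,
            question_ids=qs,
            duration_flag=not bounds.min_s <= offset - onset <= bounds.max_s,
        )
        for t, (onset, offset, supp, qs) in enumerate(raw)
    ]


def repair_continuity(
    scenes: list[ConsensusScene], narrative_duration_s: float
) -> list[ConsensusScene]:
    """Snap averaged boundaries to an exact partition of the narrative.

    Each adjacent pair's shared boundary becomes the midpoint of
    (previous offset, next onset); the first onset is clamped to 0 and the last
    offset to the narrative end.  Output scenes are exactly contiguous.
    """
    if not scenes:
        raise SegmentationError("no scenes to repair")
    onsets = [s.onset_s for s in scenes]
    offsets = [s.offset_s for s in scenes]
    bounds = [0.0]
    for i in range(len(scenes) - 1):
        bounds.append(0.5 * (offsets[i] + onsets[i + 1]))
    bounds.append(float(narrative_duration_s))
    bad = [t for t in range(len(scenes)) if bounds[t + 1] <= bounds[t]]
    if bad:
        raise SegmentationError(
            f"continuity repair would invert scene order at indices {bad}"
        )
    return [
        replace(s, index_t=t, onset_s=bounds[t], offset_s=bounds[t + 1])
        for t, s in enumerate(scenes)
    ]


def consensus_scenes(
    segmentations: list[AnnotatorSegmentation],
    bounds: DurationBounds = DurationBounds(),
    min_support: int = 2,
    narrative_duration_s: float | None = None,
    validate: bool = True,
) -> list[ConsensusScene]:
    """Full consensus pipeline: validate, match, average, repair.

    ``narrative_duration_s`` defaults to the annotators' (identical) stated
    duration.  With ``validate=True`` any invalid proposal aborts the run.
    """
    if narrative_duration_s is None:
        durations = {s.narrative_duration_s for s in segmentations}
        if len(durations) != 1:
            raise SegmentationError(
                f"annotators disagree on narrative duration: {sorted(durations)}"
            )
        narrative_duration_s = durations.pop()
    if validate:
        for seg in segmentations:
            report = validate_annotator_segmentation(seg, bounds)
            if not report.all_valid:
                failed = [c for c in report.checks if not c.valid]
                raise SegmentationError(
                    f"annotator {seg.annotator_id!r}: "
                    + "; ".join(r for c in failed for r in c.reasons)
                )
    supported, _ = match_proposals(segmentations, min_support=min_support)
    scenes = build_consensus_scenes(supported, bounds, narrative_duration_s)
    scenes = repair_continuity(scenes, narrative_duration_s)
    return [
        replace(
            s,
            duration_flag=not bounds.min_s <= s.duration_s <= bounds.max_s,
        )
        for s in scenes
    ]
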