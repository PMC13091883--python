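"""Scene-level recall scores and high/low labels from per-question answers.

Each subject answers recall questions anchored to scenes; a scene's behavioral
label is the mean of the subject's scores over that scene's questions,
binarized either at a fixed threshold or at a class-ratio quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import ConsensusScene

__all__ = [
    "RecallRecord",
    "SceneLabel",
    "score_scene_recall",
    "score_all_scenes",
    "binarize_labels",
]


@dataclass(frozen=True)
class RecallRecord:
    subject_id: str
    question_id: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"score {self.score} for ({self.subject_id}, {self.question_id}) "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class SceneLabel:
    scene_index: int
    subject_id: str
    mean_score: float
    label: str  # "high" | "low"


def _index_records(records: list[RecallRecord]) -> dict[tuple[str, str], float]:
    idx: dict[tuple[str, str], float] = {}
    for r in records:
        key = (r.subject_id, r.question_id)
        if key in idx:
            raise ValueError(f"duplicate recall record for {key}")
        idx[key] = r.score
    return idx


def score_scene_recall(
    records: list[RecallRecord],
    scene: ConsensusScene,
    subject_id: str,
    missing: str = "error",
) -> float:
    """Mean of the subject's scores over the scene's questions.

    ``missing='error'`` (default) raises if any question is unanswered;
    ``missing='available'`` averages over the answered subset with a warning.
    """
    idx = _index_records(records)
    scores = []
    absent = []
    for q in sorted(scene.question_ids):
        key = (subject_id, q)
        if key in idx:
            scores.append(idx[key])
        else:
            absent.append(q)
    if absent:
        if missing == "error":
            raise ValueError(
                f"subject {subject_id!r} missing answers for scene "
                f"{scene.index_t} questions {absent}"
            )
        warnings.warn(
            f"subject {subject_id!r}: averaging over available answers only "
            f"(missing {absent})",
            stacklevel=2,
        )
    if not scores:
        raise ValueError(f"subject {subject_id!r}: no answers for scene {scene.index_t}")
    return float(np.mean(scores))


def score_all_scenes(
    records: list[RecallRecord],
    scenes: list[ConsensusScene],
    subject_ids: list[str],
    missing: str = "error",
) -> np.ndarray:
    """(W, M) matrix of mean scene scores, scene-major to match FeatureTensor."""
    return np.array(
        [
            [score_scene_recall(records, sc, sid, missing=missing) for sid in subject_ids]
            for sc in scenes
        ]
    )


def binarize_labels(
    scores: np.ndarray,
    rule: str = "quantile",
    threshold: float = 0.5,
    quantile: float = 0.25,
    tie_policy: str = "fill",
) -> np.ndarray:
    """Binary high(1)/low(0) labels from mean scene scores.

    ``rule='threshold'`` labels high iff score >= ``threshold``.
    ``rule='quantile'`` labels the lowest ``quantile`` fraction low, matching a
    target class ratio (default 0.25, i.e. low:high of 1:3).  Scene means over
    a handful of questions are coarsely discrete, so ties at the quantile cut
    are common; ``tie_policy='fill'`` (default) fills the low quota exactly,
    breaking boundary ties deterministically by sample order, while
    ``tie_policy='high'`` sends every tied-at-the-cut sample to high (which can
    leave the low class far below — even at zero — its target share when the
    bottom score value is heavily tied).
    """
    s = np.asarray(scores, dtype=float).ravel()
    if rule == "threshold":
        return (s >= threshold).astype(int)
    if rule == "quantile":
        if not 0 < quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if tie_policy not in ("fill", "high"):
            raise ValueError(f"unknown tie_policy {tie_policy!r}")
        if np.ptp(s) == 0:
            raise ValueError("degenerate distribution: all scene scores identical")
        k = int(np.floor(quantile * s.size))
        labels = np.ones(s.size, dtype=int)
        if k > 0:
            if tie_policy == "fill":
                order = np.argsort(s, kind="stable")
                labels[order[:k]] = 0
            else:
                cut = np.sort(s)[k - 1]
                labels[s < cut] = 0
                # the cut value itself is low only when untied
                if np.sum(s == cut) == 1:
                    labels[s == cut] = 0
        return labels
    raise ValueError(f"unknown rule {rule!r}")
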