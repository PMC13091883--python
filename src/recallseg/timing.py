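"""Seconds <-> TR conversion and scene-window mapping onto the scanner run.

The acquisition geometry is: ``lead_in_trs`` TRs of scanning before the audio
clip starts, then ``clip_story_onset_s`` seconds of in-clip silence before the
narrative itself.  Narrative-relative scene times are therefore offset by
``lead_in_trs * tr_s + clip_story_onset_s`` before being binned into 0-based,
half-open TR windows (floor on onsets, ceil on offsets, so windows over-cover).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .segmentation import ConsensusScene

__all__ = [
    "AcquisitionTiming",
    "TRWindow",
    "seconds_to_tr_count",
    "tr_count_to_seconds",
    "scene_to_tr_window",
    "scenes_to_tr_windows",
]


@dataclass(frozen=True)
class AcquisitionTiming:
    tr_s: float = 1.5
    lead_in_trs: int = 8
    clip_story_onset_s: float = 0.0
    run_trs: int = 0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.lead_in_trs < 0 or self.clip_story_onset_s < 0:
            raise ValueError("lead-in must be non-negative")
        if self.run_trs <= self.lead_in_trs:
            raise ValueError("run_trs must exceed lead_in_trs")

    @property
    def story_offset_s(self) -> float:
        """Seconds of scan time before the narrative starts."""
        return self.lead_in_trs * self.tr_s + self.clip_story_onset_s


@dataclass(frozen=True)
class TRWindow:
    """Half-open, 0-based TR index window [start_tr, end_tr)."""

    start_tr: int
    end_tr: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_tr < self.end_tr:
            raise ValueError(f"invalid TR window [{self.start_tr}, {self.end_tr})")

    def __len__(self) -> int:
        return self.end_tr - self.start_tr


def seconds_to_tr_count(duration_s: float, tr_s: float = 1.5) -> int:
    """Number of TRs needed to cover ``duration_s`` (ceiling convention)."""
    if duration_s < 0:
        raise ValueError(f"negative duration {duration_s}")
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    return math.ceil(duration_s / tr_s - 1e-12)


def tr_count_to_seconds(n_trs: int, tr_s: float = 1.5) -> float:
    """Exact duration of ``n_trs`` repetitions."""
    if n_trs < 0:
        raise ValueError(f"negative TR count {n_trs}")
    return n_trs * tr_s


def scene_to_tr_window(
    scene: ConsensusScene, timing: AcquisitionTiming
) -> TRWindow:
    """Map a narrative-relative scene to its covering scanner TR window."""
    g_on = timing.story_offset_s + scene.onset_s
    g_off = timing.story_offset_s + scene.offset_s
    start = math.floor(g_on / timing.tr_s + 1e-12)
    end = math.ceil(g_off / timing.tr_s - 1e-12)
    if end > timing.run_trs:
        raise ValueError(
            f"scene {scene.index_t}: window end TR {end} exceeds run length "
            f"{timing.run_trs}"
        )
    return TRWindow(start, end)


def scenes_to_tr_windows(
    scenes: list[ConsensusScene], timing: AcquisitionTiming
) -> list[TRWindow]:
    """Map contiguous scenes to non-overlapping TR windows.

    A boundary TR spanning two scenes is assigned to the later scene: where
    raw floor/ceil windows would overlap by one TR, the overlap is dropped
    from the earlier window.
    """
    raw = [scene_to_tr_window(s, timing) for s in scenes]
    out: list[TRWindow] = []
    for i, w in enumerate(raw):
        end = w.end_tr
        if i + 1 < len(raw) and raw[i + 1].start_tr < end:
            end = raw[i + 1].start_tr
        out.append(TRWindow(w.start_tr, end))
    return out
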