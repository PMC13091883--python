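"""Readers and writers for the pipeline's interchange formats.

Formats (all diff-able text except the tensor payload):

* annotator segmentation — JSON: ``{"annotator", "narrative_duration_s",
  "scenes": [{"onset_s", "offset_s", "questions": [...]}]}``
* consensus scenes — JSON list of scene objects
* recall answers — CSV with header ``subject_id,question_id,score``
* ROI time series — TSV, one file per subject, header = ROI ids, rows = TRs,
  plus a manifest CSV mapping ``roi_id,network``
* feature tensors — ``.npy`` array payload with a JSON sidecar carrying
  (W, M, R), roi order and the scene/subject index maps
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import ClassifierSpec
from .connectivity import FeatureTensor, ROITimeSeriesSet
from .labels import RecallRecord
from .rpca import DecompositionResult, SolverConfig
from .segmentation import (
    AnnotatorSegmentation,
    ConsensusScene,
    DurationBounds,
    SceneProposal,
)
from .timing import AcquisitionTiming

__all__ = [
    "read_annotator_segmentation",
    "write_annotator_segmentation",
    "read_consensus_scenes",
    "write_consensus_scenes",
    "read_recall_csv",
    "write_recall_csv",
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_roi_manifest",
    "write_roi_manifest",
    "read_feature_tensor",
    "write_feature_tensor",
    "write_decomposition",
    "read_decomposition",
    "PipelineConfig",
]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _require(obj: dict, key: str, pointer: str):
    if key not in obj:
        raise SchemaError(f"missing key at {pointer}/{key}")
    return obj[key]


def read_annotator_segmentation(path: str | Path) -> AnnotatorSegmentation:
    with open(path) as fh:
        doc = json.load(fh)
    annot = _require(doc, "annotator", "")
    duration = float(_require(doc, "narrative_duration_s", ""))
    scenes = _require(doc, "scenes", "")
    if not isinstance(scenes, list) or not scenes:
        raise SchemaError("/scenes must be a non-empty list")
    proposals = []
    for i, sc in enumerate(scenes):
        onset = float(_require(sc, "onset_s", f"/scenes/{i}"))
        offset = float(_require(sc, "offset_s", f"/scenes/{i}"))
        questions = _require(sc, "questions", f"/scenes/{i}")
        if onset < 0:
            raise SchemaError(f"/scenes/{i}/onset_s is negative")
        try:
            proposals.append(
                SceneProposal(annot, onset, offset, frozenset(map(str, questions)))
            )
        except ValueError as exc:
            raise SchemaError(f"/scenes/{i}: {exc}") from exc
    return AnnotatorSegmentation(annot, tuple(proposals), duration)


def write_annotator_segmentation(seg: AnnotatorSegmentation, path: str | Path) -> None:
    doc = {
        "annotator": seg.annotator_id,
        "narrative_duration_s": seg.narrative_duration_s,
        "scenes": [
            {
                "onset_s": p.onset_s,
                "offset_s": p.offset_s,
                "questions": sorted(p.question_ids),
            }
            for p in seg.proposals
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def write_consensus_scenes(scenes: list[ConsensusScene], path: str | Path) -> None:
    doc = [
        {
            "index": s.index_t,
            "onset_s": s.onset_s,
            "offset_s": s.offset_s,
            "supporters": sorted(s.supporting_annotators),
            "questions": sorted(s.question_ids),
            "duration_flag": s.duration_flag,
        }
        for s in scenes
    ]
    Path(path).write_text(json.dumps(doc, indent=2))


def read_consensus_scenes(path: str | Path) -> list[ConsensusScene]:
    doc = json.loads(Path(path).read_text())
    return [
        ConsensusScene(
            index_t=int(s["index"]),
            onset_s=float(s["onset_s"]),
            offset_s=float(s["offset_s"]),
            supporting_annotators=frozenset(s["supporters"]),
            question_ids=frozenset(s["questions"]),
            duration_flag=bool(s["duration_flag"]),
        )
        for s in doc
    ]


def read_recall_csv(path: str | Path) -> list[RecallRecord]:
    records: list[RecallRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"subject_id", "question_id", "score"}
        if reader.fieldnames is None or not expected <= set(reader.fieldnames):
            raise SchemaError(
                f"recall CSV must have header subject_id,question_id,score, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            key = (row["subject_id"], row["question_id"])
            if key in seen:
                raise SchemaError(f"line {lineno}: duplicate record for {key}")
            seen.add(key)
            try:
                records.append(
                    RecallRecord(row["subject_id"], row["question_id"], float(row["score"]))
                )
            except ValueError as exc:
                raise SchemaError(f"line {lineno}: {exc}") from exc
    if not records:
        raise SchemaError("no records in recall CSV")
    return records


def write_recall_csv(records: list[RecallRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "question_id", "score"])
        for r in records:
            writer.writerow([r.subject_id, r.question_id, r.score])


def write_roi_timeseries(ts: ROITimeSeriesSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ts.roi_ids) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.10g")


def read_roi_timeseries(
    path: str | Path, subject_id: str, networks: dict[str, str] | None = None
) -> ROITimeSeriesSet:
    with open(path) as fh:
        roi_ids = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ROITimeSeriesSet(subject_id, data, roi_ids, networks or {})


def write_roi_manifest(networks: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["roi_id", "network"])
        for roi, net in networks.items():
            writer.writerow([roi, net])


def read_roi_manifest(path: str | Path) -> dict[str, str]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"roi_id", "network"} <= set(reader.fieldnames):
            raise SchemaError("manifest must have header roi_id,network")
        return {row["roi_id"]: row["network"] for row in reader}


def write_feature_tensor(tensor: FeatureTensor, stem: str | Path) -> None:
    """Write ``<stem>.npy`` (the array) and ``<stem>.json`` (the sidecar)."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), tensor.data)
    sidecar = {
        "W": tensor.data.shape[0],
        "M": tensor.data.shape[1],
        "R": tensor.n_rois,
        "r": tensor.data.shape[2],
        "subject_ids": tensor.subject_ids,
        "scene_indices": tensor.scene_indices,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_tensor(stem: str | Path) -> FeatureTensor:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    return FeatureTensor(
        data,
        sidecar["subject_ids"],
        sidecar["R"],
        scene_indices=sidecar["scene_indices"],
    )


def write_decomposition(result: DecompositionResult, stem: str | Path) -> None:
    stem = Path(stem)
    np.save(stem.parent / (stem.name + "_L.npy"), result.low_rank)
    np.save(stem.parent / (stem.name + "_S.npy"), result.sparse)
    sidecar = {
        "scene_index": result.scene_index,
        "lambda": result.lam,
        "iterations": result.iterations,
        "residual": result.residual,
        "converged": result.converged,
    }
    (stem.parent / (stem.name + ".json")).write_text(json.dumps(sidecar, indent=2))


def read_decomposition(stem: str | Path) -> DecompositionResult:
    stem = Path(stem)
    sidecar = json.loads((stem.parent / (stem.name + ".json")).read_text())
    return DecompositionResult(
        scene_index=sidecar["scene_index"],
        low_rank=np.load(stem.parent / (stem.name + "_L.npy")),
        sparse=np.load(stem.parent / (stem.name + "_S.npy")),
        lam=sidecar["lambda"],
        iterations=sidecar["iterations"],
        residual=sidecar["residual"],
        converged=sidecar["converged"],
    )


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run over a study directory.

    A study directory (as written by ``recallseg simulate`` or assembled from
    real data) holds per-story subdirectories with ``annotations/*.json``,
    ``timeseries/<subject>.tsv``, a shared ``recall.csv``, ``manifest.csv``
    and ``timing.json`` (per-story acquisition blocks).
    """

    study_dir: Path
    out_dir: Path
    stories: list[str]
    timings: dict[str, AcquisitionTiming]
    bounds: DurationBounds = field(default_factory=DurationBounds)
    min_support: int = 2
    networks: tuple[str, ...] = ("DMN", "Auditory")
    solver: SolverConfig = field(default_factory=SolverConfig)
    classifiers: tuple[ClassifierSpec, ...] = (
        ClassifierSpec("logistic"),
        ClassifierSpec("random_forest"),
        ClassifierSpec("svm"),
    )
    label_rule: str = "quantile"
    label_quantile: float = 0.25
    label_threshold: float = 0.5
    cv_unit: str = "sample"
    n_shuffles: int = 0
    seed: int = 0

    @classmethod
    def from_study_dir(cls, study_dir: str | Path, out_dir: str | Path, **kw):
        study_dir = Path(study_dir)
        timing_doc = json.loads((study_dir / "timing.json").read_text())
        timings = {
            name: AcquisitionTiming(
                block["tr_s"],
                block["lead_in_trs"],
                block["clip_story_onset_s"],
                block["run_trs"],
            )
            for name, block in timing_doc.items()
        }
        stories = sorted(timings)
        for story in stories:
            for sub in ("annotations", "timeseries"):
                p = study_dir / story / sub
                if not p.is_dir():
                    raise FileNotFoundError(f"missing {p}")
        for fname in ("recall.csv", "manifest.csv"):
            if not (study_dir / fname).is_file():
                raise FileNotFoundError(f"missing {study_dir / fname}")
        return cls(study_dir, Path(out_dir), stories, timings, **kw)


def write_study(study, study_dir: str | Path) -> Path:
    """Materialize a SyntheticStudy as the on-disk layout the pipeline reads."""
    study_dir = Path(study_dir)
    study_dir.mkdir(parents=True, exist_ok=True)
    timing_doc = {}
    for story in study.config.stories:
        sdir = study_dir / story.name
        (sdir / "annotations").mkdir(parents=True, exist_ok=True)
        (sdir / "timeseries").mkdir(parents=True, exist_ok=True)
        for seg in study.annotations[story.name]:
            write_annotator_segmentation(
                seg, sdir / "annotations" / f"{seg.annotator_id}.json"
            )
        for ts in study.timeseries[story.name]:
            write_roi_timeseries(ts, sdir / "timeseries" / f"{ts.subject_id}.tsv")
        timing = study.config.timing_for(story)
        timing_doc[story.name] = {
            "tr_s": timing.tr_s,
            "lead_in_trs": timing.lead_in_trs,
            "clip_story_onset_s": timing.clip_story_onset_s,
            "run_trs": timing.run_trs,
        }
    write_recall_csv(study.records, study_dir / "recall.csv")
    write_roi_manifest(study.config.networks(), study_dir / "manifest.csv")
    (study_dir / "timing.json").write_text(json.dumps(timing_doc, indent=2))
    return study_dir
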