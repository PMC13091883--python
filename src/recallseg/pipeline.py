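"""End-to-end orchestration: consensus -> windows -> FC -> RPCA -> classify.

``run_pipeline`` consumes a study directory (see :class:`recallseg.io.
PipelineConfig`), derives consensus scenes per story, maps them to TR windows,
computes per-network feature tensors, decomposes each scene's subjects-by-edges
matrix, builds pooled scene-level recall labels, and evaluates every
(network, variant, classifier) combination with LOOCV (optionally with a
within-story shuffle null).  Every artifact gets a JSON provenance sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .classify import calibration_curve, run_loocv, shuffle_null
from .connectivity import assemble_feature_tensor, compute_scene_fc, FeatureTensor
from .io import (
    PipelineConfig,
    read_annotator_segmentation,
    read_recall_csv,
    read_roi_manifest,
    read_roi_timeseries,
    write_consensus_scenes,
    write_decomposition,
    write_feature_tensor,
)
from .labels import binarize_labels, score_all_scenes
from .rpca import decompose_all_scenes
from .segmentation import consensus_scenes
from .timing import scenes_to_tr_windows

log = logging.getLogger("recallseg")

VARIANTS = ("fc", "lowrank", "sparse")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "study_dir": str(cfg.study_dir),
            "stories": cfg.stories,
            "min_support": cfg.min_support,
            "networks": list(cfg.networks),
            "bounds": asdict(cfg.bounds),
            "solver": asdict(cfg.solver),
            "classifiers": [asdict(c) for c in cfg.classifiers],
            "label_rule": cfg.label_rule,
            "label_quantile": cfg.label_quantile,
            "label_threshold": cfg.label_threshold,
            "cv_unit": cfg.cv_unit,
            "n_shuffles": cfg.n_shuffles,
            "seed": cfg.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(cfg: PipelineConfig) -> dict:
    return {"config_hash": _config_hash(cfg), "seed": cfg.seed, "version": __version__}


def _sidecar(path: Path, cfg: PipelineConfig, **extra) -> None:
    doc = {**_provenance(cfg), **extra}
    path.with_suffix(path.suffix + ".prov.json").write_text(json.dumps(doc, indent=2))


def assemble_study_matrix(
    study, network: str = "DMN", use_consensus: bool = True
) -> dict:
    """In-memory feature build for a (synthetic) study: scenes -> windows ->
    FC -> pooled (n, r) matrix with aligned scores and index maps.

    Scenes come from the annotator-consensus pipeline (``use_consensus=True``)
    or from the generator's ground truth.  Returns a dict with ``x`` (n, r),
    ``scores`` (mean scene recall per sample), ``story_ids``, ``groups``
    (study-unique subject index per sample) and the per-story tensors.
    """
    from .labels import score_all_scenes

    cfg = study.config
    x_parts, score_parts, story_parts, group_parts = [], [], [], []
    tensors = {}
    for s_i, story in enumerate(cfg.stories):
        if use_consensus:
            scenes = consensus_scenes(
                study.annotations[story.name], validate=False
            )
        else:
            scenes = study.truth.scenes[story.name]
        windows = scenes_to_tr_windows(scenes, cfg.timing_for(story))
        subjects = study.subjects_for(story.name)
        fcs = []
        for ts in study.timeseries[story.name]:
            sel = ts.select_network(network)
            for scene, win in zip(scenes, windows):
                fcs.append(compute_scene_fc(sel, win, scene.index_t))
        tensor = assemble_feature_tensor(fcs, subjects)
        tensors[story.name] = tensor
        x_parts.append(tensor.data.reshape(-1, tensor.data.shape[2]))
        scores = score_all_scenes(study.records, scenes, subjects)
        score_parts.append(scores.ravel())
        w, m = scores.shape
        story_parts.append(np.full(w * m, s_i))
        group_parts.append(np.tile(np.arange(m), w) + 1000 * s_i)
    return {
        "x": np.vstack(x_parts),
        "scores": np.concatenate(score_parts),
        "story_ids": np.concatenate(story_parts),
        "groups": np.concatenate(group_parts),
        "tensors": tensors,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict and writes all artifacts.

    Any stage error aborts with the stage name; partial outputs written so far
    are moved under ``<out_dir>/failed``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    try:
        summary = _run_stages(cfg, out, timings)
    except Exception as exc:
        failed = out.parent / (out.name + "-failed")
        if out.exists() and not failed.exists():
            out.rename(failed)
        raise RuntimeError(
            f"pipeline failed after stage(s) {sorted(timings) or ['setup']}: {exc}"
        ) from exc
    timings["total"] = time.time() - t0
    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    return summary


def _run_stages(cfg: PipelineConfig, out: Path, timings: dict) -> dict:
    manifest = read_roi_manifest(cfg.study_dir / "manifest.csv")
    records = read_recall_csv(cfg.study_dir / "recall.csv")

    # stage 1: consensus scenes per story
    t = time.time()
    scenes_by_story = {}
    for story in cfg.stories:
        ann_dir = cfg.study_dir / story / "annotations"
        segs = [read_annotator_segmentation(p) for p in sorted(ann_dir.glob("*.json"))]
        scenes = consensus_scenes(
            segs, cfg.bounds, min_support=cfg.min_support, validate=False
        )
        scenes_by_story[story] = scenes
        write_consensus_scenes(scenes, out / f"scenes_{story}.json")
        _sidecar(out / f"scenes_{story}.json", cfg, story=story)
        log.info("story %s: %d consensus scenes", story, len(scenes))
    timings["consensus"] = time.time() - t

    # stage 2+3: TR windows and per-network FC tensors
    t = time.time()
    tensors: dict[tuple[str, str], FeatureTensor] = {}
    subjects_by_story: dict[str, list[str]] = {}
    for story in cfg.stories:
        windows = scenes_to_tr_windows(scenes_by_story[story], cfg.timings[story])
        ts_dir = cfg.study_dir / story / "timeseries"
        paths = sorted(ts_dir.glob("*.tsv"))
        if not paths:
            raise FileNotFoundError(f"no time-series files under {ts_dir}")
        subjects_by_story[story] = [p.stem for p in paths]
        all_ts = [read_roi_timeseries(p, p.stem, manifest) for p in paths]
        for network in cfg.networks:
            fcs = []
            for ts in all_ts:
                sel = ts.select_network(network)
                for scene, win in zip(scenes_by_story[story], windows):
                    fcs.append(compute_scene_fc(sel, win, scene.index_t))
            tensor = assemble_feature_tensor(fcs, subjects_by_story[story])
            tensors[(story, network)] = tensor
            write_feature_tensor(tensor, out / f"tensor_{story}_{network}")
            _sidecar(out / f"tensor_{story}_{network}.json", cfg, story=story, network=network)
    timings["connectivity"] = time.time() - t

    # stage 4: per-scene low-rank + sparse decomposition
    t = time.time()
    decomps = {}
    for (story, network), tensor in tensors.items():
        results = decompose_all_scenes(tensor, cfg.solver)
        decomps[(story, network)] = results
        ddir = out / "decomp" / f"{story}_{network}"
        ddir.mkdir(parents=True, exist_ok=True)
        for res in results:
            write_decomposition(res, ddir / f"scene{res.scene_index:03d}")
    timings["decompose"] = time.time() - t

    # stage 5: pooled scene-level labels
    t = time.time()
    score_rows, story_ids, subject_ids = [], [], []
    for s_i, story in enumerate(cfg.stories):
        scores = score_all_scenes(
            records, scenes_by_story[story], subjects_by_story[story]
        )  # (W, M)
        score_rows.append(scores.ravel())
        w, m = scores.shape
        story_ids.append(np.full(w * m, s_i))
        subject_ids.append(
            np.tile(np.arange(m), w) + 1000 * s_i  # subjects unique across stories
        )
    mean_scores = np.concatenate(score_rows)
    story_ids = np.concatenate(story_ids)
    subject_ids = np.concatenate(subject_ids)
    labels = binarize_labels(
        mean_scores, cfg.label_rule, cfg.label_threshold, cfg.label_quantile
    )
    np.savetxt(
        out / "labels.csv",
        np.column_stack([story_ids, subject_ids, mean_scores, labels]),
        delimiter=",",
        header="story,subject,mean_score,label",
        comments="",
        fmt=["%d", "%d", "%.6f", "%d"],
    )
    _sidecar(out / "labels.csv", cfg)
    timings["labels"] = time.time() - t

    # stage 6: classification for every network x variant x classifier
    t = time.time()
    reports = {}
    combined_rows = []
    for network in cfg.networks:
        feats = {v: [] for v in VARIANTS}
        for story in cfg.stories:
            tensor = tensors[(story, network)]
            results = decomps[(story, network)]
            feats["fc"].append(tensor.data.reshape(-1, tensor.data.shape[2]))
            feats["lowrank"].append(np.vstack([r.low_rank for r in results]))
            feats["sparse"].append(np.vstack([r.sparse for r in results]))
        for variant in VARIANTS:
            x = np.vstack(feats[variant])
            null = None
            if cfg.n_shuffles > 0:
                null = shuffle_null(
                    x,
                    labels,
                    cfg.classifiers[0],
                    n_shuffles=cfg.n_shuffles,
                    seed=cfg.seed,
                    story_ids=story_ids,
                    unit=cfg.cv_unit,
                    groups=subject_ids,
                )
            for spec in cfg.classifiers:
                report = run_loocv(
                    x,
                    labels,
                    spec,
                    unit=cfg.cv_unit,
                    groups=subject_ids,
                    seed=cfg.seed,
                    variant=variant,
                )
                y_true, _, proba = report.pooled()
                report.calibration = calibration_curve(proba, y_true, n_bins=10)
                if null is not None:
                    report.shuffle_accuracy = null["null_mean"]
                key = (network, variant, spec.family)
                reports[key] = report
                doc = {
                    "network": network,
                    "variant": variant,
                    "classifier": spec.family,
                    "accuracy": report.accuracy,
                    "balanced_accuracy": report.balanced_accuracy,
                    "auc": report.auc,
                    "ci95": list(report.ci95),
                    "shuffle_null": None
                    if null is None
                    else {
                        "mean": null["null_mean"],
                        "sd": null["null_sd"],
                        "observed_percentile": null.get("observed_percentile"),
                        "majority_baseline": null["majority_baseline"],
                    },
                    "calibration": report.calibration,
                }
                rp = out / f"report_{network}_{variant}_{spec.family}.json"
                rp.write_text(json.dumps(doc, indent=2))
                _sidecar(rp, cfg)
                combined_rows.append(
                    [
                        network,
                        variant,
                        spec.family,
                        f"{report.accuracy:.4f}",
                        f"{report.balanced_accuracy:.4f}",
                        f"{report.auc:.4f}",
                        f"{report.ci95[0]:.4f}",
                        f"{report.ci95[1]:.4f}",
                    ]
                )
    timings["classify"] = time.time() - t
    with open(out / "reports.csv", "w") as fh:
        fh.write("network,variant,classifier,accuracy,balanced_accuracy,auc,ci_lo,ci_hi\n")
        for row in combined_rows:
            fh.write(",".join(row) + "\n")
    _sidecar(out / "reports.csv", cfg)

    return {
        "scenes": {s: len(v) for s, v in scenes_by_story.items()},
        "n_samples": int(mean_scores.size),
        "low_fraction": float(1 - labels.mean()),
        "reports": {
            "_".join(k): {"accuracy": r.accuracy, "auc": r.auc} for k, r in reports.items()
        },
        "out_dir": str(out),
    }
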