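"""End-to-end orchestration: quality → features → clustering → selection → quant → eval.

Two entry paths share the same internals:

* :func:`run_synthetic_experiment` runs the whole pipeline in memory on a
  seeded synthetic cohort (used by the test-suite and the acceptance
  script), returning selections, planted-pattern recovery, quantitative
  metrics of the selected images and ROC summaries.
* :func:`run_pipeline` runs on on-disk cohorts in the ``video_io`` layout
  and writes selections, quant CSV and evaluation CSVs (used by the CLI).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from elastoselect import features as feat
from elastoselect import quant as quant_mod
from elastoselect import selector as sel
from elastoselect import synthetic as synth
from elastoselect.evaluation import roc
from elastoselect.quality import QualityConfig, evaluate_quality
from elastoselect.quant import HueClassConfig
from elastoselect.video_io import (
    ROIMask,
    VideoSequence,
    pool_videos,
    read_mask,
    read_video,
    write_selection,
)

log = logging.getLogger("elastoselect")

QUANT_METRICS = ("sar", "b_g", "b_r", "g_r", "mean_hue", "mean_gray")


@dataclass
class LesionFeatures:
    """Per-lesion featurization output."""

    lesion_id: str
    label: str
    split: str
    kept_indices: list[int]
    histograms: np.ndarray  # n_kept × 512
    frame_truth: list[str] | None = None  # planted pattern labels of kept frames
    score: int | None = None


def featurize_video(video: VideoSequence, qcfg: QualityConfig) -> tuple[np.ndarray, list[int]]:
    """Quality-gate and thin a pooled video, then histogram the kept frames."""
    report = evaluate_quality(video, qcfg)
    kept = report.kept_indices
    if not kept:
        raise ValueError(f"no qualified frames for lesion {video.lesion_id}")
    kept_set = set(kept)
    X = np.stack(
        [feat.color_histogram(f).values for f in video.frames if f.index in kept_set]
    )
    return X, kept


def _reduced_table(model: feat.PCAModel, lesions: list[LesionFeatures]) -> pd.DataFrame:
    rows = []
    for lf in lesions:
        Z = feat.transform_matrix(model, lf.histograms)
        for idx, z in zip(lf.kept_indices, Z):
            rows.append({"lesion_id": lf.lesion_id, "frame_index": idx, "values": z})
    return pd.DataFrame(rows)


@dataclass
class ExperimentResult:
    """Outputs of an in-memory cohort run."""

    selections: dict
    lesions: list[LesionFeatures]
    recovery: dict  # lesion_id -> all selected frames carry the planted dominant label
    quant_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    roc_results: dict = field(default_factory=dict)
    pca_dim: int = 0

    @property
    def n_recovered(self) -> int:
        return sum(self.recovery.values())

    def selections_json(self) -> str:
        """Canonical JSON of all selections (used for determinism checks)."""
        payload = {
            lid: {
                "pattern": int(s.representative_pattern),
                "frames": [int(i) for i in s.frame_indices],
                "distances": [float(d) for d in s.distances],
                "short": bool(s.short),
            }
            for lid, s in sorted(self.selections.items())
        }
        return json.dumps(payload, sort_keys=True)


def run_synthetic_experiment(
    config: synth.SynthConfig,
    selector_config: sel.SelectorConfig = sel.SelectorConfig(),
    quality_config: QualityConfig = QualityConfig(),
    hue_config: HueClassConfig = HueClassConfig(),
    variance_target: float = 0.99,
    shifted_test: bool = False,
    with_quant: bool = True,
    split_ratio: tuple[int, ...] = (3, 1),
) -> ExperimentResult:
    """Full pipeline on a synthetic cohort, in memory.

    The cohort is split train/test (stratified by label at ``split_ratio``);
    PCA and k-means are fitted on the training split only.  When
    ``selector_config.run_twice`` is set, the update-and-predict strategy
    refreshes the centers on the pooled train+test features before the
    final assignment.  ``shifted_test`` generates the test split with the
    configured composition shift (train lesions are never shifted).
    """
    splits = synth.default_splits(config, split_ratio, ("train", "test"))
    lesions: list[LesionFeatures] = []
    shifted_splits = ("test",) if shifted_test else ()
    for i, split, videos, mask, truth in synth.iter_lesions(config, splits, shifted_splits):
        pooled = pool_videos(truth.lesion_id, videos, fps=config.fps)
        X, kept = featurize_video(pooled, quality_config)
        lesions.append(
            LesionFeatures(
                lesion_id=truth.lesion_id,
                label=truth.label,
                split=split,
                kept_indices=kept,
                histograms=X,
                frame_truth=[truth.frame_labels[k] for k in kept],
                score=truth.score,
            )
        )
        log.info("featurize lesion=%s split=%s frames_in=%d kept=%d", truth.lesion_id, split, len(pooled), len(kept))

    train = [lf for lf in lesions if lf.split == "train"]
    test = [lf for lf in lesions if lf.split == "test"]
    pca = feat.fit_pca(np.vstack([lf.histograms for lf in train]), variance_target)
    train_table = _reduced_table(pca, train)
    test_table = _reduced_table(pca, test)
    model = sel.train_kmeans(
        train_table, k=selector_config.k, seed=selector_config.seed, n_init=selector_config.n_init
    )
    if selector_config.run_twice and len(test_table):
        model, _ = sel.update_and_predict(
            model, train_table, test_table, pool_training=selector_config.pool_training
        )
    all_table = pd.concat([train_table, test_table], ignore_index=True) if len(test_table) else train_table
    assignment = sel.assign(model, all_table)

    selections, recovery = {}, {}
    truth_by_lesion = {
        lf.lesion_id: dict(zip(lf.kept_indices, lf.frame_truth or [])) for lf in lesions
    }
    for lesion_id, grp in assignment.groupby("lesion_id"):
        s = sel.select_representatives(grp, selector_config.n_representatives)
        selections[lesion_id] = s
        truth_map = truth_by_lesion[lesion_id]
        recovery[lesion_id] = all(truth_map[i] == "dominant" for i in s.frame_indices)

    result = ExperimentResult(
        selections=selections, lesions=lesions, recovery=recovery, pca_dim=pca.d
    )
    if with_quant:
        result.quant_table = _quantify_selected(config, splits, selections, shifted_splits, hue_config)
        result.roc_results = _roc_from_quant(result.quant_table)
    return result


def _quantify_selected(
    config: synth.SynthConfig,
    splits: list[str],
    selections: dict,
    shifted_splits: tuple[str, ...],
    hue_config: HueClassConfig,
) -> pd.DataFrame:
    """Regenerate each lesion (seeded, so identical) and quantify its selected frames."""
    rows = []
    for i, split, videos, mask, truth in synth.iter_lesions(config, splits, shifted_splits):
        if truth.lesion_id not in selections:
            continue
        pooled = pool_videos(truth.lesion_id, videos, fps=config.fps)
        s = selections[truth.lesion_id]
        for image_no, idx in enumerate(s.frame_indices, 1):
            q = quant_mod.quantify(pooled.frames[idx].pixels, mask, hue_config)
            row = {"lesion_id": truth.lesion_id, "label": truth.label, "group": split, "image_no": image_no}
            row.update({m: q.as_dict()[m] for m in QUANT_METRICS})
            rows.append(row)
    return pd.DataFrame(rows)


def _roc_from_quant(quant_table: pd.DataFrame) -> dict:
    """Per-metric ROC on per-lesion means of the selected images."""
    out = {}
    if quant_table.empty:
        return out
    per_lesion = quant_table.groupby(["lesion_id", "label"], as_index=False)[list(QUANT_METRICS)].mean()
    labels = per_lesion["label"].to_numpy()
    if len(set(labels)) < 2:
        return out
    for metric in QUANT_METRICS:
        vals = per_lesion[metric].to_numpy(dtype=float)
        if np.isnan(vals).any():
            continue
        out[metric] = roc(vals, labels)
    return out


def _read_cohort_dir(cohort_dir: Path, fps: float) -> dict[str, VideoSequence]:
    videos = {}
    for lesion_dir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        sources = sorted(p for p in lesion_dir.iterdir() if p.is_dir()) or [lesion_dir]
        videos[lesion_dir.name] = read_video(sources, lesion_id=lesion_dir.name, fps=fps)
    if not videos:
        raise ValueError(f"no lesion directories under {cohort_dir}")
    return videos


def run_pipeline(
    train_dir: str | Path,
    test_dir: str | Path,
    out_dir: str | Path,
    quality_config: QualityConfig = QualityConfig(),
    selector_config: sel.SelectorConfig = sel.SelectorConfig(),
    hue_config: HueClassConfig = HueClassConfig(),
    variance_target: float = 0.99,
    masks_dir: str | Path | None = None,
    metadata: pd.DataFrame | None = None,
    fps: float = 10.0,
) -> dict:
    """Disk-based pipeline: train on one cohort directory, select on another.

    Writes per-lesion representative PNGs + JSON sidecars, a resolved-config
    manifest, and (when masks are provided) a quant CSV; returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_videos = _read_cohort_dir(Path(train_dir), fps)
    test_videos = _read_cohort_dir(Path(test_dir), fps)

    def _featurize(videos: dict[str, VideoSequence], split: str) -> list[LesionFeatures]:
        lfs = []
        for lid, video in videos.items():
            X, kept = featurize_video(video, quality_config)
            log.info("stage=quality lesion=%s frames_in=%d frames_out=%d", lid, len(video), len(kept))
            lfs.append(LesionFeatures(lesion_id=lid, label="", split=split, kept_indices=kept, histograms=X))
        return lfs

    train = _featurize(train_videos, "train")
    test = _featurize(test_videos, "test")
    pca = feat.fit_pca(np.vstack([lf.histograms for lf in train]), variance_target)
    train_table = _reduced_table(pca, train)
    test_table = _reduced_table(pca, test)
    model = sel.train_kmeans(
        train_table, k=selector_config.k, seed=selector_config.seed, n_init=selector_config.n_init
    )
    if selector_config.run_twice:
        model, assignment = sel.update_and_predict(
            model, train_table, test_table, pool_training=selector_config.pool_training
        )
    else:
        assignment = sel.assign(model, test_table)

    selections = {}
    for lesion_id, grp in assignment.groupby("lesion_id"):
        s = sel.select_representatives(grp, selector_config.n_representatives)
        selections[lesion_id] = s
        write_selection(s, test_videos[lesion_id], out / "selections")
        log.info("stage=select lesion=%s pattern=%d frames=%s", lesion_id, s.representative_pattern, s.frame_indices)

    manifest = {
        "quality": vars(quality_config).copy(),
        "selector": vars(selector_config).copy(),
        "hue": vars(hue_config).copy(),
        "variance_target": variance_target,
        "pca_dim": pca.d,
        "n_train_lesions": len(train),
        "n_test_lesions": len(test),
    }

    if masks_dir is not None:
        masks_dir = Path(masks_dir)
        missing = [lid for lid in selections if not (masks_dir / f"{lid}.png").exists()]
        if missing:
            raise FileNotFoundError(f"masks missing for lesions: {missing}")
        rows = []
        label_map = (
            dict(zip(metadata["lesion_id"], metadata["label"])) if metadata is not None else {}
        )
        for lid, s in sorted(selections.items()):
            mask = read_mask(masks_dir / f"{lid}.png", lesion_id=lid)
            for image_no, idx in enumerate(s.frame_indices, 1):
                q = quant_mod.quantify(test_videos[lid].frames[idx].pixels, mask, hue_config)
                row = {"lesion_id": lid, "label": label_map.get(lid, ""), "group": "test", "image_no": image_no}
                row.update({m: q.as_dict()[m] for m in QUANT_METRICS})
                rows.append(row)
        quant_table = pd.DataFrame(rows)
        quant_table.to_csv(out / "quant.csv", index=False)
        if label_map:
            roc_results = _roc_from_quant(quant_table)
            manifest["roc"] = {
                m: {"auc": r.auc, "cutoff": r.cutoff, "sens": r.sens_at_cutoff, "spec": r.spec_at_cutoff}
                for m, r in roc_results.items()
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
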