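"""High-level orchestration shared by the CLI, the tests and the
reproduction script: materialize records, build partition arrays, train,
evaluate, run the ablation grid and the Grad-CAM localization harness.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .augmentation import (AugmentPolicy, eval_transform, to_nchw,
                           train_transform)
from .explain import grad_cam, localization_score
from .labels import FaceRecord, read_manifest
from .metrics import EvalReport, evaluate
from .model import DualAttentionCNN, ModelConfig
from .partitioning import SplitAssignment, subject_split
from .synthetic import load_image, signal_mask
from .training import TrainConfig, fit

__all__ = [
    "materialize", "partition_arrays", "train_run", "ablation_grid",
    "localization_harness", "ABLATION_GRID",
]

# configuration grid: (name, spatial, channel, label smoothing); augmentation
# stays on throughout, mirroring the standard ablation layout
ABLATION_GRID = (
    ("baseline_cnn", False, False, False),
    ("spatial_attention", True, False, False),
    ("channel_attention", False, True, False),
    ("both_attention", True, True, False),
    ("full_dual_attention", True, True, True),
)


def materialize(records: list[FaceRecord], root: Path | None = None
                ) -> list[FaceRecord]:
    """Ensure every record's ``image_ref`` is an in-memory array."""
    out = []
    for r in records:
        ref = r.image_ref
        if isinstance(ref, (str, Path)):
            path = Path(ref)
            if root is not None and not path.is_absolute():
                path = root / path
            ref = load_image(path)
        out.append(FaceRecord(image_ref=np.asarray(ref), subject_id=r.subject_id,
                              pspi_score=r.pspi_score, augmented=r.augmented))
    return out


def load_dataset_dir(data_dir: str | Path) -> list[FaceRecord]:
    data_dir = Path(data_dir)
    return materialize(read_manifest(data_dir / "manifest.csv"), root=data_dir)


def partition_arrays(records: list[FaceRecord], split: SplitAssignment
                     ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Eval-transformed NCHW arrays and labels per partition."""
    out = {}
    for part in ("train", "val", "test"):
        idx = split.indices(records, part)
        if len(idx) == 0:
            out[part] = (np.zeros((0, 3, 64, 64), np.float32),
                         np.zeros(0, dtype=int))
            continue
        images = to_nchw([eval_transform(records[i].image_ref) for i in idx])
        labels = np.array([records[i].label for i in idx])
        out[part] = (images, labels)
    return out


def _augment_builder(records: list[FaceRecord], idx_map: np.ndarray,
                     policy: AugmentPolicy):
    raw = [np.asarray(records[i].image_ref) for i in idx_map]

    def builder(indices: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return to_nchw([train_transform(raw[i], policy, rng) for i in indices])

    return builder


def train_run(records: list[FaceRecord], split: SplitAssignment,
              model_config: ModelConfig, train_config: TrainConfig,
              policy: AugmentPolicy | None = None, verbose: bool = False
              ) -> tuple[DualAttentionCNN, list[dict], EvalReport]:
    """Train on the split's train/val partitions, evaluate on test."""
    arrays = partition_arrays(records, split)
    model = DualAttentionCNN(model_config,
                             rng=np.random.default_rng(train_config.seed))
    augment_fn = None
    if policy is not None:
        augment_fn = _augment_builder(records, split.indices(records, "train"),
                                      policy)
    history = fit(model, *arrays["train"], *arrays["val"], train_config,
                  verbose=verbose, augment_fn=augment_fn)
    test_images, test_labels = arrays["test"]
    report = evaluate(test_labels, model.predict_proba(test_images))
    return model, history, report


def ablation_grid(records: list[FaceRecord], split: SplitAssignment,
                  model_config: ModelConfig, train_config: TrainConfig,
                  policy: AugmentPolicy | None = None, verbose: bool = False
                  ) -> list[dict]:
    """Run the five-configuration attention/label-smoothing grid.

    All configurations share the same records, split and seed; only the
    attention switches and the smoothing coefficient vary.
    """
    from dataclasses import replace

    rows = []
    for name, spatial, channel, smooth in ABLATION_GRID:
        mc = replace(model_config, use_spatial_attention=spatial,
                     use_channel_attention=channel)
        tc = replace(train_config,
                     label_smoothing=train_config.label_smoothing if smooth
                     else 0.0)
        _, _, report = train_run(records, split, mc, tc, policy=policy,
                                 verbose=verbose)
        rows.append({
            "configuration": name,
            "spatial_attention": spatial,
            "channel_attention": channel,
            "label_smoothing": smooth,
            "accuracy": report.accuracy,
            "macro_f1": report.macro_f1,
            "ece": report.ece,
        })
    return rows


def localization_harness(model: DualAttentionCNN, records: list[FaceRecord],
                         profiles, split: SplitAssignment,
                         min_pspi: int = 7, method: str = "elementwise") -> dict:
    """Grad-CAM localization on correctly classified high-pain test images.

    Returns the fraction of such images whose CAM mean inside the signal
    mask exceeds the mean outside, plus aggregate mass statistics.
    ``method`` is forwarded to :func:`painattn.explain.grad_cam`; the
    default is the element-wise weighting, which stays faithful under
    the flatten classifier head (the classic spatial-mean weighting can
    cancel opposing gradient signs there and is seed-fragile as a
    localization instrument).
    """
    profile_by_id = {p.subject_id: p for p in profiles}
    idx = split.indices(records, "test")
    rows = []
    hits = 0
    total = 0
    for i in idx:
        rec = records[i]
        if rec.pspi_score < min_pspi:
            continue
        image = eval_transform(rec.image_ref)
        proba = model.predict_proba(to_nchw([image]))
        pred = int(proba.argmax())
        if pred != rec.label:
            continue
        cam = grad_cam(model, image.transpose(2, 0, 1), pred, method=method)
        score = localization_score(cam.heatmap,
                                   signal_mask(profile_by_id[rec.subject_id]))
        rows.append({"subject_id": rec.subject_id, "pspi": rec.pspi_score,
                     **score})
        total += 1
        hits += score["inside_mean"] > score["outside_mean"]
    return {
        "n_images": total,
        "fraction_inside_greater": hits / total if total else float("nan"),
        "mean_mass_inside": (float(np.mean([r["mass_inside_fraction"] for r in rows]))
                             if rows else float("nan")),
        "mean_mask_area": (float(np.mean([r["mask_area_fraction"] for r in rows]))
                           if rows else float("nan")),
        "rows": rows,
    }


def content_hash(path: str | Path) -> str:
    """SHA-256 of a file, for run provenance logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(out_dir: str | Path, config: dict, inputs: dict[str, str],
                  seed: int) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run.json").write_text(json.dumps({
        "config": config,
        "input_hashes": inputs,
        "seed": seed,
    }, indent=2, sort_keys=True, default=str))
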