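"""Training losses and spacing-aware evaluation metrics.

Losses operate on soft predictions in [0, 1] against one-hot targets:
the compound training objective is the unweighted sum
L = L_dice + L_bce + L_mse, and an asymmetric Tversky alternative
(alpha = 0.7, beta = 0.3 by default, penalizing false negatives less than
Dice would weigh precision) is available for the class-imbalanced setting.

Evaluation metrics follow the standard definitions: DSC = 2|P&G|/(|P|+|G|),
RECALL = TP/(TP+FN), and HD95 = the 95th percentile of the pooled symmetric
surface-to-surface distance multiset in mm (surface voxel = mask voxel with
at least one background face-neighbour; linear-interpolation percentile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import REGION_TABLE_LABELS, REGIONS

__all__ = [
    "dice_loss",
    "bce_loss",
    "mse_loss",
    "compound_loss",
    "tversky_loss",
    "dsc",
    "recall",
    "hd95",
    "surface_voxels",
    "MetricsReport",
    "evaluate_dataset",
]

_EPS = 1e-6


def _check_pair(pred, target):
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.size == 0 or target.size == 0:
        raise ValueError("empty tensors")
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return pred, target


def _soft_axes(pred: np.ndarray):
    """Reduction axes for soft overlap losses.

    5-D tensors (batch, channel, D, W, H) are reduced per (sample, channel)
    and averaged — small foreground channels keep full weight; anything else
    is reduced globally.
    """
    return tuple(range(2, pred.ndim)) if pred.ndim == 5 else None


def dice_loss(pred, target, eps: float = _EPS) -> float:
    """1 - soft Dice with smoothing eps in numerator and denominator.

    For (B, C, D, W, H) inputs the Dice is computed per sample and channel
    and averaged.
    """
    pred, target = _check_pair(pred, target)
    ax = _soft_axes(pred)
    inter = (pred * target).sum(axis=ax)
    dice = (2.0 * inter + eps) / (pred.sum(axis=ax) + target.sum(axis=ax) + eps)
    return float(1.0 - np.mean(dice))


def bce_loss(pred, target, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy; predictions clipped away from {0, 1}."""
    pred, target = _check_pair(pred, target)
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean())


def mse_loss(pred, target) -> float:
    pred, target = _check_pair(pred, target)
    return float(((pred - target) ** 2).mean())


def compound_loss(pred, target) -> float:
    """Unweighted sum of Dice, BCE and MSE losses (the training objective)."""
    return dice_loss(pred, target) + bce_loss(pred, target) + mse_loss(pred, target)


def tversky_loss(pred, target, alpha: float = 0.7, beta: float = 0.3, eps: float = _EPS) -> float:
    """1 - TP/(TP + alpha*FP + beta*FN) on soft counts; (0.5, 0.5) = Dice.

    Reduction convention matches :func:`dice_loss` so the (0.5, 0.5)
    identity holds for every input rank.
    """
    if alpha < 0 or beta < 0 or alpha + beta == 0:
        raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")
    pred, target = _check_pair(pred, target)
    ax = _soft_axes(pred)
    tp = (pred * target).sum(axis=ax)
    fp = (pred * (1.0 - target)).sum(axis=ax)
    fn = ((1.0 - pred) * target).sum(axis=ax)
    tv = (tp + eps) / (tp + alpha * fp + beta * fn + eps)
    return float(1.0 - np.mean(tv))


def _check_masks(P, G):
    P = np.asarray(P).astype(bool)
    G = np.asarray(G).astype(bool)
    if P.shape != G.shape:
        raise ValueError(f"mask shape mismatch: {P.shape} vs {G.shape}")
    return P, G


def dsc(P, G) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    P, G = _check_masks(P, G)
    denom = P.sum() + G.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(P, G).sum() / denom)


def recall(P, G) -> float:
    """TP/(TP+FN).  Undefined (nan) when G is empty: excluded from aggregates."""
    P, G = _check_masks(P, G)
    npos = G.sum()
    if npos == 0:
        return float("nan")
    return float(np.logical_and(P, G).sum() / npos)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity cross


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 background face-neighbour (border_value=0)."""
    mask = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~eroded


def _directed_surface_distances(src_surf, dst_surf, spacing):
    """Distances (mm) from each src surface voxel to the nearest dst surface voxel."""
    dt = ndimage.distance_transform_edt(~dst_surf, sampling=spacing)
    return dt[src_surf]


def hd95(P, G, spacing_mm=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled symmetric surface distances in mm.

    Returns 0.0 when both masks are empty; nan (undefined) when exactly one
    is empty.
    """
    P, G = _check_masks(P, G)
    if not P.any() and not G.any():
        return 0.0
    if not P.any() or not G.any():
        return float("nan")
    spacing = tuple(float(s) for s in spacing_mm)
    sp = surface_voxels(P)
    sg = surface_voxels(G)
    d_pg = _directed_surface_distances(sp, sg, spacing)
    d_gp = _directed_surface_distances(sg, sp, spacing)
    pooled = np.concatenate([d_pg, d_gp])
    return float(np.percentile(pooled, 95, method="linear"))


@dataclass
class MetricsReport:
    """Per-record metrics plus per-region and overall aggregates."""

    per_record: pd.DataFrame
    per_region: pd.DataFrame
    overall: dict = field(default_factory=dict)

    def to_table(self) -> str:
        """Region-by-region delimited table (report layout)."""
        rows = self.per_region.copy()
        overall = pd.DataFrame(
            [{"region_label": "Mean", **{k: self.overall[k] for k in ("DSC", "RECALL", "HD95")}}]
        )
        out = pd.concat([rows, overall], ignore_index=True)
        return out.to_csv(sep="\t", index=False, float_format="%.4f")

    def save(self, tsv_path, json_path=None) -> None:
        from pathlib import Path
        import json

        Path(tsv_path).parent.mkdir(parents=True, exist_ok=True)
        Path(tsv_path).write_text(self.to_table())
        if json_path is not None:
            payload = {
                "per_region": self.per_region.to_dict("records"),
                "overall": self.overall,
            }
            Path(json_path).write_text(json.dumps(payload, indent=2))


def evaluate_dataset(
    predictions: dict[str, np.ndarray],
    manifest,
    masks: dict[str, np.ndarray] | None = None,
    split: str = "test",
    allow_missing: bool = False,
) -> MetricsReport:
    """Score binary predictions against ground-truth defect masks.

    Parameters
    ----------
    predictions
        Map defect_id -> binary prediction mask.
    manifest
        A :class:`~sufseg.dataset.DatasetManifest`.
    masks
        Optional defect_id -> ground-truth mask override (otherwise masks are
        read from the manifest's NIfTI paths or in-memory volume store).
    """
    from .volume import load_nifti

    records = manifest.subset(split) if split else list(manifest.records)
    missing = [r.defect_id for r in records if r.defect_id not in predictions]
    if missing and not allow_missing:
        raise ValueError(f"missing predictions for records: {missing[:5]}{'...' if len(missing) > 5 else ''}")

    mem = manifest.meta.get("volumes", {}) if hasattr(manifest, "meta") else {}
    rows = []
    spacing = (manifest.spacing_mm,) * 3
    for rec in records:
        if rec.defect_id not in predictions:
            continue
        if masks is not None and rec.defect_id in masks:
            gt = np.asarray(masks[rec.defect_id]).astype(bool)
        elif rec.defect_id in mem:
            gt = mem[rec.defect_id][1].data.astype(bool)
        else:
            gt = load_nifti(rec.mask_path).data.astype(bool)
        pred = np.asarray(predictions[rec.defect_id]).astype(bool)
        rows.append(
            {
                "defect_id": rec.defect_id,
                "skull_id": rec.skull_id,
                "region": rec.region,
                "complexity": rec.complexity,
                "DSC": dsc(pred, gt),
                "RECALL": recall(pred, gt),
                "HD95": hd95(pred, gt, spacing),
            }
        )
    per_record = pd.DataFrame(rows)
    if per_record.empty:
        raise ValueError("no records were evaluated")

    agg = (
        per_record.groupby("region")[["DSC", "RECALL", "HD95"]]
        .mean()  # nan (undefined) metrics are excluded from aggregates
        .reindex([r for r in REGIONS if r in set(per_record["region"])])
        .reset_index()
    )
    agg.insert(1, "region_label", agg["region"].map(REGION_TABLE_LABELS))
    overall = {
        "DSC": float(per_record["DSC"].mean()),
        "RECALL": float(per_record["RECALL"].mean(skipna=True)),
        "HD95": float(per_record["HD95"].mean(skipna=True)),
        "n": int(len(per_record)),
    }
    return MetricsReport(
        per_record=per_record,
        per_region=agg[["region_label", "DSC", "RECALL", "HD95"]],
        overall=overall,
    )
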