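"""Segmentation validation metrics: pixel confusion counts, rate/predictive
-value/Dice report, per-slide and cohort aggregation, and the four-colour
TP/FN/FP/TN overlay.

Positive means tumour throughout. Metrics with a zero denominator are
reported as missing (NaN), never as 0, and are excluded from cohort means
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metric_report",
    "cohort_report",
    "render_confusion_overlay",
    "OVERLAY_COLOURS",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    evaluate_mask: np.ndarray | None = None,
) -> ConfusionCounts:
    """Per-pixel confusion counts between boolean tumour masks.

    ``evaluate_mask`` restricts the evaluated pixel universe (e.g. tissue
    pixels only, so glass does not inflate the true-negative count).
    """
    pred = np.asarray(pred_mask, bool)
    truth = np.asarray(truth_mask, bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {truth.shape}")
    if evaluate_mask is not None:
        ev = np.asarray(evaluate_mask, bool)
        if ev.shape != pred.shape:
            raise ValueError("evaluate_mask shape mismatch")
        pred, truth = pred[ev], truth[ev]
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def _ratio(num, den) -> float:
    return num / den if den > 0 else float("nan")


def metric_report(counts: ConfusionCounts) -> dict:
    """TPR, TNR, FPR, FNR, PPV, NPV and Dice for one slide.

    TPR=TP/(TP+FN), TNR=TN/(TN+FP), FPR=FP/(FP+TN), FNR=FN/(FN+TP),
    PPV=TP/(TP+FP), NPV=TN/(TN+FN), Dice=2TP/(2TP+FP+FN). Undefined
    ratios (zero denominator) are NaN.
    """
    c = counts
    return {
        "tpr": _ratio(c.tp, c.tp + c.fn),
        "tnr": _ratio(c.tn, c.tn + c.fp),
        "fpr": _ratio(c.fp, c.fp + c.tn),
        "fnr": _ratio(c.fn, c.fn + c.tp),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def cohort_report(per_slide: list[ConfusionCounts] | list[dict]) -> pd.DataFrame:
    """Per-slide metric table plus unweighted cohort mean and sd rows.

    Slides where a metric is undefined are excluded from that metric's
    mean/sd with a warning.
    """
    rows = [
        metric_report(c) if isinstance(c, ConfusionCounts) else dict(c)
        for c in per_slide
    ]
    df = pd.DataFrame(rows)
    df.index = [f"slide_{i}" for i in range(len(df))]
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        warnings.warn(
            f"metrics {bad} undefined on some slides; excluded from cohort mean"
        )
    summary = pd.DataFrame(
        {"mean": df.mean(skipna=True), "sd": df.std(ddof=1, skipna=True)}
    ).T
    return pd.concat([df, summary])


OVERLAY_COLOURS = {
    "tp": (0, 170, 0),  # green
    "fn": (255, 105, 180),  # pink
    "fp": (255, 230, 0),  # yellow
    "tn": (70, 90, 220),  # blue
}


def render_confusion_overlay(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    slide_thumb: np.ndarray | None = None,
    opacity: float = 1.0,
    evaluate_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Four-colour TP (green) / FN (pink) / FP (yellow) / TN (blue)
    overlay at mask resolution; pixels outside ``evaluate_mask`` keep the
    thumbnail (or white)."""
    pred = np.asarray(pred_mask, bool)
    truth = np.asarray(truth_mask, bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shape mismatch")
    h, w = pred.shape
    if slide_thumb is not None:
        canvas = np.asarray(slide_thumb)[:h, :w].astype(np.float64).copy()
    else:
        canvas = np.full((h, w, 3), 255.0)
    layers = {
        "tp": pred & truth,
        "fn": ~pred & truth,
        "fp": pred & ~truth,
        "tn": ~pred & ~truth,
    }
    ev = (
        np.ones_like(pred)
        if evaluate_mask is None
        else np.asarray(evaluate_mask, bool)
    )
    for key, sel in layers.items():
        sel = sel & ev
        colour = np.asarray(OVERLAY_COLOURS[key], np.float64)
        canvas[sel] = (1 - opacity) * canvas[sel] + opacity * colour
    return np.clip(canvas, 0, 255).astype(np.uint8)
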