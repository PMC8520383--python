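"""Segmentation scoring against a ground-truth vessel mask, within the FOV.

Pixels inside the field of view are classified as true/false positives and
negatives; from the counts come the standard vessel-segmentation metrics:

    ACC = (TP + TN) / (TP + TN + FP + FN)        pixel accuracy
    TPR = TP / (TP + FN)                         sensitivity / recall
    FPR = FP / (FP + TN)                         fall-out on background
    precision = TP / (TP + FP)
    F = 2 * precision * TPR / (precision + TPR)  F-measure

A ratio with a zero denominator is reported as missing (None), never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .io_preprocess import FovMask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_positive(self) -> int:
        """Ground-truth vessel pixels in the FOV."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Ground-truth background pixels in the FOV."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    acc: float
    tpr: float | None
    fpr: float | None
    precision: float | None
    f_measure: float | None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def report(self) -> str:
        """Flat key-value text report."""
        lines = []
        for key, val in self.to_dict().items():
            lines.append(f"{key}\t{'NA' if val is None else f'{val:.6f}'}")
        return "\n".join(lines)


def confusion(
    pred: np.ndarray,
    truth: np.ndarray,
    fov: FovMask | None = None,
) -> ConfusionCounts:
    """Confusion counts over in-FOV pixels only."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth masks differ in shape")
    if fov is None:
        fov = FovMask.full(pred.shape)
    if fov.shape != pred.shape:
        raise ValueError("FOV mask shape does not match the masks")
    p = pred[fov.inside]
    t = truth[fov.inside]
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Compute ACC/TPR/FPR/precision/F from confusion counts."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    acc = (c.tp + c.tn) / c.total
    tpr = c.tp / c.n_positive if c.n_positive > 0 else None
    fpr = c.fp / c.n_negative if c.n_negative > 0 else None
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    if precision is not None and tpr is not None and (precision + tpr) > 0:
        f_measure = 2.0 * precision * tpr / (precision + tpr)
    else:
        f_measure = None
    return Metrics(acc=acc, tpr=tpr, fpr=fpr, precision=precision, f_measure=f_measure)
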