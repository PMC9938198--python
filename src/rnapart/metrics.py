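"""Base-, segment-, and pair-level confusion counts and derived metrics.

Three evaluation granularities share one confusion/metric vocabulary:

* **base** — per-nucleotide exterior-loop labels over unmasked
  positions, positive class = exterior.
* **segment** — confusion over maximal runs of constant truth label.
  A truth-exterior segment is a TP when at least one base inside it is
  predicted positive, else an FN; a truth-non-exterior segment is an FP
  when at least one base inside it is predicted positive, else a TN.
  This scores whether the partition boundaries are found at all, not
  how many bases agree.
* **pair** — set algebra on base pairs of predicted vs reference
  structures; TN counts all unordered position pairs not in either set.

Derived metrics: SEN = TP/(TP+FN), PRE = TP/(TP+FP),
ACC = (TP+TN)/(TP+FP+TN+FN),
MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
F1 = 2*PRE*SEN/(PRE+SEN).  A zero denominator makes the metric
``None`` ("undefined"), reported distinctly from 0 and excluded from
averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .struct_io import SecondaryStructure

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "base_confusion",
    "segment_confusion",
    "pair_confusion",
    "compute_metrics",
    "bootstrap_se",
    "pool_counts",
    "macro_average",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    mode: str = "base"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.mode != other.mode:
            raise ValueError("cannot pool confusion counts of different modes")
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.mode,
        )


@dataclass
class MetricsReport:
    sen: Optional[float]
    pre: Optional[float]
    acc: Optional[float]
    mcc: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "SEN": self.sen,
            "PRE": self.pre,
            "ACC": self.acc,
            "MCC": self.mcc,
            "F1": self.f1,
        }


def _as_binary(v: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(v)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr.astype(np.int8)


def base_confusion(
    pred: Sequence[int], truth: Sequence[int], mask: Sequence[int] | None = None
) -> ConfusionCounts:
    """Per-base confusion over unmasked positions (positive = exterior)."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: pred {len(pred)} vs truth {len(truth)}")
    if mask is None:
        keep = np.ones(len(pred), dtype=bool)
    else:
        mask = np.asarray(mask)
        if len(mask) != len(pred):
            raise ValueError("mask length mismatch")
        keep = mask.astype(bool)
    p, t = pred[keep], truth[keep]
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    return ConfusionCounts(tp, fp, tn, fn, "base")


def _truth_segments(truth: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end, label) runs of constant truth label."""
    segs = []
    k = 0
    n = len(truth)
    while k < n:
        start = k
        lab = truth[k]
        while k < n and truth[k] == lab:
            k += 1
        segs.append((start, k, int(lab)))
    return segs


def segment_confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Segment-level confusion over maximal truth-label runs.

    Exterior truth segment: TP if any predicted 1 inside, else FN.
    Non-exterior truth segment: FP if any predicted 1 inside, else TN.
    """
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: pred {len(pred)} vs truth {len(truth)}")
    tp = fp = tn = fn = 0
    for start, end, lab in _truth_segments(truth):
        hit = bool(np.any(pred[start:end] == 1))
        if lab == 1:
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    return ConfusionCounts(tp, fp, tn, fn, "segment")


def pair_confusion(
    pred_structure: SecondaryStructure, ref_structure: SecondaryStructure
) -> ConfusionCounts:
    """Base-pair confusion between predicted and reference structures."""
    n = len(ref_structure.sequence)
    if len(pred_structure.sequence) != n:
        raise ValueError(
            f"length mismatch: predicted {len(pred_structure.sequence)} "
            f"vs reference {n}"
        )
    pred = pred_structure.pairs
    ref = ref_structure.pairs
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    tn = n * (n - 1) // 2 - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn, "pair")


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """SEN/PRE/ACC/MCC/F1 from confusion counts; zero denominators -> None."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn

    def ratio(num: float, den: float) -> Optional[float]:
        return num / den if den > 0 else None

    sen = ratio(tp, tp + fn)
    pre = ratio(tp, tp + fp)
    acc = ratio(tp + tn, tp + fp + tn + fn)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den > 0 else None
    if sen is None or pre is None or (pre + sen) == 0:
        f1 = None
    else:
        f1 = 2 * pre * sen / (pre + sen)
    return MetricsReport(sen, pre, acc, mcc, f1)


def pool_counts(all_counts: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Micro-average: sum confusion counts over sequences."""
    if not all_counts:
        raise ValueError("no counts to pool")
    pooled = all_counts[0]
    for c in all_counts[1:]:
        pooled = pooled + c
    return pooled


def macro_average(
    all_counts: Sequence[ConfusionCounts],
) -> tuple[dict[str, Optional[float]], dict[str, int]]:
    """Per-sequence metric means, excluding undefined values.

    Returns the mean of each metric over the sequences where it is
    defined, plus a count of sequences excluded per metric.
    """
    if not all_counts:
        raise ValueError("no counts to average")
    reports = [compute_metrics(c).as_dict() for c in all_counts]
    means: dict[str, Optional[float]] = {}
    undefined: dict[str, int] = {}
    for key in reports[0]:
        vals = [r[key] for r in reports if r[key] is not None]
        undefined[key] = len(reports) - len(vals)
        means[key] = float(np.mean(vals)) if vals else None
    return means, undefined


def bootstrap_se(
    per_item_values: Sequence[float], B: int = 100, seed: int | None = 0
) -> tuple[float, float]:
    """Bootstrap mean and standard error over per-item values.

    Items (typically per-sequence metrics) are resampled with
    replacement ``B`` times; the SE is the standard deviation of the
    resample means.
    """
    values = np.asarray(per_item_values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 items for a bootstrap SE")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(B, len(values)))
    means = values[idx].mean(axis=1)
    return float(values.mean()), float(means.std(ddof=1))
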