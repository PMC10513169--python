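"""Detection evaluation with a centre-of-mass criterion.

A detection is correct (TP) only when the prediction is a *single* region
whose centre of mass falls inside the ground-truth balloon region; absence on
both sides is a TN; a catheter that goes entirely undetected is an FN; every
other configuration (spurious region on a catheter-free frame, multiple
regions, a region in the wrong place) is an incorrect detection, FP by
default.  Accuracy, specificity and sensitivity are computed per patient and
then averaged (unweighted) across patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .tracking import Region, TipEstimate

__all__ = [
    "Metrics",
    "MetricsReport",
    "MultiSliceGT",
    "classify_detection",
    "classify_dynamic",
    "make_multislice_gt",
    "compute_metrics",
    "aggregate_patients",
    "operator_agreement",
    "build_report",
]

Outcome = Literal["TP", "FP", "TN", "FN"]


def _mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    coords = np.argwhere(np.asarray(mask) > 0)
    return tuple(coords.mean(axis=0))


def _round_pixel(point: tuple[float, float]) -> tuple[int, int]:
    return int(np.rint(point[0])), int(np.rint(point[1]))


def _inside(point: tuple[float, float], mask: np.ndarray) -> bool:
    r, c = _round_pixel(point)
    mask = np.asarray(mask)
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        return False
    return bool(mask[r, c])


def classify_detection(pred_regions: Sequence[Region], gt_mask: np.ndarray,
                       missed_gt_label: Outcome = "FP") -> Outcome:
    """Classify one evaluated unit (image) as TP, FP, TN or FN.

    TP: exactly one predicted region whose centre of mass (nearest pixel)
    lies on a ground-truth foreground pixel.  TN: no region and empty ground
    truth.  FN: catheter present but no region predicted at all.  Everything
    else is an incorrect detection: FP by default; ``missed_gt_label="FN"``
    switches the convention for the case where a catheter is present but
    only wrong regions were predicted.
    """
    gt_mask = np.asarray(gt_mask)
    gt_present = bool(gt_mask.any())
    if len(pred_regions) == 0:
        return "TN" if not gt_present else "FN"
    if not gt_present:
        return "FP"
    if len(pred_regions) == 1 and _inside(pred_regions[0].centroid, gt_mask):
        return "TP"
    return missed_gt_label


@dataclass(frozen=True)
class MultiSliceGT:
    """Ground truth of one dynamic reduced to a single reference region."""

    slice_index: int | None  # None when all three slices are catheter-free
    mask: np.ndarray | None

    @property
    def empty(self) -> bool:
        return self.slice_index is None


def make_multislice_gt(gt_masks: np.ndarray, images: np.ndarray,
                       scoring: Literal["mean", "peak"] = "mean") -> MultiSliceGT:
    """Keep only the per-slice ground-truth region with the highest signal
    intensity across the three slices (same scoring as the tracking stage)."""
    gt_masks = np.asarray(gt_masks)
    images = np.asarray(images, dtype=np.float64)
    best: tuple[float, int] | None = None
    for k in range(gt_masks.shape[0]):
        m = gt_masks[k] > 0
        if not m.any():
            continue
        vals = images[k][m]
        score = float(vals.mean() if scoring == "mean" else vals.max())
        if best is None or score > best[0]:
            best = (score, k)
    if best is None:
        return MultiSliceGT(slice_index=None, mask=None)
    return MultiSliceGT(slice_index=best[1], mask=gt_masks[best[1]] > 0)


def classify_dynamic(tip: TipEstimate, ms_gt: MultiSliceGT,
                     missed_gt_label: Outcome = "FP") -> Outcome:
    """Classify one dynamic: the pipeline's unique tip estimate against the
    multi-slice ground-truth reference (slice must match and the tip must
    fall inside the reference region)."""
    if not tip.present:
        return "TN" if ms_gt.empty else "FN"
    if ms_gt.empty:
        return "FP"
    if tip.slice_index == ms_gt.slice_index and _inside(tip.tip, ms_gt.mask):
        return "TP"
    return missed_gt_label


@dataclass(frozen=True)
class Metrics:
    """Accuracy / specificity / sensitivity in percent (NaN = undefined)."""

    accuracy: float
    specificity: float
    sensitivity: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.accuracy, self.specificity, self.sensitivity)


def _counts(outcomes: Sequence[Outcome]) -> dict[str, int]:
    return {k: sum(1 for o in outcomes if o == k) for k in ("TP", "FP", "TN", "FN")}


def compute_metrics(outcomes: Sequence[Outcome]) -> Metrics:
    """Accuracy, specificity and sensitivity (percent) from outcome labels.

    A zero-denominator ratio (e.g. sensitivity with no positive cases) is
    reported as NaN with a warning rather than forced to 0 or 100.
    """
    if len(outcomes) == 0:
        raise ValueError("cannot compute metrics from an empty outcome list")
    c = _counts(outcomes)
    n = sum(c.values())
    acc = 100.0 * (c["TP"] + c["TN"]) / n
    if c["TP"] + c["FN"] > 0:
        sens = 100.0 * c["TP"] / (c["TP"] + c["FN"])
    else:
        warnings.warn("sensitivity undefined (no positive ground-truth cases)")
        sens = float("nan")
    if c["TN"] + c["FP"] > 0:
        spec = 100.0 * c["TN"] / (c["TN"] + c["FP"])
    else:
        warnings.warn("specificity undefined (no negative ground-truth cases)")
        spec = float("nan")
    return Metrics(accuracy=acc, specificity=spec, sensitivity=sens)


def aggregate_patients(per_patient: Mapping[str, Metrics | tuple[float, float, float]]
                       ) -> tuple[Metrics, Metrics]:
    """Unweighted mean and standard deviation of per-patient metrics.

    Accepts ``Metrics`` objects or (accuracy, specificity, sensitivity)
    triples.  NaN entries (undefined per-patient ratios) are excluded from
    the corresponding aggregate with a warning.  The spread is the population
    standard deviation over patients.
    """
    if len(per_patient) == 0:
        raise ValueError("need at least one patient")
    rows = []
    for v in per_patient.values():
        rows.append(v.as_tuple() if isinstance(v, Metrics) else tuple(v))
    arr = np.asarray(rows, dtype=np.float64)
    if np.isnan(arr).any():
        warnings.warn("undefined per-patient metrics excluded from aggregation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0)  # population convention
    return Metrics(*mean), Metrics(*sd)


@dataclass
class MetricsReport:
    """Per-patient metrics, their cross-patient aggregate, and raw counts."""

    per_patient: dict[str, Metrics] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    mean: Metrics | None = None
    sd: Metrics | None = None

    def to_dict(self) -> dict:
        fmt = lambda m: {k: (None if np.isnan(v) else round(v, 1))
                         for k, v in zip(("accuracy", "specificity", "sensitivity"),
                                         m.as_tuple())}
        return {
            "per_patient": {p: fmt(m) for p, m in self.per_patient.items()},
            "counts": self.counts,
            "mean": fmt(self.mean) if self.mean else None,
            "sd": fmt(self.sd) if self.sd else None,
        }


def build_report(outcomes_by_patient: Mapping[str, Sequence[Outcome]]) -> MetricsReport:
    """Per-patient metrics plus the unweighted cross-patient mean and sd."""
    report = MetricsReport()
    for patient, outcomes in outcomes_by_patient.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.per_patient[patient] = compute_metrics(outcomes)
        report.counts[patient] = _counts(outcomes)
    report.mean, report.sd = aggregate_patients(report.per_patient)
    return report


def operator_agreement(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    """Two segmentations agree iff each mask's centre of mass falls inside
    the other mask.  Two empty masks agree; exactly one empty disagrees."""
    mask_a = np.asarray(mask_a)
    mask_b = np.asarray(mask_b)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a shape")
    a_empty, b_empty = not mask_a.any(), not mask_b.any()
    if a_empty or b_empty:
        return a_empty and b_empty
    return _inside(_mask_centroid(mask_a), mask_b) and \
        _inside(_mask_centroid(mask_b), mask_a)
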