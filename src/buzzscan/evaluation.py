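"""Frame- and event-level performance metrics and threshold calibration.

The detector's raw output is one activation per frame per label; a frame is
called a detection when its activation strictly exceeds a threshold θ.
This module implements the full evaluation methodology:

* confusion counting at a threshold and metric curves across all operating
  points (sensitivity = tp/(tp+fn), false positive rate = fp/(fp+tn),
  precision = tp/(tp+fp), undefined when nothing is detected);
* precision-targeted calibration — the smallest θ whose precision on a
  calibration set reaches the target, which maximises sensitivity subject
  to the precision constraint;
* per-buzz sensitivity (probability an annotated buzz is detected in at
  least one of its frames) with duration-class breakdown;
* sensitivity stratified by what else overlaps a buzz frame (crickets,
  vehicles, planes, a second buzz, ...);
* exact Clopper–Pearson binomial confidence intervals for sensitivity
  estimates from a validation subsample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .annotations import LabelEvent, MatchPolicy, merge_events
from .audio_io import Frame, FrameSpec

__all__ = [
    "ConfusionCounts",
    "MetricPoint",
    "MetricCurve",
    "ThresholdCalibration",
    "BinomialInterval",
    "CalibrationError",
    "confusion_at",
    "metric_curve",
    "calibrate_threshold",
    "per_buzz_sensitivity",
    "stratified_sensitivity",
    "sensitivity_ci",
    "round_half_away",
    "DURATION_CLASSES",
]

# duration class edges in seconds; classes partition (0, inf)
DURATION_CLASSES = (
    ("<0.5", 0.0, 0.5),
    ("0.5-1.5", 0.5, 1.5),
    ("1.5-3", 1.5, 3.0),
    ("3-6", 3.0, 6.0),
    (">6", 6.0, float("inf")),
)


class CalibrationError(ValueError):
    """No threshold achieves the requested precision on the calibration set."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def false_positive_rate(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else float("nan")

    @property
    def precision(self) -> float:
        """tp/(tp+fp); NaN (undefined) when there are no detections."""
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")


@dataclass(frozen=True)
class MetricPoint:
    threshold: float
    sensitivity: float
    false_positive_rate: float
    precision: float  # NaN when undefined
    counts: ConfusionCounts


@dataclass(frozen=True)
class MetricCurve:
    points: tuple[MetricPoint, ...]

    def __post_init__(self) -> None:
        thetas = [p.threshold for p in self.points]
        if any(b <= a for a, b in zip(thetas, thetas[1:])):
            raise ValueError("curve points must be strictly increasing in threshold")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ThresholdCalibration:
    target_precision: float
    threshold: float
    achieved_precision: float
    achieved_sensitivity: float
    calibration_set_id: str = ""

    def __post_init__(self) -> None:
        if self.achieved_precision < self.target_precision:
            raise ValueError("achieved precision below target — invalid calibration")


@dataclass(frozen=True)
class BinomialInterval:
    successes: int
    trials: int
    confidence: float
    lower: float
    upper: float


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (matches conventional reporting of percentages)."""
    factor = 10.0**decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def confusion_at(activations: np.ndarray, truth: np.ndarray, threshold: float) -> ConfusionCounts:
    """Count tp/fp/tn/fn at one threshold (detection = activation > θ)."""
    a = np.asarray(activations, dtype=np.float64)
    t = np.asarray(truth, dtype=bool)
    if a.shape != t.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: activations {a.shape} vs truth {t.shape}")
    det = a > threshold
    tp = int(np.sum(det & t))
    fp = int(np.sum(det & ~t))
    fn = int(np.sum(~det & t))
    tn = int(np.sum(~det & ~t))
    return ConfusionCounts(tp, fp, tn, fn)


def metric_curve(
    activations: np.ndarray,
    truth: np.ndarray,
    thresholds: Sequence[float] | None = None,
) -> MetricCurve:
    """Sensitivity/FPR/precision at every operating point.

    The default grid is the sorted unique activation values, which
    enumerates every distinct confusion table the data can produce (as a
    threshold each value excludes itself, detection being strict).
    """
    a = np.asarray(activations, dtype=np.float64)
    t = np.asarray(truth, dtype=bool)
    if a.shape != t.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: activations {a.shape} vs truth {t.shape}")
    grid = np.unique(a) if thresholds is None else np.unique(np.asarray(thresholds, dtype=np.float64))
    pos = np.sort(a[t])
    neg = np.sort(a[~t])
    n_pos, n_neg = pos.size, neg.size
    points = []
    for theta in grid:
        tp = n_pos - int(np.searchsorted(pos, theta, side="right"))
        fp = n_neg - int(np.searchsorted(neg, theta, side="right"))
        counts = ConfusionCounts(tp, fp, n_neg - fp, n_pos - tp)
        points.append(
            MetricPoint(float(theta), counts.sensitivity, counts.false_positive_rate, counts.precision, counts)
        )
    return MetricCurve(tuple(points))


def calibrate_threshold(
    curve: MetricCurve, target_precision: float = 0.95, calibration_set_id: str = ""
) -> ThresholdCalibration:
    """Pick the smallest θ whose (defined) precision reaches the target.

    Smaller θ means more detections, so this choice maximises sensitivity
    among thresholds meeting the precision constraint.  Operating points
    with no detections have undefined precision and are skipped — they
    would be vacuously "precise".
    """
    if not curve.points:
        raise CalibrationError("empty metric curve")
    best = None
    max_prec = float("nan")
    for p in curve.points:
        if np.isnan(p.precision):
            continue
        if np.isnan(max_prec) or p.precision > max_prec:
            max_prec = p.precision
        if p.precision >= target_precision:
            best = p
            break
    if best is None:
        raise CalibrationError(
            f"no threshold achieves precision {target_precision:.3f}; "
            f"maximum achievable is {max_prec:.3f}"
        )
    return ThresholdCalibration(
        target_precision, best.threshold, best.precision, best.sensitivity, calibration_set_id
    )


def _event_frame_hits(
    event: LabelEvent,
    starts: np.ndarray,
    frame_length_s: float,
    policy: MatchPolicy,
) -> np.ndarray:
    """Mask of frames matched to one event under the overlap/containment rule."""
    ends = starts + frame_length_s
    overlap = np.minimum(event.end_s, ends) - np.maximum(event.start_s, starts)
    contained = (event.start_s >= starts - 1e-9) & (event.end_s <= ends + 1e-9)
    hit = overlap >= policy.min_overlap_s(frame_length_s) - 1e-9
    if policy.full_containment_positive:
        hit |= contained & (overlap > 0)
    return hit


def per_buzz_sensitivity(
    events: Sequence[LabelEvent],
    starts: np.ndarray,
    detected: np.ndarray,
    policy: MatchPolicy = MatchPolicy(),
    frame_length_s: float = FrameSpec().frame_length_s,
    duration_classes=DURATION_CLASSES,
) -> tuple[float, list[dict]]:
    """Fraction of (merged) events detected in at least one of their frames.

    Returns the overall per-event sensitivity and a per-duration-class table
    of dicts (class, n_events, n_detected, sensitivity).
    """
    starts = np.asarray(starts, dtype=np.float64)
    det = np.asarray(detected, dtype=bool)
    if starts.shape != det.shape:
        raise ValueError("starts and detected must have equal length")
    merged = merge_events(events) if events else []
    rows = {name: {"class": name, "n_events": 0, "n_detected": 0} for name, *_ in duration_classes}
    n_hit = 0
    for ev in merged:
        hit_frames = _event_frame_hits(ev, starts, frame_length_s, policy)
        detected_ev = bool(np.any(hit_frames & det))
        n_hit += detected_ev
        for name, lo, hi in duration_classes:
            if lo <= ev.duration_s < hi:
                rows[name]["n_events"] += 1
                rows[name]["n_detected"] += detected_ev
                break
    table = []
    for name, *_ in duration_classes:
        r = rows[name]
        r["sensitivity"] = r["n_detected"] / r["n_events"] if r["n_events"] else float("nan")
        table.append(r)
    overall = n_hit / len(merged) if merged else float("nan")
    return overall, table


def stratified_sensitivity(
    buzz_truth: np.ndarray,
    detected: np.ndarray,
    overlap_truth: Mapping[str, np.ndarray],
    multi_buzz: np.ndarray | None = None,
) -> list[dict]:
    """Sensitivity of buzz-positive frames stratified by co-occurring sound.

    Each buzz-positive frame lands in exactly one stratum: ``none`` (no
    overlap), a single non-buzz overlap label, ``multiple`` (two or more
    non-buzz overlaps), or ``multi_buzz`` (a second buzz and no non-buzz
    overlap — non-buzz strata take precedence).  Strata sizes sum to the
    number of buzz-positive frames.
    """
    buzz = np.asarray(buzz_truth, dtype=bool)
    det = np.asarray(detected, dtype=bool)
    if buzz.shape != det.shape:
        raise ValueError("buzz_truth and detected must have equal length")
    names = list(overlap_truth)
    overlaps = np.column_stack([np.asarray(overlap_truth[k], dtype=bool) for k in names]) if names else np.zeros((buzz.size, 0), dtype=bool)
    if overlaps.shape[0] != buzz.size:
        raise ValueError("overlap truth vectors must match frame count")
    mb = np.zeros(buzz.size, dtype=bool) if multi_buzz is None else np.asarray(multi_buzz, dtype=bool)

    n_over = overlaps.sum(axis=1)
    strata: dict[str, list[int]] = {}
    for i in np.flatnonzero(buzz):
        if n_over[i] == 0:
            name = "multi_buzz" if mb[i] else "none"
        elif n_over[i] == 1:
            name = names[int(np.flatnonzero(overlaps[i])[0])]
        else:
            name = "multiple"
        strata.setdefault(name, []).append(i)
    table = []
    order = ["none"] + names + ["multiple", "multi_buzz"]
    for name in order + [s for s in strata if s not in order]:
        if name not in strata:
            continue
        idx = np.asarray(strata[name])
        table.append(
            {
                "stratum": name,
                "n_frames": int(idx.size),
                "sensitivity": float(det[idx].mean()),
            }
        )
    return table


def sensitivity_ci(x: int, n: int, confidence: float = 0.95) -> BinomialInterval:
    """Exact (Clopper–Pearson) equal-tailed binomial confidence interval.

    Endpoints are beta-distribution quantiles: lower = B(α/2; x, n−x+1),
    upper = B(1−α/2; x+1, n−x); the interval always contains x/n.
    """
    if n <= 0 or not (0 <= x <= n):
        raise ValueError(f"require 0 <= x <= n with n > 0, got x={x}, n={n}")
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialInterval(x, n, confidence, lower, upper)
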