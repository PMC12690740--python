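"""End-to-end experiment harness on synthetic soundscapes.

Wires the whole method together: generate annotated scenes, extract
embeddings, train the linear head, calibrate the detection threshold to a
target precision on a held-out calibration split, then measure held-out
performance — frame-level precision/sensitivity/FPR, sensitivity by buzz
volume, and per-buzz sensitivity by duration class.  Tests, the
reproduction script and the CLI all run experiments through this module so
they share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import (
    LabelEvent,
    LabelVocabulary,
    MatchPolicy,
    frame_truth,
    frames_from_starts,
)
from .audio_io import FrameSpec, frame_audio
from .classifier import ClassifierHead, TrainConfig, train_head
from .evaluation import (
    DURATION_CLASSES,
    MetricCurve,
    ThresholdCalibration,
    calibrate_threshold,
    confusion_at,
    metric_curve,
    per_buzz_sensitivity,
)
from .features import EmbeddingProvider, extract_batch, get_provider
from .synthetic import SyntheticScene, make_scene, random_scene_spec

__all__ = [
    "SceneData",
    "ExperimentResult",
    "prepare_scene",
    "generate_split_seeds",
    "run_experiment",
]

TARGET_LABEL = "ins_buzz"


@dataclass
class SceneData:
    """Embeddings, starts, events and per-label truth for one scene."""

    starts: np.ndarray
    embeddings: np.ndarray
    events: tuple[LabelEvent, ...]
    truth: dict[str, np.ndarray]


@dataclass
class ExperimentResult:
    """Held-out metrics of one end-to-end run."""

    head: ClassifierHead
    calibration: ThresholdCalibration
    curve: MetricCurve
    test_precision: float
    test_sensitivity: float
    test_fpr: float
    n_test_frames: int
    sensitivity_by_volume: dict[str, float]
    per_buzz_overall: float
    per_buzz_by_duration: list[dict]
    extras: dict = field(default_factory=dict)


def prepare_scene(
    scene: SyntheticScene,
    provider: EmbeddingProvider,
    spec: FrameSpec,
    policy: MatchPolicy,
    labels: Sequence[str],
) -> SceneData:
    """Frame, embed and truth-label one scene."""
    frames = frame_audio(scene.clip, spec)
    X = extract_batch(provider, frames)
    starts = np.asarray([f.start_s for f in frames])
    truth = {
        lab: frame_truth(scene.truth, frames, policy, lab, spec.frame_length_s)
        for lab in labels
    }
    return SceneData(starts=starts, embeddings=X, events=scene.truth, truth=truth)


def generate_split_seeds(seed: int, counts: Sequence[int]) -> list[list[int]]:
    """Disjoint per-scene seed streams for each split."""
    root = np.random.SeedSequence(seed)
    splits = root.spawn(len(counts))
    return [
        [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
        for ss, n in zip(splits, counts)
    ]


def _volume_truth(
    scene: SyntheticScene,
    starts: np.ndarray,
    spec: FrameSpec,
    policy: MatchPolicy,
    tag: str | None,
) -> np.ndarray:
    """Frames positive specifically for buzzes of one volume tag."""
    frames = frames_from_starts(starts)
    if tag is None:
        events = [
            e for e in scene.truth if e.label == TARGET_LABEL and not (e.tags & {"quiet", "loud"})
        ]
    else:
        events = [e for e in scene.truth if e.label == TARGET_LABEL and tag in e.tags]
    return frame_truth(events, frames, policy, TARGET_LABEL, spec.frame_length_s)


def run_experiment(
    seed: int = 0,
    n_train: int = 50,
    n_cal: int = 15,
    n_test: int = 20,
    scene_duration_s: float = 300.0,
    event_rate_per_min: float = 2.0,
    target_precision: float = 0.95,
    provider: EmbeddingProvider | None = None,
    spec: FrameSpec = FrameSpec(),
    policy: MatchPolicy = MatchPolicy(),
    train_config: TrainConfig | None = None,
) -> ExperimentResult:
    """Train, calibrate and evaluate the pipeline on synthetic scenes.

    Scenes in the three splits come from disjoint deterministic seed
    streams, so the calibration and test sets are independent draws from
    the same soundscape distribution as the training set.
    """
    provider = provider or get_provider()
    train_config = train_config or TrainConfig(seed=seed)
    vocab = LabelVocabulary()
    labels = list(vocab.labels)

    seeds = generate_split_seeds(seed, [n_train, n_cal, n_test])
    splits: list[list[SceneData]] = []
    scenes_by_split: list[list[SyntheticScene]] = []
    for split_seeds in seeds:
        datas, scenes = [], []
        for s in split_seeds:
            scene = make_scene(random_scene_spec(s, scene_duration_s, event_rate_per_min))
            datas.append(prepare_scene(scene, provider, spec, policy, labels))
            scenes.append(scene)
        splits.append(datas)
        scenes_by_split.append(scenes)
    train_data, cal_data, test_data = splits

    X_train = np.vstack([d.embeddings for d in train_data])
    trainable = {}
    for lab in labels:
        y = np.concatenate([d.truth[lab] for d in train_data])
        if 0 < y.sum() < y.size:
            trainable[lab] = y
    head = train_head(X_train, trainable, vocab, provider.provider_id, train_config)

    def label_activations(datas: list[SceneData]) -> np.ndarray:
        col = vocab.index(TARGET_LABEL)
        return np.concatenate(
            [d.embeddings @ head.weights[:, col] + head.bias[col] for d in datas]
        )

    cal_act = label_activations(cal_data)
    cal_truth = np.concatenate([d.truth[TARGET_LABEL] for d in cal_data])
    curve = metric_curve(cal_act, cal_truth)
    calibration = calibrate_threshold(curve, target_precision, f"synthetic-cal-seed{seed}")

    test_act = label_activations(test_data)
    test_truth = np.concatenate([d.truth[TARGET_LABEL] for d in test_data])
    counts = confusion_at(test_act, test_truth, calibration.threshold)

    detected = test_act > calibration.threshold
    vol_sens = {}
    offset = 0
    vol_masks = {tag: [] for tag in ("quiet", None, "loud")}
    for scene, d in zip(scenes_by_split[2], test_data):
        for tag in vol_masks:
            vol_masks[tag].append(_volume_truth(scene, d.starts, spec, policy, tag))
        offset += d.starts.size
    for tag, masks in vol_masks.items():
        mask = np.concatenate(masks)
        name = tag if tag is not None else "normal"
        vol_sens[name] = float(detected[mask].mean()) if mask.any() else float("nan")

    # per-buzz sensitivity accumulated over test scenes
    n_events = {name: 0 for name, *_ in DURATION_CLASSES}
    n_hit = {name: 0 for name, *_ in DURATION_CLASSES}
    total_events = total_hit = 0
    pos = 0
    for scene, d in zip(scenes_by_split[2], test_data):
        det_scene = detected[pos : pos + d.starts.size]
        pos += d.starts.size
        buzz_events = [e for e in scene.truth if e.label == TARGET_LABEL]
        if not buzz_events:
            continue
        overall, table = per_buzz_sensitivity(
            buzz_events, d.starts, det_scene, policy, spec.frame_length_s
        )
        for row in table:
            n_events[row["class"]] += row["n_events"]
            n_hit[row["class"]] += row["n_detected"]
            total_events += row["n_events"]
            total_hit += row["n_detected"]
    by_duration = [
        {
            "class": name,
            "n_events": n_events[name],
            "n_detected": n_hit[name],
            "sensitivity": n_hit[name] / n_events[name] if n_events[name] else float("nan"),
        }
        for name, *_ in DURATION_CLASSES
    ]

    return ExperimentResult(
        head=head,
        calibration=calibration,
        curve=curve,
        test_precision=counts.precision,
        test_sensitivity=counts.sensitivity,
        test_fpr=counts.false_positive_rate,
        n_test_frames=counts.total,
        sensitivity_by_volume=vol_sens,
        per_buzz_overall=total_hit / total_events if total_events else float("nan"),
        per_buzz_by_duration=by_duration,
        extras={"n_train_frames": X_train.shape[0], "trained_labels": sorted(trainable)},
    )
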