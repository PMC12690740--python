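"""Analysis pipeline: audio file -> per-frame activation or detection CSV.

One CSV is written per input file: a ``start`` column (frame start time in
seconds) and one column per output neuron with its raw activation.  In
detections mode a calibrated threshold converts activations to booleans; a
frame is a detection when its activation is strictly greater than θ, so
boundary equality is not a detection.  Results for a file depend only on
that file, the head, and the frame geometry — never on batch composition
or worker count.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .audio_io import AudioClip, FrameSpec, frame_audio, read_audio, resample
from .classifier import ActivationRecord, ClassifierHead, activations as head_activations
from .evaluation import ThresholdCalibration
from .features import EmbeddingProvider, extract_batch

__all__ = [
    "FrameTable",
    "DetectionTable",
    "BatchReport",
    "analyze_clip",
    "analyze_file",
    "analyze_batch",
    "write_frame_csv",
    "read_frame_csv",
]


@dataclass(frozen=True)
class FrameTable:
    """Per-frame raw activations for one audio source."""

    source_path: str
    vocabulary: tuple[str, ...]
    starts: np.ndarray
    activations: np.ndarray  # (n_frames, K)

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=np.float64)
        a = np.asarray(self.activations, dtype=np.float64)
        if a.shape != (s.size, len(self.vocabulary)):
            raise ValueError(f"activations shape {a.shape} inconsistent with "
                             f"{s.size} frames x {len(self.vocabulary)} labels")
        if s.size > 1 and np.any(np.diff(s) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        object.__setattr__(self, "starts", s)
        object.__setattr__(self, "activations", a)

    def column(self, label: str) -> np.ndarray:
        return self.activations[:, self.vocabulary.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.activations, columns=list(self.vocabulary))
        df.insert(0, "start", self.starts)
        return df


@dataclass(frozen=True)
class DetectionTable:
    """Binary detections (plus activations) at calibrated thresholds."""

    source_path: str
    vocabulary: tuple[str, ...]
    starts: np.ndarray
    activations: np.ndarray
    thresholds: dict[str, float]  # per detected label
    calibration_ref: str = ""

    @property
    def detected(self) -> dict[str, np.ndarray]:
        vocab = list(self.vocabulary)
        return {
            lab: self.activations[:, vocab.index(lab)] > theta
            for lab, theta in self.thresholds.items()
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.activations, columns=list(self.vocabulary))
        df.insert(0, "start", self.starts)
        for lab, det in self.detected.items():
            df[f"detected_{lab}"] = det
        return df


@dataclass
class BatchReport:
    """Outcome of a batch run: output paths plus isolated failures."""

    outputs: dict[str, Path] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def analyze_clip(
    clip: AudioClip,
    head: ClassifierHead,
    provider: EmbeddingProvider,
    spec: FrameSpec = FrameSpec(),
    mode: Literal["activations", "detections"] = "activations",
    calibration: ThresholdCalibration | Mapping[str, float] | None = None,
    target_labels: Sequence[str] = ("ins_buzz",),
) -> FrameTable | DetectionTable:
    """Run the pipeline on an in-memory clip (see :func:`analyze_file`)."""
    if head.provider_id != provider.provider_id:
        raise ValueError(
            f"head was trained on provider {head.provider_id!r} but "
            f"{provider.provider_id!r} was supplied"
        )
    clip = resample(clip, spec.model_sample_rate)
    frames = frame_audio(clip, spec)
    X = extract_batch(provider, frames)
    starts = [f.start_s for f in frames]
    records = head_activations(head, X, starts) if frames else []
    act = np.vstack([r.activations for r in records]) if records else np.empty((0, len(head.vocabulary)))
    table = FrameTable(clip.source_path, head.vocabulary.labels, np.asarray(starts), act)
    if mode == "activations":
        return table
    if calibration is None:
        raise ValueError("detections mode requires a calibration (threshold per label)")
    if isinstance(calibration, ThresholdCalibration):
        thresholds = {lab: calibration.threshold for lab in target_labels}
        ref = calibration.calibration_set_id
    else:
        thresholds = dict(calibration)
        ref = ""
    return DetectionTable(clip.source_path, head.vocabulary.labels, table.starts, table.activations, thresholds, ref)


def analyze_file(
    path: str | Path,
    head: ClassifierHead,
    provider: EmbeddingProvider,
    spec: FrameSpec = FrameSpec(),
    mode: Literal["activations", "detections"] = "activations",
    calibration: ThresholdCalibration | Mapping[str, float] | None = None,
    target_labels: Sequence[str] = ("ins_buzz",),
) -> FrameTable | DetectionTable:
    """Decode, resample, frame, embed and classify one audio file.

    ``mode="activations"`` yields the raw per-neuron logits;
    ``mode="detections"`` additionally thresholds the requested labels with
    the supplied calibration.
    """
    clip = read_audio(path)
    return analyze_clip(clip, head, provider, spec, mode, calibration, target_labels)


def output_name(input_path: str | Path, suffix: str = "_buzzscan.csv") -> str:
    return Path(input_path).stem + suffix


def write_frame_csv(table: FrameTable | DetectionTable, path: str | Path) -> None:
    """Write the CSV contract: start to ms precision, activations to 6
    significant digits, header ``start,<label1>,...`` in vocabulary order."""
    df = table.to_frame()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    formatted = df.copy()
    formatted["start"] = [f"{s:.3f}" for s in df["start"]]
    for col in table.vocabulary:
        formatted[col] = [f"{v:.6g}" for v in df[col]]
    formatted.to_csv(path, index=False)


def read_frame_csv(path: str | Path) -> pd.DataFrame:
    """Read back a written CSV; numeric columns parsed, booleans restored."""
    df = pd.read_csv(path)
    for col in df.columns:
        if col.startswith("detected_"):
            df[col] = df[col].astype(bool)
    return df


def _analyze_one(args) -> tuple[str, str | None, str | None]:
    path, head, provider, spec, mode, calibration, target_labels, out_dir = args
    try:
        table = analyze_file(path, head, provider, spec, mode, calibration, target_labels)
        out = Path(out_dir) / output_name(path)
        write_frame_csv(table, out)
        return str(path), str(out), None
    except Exception as exc:
        return str(path), None, f"{type(exc).__name__}: {exc}"


def analyze_batch(
    paths: Sequence[str | Path],
    head: ClassifierHead,
    provider: EmbeddingProvider,
    out_dir: str | Path,
    spec: FrameSpec = FrameSpec(),
    mode: Literal["activations", "detections"] = "activations",
    calibration: ThresholdCalibration | Mapping[str, float] | None = None,
    target_labels: Sequence[str] = ("ins_buzz",),
    workers: int = 1,
) -> BatchReport:
    """Analyze many files, one CSV each; failures are isolated per file.

    Outputs are bitwise identical for any worker count: each file's result
    depends only on its own bytes and the shared model.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jobs = [
        (str(p), head, provider, spec, mode, calibration, tuple(target_labels), str(out_dir))
        for p in paths
    ]
    report = BatchReport()
    if workers <= 1:
        results = [_analyze_one(j) for j in jobs]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_analyze_one, jobs))
    for path, out, err in results:
        if err is None:
            report.outputs[path] = Path(out)
        else:
            report.failures[path] = err
    return report
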