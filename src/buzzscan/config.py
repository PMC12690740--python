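"""YAML configuration mirroring the CLI flags.

A config file names the label vocabulary (with optional collapse map),
frame geometry, matching policy and detection thresholds, so a deployment
can be described in one reviewed file instead of a flag soup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotations import LabelVocabulary, MatchPolicy
from .audio_io import FrameSpec

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    vocabulary: LabelVocabulary = LabelVocabulary()
    frame_spec: FrameSpec = FrameSpec()
    match_policy: MatchPolicy = MatchPolicy()
    provider: str = "builtin-logmel-v1"
    target_precision: float = 0.95
    thresholds: dict[str, float] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    vocab_cfg = raw.get("vocabulary", {})
    vocab = LabelVocabulary(
        tuple(vocab_cfg.get("labels", LabelVocabulary().labels)),
        dict(vocab_cfg.get("collapse_map", {})),
    )
    fs = raw.get("frame_spec", {})
    spec = FrameSpec(
        frame_length_s=float(fs.get("frame_length_s", 0.96)),
        hop_s=float(fs.get("hop_s", fs.get("frame_length_s", 0.96))),
        model_sample_rate=int(fs.get("model_sample_rate", 16000)),
    )
    mp = raw.get("match_policy", {})
    policy = MatchPolicy(
        min_overlap_fraction=float(mp.get("min_overlap_fraction", 0.10)),
        full_containment_positive=bool(mp.get("full_containment_positive", True)),
        background_policy=mp.get("background_policy", "exclude"),
    )
    return RunConfig(
        vocabulary=vocab,
        frame_spec=spec,
        match_policy=policy,
        provider=raw.get("provider", "builtin-logmel-v1"),
        target_precision=float(raw.get("target_precision", 0.95)),
        thresholds={k: float(v) for k, v in raw.get("thresholds", {}).items()},
    )
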