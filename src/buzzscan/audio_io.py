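"""Audio reading, resampling, and segmentation into fixed-length analysis frames.

The classifier consumes non-overlapping 0.96-s frames at 16 kHz, the frame
geometry used by the AudioSet family of embedding backbones.  Long field
recordings are decoded once, resampled in memory, and tiled into frames;
trailing audio shorter than one frame is dropped rather than zero-padded,
so every frame corresponds to real recorded sound.

Only uncompressed WAV (PCM 16/24/32-bit and IEEE float) is decoded.
Compressed field formats (MP3/OGG/FLAC) are recognised by their magic bytes
and rejected with an explicit error naming the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioClip",
    "FrameSpec",
    "Frame",
    "UnsupportedFormatError",
    "read_audio",
    "write_wav",
    "resample",
    "frame_audio",
]

# magic bytes of codecs we can name but not decode
_COMPRESSED_MAGIC = {
    b"fLaC": "FLAC",
    b"OggS": "OGG/Vorbis",
    b"ID3": "MP3",
    b"\xff\xfb": "MP3",
    b"\xff\xf3": "MP3",
    b"\xff\xf2": "MP3",
}


class UnsupportedFormatError(ValueError):
    """Raised when a file is not a decodable audio format."""


@dataclass(frozen=True)
class AudioClip:
    """A mono audio signal with amplitudes in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D (mono), got shape {samples.shape}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class FrameSpec:
    """Geometry of the analysis frames.

    Defaults are 0.96-s non-overlapping frames at a 16 kHz model rate.
    """

    frame_length_s: float = 0.96
    hop_s: float = 0.96
    model_sample_rate: int = 16000

    def __post_init__(self) -> None:
        if not (0 < self.hop_s <= self.frame_length_s):
            raise ValueError(
                f"require 0 < hop_s <= frame_length_s, got hop_s={self.hop_s}, "
                f"frame_length_s={self.frame_length_s}"
            )
        if self.model_sample_rate <= 0:
            raise ValueError("model_sample_rate must be positive")

    @property
    def frame_length_samples(self) -> int:
        return round(self.frame_length_s * self.model_sample_rate)


@dataclass(frozen=True)
class Frame:
    """One fixed-length analysis frame cut from a clip."""

    index: int
    start_s: float
    waveform: np.ndarray = field(repr=False)


def _sniff_compressed(path: Path) -> str | None:
    with open(path, "rb") as fh:
        head = fh.read(4)
    for magic, name in _COMPRESSED_MAGIC.items():
        if head.startswith(magic):
            return name
    return None


def read_audio(path: str | Path) -> AudioClip:
    """Decode a WAV file to a mono float clip at its native sample rate.

    Integer PCM is scaled to [-1, 1]; stereo is mixed to mono by channel
    mean.  Compressed formats raise :class:`UnsupportedFormatError` naming
    the path and detected codec.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    codec = _sniff_compressed(path)
    if codec is not None:
        raise UnsupportedFormatError(
            f"cannot decode {codec} file {path}: only uncompressed WAV is supported"
        )
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # wavfile raises bare ValueError on bad headers
        raise UnsupportedFormatError(f"cannot decode {path} as WAV: {exc}") from exc
    samples = _to_float_mono(data)
    return AudioClip(samples=samples, sample_rate=int(rate), source_path=str(path))


def _to_float_mono(data: np.ndarray) -> np.ndarray:
    if data.ndim == 2:
        data = data.mean(axis=1) if np.issubdtype(data.dtype, np.floating) else data.astype(np.float64).mean(axis=1)
    if np.issubdtype(data.dtype, np.floating):
        return np.asarray(data, dtype=np.float64)
    info = np.iinfo(data.dtype) if data.dtype != np.float64 else None
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64) / float(-int(np.iinfo(data.dtype).min))


def write_wav(path: str | Path, clip: AudioClip, subtype: str = "pcm16") -> None:
    """Write a clip as WAV; ``subtype`` is ``pcm16`` or ``float32``.

    float32 round-trips float64 samples to float32 precision; pcm16
    quantises to 16-bit integers.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if subtype == "pcm16":
        scaled = np.clip(np.round(clip.samples * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(str(path), clip.sample_rate, scaled)
    elif subtype == "float32":
        wavfile.write(str(path), clip.sample_rate, clip.samples.astype(np.float32))
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}; use 'pcm16' or 'float32'")


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Resample a clip to ``target_rate`` with a polyphase filter.

    The identity case is returned unchanged.  Duration is preserved to
    within one output sample and pure tones keep their frequency.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == clip.sample_rate:
        return clip
    ratio = Fraction(int(target_rate), int(clip.sample_rate)).limit_denominator(10_000)
    out = resample_poly(clip.samples, ratio.numerator, ratio.denominator)
    expected = int(round(clip.samples.size * target_rate / clip.sample_rate))
    if out.size > expected:
        out = out[:expected]
    elif out.size < expected:
        out = np.pad(out, (0, expected - out.size))
    return AudioClip(samples=out, sample_rate=int(target_rate), source_path=clip.source_path)


def frame_audio(clip: AudioClip, spec: FrameSpec = FrameSpec()) -> list[Frame]:
    """Cut a clip into fixed-length frames; trailing partial audio is dropped.

    The clip must already be at ``spec.model_sample_rate``; callers resample
    first.  Frame count is ``floor((duration - frame_length)/hop) + 1`` for
    clips at least one frame long, else zero.
    """
    if clip.sample_rate != spec.model_sample_rate:
        raise ValueError(
            f"clip sample rate {clip.sample_rate} != model rate "
            f"{spec.model_sample_rate}; resample first"
        )
    n = spec.frame_length_samples
    hop = round(spec.hop_s * spec.model_sample_rate)
    if clip.samples.size < n:
        return []
    count = (clip.samples.size - n) // hop + 1
    frames = []
    for i in range(count):
        start = i * hop
        frames.append(
            Frame(index=i, start_s=start / spec.model_sample_rate, waveform=clip.samples[start : start + n])
        )
    return frames
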