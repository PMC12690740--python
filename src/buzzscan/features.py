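"""Frame embeddings through a pluggable provider contract.

A provider maps one fixed-length frame waveform to a fixed-dimension real
vector.  The classification head is trained on these vectors, so any
backbone honouring the contract (deterministic, fixed dimension, declared
sample rate and frame length) can stand behind it — including large
pretrained audio embedders.  The built-in provider is a deterministic
log-mel summary extractor needing no downloaded weights:

* STFT with 25 ms Hann windows and a 10 ms hop (96 windows per 0.96-s
  frame at 16 kHz);
* 64 HTK-mel triangular bands spanning 60–7800 Hz; log energies with a
  1e-6 floor;
* per-band mean and standard deviation over time (128 values), plus the
  spectral-centroid mean, spectral-flux mean, RMS energy and zero-crossing
  rate — dimension 132.

Buzzes are quasi-harmonic tones, so their energy concentrates in a few
low-mel bands; broadband interferers spread it, which makes these summary
statistics linearly separable for the events of interest.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.signal import get_window

from .audio_io import Frame

__all__ = [
    "EmbeddingProvider",
    "LogMelProvider",
    "get_provider",
    "extract_embedding",
    "extract_batch",
]


class EmbeddingProvider(Protocol):
    """Contract every embedding backbone must honour."""

    provider_id: str
    dimension: int
    expected_sample_rate: int
    expected_frame_length_s: float

    def embed(self, waveform: np.ndarray) -> np.ndarray: ...


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    # HTK mel scale
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int, fmin: float, fmax: float) -> np.ndarray:
    """Triangular HTK-mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bins_hz = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_mels, bins_hz.size))
    for i in range(n_mels):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bins_hz - left) / max(center - left, 1e-12)
        down = (right - bins_hz) / max(right - center, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


@dataclass
class LogMelProvider:
    """Deterministic log-mel summary extractor (see module docstring)."""

    provider_id: str = "builtin-logmel-v1"
    expected_sample_rate: int = 16000
    expected_frame_length_s: float = 0.96
    n_mels: int = 64
    fmin: float = 60.0
    fmax: float = 7800.0
    win_s: float = 0.025
    hop_s: float = 0.010
    log_floor: float = 1e-6
    _fb: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    _window: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.n_fft = 512
        self.win_length = round(self.win_s * self.expected_sample_rate)
        self.hop_length = round(self.hop_s * self.expected_sample_rate)
        self._fb = mel_filterbank(self.n_mels, self.n_fft, self.expected_sample_rate, self.fmin, self.fmax)
        self._window = get_window("hann", self.win_length, fftbins=True).astype(np.float64)

    @property
    def dimension(self) -> int:
        return 2 * self.n_mels + 4

    @property
    def expected_samples(self) -> int:
        return round(self.expected_frame_length_s * self.expected_sample_rate)

    def embed(self, waveform: np.ndarray) -> np.ndarray:
        x = np.asarray(waveform, dtype=np.float64)
        if x.ndim != 1 or x.size != self.expected_samples:
            raise ValueError(
                f"waveform must be 1-D with {self.expected_samples} samples, "
                f"got shape {np.shape(waveform)}"
            )
        n_windows = 1 + (x.size - self.win_length) // self.hop_length
        idx = np.arange(self.win_length)[None, :] + self.hop_length * np.arange(n_windows)[:, None]
        segments = x[idx] * self._window
        spec = np.abs(np.fft.rfft(segments, n=self.n_fft, axis=1)) ** 2  # power
        mel = spec @ self._fb.T  # (n_windows, n_mels)
        logmel = np.log(mel + self.log_floor)
        band_mean = logmel.mean(axis=0)
        band_std = logmel.std(axis=0)
        freqs = np.arange(self.n_fft // 2 + 1) * self.expected_sample_rate / self.n_fft
        power_sum = spec.sum(axis=1)
        centroid = (spec @ freqs) / np.maximum(power_sum, 1e-30)
        flux = np.sqrt(((np.diff(spec, axis=0)) ** 2).sum(axis=1)) if n_windows > 1 else np.zeros(1)
        rms = float(np.sqrt(np.mean(x**2)))
        zcr = float(np.mean(np.abs(np.diff(np.signbit(x).astype(np.float64)))))
        vec = np.concatenate(
            [band_mean, band_std, [centroid.mean(), flux.mean(), rms, zcr]]
        )
        return vec


_REGISTRY = {"builtin-logmel-v1": LogMelProvider}


def get_provider(name: str = "builtin-logmel-v1", **kwargs) -> EmbeddingProvider:
    """Construct a registered provider by name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown provider {name!r}; registered: {sorted(_REGISTRY)}") from None
    return cls(**kwargs)


def register_provider(name: str, factory) -> None:
    """Attach an external backbone under the provider contract."""
    _REGISTRY[name] = factory


def extract_embedding(provider: EmbeddingProvider, waveform: np.ndarray) -> np.ndarray:
    """Embed one frame waveform; deterministic for identical input."""
    return provider.embed(waveform)


def extract_batch(
    provider: EmbeddingProvider, frames: Sequence[Frame], workers: int = 1
) -> np.ndarray:
    """Embed frames in order; result independent of worker count.

    Returns an (n_frames, dimension) matrix.  Errors are re-raised with the
    offending frame index.
    """
    if not frames:
        return np.empty((0, provider.dimension))

    def one(i_frame):
        i, frame = i_frame
        try:
            return provider.embed(frame.waveform)
        except Exception as exc:
            raise RuntimeError(f"embedding failed for frame {i}: {exc}") from exc

    if workers <= 1:
        rows = [one(x) for x in enumerate(frames)]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            rows = list(pool.map(one, enumerate(frames)))
    return np.vstack(rows)
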