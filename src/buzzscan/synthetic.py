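"""Synthetic annotated soundscapes for end-to-end pipeline exercise.

Generates field-recording stand-ins with exact ground truth: insect flight
buzzes as quasi-harmonic tones around a 230 Hz honey-bee-like fundamental
(with lower- and higher-pitched classes), cricket trills, vehicle and
plane broadband interferers, sirens, and white/pink background noise.
Each scene carries a label track mirroring the annotation vocabulary, so
training, calibration, evaluation and activity analysis run with no
external data.

The recipes are acoustic caricatures, not species models: a buzz is a
jittered harmonic stack, a cricket a 4.5 kHz pulse train, a vehicle a
low-passed noise swell, a plane a broadband drone with a 100 Hz hum, a
siren a slow 700–1500 Hz FM sweep.  They reproduce the *structure* of the
detection problem — tonal target vs broadband/pulsed interferers at
controlled SNR — not its full acoustic difficulty.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from .audio_io import AudioClip, write_wav
from .annotations import LabelEvent, write_label_track

__all__ = [
    "EventSpec",
    "SceneSpec",
    "SyntheticScene",
    "KIND_TO_LABEL",
    "PITCH_DEFAULTS",
    "make_buzz",
    "make_event_waveform",
    "make_scene",
    "sample_events",
    "make_dataset",
]

# fixture fundamentals for the three buzz pitch classes (Hz); the medium
# class sits at the honey-bee flight tone, low/high are fixture choices
PITCH_DEFAULTS = {"buzz_low": 130.0, "buzz_medium": 230.0, "buzz_high": 450.0}

KIND_TO_LABEL = {
    "buzz_low": ("ins_buzz", "low"),
    "buzz_medium": ("ins_buzz", "medium"),
    "buzz_high": ("ins_buzz", "high"),
    "cricket": ("ins_trill", None),
    "vehicle": ("mech_auto", None),
    "plane": ("mech_plane", None),
    "siren": ("mech_siren", None),
}

# event-kind mixture for random scenes; buzzes dominate as in flowering-field audio
DEFAULT_KIND_WEIGHTS = {
    "buzz_medium": 0.35,
    "buzz_low": 0.08,
    "buzz_high": 0.07,
    "cricket": 0.20,
    "vehicle": 0.12,
    "plane": 0.12,
    "siren": 0.06,
}

# buzz SNR levels (dB over background in-window RMS) and their volume tags
BUZZ_SNR_LEVELS = ((0.0, "quiet"), (10.0, None), (20.0, "loud"))
BUZZ_SNR_PROBS = (0.25, 0.55, 0.20)


@dataclass(frozen=True)
class EventSpec:
    kind: str
    start_s: float
    duration_s: float
    snr_db: float
    fundamental_hz: float | None = None
    am_rate_hz: float | None = None
    volume_tag: str | None = None  # quiet / loud / None

    def __post_init__(self) -> None:
        if self.kind not in KIND_TO_LABEL:
            raise ValueError(f"unknown event kind {self.kind!r}; known: {sorted(KIND_TO_LABEL)}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class SceneSpec:
    duration_s: float = 300.0
    seed: int = 0
    sample_rate: int = 16000
    background_kind: str = "pink"  # or "white"
    background_rms: float = 0.03
    events: tuple[EventSpec, ...] = ()

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.start_s < 0 or ev.start_s + ev.duration_s > self.duration_s + 1e-9:
                raise ValueError(f"event {ev} does not fit in {self.duration_s}-s scene")
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class SyntheticScene:
    clip: AudioClip
    truth: tuple[LabelEvent, ...]
    spec: SceneSpec


def _smooth_noise(n: int, sr: int, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise low-passed to slow variation (for jitter/envelopes)."""
    raw = rng.standard_normal(n)
    sos = butter(2, cutoff_hz, fs=sr, output="sos")
    x = sosfilt(sos, raw)
    sd = x.std()
    return x / sd if sd > 0 else x


def make_buzz(
    kind: str,
    duration_s: float,
    fundamental_hz: float | None = None,
    sample_rate: int = 16000,
    seed: int | np.random.Generator = 0,
    am_rate_hz: float | None = None,
) -> np.ndarray:
    """Quasi-harmonic insect flight tone, peak-normalised to <= 1.

    Fundamental plus 4 harmonics with 1/k amplitude decay and slow ±3%
    frequency jitter.  The high pitch class is additionally amplitude- and
    frequency-modulated at 8–15 Hz, emulating the erratic, quavering sound
    of small-fly flight.
    """
    if kind not in PITCH_DEFAULTS:
        raise ValueError(f"unknown buzz kind {kind!r}; known: {sorted(PITCH_DEFAULTS)}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f0 = fundamental_hz if fundamental_hz is not None else PITCH_DEFAULTS[kind]
    sr = sample_rate
    n = round(duration_s * sr)
    t = np.arange(n) / sr
    jitter = 0.03 * _smooth_noise(n, sr, 3.0, rng)
    am_rate = am_rate_hz if am_rate_hz is not None else float(rng.uniform(8.0, 15.0))
    if kind == "buzz_high":
        jitter = jitter + 0.05 * np.sin(2 * np.pi * am_rate * t + rng.uniform(0, 2 * np.pi))
    freq = f0 * (1.0 + jitter)
    phase = 2 * np.pi * np.cumsum(freq) / sr
    x = np.zeros(n)
    for k in range(1, 6):
        x += np.sin(k * phase + rng.uniform(0, 2 * np.pi)) / k
    if kind == "buzz_high":
        x *= 1.0 + 0.5 * np.sin(2 * np.pi * am_rate * t)
    x *= _attack_release(n, sr)
    peak = np.abs(x).max()
    return x / peak if peak > 1.0 else x


def _attack_release(n: int, sr: int, ramp_s: float = 0.02) -> np.ndarray:
    ramp = min(max(round(ramp_s * sr), 1), n // 2)
    env = np.ones(n)
    env[:ramp] = np.linspace(0, 1, ramp)
    env[-ramp:] = np.linspace(1, 0, ramp)
    return env


def _cricket(n: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / sr
    carrier = np.sin(2 * np.pi * 4500.0 * t)
    gate = (np.sin(2 * np.pi * 30.0 * t + rng.uniform(0, 2 * np.pi)) > 0).astype(float)
    return carrier * gate * _attack_release(n, sr)


def _vehicle(n: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    brown = np.cumsum(rng.standard_normal(n))
    brown -= np.linspace(brown[0], brown[-1], n)  # detrend, avoid DC ramp
    sos = butter(4, 500.0, fs=sr, output="sos")
    x = sosfilt(sos, brown)
    swell = np.sin(np.linspace(0, np.pi, n)) ** 2  # pass-by loudness envelope
    x = x * swell
    sd = x.std()
    return x / sd if sd > 0 else x


def _plane(n: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    sos = butter(2, 2000.0, fs=sr, output="sos")
    drone = sosfilt(sos, noise)
    t = np.arange(n) / sr
    hum = 0.6 * np.sin(2 * np.pi * 100.0 * t)
    slow = 1.0 + 0.3 * _smooth_noise(n, sr, 0.5, rng)
    x = (drone + hum) * slow * _attack_release(n, sr, 0.1)
    sd = x.std()
    return x / sd if sd > 0 else x


def _siren(n: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / sr
    # triangle sweep between 700 and 1500 Hz at 0.5 Hz
    tri = 2 * np.abs((0.5 * t + rng.uniform(0, 1)) % 1.0 - 0.5)
    freq = 700.0 + 800.0 * tri
    phase = 2 * np.pi * np.cumsum(freq) / sr
    return np.sin(phase) * _attack_release(n, sr)


def make_event_waveform(ev: EventSpec, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """Synthesise one event at unit peak scale (SNR applied during mixing)."""
    n = round(ev.duration_s * sample_rate)
    if ev.kind in PITCH_DEFAULTS:
        return make_buzz(ev.kind, ev.duration_s, ev.fundamental_hz, sample_rate, rng, ev.am_rate_hz)
    if ev.kind == "cricket":
        return _cricket(n, sample_rate, rng)
    if ev.kind == "vehicle":
        return _vehicle(n, sample_rate, rng)
    if ev.kind == "plane":
        return _plane(n, sample_rate, rng)
    if ev.kind == "siren":
        return _siren(n, sample_rate, rng)
    raise ValueError(f"unknown event kind {ev.kind!r}")


def _background(n: int, kind: str, rms: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if kind == "white":
        x = white
    elif kind == "pink":
        # -3 dB/octave via cumulative first-order shaping
        sos = butter(1, 200.0, fs=16000, output="sos")
        x = sosfilt(sos, white) + 0.3 * white
    else:
        raise ValueError(f"unknown background kind {kind!r}")
    return x * (rms / max(x.std(), 1e-12))


def make_scene(spec: SceneSpec) -> SyntheticScene:
    """Mix a scene's events into its background at the requested SNRs.

    Per-event SNR is defined as event RMS over background RMS inside the
    event window.  After mixing, the scene is peak-normalised to 0.9 only
    if it would clip; normalisation rescales signal and noise together, so
    SNRs are preserved.
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n = round(spec.duration_s * sr)
    mix = _background(n, spec.background_kind, spec.background_rms, rng)
    bg_rms = max(mix.std(), 1e-12)
    truth = []
    for ev in spec.events:
        w = make_event_waveform(ev, sr, rng)
        target_rms = bg_rms * 10.0 ** (ev.snr_db / 20.0)
        w = w * (target_rms / max(np.sqrt(np.mean(w**2)), 1e-12))
        i0 = round(ev.start_s * sr)
        mix[i0 : i0 + w.size] += w[: max(0, n - i0)]
        label, pitch = KIND_TO_LABEL[ev.kind]
        tags = frozenset({ev.volume_tag}) if ev.volume_tag else frozenset()
        truth.append(
            LabelEvent(ev.start_s, ev.start_s + ev.duration_s, label, tags, pitch)
        )
    peak = np.abs(mix).max()
    if peak > 0.9:
        mix *= 0.9 / peak
    clip = AudioClip(samples=mix, sample_rate=sr, source_path=f"<scene seed={spec.seed}>")
    truth.sort(key=lambda e: (e.start_s, e.end_s, e.label))
    return SyntheticScene(clip=clip, truth=tuple(truth), spec=spec)


def _sample_duration(kind: str, rng: np.random.Generator) -> float:
    if kind.startswith("buzz"):
        # lognormal around ~1 s: short fly-bys through long foraging bouts
        return float(np.clip(rng.lognormal(mean=0.0, sigma=0.9), 0.15, 12.0))
    if kind == "cricket":
        return float(rng.uniform(2.0, 8.0))
    if kind == "vehicle":
        return float(rng.uniform(4.0, 12.0))
    if kind == "plane":
        return float(rng.uniform(8.0, 20.0))
    return float(rng.uniform(3.0, 8.0))  # siren


def sample_events(
    duration_s: float,
    event_rate_per_min: float,
    rng: np.random.Generator,
    kind_weights: dict[str, float] | None = None,
) -> list[EventSpec]:
    """Poisson event arrivals with uniform placement, truncated to fit.

    Overlapping events are allowed deliberately — they exercise the
    overlap-stratified evaluation.  Buzz SNRs are drawn from the quiet /
    normal / loud levels; interferers get a broad 5–25 dB range.
    """
    weights = kind_weights or DEFAULT_KIND_WEIGHTS
    kinds = sorted(weights)
    probs = np.array([weights[k] for k in kinds])
    probs = probs / probs.sum()
    n_events = rng.poisson(event_rate_per_min * duration_s / 60.0)
    events = []
    for _ in range(n_events):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        dur = min(_sample_duration(kind, rng), duration_s)
        start = float(rng.uniform(0.0, duration_s - dur))
        if kind.startswith("buzz"):
            level = int(rng.choice(len(BUZZ_SNR_LEVELS), p=BUZZ_SNR_PROBS))
            snr, tag = BUZZ_SNR_LEVELS[level]
        else:
            snr, tag = float(rng.uniform(5.0, 25.0)), None
        events.append(
            EventSpec(kind=kind, start_s=start, duration_s=dur, snr_db=snr, volume_tag=tag)
        )
    events.sort(key=lambda e: e.start_s)
    return events


def random_scene_spec(
    scene_seed: int,
    duration_s: float = 300.0,
    event_rate_per_min: float = 2.0,
    sample_rate: int = 16000,
    kind_weights: dict[str, float] | None = None,
) -> SceneSpec:
    """A fully random scene, reproducible from its seed alone."""
    rng = np.random.default_rng(scene_seed)
    events = sample_events(duration_s, event_rate_per_min, rng, kind_weights)
    return SceneSpec(
        duration_s=duration_s,
        seed=scene_seed,
        sample_rate=sample_rate,
        events=tuple(events),
    )


def make_dataset(
    n_train_scenes: int,
    n_test_scenes: int,
    scene_duration_s: float = 300.0,
    event_rate_per_min: float = 2.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[dict]:
    """Generate train/test scene collections with disjoint seed streams.

    Returns a manifest (list of dicts: split, index, seed, path or None,
    n_events).  When ``out_dir`` is given, writes PCM-16 WAVs, label
    tracks, and ``manifest.csv``; byte-identical across runs for a fixed
    seed.
    """
    if n_train_scenes <= 0 or n_test_scenes <= 0:
        raise ValueError("scene counts must be positive")
    root = np.random.SeedSequence(seed)
    train_ss, test_ss = root.spawn(2)
    manifest = []
    specs = []
    for split, ss, count in (("train", train_ss, n_train_scenes), ("test", test_ss, n_test_scenes)):
        for i, child in enumerate(ss.spawn(count)):
            scene_seed = int(child.generate_state(1)[0] % (2**31))
            spec = random_scene_spec(scene_seed, scene_duration_s, event_rate_per_min)
            specs.append((split, i, spec))
            manifest.append(
                {"split": split, "index": i, "seed": scene_seed, "path": None,
                 "labels_path": None, "n_events": len(spec.events)}
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for row, (split, i, spec) in zip(manifest, specs):
            scene = make_scene(spec)
            wav = out_dir / f"{split}_{i:03d}.wav"
            labels = out_dir / f"{split}_{i:03d}.txt"
            write_wav(wav, scene.clip, subtype="pcm16")
            write_label_track(scene.truth, labels)
            row["path"] = str(wav)
            row["labels_path"] = str(labels)
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(manifest[0]))
            writer.writeheader()
            writer.writerows(manifest)
    else:
        for row, (_, _, spec) in zip(manifest, specs):
            row["spec"] = spec
    return manifest
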