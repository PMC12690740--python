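"""Linear multi-label classification head over frame embeddings.

The head maps a D-dimensional embedding to K raw activations (pre-sigmoid
logits), one per vocabulary label.  Labels are treated as independent
binary outcomes — field frames genuinely contain co-occurring events (a
buzz over cricket trills), so a softmax would force a false exclusivity.
Raw activations are unbounded and typically negative for absent events;
the detection threshold is calibrated downstream on these logits.

Training minimises mean per-label binary cross-entropy with an optional L2
penalty by full-batch gradient descent with a fixed, data-derived step —
chosen for bit-reproducibility under a fixed seed rather than for speed.
Features are standardised internally for conditioning; the standardisation
is folded back into the returned weights so that inference is always the
plain affine map ``activation = W^T e + b`` on raw embeddings.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import LabelVocabulary

__all__ = [
    "TrainConfig",
    "ClassifierHead",
    "ActivationRecord",
    "TrainingError",
    "HeadLoadError",
    "train_head",
    "activations",
    "save_head",
    "load_head",
]

SCHEMA_VERSION = 1


class TrainingError(ValueError):
    """Unusable training data (empty, or a label with only one class)."""


class HeadLoadError(ValueError):
    """Corrupt or incompatible head archive."""


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent settings for head training.

    ``learning_rate`` scales the analytically safe step 1/L, where L bounds
    the logistic-loss curvature on the standardised features; at 1.0 the
    loss is guaranteed non-increasing.
    """

    max_epochs: int = 2000
    learning_rate: float = 1.0
    l2_penalty: float = 1e-4
    tol: float = 1e-7
    seed: int = 0
    init_scale: float = 0.01


@dataclass(frozen=True)
class ActivationRecord:
    """Raw activations of all K output neurons for one frame."""

    start_s: float
    activations: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.activations, dtype=np.float64)
        if not np.all(np.isfinite(a)):
            raise ValueError("activations must be finite")
        object.__setattr__(self, "activations", a)


@dataclass(frozen=True)
class ClassifierHead:
    """Affine map from embeddings to per-label logits."""

    weights: np.ndarray  # (D, K)
    bias: np.ndarray  # (K,)
    vocabulary: LabelVocabulary
    provider_id: str
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        b = np.asarray(self.bias, dtype=np.float64)
        if w.ndim != 2 or b.ndim != 1 or w.shape[1] != b.size:
            raise ValueError(f"inconsistent parameter shapes {w.shape} / {b.shape}")
        if b.size != len(self.vocabulary):
            raise ValueError(
                f"bias length {b.size} != vocabulary size {len(self.vocabulary)}"
            )
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
            raise ValueError("head parameters must be finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias", b)

    @property
    def dimension(self) -> int:
        return self.weights.shape[0]


def _bce_loss_and_grad(
    w: np.ndarray, b: np.ndarray, X: np.ndarray, Y: np.ndarray, l2: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean-per-element BCE-with-logits and its gradients."""
    n, _ = X.shape
    k = Y.shape[1]
    z = X @ w + b
    # stable log(1 + e^z) and sigmoid
    loss = np.mean(np.logaddexp(0.0, z) - Y * z) + 0.5 * l2 * np.sum(w * w) / k
    p = 1.0 / (1.0 + np.exp(-z))
    g = (p - Y) / (n * k)
    gw = X.T @ g + l2 * w / k
    gb = g.sum(axis=0)
    return float(loss), gw, gb


def train_head(
    embeddings: np.ndarray,
    frame_labels: Mapping[str, np.ndarray],
    vocabulary: LabelVocabulary | None = None,
    provider_id: str = "builtin-logmel-v1",
    config: TrainConfig = TrainConfig(),
) -> ClassifierHead:
    """Fit the linear head on embeddings and per-frame boolean truth.

    ``frame_labels`` maps each label to be trained to a boolean vector with
    one entry per embedding; every trained label needs at least one positive
    and one negative example.  Labels of the vocabulary absent from
    ``frame_labels`` get zero weights (their activations stay at a large
    negative bias so they never fire).
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise TrainingError(f"embeddings must be a non-empty 2-D array, got shape {X.shape}")
    vocabulary = vocabulary or LabelVocabulary(tuple(frame_labels))
    trained = [lab for lab in vocabulary.labels if lab in frame_labels]
    if not trained:
        raise TrainingError("no vocabulary label present in frame_labels")
    Y = np.column_stack([np.asarray(frame_labels[lab], dtype=bool) for lab in trained]).astype(np.float64)
    if Y.shape[0] != X.shape[0]:
        raise TrainingError(f"{X.shape[0]} embeddings but {Y.shape[0]} label rows")
    for j, lab in enumerate(trained):
        pos = Y[:, j].sum()
        if pos == 0 or pos == Y.shape[0]:
            raise TrainingError(
                f"label {lab!r} has a single class ({int(pos)}/{Y.shape[0]} positive); "
                "training needs both classes"
            )

    # standardise for conditioning; folded back into (w, b) at the end
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma < 1e-12] = 1.0
    Xs = (X - mu) / sigma

    n, d = Xs.shape
    k = Y.shape[1]
    # curvature bound via trace(X^T X / n): L <= mean row-norm^2 / (4k) + l2/k
    lipschitz = 0.25 * float(np.mean((Xs * Xs).sum(axis=1))) / k + config.l2_penalty / k
    step = config.learning_rate / max(lipschitz, 1e-12)

    rng = np.random.default_rng(config.seed)
    w = rng.normal(0.0, config.init_scale, size=(d, k))
    b = np.zeros(k)
    losses = []
    prev = np.inf
    for epoch in range(config.max_epochs):
        loss, gw, gb = _bce_loss_and_grad(w, b, Xs, Y, config.l2_penalty)
        losses.append(loss)
        if prev - loss < config.tol * max(abs(prev), 1.0) and epoch > 0:
            break
        prev = loss
        w -= step * gw
        b -= step * gb

    # fold standardisation into raw-embedding coordinates
    w_raw = w / sigma[:, None]
    b_raw = b - (mu / sigma) @ w

    K = len(vocabulary)
    W_full = np.zeros((d, K))
    b_full = np.full(K, -30.0)  # untrained labels never fire
    for j, lab in enumerate(trained):
        col = vocabulary.index(lab)
        W_full[:, col] = w_raw[:, j]
        b_full[col] = b_raw[j]

    meta = {
        "epochs_run": len(losses),
        "learning_rate": config.learning_rate,
        "l2_penalty": config.l2_penalty,
        "seed": config.seed,
        "final_loss": losses[-1],
        "loss_curve": [float(x) for x in losses[:: max(1, len(losses) // 200)]],
        "trained_labels": trained,
    }
    return ClassifierHead(W_full, b_full, vocabulary, provider_id, meta)


def activations(
    head: ClassifierHead, embeddings: np.ndarray, starts: Sequence[float]
) -> list[ActivationRecord]:
    """Raw logits for each embedding: ``W^T e + b`` per label, order kept."""
    X = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if X.shape[0] == 0:
        return []
    if X.shape[1] != head.dimension:
        raise ValueError(
            f"embedding dimension {X.shape[1]} != head dimension {head.dimension}"
        )
    if X.shape[0] != len(starts):
        raise ValueError(f"{X.shape[0]} embeddings but {len(starts)} start times")
    Z = X @ head.weights + head.bias
    return [ActivationRecord(float(s), z) for s, z in zip(starts, Z)]


def save_head(head: ClassifierHead, path: str | Path) -> None:
    """Serialise a head as a zip archive: JSON header + raw parameter block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "schema_version": SCHEMA_VERSION,
        "provider_id": head.provider_id,
        "labels": list(head.vocabulary.labels),
        "collapse_map": dict(head.vocabulary.collapse_map),
        "dimension": head.dimension,
        "training_meta": head.training_meta,
    }
    buf = io.BytesIO()
    np.save(buf, head.weights, allow_pickle=False)
    wb = buf.getvalue()
    buf = io.BytesIO()
    np.save(buf, head.bias, allow_pickle=False)
    bb = buf.getvalue()
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        zf.writestr("weights.npy", wb)
        zf.writestr("bias.npy", bb)


def load_head(path: str | Path) -> ClassifierHead:
    """Load a head archive; bit-exact inverse of :func:`save_head`."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            weights = np.load(io.BytesIO(zf.read("weights.npy")), allow_pickle=False)
            bias = np.load(io.BytesIO(zf.read("bias.npy")), allow_pickle=False)
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, ValueError) as exc:
        raise HeadLoadError(f"cannot read head archive {path}: {exc}") from exc
    version = header.get("schema_version")
    if version != SCHEMA_VERSION:
        raise HeadLoadError(
            f"head archive {path} has schema version {version}; expected {SCHEMA_VERSION}"
        )
    vocab = LabelVocabulary(tuple(header["labels"]), dict(header.get("collapse_map", {})))
    return ClassifierHead(weights, bias, vocab, header["provider_id"], header.get("training_meta", {}))
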