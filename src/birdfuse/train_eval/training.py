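"""Training loops and the robustness protocol.

Reference hyperparameters: the audio MLP trains with Adam at learning rate
1e-4, batch 16, 75 epochs, and L2 regularization (0.01) on the output
layer; the acoustic LSTM classifier trains with RMSprop at 1e-3, batch 64.
Fusion models default to Adam at 1e-3 for desk-scale convergence (no
optimizer is prescribed for them); everything is overridable through
:class:`TrainConfig`.  All loops are single-threaded NumPy and therefore
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ..audio_features.features import FeatureTable, build_feature_set
from ..audio_features.io import AudioClip, load_wav
from ..audio_features.cepstral import mfcc_block
from ..audio_features.spectral import FrameSpec, spectrogram
from ..cli_io.manifest import DatasetManifest
from ..encoders.backbone import BackboneConfig, preprocess_image
from ..errors import InvalidConfigError, InvalidInputError, SchemaError
from ..feature_selection import SelectionResult
from ..fusion_classify import optimize_alpha, predict_label
from .metrics import MetricsReport, evaluate, label_encode
from .models import (
    AcousticLSTMClassifier,
    AudioMLP,
    EarlyFusionModel,
    LateFusionModel,
    VisualCNNClassifier,
    _Standardizer,
)
from .optim import make_optimizer
from ..encoders.layers import softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "RobustnessConfig",
    "MultimodalArrays",
    "load_multimodal_arrays",
    "multimodal_from_synth",
    "train_audio_mlp",
    "train_acoustic_lstm",
    "train_visual_cnn",
    "train_fusion",
    "robustness_eval",
]

MODEL_KINDS = ("audio_mlp", "acoustic_lstm", "visual_cnn", "early_fusion", "late_fusion")

_DEFAULTS = {
    # model_kind: (optimizer, lr, batch_size, epochs)
    "audio_mlp": ("adam", 1e-4, 16, 75),
    "acoustic_lstm": ("rmsprop", 1e-3, 64, 75),
    "visual_cnn": ("adam", 1e-3, 16, 30),
    "early_fusion": ("adam", 1e-3, 16, 30),
    "late_fusion": ("adam", 1e-3, 16, 30),
}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; ``None`` fields fall back to the
    per-model-kind defaults above."""

    model_kind: str = "audio_mlp"
    optimizer: str | None = None
    learning_rate: float | None = None
    batch_size: int | None = None
    epochs: int | None = None
    l2_output: float = 0.01
    hidden_size: int = 32
    embedding_dim: int = 32
    image_size: int = 32
    backbone_variant: str = "tiny"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise InvalidConfigError(
                f"model_kind must be one of {MODEL_KINDS}, got {self.model_kind!r}"
            )

    def resolved(self) -> "TrainConfig":
        opt, lr, batch, epochs = _DEFAULTS[self.model_kind]
        return replace(
            self,
            optimizer=self.optimizer or opt,
            learning_rate=self.learning_rate if self.learning_rate is not None else lr,
            batch_size=self.batch_size if self.batch_size is not None else batch,
            epochs=self.epochs if self.epochs is not None else epochs,
        )


@dataclass(frozen=True)
class RobustnessConfig:
    """Degradation protocol: white noise injected into the audio at
    ``audio_snr_db`` (inf = none) and/or one modality dropped."""

    audio_snr_db: float = -5.0
    drop_modality: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drop_modality not in ("none", "visual", "acoustic"):
            raise InvalidConfigError(
                f"drop_modality must be none/visual/acoustic, got {self.drop_modality!r}"
            )


@dataclass
class MultimodalArrays:
    """Per-sample aligned arrays assembled from a manifest."""

    images: np.ndarray  # (N, S, S, 3)
    sequences: np.ndarray  # (N, T, F) MFCC frames
    clips: list[AudioClip]
    labels: np.ndarray  # (N,) int
    splits: np.ndarray  # (N,) str
    ids: list[str]
    class_names: tuple[str, ...]
    frame_spec: FrameSpec
    frame_stride: int = 1

    def mask(self, split: str) -> np.ndarray:
        return self.splits == split


def _sequence_from_clip(clip: AudioClip, frame_spec: FrameSpec, stride: int) -> np.ndarray:
    return mfcc_block(spectrogram(clip, frame_spec))[::stride]


def load_multimodal_arrays(
    manifest: DatasetManifest,
    image_size: int = 32,
    frame_spec: FrameSpec | None = None,
    frame_stride: int = 1,
) -> MultimodalArrays:
    """Load and preprocess every manifest row into aligned arrays.

    Raises an :class:`OSError` naming the offending row if a referenced
    file is missing.
    """
    frame_spec = frame_spec or FrameSpec()
    encoding = label_encode([r.species for r in manifest])
    images, seqs, clips, labels, splits, ids = [], [], [], [], [], []
    for row in manifest:
        image_path = manifest.resolve_image(row)
        audio_path = manifest.resolve_audio(row)
        for p in (image_path, audio_path):
            if not p.exists():
                raise OSError(f"manifest row {row.id!r}: file not found: {p}")
        from PIL import Image

        with Image.open(image_path) as im:
            raw = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        images.append(preprocess_image(raw, size=image_size))
        clip = load_wav(audio_path)
        clips.append(clip)
        seqs.append(_sequence_from_clip(clip, frame_spec, frame_stride))
        labels.append(encoding[row.species])
        splits.append(row.split)
        ids.append(row.id)
    min_t = min(s.shape[0] for s in seqs)
    seqs = [s[:min_t] for s in seqs]
    return MultimodalArrays(
        images=np.stack(images),
        sequences=np.stack(seqs),
        clips=clips,
        labels=np.array(labels, dtype=int),
        splits=np.array(splits),
        ids=ids,
        class_names=tuple(sorted(encoding, key=encoding.get)),
        frame_spec=frame_spec,
        frame_stride=frame_stride,
    )


def multimodal_from_synth(
    synth_config,
    specs=None,
    frame_spec: FrameSpec | None = None,
    frame_stride: int = 1,
) -> MultimodalArrays:
    """Render a synthetic dataset directly into aligned in-memory arrays
    (no files), ready for :func:`train_fusion` / :func:`robustness_eval`."""
    from ..synth_data import iter_samples

    frame_spec = frame_spec or FrameSpec()
    images, seqs, clips, labels, splits, ids = [], [], [], [], [], []
    names: list[str] = []
    for sample in iter_samples(synth_config, specs):
        if sample.spec.name not in names:
            names.append(sample.spec.name)
        images.append(sample.image)
        clips.append(sample.clip)
        seqs.append(_sequence_from_clip(sample.clip, frame_spec, frame_stride))
        labels.append(sample.class_index)
        splits.append(sample.split)
        ids.append(f"{sample.spec.name}_{sample.item_index:03d}")
    return MultimodalArrays(
        images=np.stack(images),
        sequences=np.stack(seqs),
        clips=clips,
        labels=np.array(labels, dtype=int),
        splits=np.array(splits),
        ids=ids,
        class_names=tuple(names),
        frame_spec=frame_spec,
        frame_stride=frame_stride,
    )


def _onehot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((labels.size, k))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_audio_mlp(
    features: np.ndarray | Sequence[FeatureTable],
    labels: Sequence[str] | np.ndarray | None = None,
    config: TrainConfig | None = None,
    selection: SelectionResult | None = None,
) -> tuple[AudioMLP, list[float]]:
    """Train the fully connected audio classifier on SET4 vectors.

    ``features`` may be a numeric matrix with string ``labels``, or a list
    of :class:`FeatureTable` (then ``selection`` picks the SET4 columns).
    Returns the model and the per-epoch mean training loss trace.
    """
    config = (config or TrainConfig(model_kind="audio_mlp")).resolved()
    feature_names = None
    is_tables = (
        not isinstance(features, np.ndarray)
        and len(features) > 0
        and isinstance(features[0], FeatureTable)
    )
    if is_tables:
        if selection is None:
            raise InvalidInputError("training from FeatureTables requires a SelectionResult")
        feature_names = tuple(selection.selected)
        X = np.stack([build_feature_set(t, "SET4", selection) for t in features])
        y_names = [t.label for t in features]
    else:
        X = np.asarray(features, dtype=np.float64)
        if labels is None:
            raise InvalidInputError("labels are required with a feature matrix")
        y_names = list(labels)
    if X.ndim != 2:
        raise SchemaError(f"expected a 2-D feature matrix, got shape {X.shape}")
    encoding = label_encode(y_names)
    y = np.array([encoding[n] for n in y_names])
    class_names = tuple(sorted(encoding, key=encoding.get))

    model = AudioMLP(
        n_features=X.shape[1],
        class_names=class_names,
        seed=config.seed,
        feature_names=feature_names,
    )
    model.scaler = _Standardizer.fit(X, axes=0)
    Xs = model.scaler(X)
    Y = _onehot(y, len(class_names))
    opt = make_optimizer(config.optimizer, model.params(), config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    losses = []
    for _ in range(config.epochs):
        epoch_loss, n_batches = 0.0, 0
        for idx in _epoch_batches(X.shape[0], config.batch_size, rng):
            opt.zero_grad()
            logits = model.forward_logits(Xs[idx])
            loss, _, dlogits = softmax_cross_entropy(logits, Y[idx])
            model.backward(dlogits)
            # L2 penalty applies to the output layer only
            if config.l2_output > 0:
                loss += config.l2_output * float((model.out.W.value**2).sum())
                model.out.W.grad += 2.0 * config.l2_output * model.out.W.value
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return model, losses


def train_acoustic_lstm(
    sequences: np.ndarray | Sequence[np.ndarray],
    labels: Sequence[str],
    config: TrainConfig | None = None,
) -> tuple[AcousticLSTMClassifier, list[float]]:
    """Train the LSTM acoustic classifier on MFCC sequences."""
    config = (config or TrainConfig(model_kind="acoustic_lstm")).resolved()
    seqs = np.stack([np.asarray(s, dtype=np.float64) for s in sequences])
    if seqs.ndim != 3 or seqs.shape[0] == 0:
        raise InvalidInputError(f"expected non-empty (N, T, F) sequences, got {seqs.shape}")
    encoding = label_encode(labels)
    y = np.array([encoding[n] for n in labels])
    class_names = tuple(sorted(encoding, key=encoding.get))
    model = AcousticLSTMClassifier(
        input_size=seqs.shape[2],
        class_names=class_names,
        hidden_size=config.hidden_size,
        embedding_dim=config.embedding_dim,
        seed=config.seed,
    )
    model.scaler = _Standardizer.fit(seqs, axes=(0, 1))
    Y = _onehot(y, len(class_names))
    opt = make_optimizer(config.optimizer, model.params(), config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    losses = []
    for _ in range(config.epochs):
        epoch_loss, n_batches = 0.0, 0
        for idx in _epoch_batches(seqs.shape[0], config.batch_size, rng):
            opt.zero_grad()
            logits = model.forward_logits(seqs[idx])
            loss, _, dlogits = softmax_cross_entropy(logits, Y[idx])
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return model, losses


def _train_visual(
    images: np.ndarray, y: np.ndarray, class_names, config: TrainConfig
) -> VisualCNNClassifier:
    model = VisualCNNClassifier(
        class_names=class_names,
        backbone_config=BackboneConfig(
            variant=config.backbone_variant,
            embedding_dim=config.embedding_dim
            if config.backbone_variant == "tiny"
            else 2048,
        ),
        seed=config.seed,
    )
    Y = _onehot(y, len(class_names))
    opt = make_optimizer(config.optimizer, model.params(), config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    for _ in range(config.epochs):
        for idx in _epoch_batches(images.shape[0], config.batch_size, rng):
            opt.zero_grad()
            logits = model.forward_logits(images[idx])
            _, _, dlogits = softmax_cross_entropy(logits, Y[idx])
            model.backward(dlogits)
            opt.step()
    return model


def train_visual_cnn(
    images: np.ndarray,
    labels: Sequence[str],
    config: TrainConfig | None = None,
) -> VisualCNNClassifier:
    """Train the standalone visual classifier (tiny backbone by default)."""
    config = (config or TrainConfig(model_kind="visual_cnn")).resolved()
    encoding = label_encode(labels)
    y = np.array([encoding[n] for n in labels])
    class_names = tuple(sorted(encoding, key=encoding.get))
    return _train_visual(np.asarray(images, dtype=np.float64), y, class_names, config)


def train_fusion(
    data: MultimodalArrays,
    mode: str = "early",
    config: TrainConfig | None = None,
):
    """Train a fusion model on the train split of ``data``.

    ``early`` jointly optimizes the tiny visual backbone, the LSTM acoustic
    encoder and the classification head on concatenated embeddings.
    ``late`` trains the two unimodal classifiers independently and then
    grid-searches the fusion weight alpha on the validation split.
    """
    if mode not in ("early", "late"):
        raise InvalidConfigError(f"fusion mode must be 'early' or 'late', got {mode!r}")
    config = (config or TrainConfig(model_kind=f"{mode}_fusion")).resolved()
    train = data.mask("train")
    if not np.any(train):
        raise InvalidInputError("manifest has no train split")
    images, seqs = data.images[train], data.sequences[train]
    y = data.labels[train]
    Y = _onehot(y, len(data.class_names))

    if mode == "early":
        model = EarlyFusionModel(
            input_size=seqs.shape[2],
            class_names=data.class_names,
            backbone_config=BackboneConfig(
                variant=config.backbone_variant, embedding_dim=config.embedding_dim
            ),
            hidden_size=config.hidden_size,
            acoustic_dim=config.embedding_dim,
            seed=config.seed,
        )
        model.scaler = _Standardizer.fit(seqs, axes=(0, 1))
        opt = make_optimizer(config.optimizer, model.params(), config.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
        for _ in range(config.epochs):
            for idx in _epoch_batches(images.shape[0], config.batch_size, rng):
                opt.zero_grad()
                logits = model.forward_logits(images[idx], seqs[idx])
                _, _, dlogits = softmax_cross_entropy(logits, Y[idx])
                model.backward(dlogits)
                opt.step()
        return model

    visual = _train_visual(images, y, data.class_names, config)
    # acoustic branch keeps its reference optimizer (RMSprop @ 1e-3) but
    # inherits the fusion config's batch size and epoch budget
    acoustic, _ = train_acoustic_lstm(
        seqs, [data.class_names[i] for i in y],
        replace(config, model_kind="acoustic_lstm", optimizer=None,
                learning_rate=None).resolved(),
    )
    val = data.mask("val")
    if not np.any(val):  # fall back to train split for the alpha search
        val = train
    alpha = optimize_alpha(
        visual.predict_proba(data.images[val]),
        acoustic.predict_proba(data.sequences[val]),
        data.labels[val],
    )
    return LateFusionModel(visual=visual, acoustic=acoustic, alpha=alpha)


def _degrade_clips(
    clips: list[AudioClip], snr_db: float, seed: int
) -> list[AudioClip]:
    out = []
    for i, clip in enumerate(clips):
        if not np.isfinite(snr_db):
            out.append(clip)
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, 41, i]))
        rms = np.sqrt(np.mean(clip.samples**2))
        noise = rng.normal(0.0, rms / 10.0 ** (snr_db / 20.0), len(clip))
        x = clip.samples + noise
        peak = np.max(np.abs(x))
        if peak > 1.0:
            x = x / peak
        out.append(AudioClip(samples=x, sample_rate=clip.sample_rate))
    return out


def robustness_eval(
    model,
    data: MultimodalArrays,
    rc: RobustnessConfig,
    split: str = "test",
) -> tuple[MetricsReport, MetricsReport]:
    """Evaluate ``model`` on clean vs. degraded inputs of the same split.

    Degradation adds seeded white noise to the audio at ``rc.audio_snr_db``
    and/or drops one modality: for early fusion the dropped embedding slice
    is zero-filled; for late fusion dropping visual forces alpha to 0
    (acoustic-only) and dropping acoustic forces alpha to 1.
    """
    mask = data.mask(split)
    if not np.any(mask):
        raise InvalidInputError(f"no rows in split {split!r}")
    labels = data.labels[mask]
    images = data.images[mask]
    seqs = data.sequences[mask]
    k = len(data.class_names)

    if isinstance(model, (VisualCNNClassifier,)) and rc.drop_modality == "visual":
        raise InvalidConfigError("cannot drop the only modality of a visual model")
    if isinstance(model, (AcousticLSTMClassifier, AudioMLP)) and rc.drop_modality == "acoustic":
        raise InvalidConfigError("cannot drop the only modality of an acoustic model")

    def predict(imgs, sqs, drop: str) -> np.ndarray:
        if isinstance(model, EarlyFusionModel):
            probs = model.predict_proba(
                imgs, sqs, drop_visual=drop == "visual", drop_acoustic=drop == "acoustic"
            )
        elif isinstance(model, LateFusionModel):
            override = {"none": None, "visual": 0.0, "acoustic": 1.0}[drop]
            probs = model.predict_proba(imgs, sqs, alpha_override=override)
        elif isinstance(model, VisualCNNClassifier):
            probs = model.predict_proba(imgs)
        elif isinstance(model, AcousticLSTMClassifier):
            probs = model.predict_proba(sqs)
        else:
            raise InvalidConfigError(f"unsupported model type {type(model).__name__}")
        return predict_label(probs)

    clean = evaluate(predict(images, seqs, "none"), labels, k, data.class_names)

    clean_clips = [c for c, m in zip(data.clips, mask) if m]
    noisy_clips = _degrade_clips(clean_clips, rc.audio_snr_db, rc.seed)
    if noisy_clips is clean_clips or all(a is b for a, b in zip(noisy_clips, clean_clips)):
        noisy_seqs = seqs
    else:
        t = data.sequences.shape[1]
        noisy_seqs = np.stack(
            [
                _sequence_from_clip(c, data.frame_spec, data.frame_stride)[:t]
                for c in noisy_clips
            ]
        )
    degraded = evaluate(
        predict(images, noisy_seqs, rc.drop_modality), labels, k, data.class_names
    )
    return clean, degraded
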