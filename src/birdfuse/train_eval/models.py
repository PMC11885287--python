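"""Trainable model classes: audio MLP, acoustic LSTM classifier, fusion models.

Every model knows its class-name ordering, exposes ``predict_proba`` and a
flat ``state()`` of named arrays plus JSON-safe metadata for the model
archive.  Prediction is deterministic given weights.
"""

from __future__ import annotations

import numpy as np

from ..encoders.backbone import BackboneConfig, VisualBackbone
from ..encoders.layers import Dense, Param, Sequential
from ..encoders.recurrent import LSTMEncoder
from ..errors import InvalidConfigError, SchemaError, ShapeError
from ..fusion_classify import late_fuse, softmax

__all__ = [
    "AudioMLP",
    "AcousticLSTMClassifier",
    "VisualCNNClassifier",
    "EarlyFusionModel",
    "LateFusionModel",
]

_PREDICT_BATCH = 64


class _Standardizer:
    """Feature z-scoring fitted on training data (sigma floored at 1e-8)."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = mean
        self.std = np.maximum(std, 1e-8)

    @classmethod
    def fit(cls, x: np.ndarray, axes) -> "_Standardizer":
        return cls(np.asarray(x).mean(axis=axes), np.asarray(x).std(axis=axes))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


class AudioMLP:
    """21 -> 256 -> 128 -> 32 -> K fully connected softmax classifier."""

    kind = "audio_mlp"

    def __init__(
        self,
        n_features: int,
        class_names: tuple[str, ...],
        seed: int = 0,
        hidden: tuple[int, ...] = (256, 128, 32),
        feature_names: tuple[str, ...] | None = None,
    ):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        sizes = (n_features, *hidden)
        layers = [
            Dense(sizes[i], sizes[i + 1], activation="relu", rng=rng)
            for i in range(len(hidden))
        ]
        self.net = Sequential(*layers)
        self.out = Dense(sizes[-1], len(class_names), rng=rng)
        self.class_names = tuple(class_names)
        self.feature_names = tuple(feature_names) if feature_names else None
        self.scaler = _Standardizer(np.zeros(n_features), np.ones(n_features))

    @property
    def n_features(self) -> int:
        return self.net.layers[0].W.value.shape[0]

    def params(self) -> list[Param]:
        return self.net.params() + self.out.params()

    def named_params(self) -> dict[str, Param]:
        out = self.net.named_params("net.")
        out.update(self.out.named_params("out."))
        return out

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.out.forward(self.net.forward(x))

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(self.out.backward(dlogits))

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if x.shape[1] != self.n_features:
            raise SchemaError(
                f"model expects {self.n_features} features, got {x.shape[1]}"
            )
        return softmax(self.forward_logits(self.scaler(x)))

    def state(self) -> tuple[dict[str, np.ndarray], dict]:
        arrays = {k: p.value for k, p in self.named_params().items()}
        arrays["scaler.mean"] = self.scaler.mean
        arrays["scaler.std"] = self.scaler.std
        meta = {
            "class_names": list(self.class_names),
            "n_features": self.n_features,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "hidden": [l.W.value.shape[1] for l in self.net.layers],
        }
        return arrays, meta

    @classmethod
    def from_state(cls, arrays: dict[str, np.ndarray], meta: dict) -> "AudioMLP":
        model = cls(
            n_features=int(meta["n_features"]),
            class_names=tuple(meta["class_names"]),
            hidden=tuple(meta["hidden"]),
            feature_names=tuple(meta["feature_names"]) if meta.get("feature_names") else None,
        )
        for k, p in model.named_params().items():
            p.value[...] = arrays[k]
        model.scaler = _Standardizer(arrays["scaler.mean"], arrays["scaler.std"])
        return model


class AcousticLSTMClassifier:
    """LSTM over MFCC sequences -> dense embedding head -> softmax classifier."""

    kind = "acoustic_lstm"

    def __init__(
        self,
        input_size: int,
        class_names: tuple[str, ...],
        hidden_size: int = 32,
        embedding_dim: int = 32,
        seed: int = 0,
    ):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
        self.encoder = LSTMEncoder(input_size, hidden_size, rng)
        self.embed_head = Dense(hidden_size, embedding_dim, rng=rng)
        self.clf = Dense(embedding_dim, len(class_names), rng=rng)
        self.class_names = tuple(class_names)
        self.scaler = _Standardizer(np.zeros(input_size), np.ones(input_size))

    @property
    def embedding_dim(self) -> int:
        return self.embed_head.W.value.shape[1]

    def params(self) -> list[Param]:
        return self.encoder.params() + self.embed_head.params() + self.clf.params()

    def named_params(self) -> dict[str, Param]:
        out = self.encoder.named_params("enc.")
        out.update(self.embed_head.named_params("embed."))
        out.update(self.clf.named_params("clf."))
        return out

    def embed(self, sequences: np.ndarray) -> np.ndarray:
        """(N, T, F) -> (N, embedding_dim)."""
        return self.embed_head.forward(self.encoder.forward(self.scaler(sequences)))

    def forward_logits(self, sequences: np.ndarray) -> np.ndarray:
        return self.clf.forward(self.embed(sequences))

    def backward(self, dlogits: np.ndarray) -> None:
        self.encoder.backward(self.embed_head.backward(self.clf.backward(dlogits)))

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        seqs = np.asarray(sequences, dtype=np.float64)
        if seqs.ndim == 2:
            seqs = seqs[None]
        probs = [
            softmax(self.forward_logits(seqs[i : i + _PREDICT_BATCH]))
            for i in range(0, seqs.shape[0], _PREDICT_BATCH)
        ]
        return np.concatenate(probs, axis=0)

    def state(self) -> tuple[dict[str, np.ndarray], dict]:
        arrays = {k: p.value for k, p in self.named_params().items()}
        arrays["scaler.mean"] = self.scaler.mean
        arrays["scaler.std"] = self.scaler.std
        meta = {
            "class_names": list(self.class_names),
            "input_size": self.encoder.cell.input_size,
            "hidden_size": self.encoder.cell.hidden_size,
            "embedding_dim": self.embedding_dim,
        }
        return arrays, meta

    @classmethod
    def from_state(cls, arrays, meta) -> "AcousticLSTMClassifier":
        model = cls(
            input_size=int(meta["input_size"]),
            class_names=tuple(meta["class_names"]),
            hidden_size=int(meta["hidden_size"]),
            embedding_dim=int(meta["embedding_dim"]),
        )
        for k, p in model.named_params().items():
            p.value[...] = arrays[k]
        model.scaler = _Standardizer(arrays["scaler.mean"], arrays["scaler.std"])
        return model


class VisualCNNClassifier:
    """Visual backbone plus softmax head."""

    kind = "visual_cnn"

    def __init__(
        self,
        class_names: tuple[str, ...],
        backbone_config: BackboneConfig | None = None,
        seed: int = 0,
    ):
        self.backbone_config = backbone_config or BackboneConfig()
        self.backbone = VisualBackbone(self.backbone_config, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        self.clf = Dense(self.backbone.embedding_dim, len(class_names), rng=rng)
        self.class_names = tuple(class_names)

    def params(self) -> list[Param]:
        return self.backbone.params() + self.clf.params()

    def named_params(self) -> dict[str, Param]:
        out = self.backbone.named_params("bb.")
        out.update(self.clf.named_params("clf."))
        return out

    def forward_logits(self, images: np.ndarray) -> np.ndarray:
        return self.clf.forward(self.backbone.forward(images))

    def backward(self, dlogits: np.ndarray) -> None:
        self.backbone.backward(self.clf.backward(dlogits))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        imgs = np.asarray(images, dtype=np.float64)
        if imgs.ndim == 3:
            imgs = imgs[None]
        probs = [
            softmax(self.forward_logits(imgs[i : i + _PREDICT_BATCH]))
            for i in range(0, imgs.shape[0], _PREDICT_BATCH)
        ]
        return np.concatenate(probs, axis=0)

    def state(self) -> tuple[dict[str, np.ndarray], dict]:
        arrays = {k: p.value for k, p in self.named_params().items()}
        meta = {
            "class_names": list(self.class_names),
            "variant": self.backbone_config.variant,
            "embedding_dim": self.backbone_config.embedding_dim,
        }
        return arrays, meta

    @classmethod
    def from_state(cls, arrays, meta) -> "VisualCNNClassifier":
        model = cls(
            class_names=tuple(meta["class_names"]),
            backbone_config=BackboneConfig(
                variant=meta["variant"], embedding_dim=int(meta["embedding_dim"])
            ),
        )
        for k, p in model.named_params().items():
            p.value[...] = arrays[k]
        return model


class EarlyFusionModel:
    """Jointly trained ``classify(concat(visual_embed, acoustic_embed))``.

    The visual slice can be zero-filled at prediction time to emulate a
    missing visual modality.
    """

    kind = "early_fusion"

    def __init__(
        self,
        input_size: int,
        class_names: tuple[str, ...],
        backbone_config: BackboneConfig | None = None,
        hidden_size: int = 32,
        acoustic_dim: int = 32,
        seed: int = 0,
    ):
        self.backbone_config = backbone_config or BackboneConfig()
        self.backbone = VisualBackbone(self.backbone_config, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
        self.encoder = LSTMEncoder(input_size, hidden_size, rng)
        self.embed_head = Dense(hidden_size, acoustic_dim, rng=rng)
        self.head = Dense(self.backbone.embedding_dim + acoustic_dim, len(class_names), rng=rng)
        self.class_names = tuple(class_names)
        self.scaler = _Standardizer(np.zeros(input_size), np.ones(input_size))

    @property
    def visual_dim(self) -> int:
        return self.backbone.embedding_dim

    @property
    def acoustic_dim(self) -> int:
        return self.embed_head.W.value.shape[1]

    @property
    def fused_dim(self) -> int:
        return self.visual_dim + self.acoustic_dim

    def params(self) -> list[Param]:
        return (
            self.backbone.params()
            + self.encoder.params()
            + self.embed_head.params()
            + self.head.params()
        )

    def named_params(self) -> dict[str, Param]:
        out = self.backbone.named_params("bb.")
        out.update(self.encoder.named_params("enc."))
        out.update(self.embed_head.named_params("embed."))
        out.update(self.head.named_params("head."))
        return out

    def forward_logits(
        self,
        images: np.ndarray,
        sequences: np.ndarray,
        drop_visual: bool = False,
        drop_acoustic: bool = False,
    ) -> np.ndarray:
        v = self.backbone.forward(images)
        a = self.embed_head.forward(self.encoder.forward(self.scaler(sequences)))
        if drop_visual:
            v = np.zeros_like(v)
        if drop_acoustic:
            a = np.zeros_like(a)
        fused = np.concatenate([v, a], axis=1)
        return self.head.forward(fused)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        self.backbone.backward(dfused[:, : self.visual_dim])
        self.encoder.backward(self.embed_head.backward(dfused[:, self.visual_dim :]))

    def predict_proba(
        self,
        images: np.ndarray,
        sequences: np.ndarray,
        drop_visual: bool = False,
        drop_acoustic: bool = False,
    ) -> np.ndarray:
        imgs = np.asarray(images, dtype=np.float64)
        seqs = np.asarray(sequences, dtype=np.float64)
        if imgs.ndim == 3:
            imgs, seqs = imgs[None], seqs[None]
        if imgs.shape[0] != seqs.shape[0]:
            raise ShapeError(
                f"{imgs.shape[0]} images but {seqs.shape[0]} audio sequences"
            )
        out = []
        for i in range(0, imgs.shape[0], _PREDICT_BATCH):
            logits = self.forward_logits(
                imgs[i : i + _PREDICT_BATCH],
                seqs[i : i + _PREDICT_BATCH],
                drop_visual=drop_visual,
                drop_acoustic=drop_acoustic,
            )
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def state(self) -> tuple[dict[str, np.ndarray], dict]:
        arrays = {k: p.value for k, p in self.named_params().items()}
        arrays["scaler.mean"] = self.scaler.mean
        arrays["scaler.std"] = self.scaler.std
        meta = {
            "class_names": list(self.class_names),
            "variant": self.backbone_config.variant,
            "embedding_dim": self.backbone_config.embedding_dim,
            "input_size": self.encoder.cell.input_size,
            "hidden_size": self.encoder.cell.hidden_size,
            "acoustic_dim": self.acoustic_dim,
        }
        return arrays, meta

    @classmethod
    def from_state(cls, arrays, meta) -> "EarlyFusionModel":
        model = cls(
            input_size=int(meta["input_size"]),
            class_names=tuple(meta["class_names"]),
            backbone_config=BackboneConfig(
                variant=meta["variant"], embedding_dim=int(meta["embedding_dim"])
            ),
            hidden_size=int(meta["hidden_size"]),
            acoustic_dim=int(meta["acoustic_dim"]),
        )
        for k, p in model.named_params().items():
            p.value[...] = arrays[k]
        model.scaler = _Standardizer(arrays["scaler.mean"], arrays["scaler.std"])
        return model


class LateFusionModel:
    """Independently trained per-modality classifiers blended by alpha."""

    kind = "late_fusion"

    def __init__(
        self,
        visual: VisualCNNClassifier,
        acoustic: AcousticLSTMClassifier,
        alpha: float,
    ):
        if visual.class_names != acoustic.class_names:
            raise InvalidConfigError("late-fusion branches disagree on class names")
        if not (0.0 <= alpha <= 1.0):
            raise InvalidConfigError(f"alpha must be in [0, 1], got {alpha}")
        self.visual = visual
        self.acoustic = acoustic
        self.alpha = float(alpha)
        self.class_names = visual.class_names

    def predict_proba(
        self,
        images: np.ndarray,
        sequences: np.ndarray,
        alpha_override: float | None = None,
    ) -> np.ndarray:
        alpha = self.alpha if alpha_override is None else alpha_override
        return late_fuse(
            self.visual.predict_proba(images),
            self.acoustic.predict_proba(sequences),
            alpha,
        )

    def state(self) -> tuple[dict[str, np.ndarray], dict]:
        v_arrays, v_meta = self.visual.state()
        a_arrays, a_meta = self.acoustic.state()
        arrays = {f"visual.{k}": v for k, v in v_arrays.items()}
        arrays.update({f"acoustic.{k}": v for k, v in a_arrays.items()})
        meta = {"alpha": self.alpha, "visual": v_meta, "acoustic": a_meta,
                "class_names": list(self.class_names)}
        return arrays, meta

    @classmethod
    def from_state(cls, arrays, meta) -> "LateFusionModel":
        v_arrays = {k[len("visual."):]: v for k, v in arrays.items() if k.startswith("visual.")}
        a_arrays = {k[len("acoustic."):]: v for k, v in arrays.items() if k.startswith("acoustic.")}
        return cls(
            visual=VisualCNNClassifier.from_state(v_arrays, meta["visual"]),
            acoustic=AcousticLSTMClassifier.from_state(a_arrays, meta["acoustic"]),
            alpha=float(meta["alpha"]),
        )


MODEL_CLASSES = {
    cls.kind: cls
    for cls in (AudioMLP, AcousticLSTMClassifier, VisualCNNClassifier,
                EarlyFusionModel, LateFusionModel)
}
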