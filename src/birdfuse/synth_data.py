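"""Seeded synthetic multimodal datasets: class-structured calls, images, manifest.

Each species is defined by a harmonic-chirp call signature (fundamental,
linear FM slope, syllable pattern) and a visual signature (body hue and
ellipse aspect).  Calls are 3-harmonic linear-FM syllable trains in white
noise at a configurable SNR; images are a colored elliptical "body" with
jittered pose on a noisy gray background.  Everything is a pure function of
its seed, so regeneration is byte-identical.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
from PIL import Image

from .audio_features.io import AudioClip, save_wav
from .cli_io.manifest import DatasetManifest, ManifestRow, write_manifest
from .errors import InvalidConfigError

__all__ = [
    "SpeciesSpec",
    "SynthConfig",
    "make_species_specs",
    "make_complementary_specs",
    "render_call",
    "render_image",
    "split_counts",
    "iter_samples",
    "generate_dataset",
]

F0_RANGE = (500.0, 4000.0)  # Hz, log-spaced across classes


@dataclass(frozen=True)
class SpeciesSpec:
    """Per-class call and appearance signature."""

    name: str
    f0: float  # fundamental of call syllables, Hz
    chirp_rate: float  # linear FM slope, Hz/s
    n_syllables: int
    syllable_dur: float  # seconds
    hue: float  # degrees in [0, 360)
    body_aspect: float  # ellipse major/minor ratio

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise InvalidConfigError(f"{self.name}: f0 must be > 0, got {self.f0}")
        if self.n_syllables < 1 or self.syllable_dur <= 0:
            raise InvalidConfigError(f"{self.name}: invalid syllable pattern")
        if not (0.0 <= self.hue < 360.0):
            raise InvalidConfigError(f"{self.name}: hue must be in [0, 360)")

    @property
    def f0_max(self) -> float:
        """Largest instantaneous fundamental over one syllable."""
        return max(self.f0, self.f0 + self.chirp_rate * self.syllable_dur)


@dataclass(frozen=True)
class SynthConfig:
    n_classes: int = 8
    n_per_class: int = 20
    sample_rate: int = 22050
    clip_seconds: float = 5.0
    image_size: int = 224
    snr_db: float = 20.0
    class_separation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise InvalidConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_per_class < 1:
            raise InvalidConfigError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.image_size < 32:
            raise InvalidConfigError(f"image_size must be >= 32, got {self.image_size}")
        if not (0.0 <= self.class_separation <= 1.0):
            raise InvalidConfigError("class_separation must be in [0, 1]")
        n = self.clip_seconds * self.sample_rate
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise InvalidConfigError(
                f"clip_seconds * sample_rate must be a positive integer, got {n}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.clip_seconds * self.sample_rate))


def _subseed(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def make_species_specs(
    n_classes: int, class_separation: float, seed: int
) -> list[SpeciesSpec]:
    """Deterministic class signatures.

    Fundamentals are log-spaced over 500-4000 Hz, then multiplicatively
    jittered with amplitude proportional to ``1 - class_separation``; hues
    are evenly spaced on the color circle.
    """
    if n_classes < 2:
        raise InvalidConfigError(f"n_classes must be >= 2, got {n_classes}")
    if not (0.0 <= class_separation <= 1.0):
        raise InvalidConfigError("class_separation must be in [0, 1]")
    rng = _subseed(seed, 101)
    base_f0 = np.geomspace(F0_RANGE[0], F0_RANGE[1], n_classes)
    jitter = np.exp(rng.uniform(-1.0, 1.0, n_classes) * 0.25 * (1.0 - class_separation))
    f0 = base_f0 * jitter
    specs = []
    for i in range(n_classes):
        syllable_dur = 0.2 + 0.05 * (i % 3)
        specs.append(
            SpeciesSpec(
                name=f"species{i:02d}",
                f0=float(f0[i]),
                chirp_rate=float(((-1) ** i) * 0.6 * f0[i]),
                n_syllables=3 + (i % 3),
                syllable_dur=syllable_dur,
                hue=360.0 * i / n_classes,
                body_aspect=1.0 + 1.5 * i / max(n_classes - 1, 1),
            )
        )
    return specs


def make_complementary_specs() -> list[SpeciesSpec]:
    """Four species carrying complementary class information.

    Species 0/1 share the visual signature and 2/3 share another, while
    0/2 share the call fundamental and 1/3 share another: images alone or
    calls alone can each separate only one of the two class pairings, but
    together they identify all four classes.
    """
    visual = [(30.0, 1.4), (30.0, 1.4), (210.0, 2.2), (210.0, 2.2)]
    f0s = [900.0, 1800.0, 900.0, 1800.0]
    return [
        SpeciesSpec(
            name=f"species{i:02d}",
            f0=f0s[i],
            chirp_rate=0.4 * f0s[i],
            n_syllables=4,
            syllable_dur=0.2,
            hue=visual[i][0],
            body_aspect=visual[i][1],
        )
        for i in range(4)
    ]


def render_call(spec: SpeciesSpec, config: SynthConfig, seed: int) -> AudioClip:
    """Synthesize one call clip: FM harmonic-stack syllables in white noise.

    Each syllable is a linear chirp from ``spec.f0`` with harmonics 1-3 at
    amplitudes 1, 1/2, 1/3 under a Hann envelope; harmonics whose peak
    instantaneous frequency would exceed 98% of Nyquist are omitted to
    avoid aliasing.  White Gaussian noise is added at ``config.snr_db``
    relative to whole-clip signal RMS (``snr_db = inf`` disables it), and
    the waveform is peak-normalized to 0.9.
    """
    nyquist = config.sample_rate / 2.0
    if spec.f0_max > 0.98 * nyquist:
        raise InvalidConfigError(
            f"{spec.name}: fundamental sweep up to {spec.f0_max:.0f} Hz exceeds "
            f"the usable band below Nyquist ({nyquist:.0f} Hz)"
        )
    total_syllable = spec.n_syllables * spec.syllable_dur
    if total_syllable >= config.clip_seconds:
        raise InvalidConfigError(
            f"{spec.name}: {spec.n_syllables} syllables of {spec.syllable_dur} s "
            f"do not fit in a {config.clip_seconds} s clip"
        )
    rng = np.random.default_rng(seed)
    n = config.n_samples
    x = np.zeros(n)
    n_syl = int(round(spec.syllable_dur * config.sample_rate))
    t = np.arange(n_syl) / config.sample_rate
    phase = 2.0 * np.pi * (spec.f0 * t + 0.5 * spec.chirp_rate * t**2)
    envelope = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n_syl) / max(n_syl - 1, 1))
    syllable = np.zeros(n_syl)
    for k in (1, 2, 3):
        if k * spec.f0_max <= 0.98 * nyquist:
            syllable += np.sin(k * phase) / k
    syllable *= envelope

    gap = (config.clip_seconds - total_syllable) / (spec.n_syllables + 1)
    for i in range(spec.n_syllables):
        onset = gap * (i + 1) + spec.syllable_dur * i
        onset += rng.uniform(-0.3, 0.3) * gap
        start = int(round(onset * config.sample_rate))
        start = min(max(start, 0), n - n_syl)
        x[start : start + n_syl] += syllable

    if np.isfinite(config.snr_db):
        rms = np.sqrt(np.mean(x**2))
        noise_std = rms / 10.0 ** (config.snr_db / 20.0)
        x = x + rng.normal(0.0, noise_std, n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return AudioClip(samples=x, sample_rate=config.sample_rate)


def _hue_to_rgb(hue_deg: float, saturation: float = 0.85, value: float = 0.75):
    return np.array(colorsys.hsv_to_rgb(hue_deg / 360.0, saturation, value))


def render_image(
    spec: SpeciesSpec, config: SynthConfig, seed: int, return_mask: bool = False
):
    """Render one class image: hue-colored ellipse body on a noisy gray field.

    Returns an ``image_size x image_size x 3`` float array in ``[0, 1]``
    (plus the boolean body mask when ``return_mask``).  Pixel noise is
    Gaussian with standard deviation ``0.12 * (1 - class_separation)``,
    clipped back into range, so full separation renders noise-free.
    """
    rng = np.random.default_rng(seed)
    size = config.image_size
    img = np.full((size, size, 3), 0.45)

    cx = size / 2.0 + rng.uniform(-0.1, 0.1) * size
    cy = size / 2.0 + rng.uniform(-0.1, 0.1) * size
    angle = rng.uniform(-np.pi / 6.0, np.pi / 6.0)
    a = 0.28 * size * np.sqrt(spec.body_aspect)
    b = 0.28 * size / np.sqrt(spec.body_aspect)
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    v = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[mask] = _hue_to_rgb(spec.hue)

    sigma = 0.12 * (1.0 - config.class_separation)
    if sigma > 0:
        img = img + rng.normal(0.0, sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    if return_mask:
        return img, mask
    return img


def split_counts(n: int) -> tuple[int, int, int]:
    """70/15/15 counts for one class; remainders go to train."""
    n_val = int(0.15 * n)
    n_test = int(0.15 * n)
    return n - n_val - n_test, n_val, n_test


class Sample(NamedTuple):
    class_index: int
    item_index: int
    spec: SpeciesSpec
    image: np.ndarray
    clip: AudioClip
    split: str


def iter_samples(
    config: SynthConfig, specs: list[SpeciesSpec] | None = None
) -> Iterator[Sample]:
    """Generate every dataset sample in memory, in manifest order.

    ``specs`` overrides the default class signatures (e.g. the complementary
    set); its length must match ``config.n_classes``.
    """
    if specs is None:
        specs = make_species_specs(config.n_classes, config.class_separation, config.seed)
    if len(specs) != config.n_classes:
        raise InvalidConfigError(
            f"{len(specs)} species specs for n_classes={config.n_classes}"
        )
    n_train, n_val, n_test = split_counts(config.n_per_class)
    for ci, spec in enumerate(specs):
        order = _subseed(config.seed, ci, 2).permutation(config.n_per_class)
        split_of = {}
        for pos, j in enumerate(order):
            split_of[int(j)] = (
                "train" if pos < n_train else "val" if pos < n_train + n_val else "test"
            )
        for j in range(config.n_per_class):
            audio_seed = _subseed(config.seed, ci, j, 0).integers(0, 2**32)
            image_seed = _subseed(config.seed, ci, j, 1).integers(0, 2**32)
            yield Sample(
                class_index=ci,
                item_index=j,
                spec=spec,
                image=render_image(spec, config, int(image_seed)),
                clip=render_call(spec, config, int(audio_seed)),
                split=split_of[j],
            )


def generate_dataset(
    config: SynthConfig,
    out_dir: str | Path,
    specs: list[SpeciesSpec] | None = None,
) -> DatasetManifest:
    """Write WAVs, PNGs and ``manifest.csv`` under ``out_dir``.

    The split is stratified per class: a seeded shuffle followed by a
    contiguous 70/15/15 cut (remainders to train).  Same config and seed
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        (out_dir / "audio").mkdir(parents=True, exist_ok=True)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    rows = []
    for sample in iter_samples(config, specs):
        stem = f"{sample.spec.name}_{sample.item_index:03d}"
        audio_rel = f"audio/{stem}.wav"
        image_rel = f"images/{stem}.png"
        save_wav(sample.clip, out_dir / audio_rel)
        pixels = np.clip(np.rint(sample.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(pixels, mode="RGB").save(out_dir / image_rel)
        rows.append(
            ManifestRow(
                id=stem,
                species=sample.spec.name,
                image_path=image_rel,
                audio_path=audio_rel,
                split=sample.split,
            )
        )
    manifest = DatasetManifest(rows=tuple(rows), root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
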