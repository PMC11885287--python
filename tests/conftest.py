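"""Shared fixtures: small seeded synthetic configs, clips and datasets."""

from __future__ import annotations

import numpy as np
import pytest

from birdfuse.audio_features import AudioClip, FrameSpec
from birdfuse.synth_data import (
    SpeciesSpec,
    SynthConfig,
    generate_dataset,
    make_species_specs,
    render_call,
)

# desk-scale defaults shared by most tests: 16 kHz, 2 s clips, 32 px images
TEST_SR = 16000
TEST_FRAMES = FrameSpec(frame_length=512, hop=256)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        n_classes=3,
        n_per_class=4,
        sample_rate=TEST_SR,
        clip_seconds=2.0,
        image_size=32,
        snr_db=20.0,
        class_separation=0.9,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_specs(small_config) -> list[SpeciesSpec]:
    return make_species_specs(
        small_config.n_classes, small_config.class_separation, small_config.seed
    )


@pytest.fixture(scope="session")
def call_clip(small_specs, small_config) -> AudioClip:
    return render_call(small_specs[0], small_config, seed=7)


@pytest.fixture(scope="session")
def noisy_clip() -> AudioClip:
    rng = np.random.default_rng(42)
    return AudioClip(rng.normal(0.0, 0.1, TEST_SR * 2), TEST_SR)


@pytest.fixture(scope="session")
def tone_clip() -> AudioClip:
    t = np.arange(TEST_SR * 2) / TEST_SR
    return AudioClip(0.5 * np.sin(2 * np.pi * 1000.0 * t), TEST_SR)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_config):
    """A generated on-disk dataset shared by I/O-level tests."""
    out = tmp_path_factory.mktemp("synthset")
    manifest = generate_dataset(small_config, out)
    return out, manifest
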