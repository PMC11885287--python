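"""Audio preprocessing: spectral-subtraction denoising and fixed-length segmentation."""

from __future__ import annotations

import numpy as np

from ..errors import InvalidInputError
from .io import AudioClip
from .spectral import FrameSpec, istft, stft

__all__ = ["denoise", "segment"]


def denoise(
    clip: AudioClip,
    noise_seconds: float = 0.5,
    floor_beta: float = 0.01,
    spec: FrameSpec | None = None,
    oversubtraction: float = 1.5,
) -> AudioClip:
    """Spectral subtraction against a noise profile from the clip head.

    The mean magnitude spectrum of the first ``noise_seconds`` (scaled by
    the ``oversubtraction`` factor, a standard guard against the positive
    residual that plain mean subtraction leaves on noise) is subtracted
    from every frame's magnitude, floored at ``floor_beta`` times the noise
    spectrum; the original phase is kept and the signal is resynthesized at
    the input length.

    Raises
    ------
    InvalidInputError
        If the clip is not longer than ``noise_seconds``.
    """
    if clip.duration <= noise_seconds:
        raise InvalidInputError(
            f"clip of {clip.duration:.3f} s is not longer than the "
            f"noise window of {noise_seconds} s"
        )
    spec = spec or FrameSpec()
    X = stft(clip, spec)
    mag = np.abs(X)
    phase = np.angle(X)
    n_noise_frames = max(1, int(noise_seconds * clip.sample_rate / spec.hop))
    noise_profile = mag[:n_noise_frames].mean(axis=0)
    cleaned = np.maximum(
        mag - oversubtraction * noise_profile[None, :],
        floor_beta * noise_profile[None, :],
    )
    y = istft(cleaned * np.exp(1j * phase), spec, len(clip))
    return AudioClip(samples=y, sample_rate=clip.sample_rate)


def segment(clip: AudioClip, seconds: float = 5.0) -> list[AudioClip]:
    """Cut a clip into non-overlapping windows of exactly ``seconds``.

    A final remainder of at least 1 s is zero-padded to full length and
    kept; a shorter remainder is dropped.  A clip shorter than ``seconds``
    yields exactly one zero-padded segment.
    """
    if seconds <= 0:
        raise InvalidInputError(f"segment length must be > 0, got {seconds}")
    n = int(round(seconds * clip.sample_rate))
    x = clip.samples
    segments: list[AudioClip] = []
    for start in range(0, max(len(x), 1), n):
        chunk = x[start : start + n]
        if chunk.size == 0:
            break
        if chunk.size < n:
            is_only = not segments
            keep = chunk.size >= clip.sample_rate  # remainder >= 1 s
            if not (is_only or keep):
                break
            chunk = np.pad(chunk, (0, n - chunk.size))
        segments.append(AudioClip(samples=chunk, sample_rate=clip.sample_rate))
    return segments
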