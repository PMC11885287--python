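"""Cepstral feature blocks: MFCC (mel filterbank) and GFCC (gammatone filterbank).

Both use the midpoint cosine transform

    c_m = sum_{n=1..N} X_n * cos(m * (n - 0.5) * pi / N),   m = 1..n_keep

applied to compressed filterbank energies: natural log for MFCC, cube root
for GFCC.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidConfigError
from .io import AudioClip
from .spectral import FrameSpec, Spectrogram, spectrogram

__all__ = [
    "mel_filterbank",
    "gammatone_filterbank",
    "cosine_transform",
    "delta",
    "mfcc_block",
    "gfcc_block",
]

LOG_FLOOR = 1e-10


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, bin_freqs: np.ndarray) -> np.ndarray:
    """Triangular mel filters over ``bin_freqs`` (0 Hz to Nyquist).

    Returns a ``(n_mels, n_bins)`` matrix; each filter is normalized to unit
    weight sum so a flat power spectrum yields equal band energies.
    """
    n_bins = bin_freqs.size
    if n_mels > n_bins:
        raise InvalidConfigError(
            f"n_mels={n_mels} exceeds the number of spectrogram bins ({n_bins})"
        )
    nyquist = bin_freqs[-1]
    edges = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(nyquist), n_mels + 2))
    fb = np.zeros((n_mels, n_bins))
    for j in range(n_mels):
        lo, mid, hi = edges[j], edges[j + 1], edges[j + 2]
        up = (bin_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - mid, 1e-12)
        fb[j] = np.clip(np.minimum(up, down), 0.0, None)
        total = fb[j].sum()
        if total <= 0.0:
            raise InvalidConfigError(
                f"mel filter {j} is empty; decrease n_mels or increase frame_length"
            )
        fb[j] /= total
    return fb


def _erb(f):
    return 24.7 * (4.37 * np.asarray(f, dtype=np.float64) / 1000.0 + 1.0)


def _hz_to_erb_rate(f):
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=np.float64))


def _erb_rate_to_hz(u):
    return (10.0 ** (np.asarray(u, dtype=np.float64) / 21.4) - 1.0) / 0.00437


def gammatone_filterbank(
    n_filters: int, bin_freqs: np.ndarray, f_min: float = 50.0
) -> np.ndarray:
    """ERB-spaced gammatone magnitude-response weights, ``(n_filters, n_bins)``.

    Center frequencies are uniform on the ERB-rate scale between ``f_min``
    and 0.95 x Nyquist.  Each filter uses the 4th-order gammatone power
    response ``(1 + ((f - fc)/b)^2)^-3`` with bandwidth ``b = 1.019 ERB(fc)``,
    normalized to unit weight sum.
    """
    n_bins = bin_freqs.size
    if n_filters > n_bins:
        raise InvalidConfigError(
            f"n_filters={n_filters} exceeds the number of spectrogram bins ({n_bins})"
        )
    f_max = 0.95 * bin_freqs[-1]
    centers = _erb_rate_to_hz(
        np.linspace(_hz_to_erb_rate(f_min), _hz_to_erb_rate(f_max), n_filters)
    )
    fb = np.zeros((n_filters, n_bins))
    for j, fc in enumerate(centers):
        b = 1.019 * _erb(fc)
        fb[j] = (1.0 + ((bin_freqs - fc) / b) ** 2) ** -3.0
        fb[j] /= fb[j].sum()
    return fb


def cosine_transform(energies: np.ndarray, n_keep: int) -> np.ndarray:
    """Midpoint DCT of compressed band energies, coefficients ``m = 1..n_keep``."""
    energies = np.atleast_2d(energies)
    n_bands = energies.shape[1]
    n = np.arange(1, n_bands + 1)
    m = np.arange(1, n_keep + 1)
    basis = np.cos(np.outer(m, (n - 0.5) * np.pi / n_bands))  # (n_keep, n_bands)
    return energies @ basis.T


def delta(x: np.ndarray) -> np.ndarray:
    """First temporal difference by centered differences, edges replicated."""
    padded = np.concatenate([x[:1], x, x[-1:]], axis=0)
    return (padded[2:] - padded[:-2]) / 2.0


def mfcc_block(spect: Spectrogram, n_mels: int = 26, n_keep: int = 13) -> np.ndarray:
    """MFCC matrix of shape ``(frames, 3 * n_keep)``: static + delta + delta-delta.

    Per frame: mel filterbank energies of the power spectrum, natural log
    floored at ``1e-10``, midpoint cosine transform keeping ``n_keep``
    coefficients, then first and second centered temporal differences.
    """
    if n_keep > n_mels:
        raise InvalidConfigError(f"n_keep={n_keep} exceeds n_mels={n_mels}")
    fb = mel_filterbank(n_mels, spect.bin_freqs)
    energies = spect.magnitudes**2 @ fb.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    static = cosine_transform(log_e, n_keep)
    d1 = delta(static)
    d2 = delta(d1)
    return np.concatenate([static, d1, d2], axis=1)


def gfcc_block(
    clip: AudioClip,
    n_filters: int = 26,
    n_keep: int = 13,
    spec: FrameSpec | None = None,
) -> np.ndarray:
    """GFCC matrix of shape ``(frames, n_keep)``.

    ERB-spaced gammatone band energies of the per-frame power spectrum,
    cube-root compression, then the midpoint cosine transform.
    """
    if n_keep > n_filters:
        raise InvalidConfigError(f"n_keep={n_keep} exceeds n_filters={n_filters}")
    spect = spectrogram(clip, spec)
    fb = gammatone_filterbank(n_filters, spect.bin_freqs)
    energies = spect.magnitudes**2 @ fb.T
    compressed = np.cbrt(energies)
    return cosine_transform(compressed, n_keep)
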