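"""Framing, STFT magnitude spectrogram and frame-level spectral descriptors.

Framing convention (shared by every per-frame feature in the package):
centered frames with reflect padding of ``frame_length // 2`` on both sides,
Hann window, ``1 + len(x) // hop`` frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidInputError
from .io import AudioClip

__all__ = [
    "FrameSpec",
    "Spectrogram",
    "frame_signal",
    "stft",
    "istft",
    "spectrogram",
    "spectral_descriptors",
    "chroma",
    "tempo_harmonics",
]


@dataclass(frozen=True)
class FrameSpec:
    """STFT framing parameters (Hann window)."""

    frame_length: int = 2048
    hop: int = 512

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_length):
            raise InvalidInputError(
                f"require 0 < hop <= frame_length, got hop={self.hop}, "
                f"frame_length={self.frame_length}"
            )

    @property
    def window(self) -> np.ndarray:
        # periodic Hann: satisfies COLA for hop <= frame_length / 2
        n = np.arange(self.frame_length)
        return 0.5 - 0.5 * np.cos(2.0 * np.pi * n / self.frame_length)


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude spectrogram: ``magnitudes[t, f]`` with axis labels."""

    magnitudes: np.ndarray = field(repr=False)  # (frames, bins), >= 0
    bin_freqs: np.ndarray = field(repr=False)  # Hz, ascending 0..Nyquist
    frame_times: np.ndarray = field(repr=False)  # seconds
    frame_spec: FrameSpec = FrameSpec()

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[1]


def frame_signal(x: np.ndarray, spec: FrameSpec) -> np.ndarray:
    """Slice ``x`` into centered, reflect-padded frames (frames, frame_length)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < spec.frame_length:
        raise InvalidInputError(
            f"signal of {x.size} samples is shorter than one frame "
            f"({spec.frame_length})"
        )
    pad = spec.frame_length // 2
    padded = np.pad(x, pad, mode="reflect")
    n_frames = 1 + x.size // spec.hop
    idx = np.arange(spec.frame_length)[None, :] + spec.hop * np.arange(n_frames)[:, None]
    return padded[idx]


def stft(clip: AudioClip, spec: FrameSpec) -> np.ndarray:
    """Complex STFT matrix of shape (frames, frame_length // 2 + 1)."""
    frames = frame_signal(clip.samples, spec)
    return np.fft.rfft(frames * spec.window[None, :], axis=1)


def istft(matrix: np.ndarray, spec: FrameSpec, length: int) -> np.ndarray:
    """Inverse of :func:`stft` by windowed overlap-add, trimmed to ``length``."""
    window = spec.window
    frames = np.fft.irfft(matrix, n=spec.frame_length, axis=1)
    pad = spec.frame_length // 2
    total = pad * 2 + length
    out = np.zeros(total)
    norm = np.zeros(total)
    for m in range(frames.shape[0]):
        start = m * spec.hop
        stop = min(start + spec.frame_length, total)
        k = stop - start
        if k <= 0:
            break
        out[start:stop] += frames[m, :k] * window[:k]
        norm[start:stop] += window[:k] ** 2
    norm[norm < 1e-12] = 1.0
    return (out / norm)[pad : pad + length]


def spectrogram(clip: AudioClip, spec: FrameSpec | None = None) -> Spectrogram:
    """Magnitude STFT of ``clip``.

    Raises :class:`InvalidInputError` if the clip is shorter than one frame.
    """
    spec = spec or FrameSpec()
    mags = np.abs(stft(clip, spec))
    bins = spec.frame_length // 2 + 1
    bin_freqs = np.arange(bins) * clip.sample_rate / spec.frame_length
    frame_times = np.arange(mags.shape[0]) * spec.hop / clip.sample_rate
    return Spectrogram(
        magnitudes=mags, bin_freqs=bin_freqs, frame_times=frame_times, frame_spec=spec
    )


def spectral_descriptors(spect: Spectrogram, clip: AudioClip) -> dict[str, np.ndarray]:
    """Per-frame spectral centroid, bandwidth, rolloff, flux and ZCR.

    Conventions: rolloff threshold 0.85 of cumulative magnitude; flux is the
    Euclidean norm of positive magnitude increments (first frame 0); ZCR is
    the fraction of adjacent sample pairs whose product is negative; silent
    frames get centroid = bandwidth = rolloff = 0.
    """
    S = spect.magnitudes
    f = spect.bin_freqs
    totals = S.sum(axis=1)
    silent = totals <= 0.0
    safe = np.where(silent, 1.0, totals)

    centroid = (S * f[None, :]).sum(axis=1) / safe
    bandwidth = np.sqrt((S * (f[None, :] - centroid[:, None]) ** 2).sum(axis=1) / safe)
    centroid[silent] = 0.0
    bandwidth[silent] = 0.0

    cum = np.cumsum(S, axis=1)
    reach = cum >= 0.85 * totals[:, None]
    first = np.argmax(reach, axis=1)
    rolloff = f[first]
    rolloff[silent] = 0.0

    diff = np.diff(S, axis=0)
    flux = np.zeros(S.shape[0])
    flux[1:] = np.sqrt((np.maximum(diff, 0.0) ** 2).sum(axis=1))

    frames = frame_signal(clip.samples, spect.frame_spec)
    sign_change = (frames[:, :-1] * frames[:, 1:]) < 0
    zcr = sign_change.sum(axis=1) / (spect.frame_spec.frame_length - 1)

    return {
        "centroid": centroid,
        "bandwidth": bandwidth,
        "rolloff": rolloff,
        "flux": flux,
        "zcr": zcr.astype(np.float64),
    }


def chroma(spect: Spectrogram, min_freq: float = 50.0) -> np.ndarray:
    """Fold bin energies onto 12 pitch classes (frames x 12).

    Bins are assigned to the nearest semitone relative to A4 = 440 Hz
    (column 0 = C, column 9 = A); bins below ``min_freq`` are ignored.  Each
    frame is normalized to unit maximum; all-zero frames stay zero.
    """
    f = spect.bin_freqs
    keep = f >= min_freq
    midi = np.rint(69.0 + 12.0 * np.log2(f[keep] / 440.0)).astype(int)
    pitch_class = midi % 12
    energy = spect.magnitudes[:, keep] ** 2
    out = np.zeros((spect.n_frames, 12))
    for pc in range(12):
        cols = pitch_class == pc
        if np.any(cols):
            out[:, pc] = energy[:, cols].sum(axis=1)
    peak = out.max(axis=1, keepdims=True)
    peak[peak <= 0.0] = 1.0
    return out / peak


def tempo_harmonics(
    clip: AudioClip,
    spec: FrameSpec | None = None,
    lag_range: tuple[float, float] = (0.25, 2.0),
    voiced_frac: float = 0.1,
) -> dict[str, float]:
    """Clip-level tempo (BPM) and harmonic energy ratio.

    Tempo is 60 / lag of the highest onset-envelope autocorrelation peak in
    ``lag_range`` seconds, where the onset envelope is the positive part of
    frame-energy increments.  The harmonic ratio is the fraction of spectral
    energy within +/-3% of the 2nd and 3rd multiples of the per-frame peak
    frequency, averaged over voiced frames (energy above ``voiced_frac`` of
    the maximum frame energy).

    Raises :class:`InvalidInputError` for clips shorter than one second.
    """
    if clip.duration < 1.0:
        raise InvalidInputError(
            f"tempo_harmonics requires >= 1 s of audio, got {clip.duration:.3f} s"
        )
    spec = spec or FrameSpec()
    spect = spectrogram(clip, spec)
    power = spect.magnitudes**2
    energy = power.sum(axis=1)

    onset = np.maximum(np.diff(energy, prepend=energy[0]), 0.0)
    onset = onset - onset.mean()
    ac = np.correlate(onset, onset, mode="full")[onset.size - 1 :]
    frame_dt = spec.hop / clip.sample_rate
    lo = max(1, int(np.ceil(lag_range[0] / frame_dt)))
    hi = min(ac.size - 1, int(np.floor(lag_range[1] / frame_dt)))
    if hi < lo or not np.any(ac[lo : hi + 1] > 0):
        tempo = 0.0
    else:
        lag = lo + int(np.argmax(ac[lo : hi + 1]))
        tempo = 60.0 / (lag * frame_dt)

    voiced = energy > voiced_frac * energy.max() if energy.max() > 0 else energy > 0
    if not np.any(voiced):
        return {"tempo_bpm": tempo, "harmonic_ratio": 0.0}
    f = spect.bin_freqs
    ratios = []
    for t in np.flatnonzero(voiced):
        peak_f = f[np.argmax(spect.magnitudes[t])]
        if peak_f <= 0:
            continue
        band = np.zeros(f.size, dtype=bool)
        for mult in (2, 3):
            band |= (f >= 0.97 * mult * peak_f) & (f <= 1.03 * mult * peak_f)
        ratios.append(power[t, band].sum() / power[t].sum())
    harmonic_ratio = float(np.mean(ratios)) if ratios else 0.0
    return {"tempo_bpm": float(tempo), "harmonic_ratio": harmonic_ratio}
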