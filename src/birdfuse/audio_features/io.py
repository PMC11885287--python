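"""WAV input/output and the core :class:`AudioClip` container.

All DSP in the package consumes :class:`AudioClip`: a mono float waveform in
``[-1, 1]`` with an explicit sample rate.  Files are plain RIFF/PCM WAV read
and written through :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from ..errors import FormatError, InvalidInputError

__all__ = ["AudioClip", "load_wav", "save_wav"]

# Full-scale divisor for each integer PCM width.
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


@dataclass(frozen=True)
class AudioClip:
    """Mono waveform with sample rate.

    Parameters
    ----------
    samples : ndarray
        1-D float array of amplitudes in ``[-1, 1]``.
    sample_rate : int
        Sampling frequency in Hz.
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise InvalidInputError(
                f"AudioClip must be mono (1-D); got shape {samples.shape}"
            )
        if samples.size == 0:
            raise InvalidInputError("AudioClip must be non-empty")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("AudioClip contains non-finite samples")
        if self.sample_rate <= 0:
            raise InvalidInputError(f"sample_rate must be > 0, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


def load_wav(path: str | Path) -> AudioClip:
    """Read a RIFF/PCM WAV file as a mono :class:`AudioClip`.

    Stereo (or any multi-channel) input is mixed down by averaging channels.
    Integer PCM samples are scaled to ``[-1, 1]`` by the full-scale value of
    their width; float WAVs are taken as-is.

    Raises
    ------
    FormatError
        If the file is missing, truncated, or not a PCM WAV.
    """
    path = Path(path)
    import struct

    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, OSError, EOFError, struct.error) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.size == 0:
        raise FormatError(f"WAV file {path} contains no samples")
    if data.ndim == 2:
        data = data.mean(axis=1)
    elif data.ndim != 1:
        raise FormatError(f"WAV file {path} has unsupported layout {data.shape}")
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit PCM is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"WAV file {path} has unsupported dtype {data.dtype}")
    return AudioClip(samples=samples, sample_rate=int(rate))


def save_wav(clip: AudioClip, path: str | Path) -> None:
    """Write ``clip`` as 16-bit PCM mono WAV.

    Quantization rounds ``x * 32768`` and clamps to the int16 range, so a
    write/read round trip is exact to within ``1/32768`` for in-range input.
    """
    path = Path(path)
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.clip(np.rint(x * 32768.0), -32768, 32767).astype(np.int16)
    try:
        wavfile.write(str(path), clip.sample_rate, pcm)
    except OSError as exc:
        raise FormatError(f"cannot write WAV file {path}: {exc}") from exc
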