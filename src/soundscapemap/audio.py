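"""Audio ingestion and fixed-resolution spectrograms.

All downstream eco-acoustic indices operate on one common substrate: a
linear-magnitude short-time Fourier transform with non-overlapping
windows, so that the frequency resolution ``FR = rate / window_len`` and
the time resolution ``TR = 1 / FR`` are exact reciprocals (e.g. 48 kHz /
1024 points -> FR = 46.875 Hz, TR ~ 21.3 ms).  The spectrogram is then
tiled into contiguous 1-second blocks, the integration unit at which
every index is evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "AudioClip",
    "SpectrogramParams",
    "Spectrogram",
    "read_wav",
    "write_wav",
    "compute_spectrogram",
    "band_mask",
    "tile_windows",
]


class AudioFormatError(ValueError):
    """Unreadable or unsupported audio input."""


class InsufficientInputError(ValueError):
    """Input too short for the requested analysis."""


@dataclass
class AudioClip:
    """Mono waveform in full-scale units [-1, 1] with its sampling rate."""

    samples: np.ndarray
    rate: float
    site_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioFormatError("AudioClip requires a 1-D sample array")
        if self.samples.size < 1:
            raise InsufficientInputError("empty audio clip")
        if not np.all(np.isfinite(self.samples)):
            raise AudioFormatError("audio samples must be finite")
        if self.rate <= 0:
            raise AudioFormatError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.samples.size / self.rate


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT geometry. Default: 1024-point Hann windows, no overlap.

    With no overlap the frame step equals the window, so the time
    resolution is exactly the reciprocal of the frequency resolution.
    """

    window_len: int = 1024
    hop: int | None = None
    window_fn: str = "hann"

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if self.hop is None:
            object.__setattr__(self, "hop", self.window_len)
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.window_fn not in ("hann", "rectangular"):
            raise ValueError(f"unknown window_fn {self.window_fn!r}")

    def fr(self, rate: float) -> float:
        """Frequency resolution in Hz."""
        return rate / self.window_len

    def tr(self, rate: float) -> float:
        """Time resolution in seconds (1/FR when hop == window_len)."""
        return self.window_len / rate


@dataclass
class Spectrogram:
    """Linear-magnitude time-frequency matrix.

    ``A[k, t]`` is the magnitude of frequency bin ``k`` (centre k*FR Hz)
    in frame ``t``; ``times`` marks frame starts in seconds.
    """

    A: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    params: SpectrogramParams
    rate: float
    site_id: str = ""

    @property
    def fr(self) -> float:
        return self.params.fr(self.rate)

    @property
    def tr(self) -> float:
        return self.params.tr(self.rate)

    @property
    def n_frames(self) -> int:
        return self.A.shape[1]

    def to_csv(self, path) -> None:
        """Debug dump: rows = frequency bins, first column = bin Hz."""
        out = np.column_stack([self.freqs, self.A])
        header = "freq_hz," + ",".join(f"t{t:.6f}" for t in self.times)
        np.savetxt(path, out, delimiter=",", header=header, comments="")


_PCM_SCALE = {
    np.dtype(np.int16): 2**15,
    np.dtype(np.int32): 2**31,
}


def read_wav(path, site_id: str = "") -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    Integer PCM is rescaled to [-1, 1] by the type's full-scale value
    (16-bit 32767 -> 32767/32768).  Multi-channel files are reduced to
    channel 0 with a warning.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InsufficientInputError(f"zero-length WAV file: {path}")
    if data.ndim == 2:
        logger.warning("%s has %d channels; using channel 0", path, data.shape[1])
        data = data[:, 0]
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")
    return AudioClip(samples=samples, rate=float(rate), site_id=site_id)


def write_wav(path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV, clipping to full scale."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, int(clip.rate), (x * 32767.0).astype(np.int16))


def _window(params: SpectrogramParams) -> np.ndarray:
    if params.window_fn == "hann":
        return np.hanning(params.window_len)
    return np.ones(params.window_len)


def compute_spectrogram(
    clip: AudioClip, params: SpectrogramParams | None = None
) -> Spectrogram:
    """Magnitude STFT of a clip; trailing samples short of a window drop.

    Frames are ``floor((len - window_len) / hop) + 1``; row ``k`` holds
    the magnitude of the DFT at ``k * FR`` Hz for ``k`` in
    ``0..window_len//2``.
    """
    params = params or SpectrogramParams()
    n, win, hop = clip.samples.size, params.window_len, params.hop
    if n < win:
        raise InsufficientInputError(
            f"clip of {n} samples shorter than one {win}-sample window"
        )
    frames = (n - win) // hop + 1
    idx = hop * np.arange(frames)[:, None] + np.arange(win)[None, :]
    segs = clip.samples[idx] * _window(params)[None, :]
    A = np.abs(np.fft.rfft(segs, axis=1)).T  # bins x frames
    fr = params.fr(clip.rate)
    freqs = fr * np.arange(A.shape[0])
    times = (hop / clip.rate) * np.arange(frames)
    return Spectrogram(A=A, freqs=freqs, times=times, params=params,
                       rate=clip.rate, site_id=clip.site_id)


def band_mask(spec: Spectrogram, f_lo: float = 100.0, f_hi: float = 24000.0) -> Spectrogram:
    """Restrict a spectrogram to rows with centre frequency in [f_lo, f_hi]."""
    keep = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not keep.any():
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz contains no spectrogram rows")
    return replace(spec, A=spec.A[keep], freqs=spec.freqs[keep])


def tile_windows(spec: Spectrogram, integration: float = 1.0) -> list[Spectrogram]:
    """Cut a spectrogram into contiguous non-overlapping integration blocks.

    Each block spans ``J = floor(integration / TR)`` frames; a trailing
    partial block is dropped (and logged).  J must be at least 2 because
    the acoustic complexity index differences adjacent frames.
    """
    tr = spec.tr
    if integration < tr:
        raise ValueError("integration shorter than one frame")
    J = int(integration / tr)
    if J < 2:
        raise ValueError(
            f"integration {integration}s yields {J} frame(s) per block; need >= 2"
        )
    n_blocks = spec.n_frames // J
    if n_blocks == 0:
        raise InsufficientInputError(
            f"{spec.n_frames} frames cannot fill one {J}-frame block"
        )
    dropped = spec.n_frames - n_blocks * J
    if dropped:
        logger.info("tile_windows: dropping %d trailing frames (< %gs block)",
                    dropped, integration)
    blocks = []
    for b in range(n_blocks):
        sl = slice(b * J, (b + 1) * J)
        blocks.append(replace(spec, A=spec.A[:, sl], times=spec.times[sl]))
    return blocks
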