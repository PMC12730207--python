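"""Audio loading and conditioning.

Every recording entering the feature pipeline is put into a canonical form:
mono, 11,025 Hz, high-passed at 20 Hz to strip rumble/handling noise, then
cut into fixed-length frames with 50% overlap.  Frame-granularity feature
modes additionally drop near-silent frames with a min–max interpolated
energy threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, resample_poly, sosfiltfilt

__all__ = [
    "TARGET_FS",
    "AudioClip",
    "FrameSequence",
    "load_audio",
    "resample_clip",
    "highpass_20hz",
    "preprocess_clip",
    "frame_signal",
    "frame_energies_time",
    "silence_threshold",
    "remove_silent_frames",
]

log = logging.getLogger(__name__)

#: Canonical sampling frequency of the pipeline, Hz.
TARGET_FS = 11_025

# Integer PCM full-scale divisors for scipy.io.wavfile dtypes.
_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
    np.dtype(np.uint8): 2.0**7,  # uint8 WAV is offset-binary
}


@dataclass
class AudioClip:
    """A mono sampled signal with its sampling frequency.

    ``samples`` are dimensionless amplitudes, nominally in [-1, 1].
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip.samples must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise ValueError("AudioClip.samples must be non-empty")
        if not self.fs > 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.fs


@dataclass
class FrameSequence:
    """A signal cut into ``Ns_i`` complete frames of ``NS`` samples, hop ``NS//2``."""

    frames: np.ndarray  # shape (Ns_i, NS)
    NS: int
    hop: int
    fs: float
    frame_duration_ms: float
    source_id: str | None = None
    label: str | None = None
    kept_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def Ns_i(self) -> int:
        return int(self.frames.shape[0])


def load_audio(path: str | Path, label: str | None = None) -> AudioClip:
    """Read a WAV file (PCM 8/16/24/32-bit or float) as a mono [-1, 1] clip.

    Multi-channel inputs are averaged down to one channel.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(str(path))
    except Exception as exc:  # unreadable / not a RIFF file
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path} contains no samples")
    data = np.asarray(data)
    if data.dtype in _PCM_SCALE:
        if data.dtype == np.dtype(np.uint8):
            samples = (data.astype(np.float64) - 128.0) / _PCM_SCALE[data.dtype]
        else:
            samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:  # float32 / float64 WAV
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioClip(samples=samples, fs=float(fs), label=label, source_id=path.stem)


def resample_clip(clip: AudioClip, target_fs: float = TARGET_FS) -> AudioClip:
    """Band-limited (polyphase) resampling to ``target_fs``.

    A clip already at the target rate is returned unchanged.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if clip.fs == target_fs:
        return clip
    ratio = Fraction(int(round(target_fs)), int(round(clip.fs)))
    out = resample_poly(clip.samples, ratio.numerator, ratio.denominator)
    return replace(clip, samples=out, fs=float(target_fs))


def highpass_20hz(clip: AudioClip, cutoff_hz: float = 20.0, order: int = 4) -> AudioClip:
    """Zero-phase Butterworth high-pass removing DC and sub-audio rumble.

    Applied forward-backward (``sosfiltfilt``), so the effective attenuation
    slope is doubled and the passband is phase-undistorted.
    """
    sos = butter(order, cutoff_hz, btype="highpass", fs=clip.fs, output="sos")
    return replace(clip, samples=sosfiltfilt(sos, clip.samples))


def preprocess_clip(clip: AudioClip, target_fs: float = TARGET_FS) -> AudioClip:
    """Resample to the canonical rate, then 20 Hz high-pass."""
    return highpass_20hz(resample_clip(clip, target_fs))


def frame_signal(clip: AudioClip, frame_duration_ms: float) -> FrameSequence:
    """Cut a clip into complete frames with 50% overlap.

    ``NS = round(fs * duration_ms / 1000)``, ``hop = NS // 2``; a trailing
    partial frame is discarded.  A clip shorter than one frame yields an
    empty sequence (``Ns_i = 0``) rather than an error.
    """
    if not 10 <= frame_duration_ms <= 200:
        raise ValueError(
            f"frame_duration_ms must lie in [10, 200], got {frame_duration_ms}"
        )
    NS = int(round(clip.fs * frame_duration_ms / 1000.0))
    hop = NS // 2
    x = clip.samples
    if x.size < NS:
        log.warning(
            "clip %s shorter than one %g ms frame; empty frame sequence",
            clip.source_id, frame_duration_ms,
        )
        frames = np.empty((0, NS))
    else:
        n_frames = (x.size - NS) // hop + 1
        idx = hop * np.arange(n_frames)[:, None] + np.arange(NS)[None, :]
        frames = x[idx]
    return FrameSequence(
        frames=frames, NS=NS, hop=hop, fs=clip.fs,
        frame_duration_ms=frame_duration_ms,
        source_id=clip.source_id, label=clip.label,
    )


def frame_energies_time(frames: FrameSequence) -> np.ndarray:
    """Per-frame time-domain energy: sum of squared samples."""
    return np.einsum("ij,ij->i", frames.frames, frames.frames)


def silence_threshold(energies: np.ndarray, ET: float) -> float:
    """Min–max interpolated activity threshold ``TE = mE + ET * (ME - mE)``."""
    mE = float(np.min(energies))
    ME = float(np.max(energies))
    return mE + ET * (ME - mE)


def remove_silent_frames(
    frames: FrameSequence, ET: float
) -> tuple[FrameSequence, float]:
    """Keep frames whose energy strictly exceeds the min–max threshold.

    The threshold uses this recording's own min/max frame energies.  Returns
    the filtered sequence and the fraction of frames kept.  With all-equal
    energies the strict inequality keeps nothing; this is flagged in the log.
    """
    if frames.Ns_i < 1:
        raise ValueError("cannot remove silence from an empty frame sequence")
    E = frame_energies_time(frames)
    TE = silence_threshold(E, ET)
    mask = E > TE
    if not mask.any():
        log.warning(
            "silence removal dropped every frame of %s (ET=%g)", frames.source_id, ET
        )
    kept = replace(frames, frames=frames.frames[mask], kept_mask=mask)
    return kept, float(mask.mean())
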