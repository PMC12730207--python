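"""Per-vocalization scalar features.

Three scalars summarize a whole vocalization: its duration d (seconds), the
rate R of frames whose spectral energy strictly exceeds a min-max
interpolated threshold, and the interval [Lf, Hf] of frequencies whose
spectral magnitude strictly exceeds an analogous threshold in at least one
frame.  The thresholds interpolate between the recording's own minimum and
maximum by the unitless fractions ET (energy) and ftT (spectral magnitude),
so both features are level-invariant.

Spectra are one-sided DFTs of the unwindowed frames; the DC bin is excluded
(the 20 Hz high-pass has already removed it), so NF = NS // 2 bins at
frequencies j * fs / NS, j = 1 .. NS // 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft

from .preprocess import FrameSequence

__all__ = [
    "ScalarFeatureSet",
    "ActivityThresholds",
    "frame_spectra",
    "frame_stft_energies",
    "active_frame_rate",
    "active_frequency_interval",
    "interval_reduction",
    "compute_scalar_features",
]


@dataclass
class ScalarFeatureSet:
    d: float   # duration, s
    R: float   # active-frame rate, [0, 1]
    Lf: float  # lowest active frequency, Hz
    Hf: float  # highest active frequency, Hz

    def as_array(self) -> np.ndarray:
        return np.array([self.d, self.R, self.Lf, self.Hf])


@dataclass
class ActivityThresholds:
    """The min/max statistics and interpolated thresholds behind R and [Lf, Hf]."""

    mE: float | None = None
    ME: float | None = None
    TE: float | None = None
    mft: float | None = None
    Mft: float | None = None
    Tft: float | None = None
    ET: float | None = None
    ftT: float | None = None


def frame_spectra(frames: FrameSequence) -> np.ndarray:
    """One-sided spectral magnitudes |FT_n(j)|, j = 1..NS//2 (DC excluded).

    Shape (Ns_i, NS//2).  No window taper is applied.
    """
    if frames.Ns_i < 1:
        raise ValueError("frame sequence is empty")
    spec = rfft(frames.frames, axis=1)
    nf = frames.NS // 2
    return np.abs(spec[:, 1 : nf + 1])


def frame_stft_energies(frames: FrameSequence) -> np.ndarray:
    """Per-frame spectral energy ``E(n) = sum_j |FT_n(j)|^2`` over the NF bins."""
    mag = frame_spectra(frames)
    return np.einsum("ij,ij->i", mag, mag)


def active_frame_rate(
    E: np.ndarray, ET: float
) -> tuple[float, int, ActivityThresholds]:
    """Fraction of frames whose energy strictly exceeds TE = mE + ET (ME - mE).

    Returns (R, HE, thresholds).  With all-equal energies the strict
    inequality makes R = 0 for every ET.
    """
    E = np.asarray(E, dtype=np.float64)
    if E.size == 0:
        raise ValueError("active-frame rate undefined for an empty vocalization")
    mE, ME = float(E.min()), float(E.max())
    TE = mE + ET * (ME - mE)
    HE = int(np.count_nonzero(E > TE))
    thr = ActivityThresholds(mE=mE, ME=ME, TE=TE, ET=ET)
    return HE / E.size, HE, thr


def active_frequency_interval(
    frames: FrameSequence, ftT: float
) -> tuple[float, float, ActivityThresholds]:
    """Lowest/highest frequencies active in at least one frame.

    The threshold Tft = mft + ftT (Mft - mft) interpolates between the
    minimum and maximum spectral magnitude over *all* frames and bins of the
    vocalization; a bin is active when it strictly exceeds Tft in any frame.
    If no bin is active (e.g. ftT = 1) the interval degenerates to the
    frequency of the globally strongest bin.
    """
    mag = frame_spectra(frames)
    mft, Mft = float(mag.min()), float(mag.max())
    Tft = mft + ftT * (Mft - mft)
    thr = ActivityThresholds(mft=mft, Mft=Mft, Tft=Tft, ftT=ftT)
    bin_freqs = np.arange(1, frames.NS // 2 + 1) * frames.fs / frames.NS
    active = (mag > Tft).any(axis=0)
    if not active.any():
        peak_bin = int(np.argmax(mag.max(axis=0)))
        f = float(bin_freqs[peak_bin])
        return f, f, thr
    idx = np.nonzero(active)[0]
    return float(bin_freqs[idx[0]]), float(bin_freqs[idx[-1]]), thr


def interval_reduction(frames: FrameSequence, ftT: float) -> float:
    """Share of the analyzable band retained by the active-frequency interval.

    ``(Hf - Lf) / (fs/2 - fs/NS)`` — the analyzable band spans bin 1 to bin
    NS/2.  A degenerate interval returns 0.
    """
    Lf, Hf, _ = active_frequency_interval(frames, ftT)
    full = frames.fs / 2.0 - frames.fs / frames.NS
    return (Hf - Lf) / full


def compute_scalar_features(
    frames: FrameSequence, ET: float, ftT: float, duration_s: float | None = None
) -> ScalarFeatureSet:
    """d, R, Lf, Hf for one framed vocalization.

    ``duration_s`` is the true recording duration; when omitted, the span
    covered by the complete frames is used.
    """
    if duration_s is None:
        n_samples = frames.NS + (frames.Ns_i - 1) * frames.hop if frames.Ns_i else 0
        duration_s = n_samples / frames.fs
    d = duration_s
    R, _, _ = active_frame_rate(frame_stft_energies(frames), ET)
    Lf, Hf, _ = active_frequency_interval(frames, ftT)
    return ScalarFeatureSet(d=d, R=R, Lf=Lf, Hf=Hf)
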