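"""Cochlear filterbank features.

The core auditory front-end: a bank of 4th-order gammatone filters whose
center frequencies are equally spaced on the ERB-rate scale, so that — as in
the cochlea — spacing is proportional to filter bandwidth.  Per frame, the
bank yields N output energies ``S[g]``; optionally the orthonormal type-II
DCT of their base-10 logarithms gives cepstral-like coefficients ``GC``.
Frame-to-frame differences (delta vectors) track the signal dynamics, and a
whole vocalization is summarized by the mean and standard deviation of the
concatenated [GC, delta] vectors.

A mel-spaced triangular filterbank with the same N and frequency interval is
provided as the classical baseline front-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, idct, rfft, rfftfreq
from scipy.signal import sosfilt, sosfreqz

__all__ = [
    "erb_bandwidth",
    "erb_rate",
    "inverse_erb_rate",
    "hz_to_mel",
    "mel_to_hz",
    "GammatoneFilterbank",
    "TriangularFilterbank",
    "design_gammatone_bank",
    "design_triangular_bank",
    "filter_energies",
    "triangular_energies",
    "gc_coefficients",
    "delta_sequence",
    "aggregate_vocalization",
    "VocalizationAggregate",
]

# Glasberg & Moore ERB constants
_EAR_Q = 9.26449  # 1000 / (24.7 * 4.37)
_MIN_BW = 24.7

#: Bandwidth correction factor of the 4th-order gammatone (Patterson/Holdsworth).
GAMMATONE_B = 1.019


def erb_bandwidth(f: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth at frequency ``f`` (Hz):
    ``ERB(f) = 24.7 * (4.37 f / 1000 + 1)``."""
    return _MIN_BW * (4.37 * np.asarray(f, dtype=float) / 1000.0 + 1.0)


def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-rate scale: ``21.4 * log10(1 + 0.00437 f)`` (auditory-filter number)."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=float))


def inverse_erb_rate(e: np.ndarray | float) -> np.ndarray | float:
    """Frequency (Hz) at a given ERB-rate value."""
    return (np.power(10.0, np.asarray(e, dtype=float) / 21.4) - 1.0) / 0.00437


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (np.power(10.0, np.asarray(m, dtype=float) / 2595.0) - 1.0)


@dataclass
class GammatoneFilterbank:
    """Bank of N 4th-order gammatone filters, ERB-rate-equispaced centers."""

    N: int
    fs: float
    center_freqs: np.ndarray  # Hz, ascending
    bandwidths: np.ndarray    # ERB at each center, Hz
    sos: np.ndarray           # (N, 4, 6) second-order sections per filter
    order: int = 4

    def to_dict(self) -> dict:
        return {
            "kind": "gammatone",
            "N": self.N,
            "fs": self.fs,
            "order": self.order,
            "center_freqs": self.center_freqs.tolist(),
            "bandwidths": self.bandwidths.tolist(),
        }


@dataclass
class TriangularFilterbank:
    """Bank of N triangular magnitude weightings, mel-equispaced centers.

    ``responses`` holds the triangle weights over the one-sided FFT bins of
    an ``NS``-sample frame.
    """

    N: int
    fs: float
    NS: int
    center_freqs: np.ndarray  # Hz
    responses: np.ndarray     # (N, NS//2 + 1)

    def to_dict(self) -> dict:
        return {
            "kind": "triangular",
            "N": self.N,
            "fs": self.fs,
            "NS": self.NS,
            "center_freqs": self.center_freqs.tolist(),
        }


def _gammatone_sos(cf: float, fs: float) -> np.ndarray:
    """Second-order-section cascade of one 4th-order gammatone filter.

    All-pole approximation realized as four biquads sharing the same poles
    (Slaney-style); the cascade is normalized to unit magnitude response at
    the center frequency.
    """
    T = 1.0 / fs
    B = 2.0 * np.pi * GAMMATONE_B * float(erb_bandwidth(cf))
    theta = 2.0 * np.pi * cf * T
    expB = np.exp(B * T)

    b1 = -2.0 * np.cos(theta) / expB
    b2 = np.exp(-2.0 * B * T)

    k1 = np.sqrt(3.0 + 2.0 ** 1.5)
    k2 = np.sqrt(3.0 - 2.0 ** 1.5)
    # Zeros of the four cascade stages (Slaney 1993 all-pole gammatone).
    a11 = -(2.0 * T * np.cos(theta) / expB + 2.0 * k1 * T * np.sin(theta) / expB) / 2.0
    a12 = -(2.0 * T * np.cos(theta) / expB - 2.0 * k1 * T * np.sin(theta) / expB) / 2.0
    a13 = -(2.0 * T * np.cos(theta) / expB + 2.0 * k2 * T * np.sin(theta) / expB) / 2.0
    a14 = -(2.0 * T * np.cos(theta) / expB - 2.0 * k2 * T * np.sin(theta) / expB) / 2.0

    sos = np.array(
        [
            [T, a11, 0.0, 1.0, b1, b2],
            [T, a12, 0.0, 1.0, b1, b2],
            [T, a13, 0.0, 1.0, b1, b2],
            [T, a14, 0.0, 1.0, b1, b2],
        ]
    )
    # unit gain at cf
    _, h = sosfreqz(sos, worN=np.array([theta]))
    sos[0, :3] /= np.abs(h[0])
    return sos


def design_gammatone_bank(
    N: int, fs: float, fmin: float = 50.0, fmax: float | None = None
) -> GammatoneFilterbank:
    """Design N gammatone filters with centers ERB-rate-equispaced on
    [fmin, fmax] inclusive.

    Defaults cover the post-high-pass band up to the Nyquist frequency.
    """
    if fmax is None:
        fmax = fs / 2.0
    if not 2 <= N <= 128:
        raise ValueError(f"N must lie in [2, 128], got {N}")
    if not 0 < fmin < fmax:
        raise ValueError(f"need 0 < fmin < fmax, got fmin={fmin}, fmax={fmax}")
    if fmax > fs / 2.0:
        raise ValueError(f"fmax={fmax} exceeds Nyquist frequency {fs / 2}")
    grid = np.linspace(erb_rate(fmin), erb_rate(fmax), N)
    cfs = np.asarray(inverse_erb_rate(grid), dtype=float)
    # pin the endpoints exactly: the inverse map is analytic but round-trips
    # through log10/power
    cfs[0], cfs[-1] = fmin, fmax
    sos = np.stack([_gammatone_sos(cf, fs) for cf in cfs])
    return GammatoneFilterbank(
        N=N, fs=fs, center_freqs=cfs,
        bandwidths=np.asarray(erb_bandwidth(cfs), dtype=float), sos=sos,
    )


def design_triangular_bank(
    N: int, fs: float, fmin: float = 50.0, fmax: float | None = None, *, NS: int
) -> TriangularFilterbank:
    """Design N triangular filters with centers mel-equispaced on
    [fmin, fmax] inclusive, over the one-sided FFT bins of an NS-sample frame.

    Each triangle rises from the previous center and falls to the next; the
    outer edges sit one mel step beyond the end centers, clipped to [0, fs/2].
    """
    if fmax is None:
        fmax = fs / 2.0
    if not 2 <= N <= 128:
        raise ValueError(f"N must lie in [2, 128], got {N}")
    if not 0 < fmin < fmax:
        raise ValueError(f"need 0 < fmin < fmax, got fmin={fmin}, fmax={fmax}")
    if fmax > fs / 2.0:
        raise ValueError(f"fmax={fmax} exceeds Nyquist frequency {fs / 2}")
    mels = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), N)
    step = (mels[-1] - mels[0]) / (N - 1)
    edges_mel = np.concatenate([[mels[0] - step], mels, [mels[-1] + step]])
    edges_hz = np.clip(np.asarray(mel_to_hz(edges_mel), dtype=float), 0.0, fs / 2.0)
    cfs = edges_hz[1:-1]

    freqs = rfftfreq(NS, d=1.0 / fs)
    responses = np.zeros((N, freqs.size))
    for g in range(N):
        lo, c, hi = edges_hz[g], edges_hz[g + 1], edges_hz[g + 2]
        rise = (freqs - lo) / (c - lo) if c > lo else (freqs >= c).astype(float)
        fall = (hi - freqs) / (hi - c) if hi > c else (freqs <= c).astype(float)
        responses[g] = np.clip(np.minimum(rise, fall), 0.0, 1.0)
    return TriangularFilterbank(N=N, fs=fs, NS=NS, center_freqs=cfs, responses=responses)


def filter_energies(bank: GammatoneFilterbank, frames: np.ndarray) -> np.ndarray:
    """Gammatone output energies per frame: ``S[g] = sum(y_g^2)``.

    ``frames`` may be a single frame (1-D) or a stack (n_frames, NS); the
    result is (N,) or (n_frames, N).  Each frame is filtered independently
    (zero initial filter state at the frame start).
    """
    x = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if x.shape[1] < 2:
        raise ValueError("frames must contain at least 2 samples")
    S = np.empty((x.shape[0], bank.N))
    for g in range(bank.N):
        y = sosfilt(bank.sos[g], x, axis=1)
        S[:, g] = np.einsum("ij,ij->i", y, y)
    return S[0] if np.asarray(frames).ndim == 1 else S


def triangular_energies(bank: TriangularFilterbank, frames: np.ndarray) -> np.ndarray:
    """Triangle-weighted spectral energies per frame.

    ``S[g] = sum_j w_g(j) |FT(j)|^2`` over the one-sided FFT of the frame.
    """
    x = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if x.shape[1] != bank.NS:
        raise ValueError(f"frame length {x.shape[1]} != bank NS {bank.NS}")
    mag2 = np.abs(rfft(x, axis=1)) ** 2
    S = mag2 @ bank.responses.T
    return S[0] if np.asarray(frames).ndim == 1 else S


def gc_coefficients(
    S: np.ndarray, use_log_dct: bool = True, floor_eps: float = 1e-12
) -> np.ndarray:
    """GC feature vectors from filter energies.

    With ``use_log_dct`` the orthonormal type-II DCT of log10(S) (energies
    floored at ``floor_eps`` so silent frames stay finite); otherwise the raw
    energies pass through unchanged.  Works on one vector or a frame stack.
    """
    S = np.asarray(S, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("filter energies must be non-negative")
    if not use_log_dct:
        return S.copy()
    return dct(np.log10(np.maximum(S, floor_eps)), type=2, norm="ortho", axis=-1)


def invert_gc(GC: np.ndarray) -> np.ndarray:
    """Inverse of the log-DCT map (diagnostic): energies from coefficients."""
    return 10.0 ** idct(np.asarray(GC, dtype=np.float64), type=2, norm="ortho", axis=-1)


def delta_sequence(GCs: np.ndarray) -> np.ndarray:
    """Frame-to-frame differences; the first frame's delta is the zero vector."""
    GCs = np.atleast_2d(np.asarray(GCs, dtype=np.float64))
    delta = np.zeros_like(GCs)
    if GCs.shape[0] > 1:
        delta[1:] = np.diff(GCs, axis=0)
    return delta


@dataclass
class VocalizationAggregate:
    """Mean and population standard deviation of per-frame [GC, delta] vectors."""

    AVGC: np.ndarray  # length 2N
    STDGC: np.ndarray  # length 2N


def aggregate_vocalization(GCs: np.ndarray, deltas: np.ndarray) -> VocalizationAggregate:
    """Summarize a vocalization by elementwise mean/SD over frames.

    The aggregated vector is the concatenation [GC, delta] per frame (length
    2N); the standard deviation is the population SD (divide by the frame
    count).  A single frame yields a zero SD vector.
    """
    GCs = np.atleast_2d(np.asarray(GCs, dtype=np.float64))
    deltas = np.atleast_2d(np.asarray(deltas, dtype=np.float64))
    if GCs.shape != deltas.shape:
        raise ValueError("GC and delta stacks must have identical shapes")
    combined = np.hstack([GCs, deltas])
    return VocalizationAggregate(
        AVGC=combined.mean(axis=0), STDGC=combined.std(axis=0, ddof=0)
    )
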