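"""Assembly of the four feature-formation modes.

Two axes define the four modes:

* granularity — one vector per **vocalization** (P1, P3) built as
  ``[d, R, Lf, Hf, AVGC, STDGC]`` (length 4 + 4N), or one vector per
  retained **frame** (P2, P4) built as ``[GC, delta]`` (length 2N);
* cochlear coefficients — raw gammatone energies (P1, P2) or their
  log10 + orthonormal-DCT transform (P3, P4).

Frame-granularity modes drop near-silent frames (energy threshold ET)
before emitting vectors; vocalization modes aggregate over all frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cochlear
from .cochlear import GammatoneFilterbank, TriangularFilterbank
from .preprocess import (
    AudioClip,
    frame_energies_time,
    frame_signal,
    silence_threshold,
)
from .scalar import compute_scalar_features

__all__ = ["FeatureParams", "FeatureVector", "vector_length", "build_vectors"]

MODES = ("P1", "P2", "P3", "P4")
_FRAME_MODES = frozenset({"P2", "P4"})
_LOG_DCT_MODES = frozenset({"P3", "P4"})


@dataclass(frozen=True)
class FeatureParams:
    """Knobs of the feature pipeline.

    N: filterbank size; ET / ftT: activity-threshold fractions;
    frame_duration_ms: analysis frame length; fmin/fmax: filterbank band
    (fmax None means Nyquist); include_deltas: append delta vectors
    (the default formation); use_triangular: swap in the mel-triangular
    baseline filterbank.
    """

    N: int = 30
    ET: float = 0.005
    ftT: float = 0.1
    frame_duration_ms: float = 40.0
    fmin: float = 50.0
    fmax: float | None = None
    include_deltas: bool = True
    use_triangular: bool = False

    def to_dict(self) -> dict:
        return {
            "N": self.N, "ET": self.ET, "ftT": self.ftT,
            "frame_duration_ms": self.frame_duration_ms,
            "fmin": self.fmin, "fmax": self.fmax,
            "include_deltas": self.include_deltas,
            "use_triangular": self.use_triangular,
        }


@dataclass
class FeatureVector:
    values: np.ndarray
    mode: str
    species_label: str | None
    source_id: str | None
    frame_index: int | None = None  # present iff frame granularity

    @property
    def granularity(self) -> str:
        return "frame" if self.frame_index is not None else "vocalization"


def vector_length(mode: str, N: int, include_deltas: bool = True) -> int:
    """Closed-form vector length for a mode and filterbank size."""
    per_frame = 2 * N if include_deltas else N
    if mode in ("P1", "P3"):
        return 4 + 2 * per_frame
    return per_frame


def _design_bank(
    params: FeatureParams, fs: float, NS: int
) -> GammatoneFilterbank | TriangularFilterbank:
    if params.use_triangular:
        return cochlear.design_triangular_bank(
            params.N, fs, params.fmin, params.fmax, NS=NS
        )
    return cochlear.design_gammatone_bank(params.N, fs, params.fmin, params.fmax)


def _frame_bank_energies(bank, frames: np.ndarray) -> np.ndarray:
    if isinstance(bank, TriangularFilterbank):
        return cochlear.triangular_energies(bank, frames)
    return cochlear.filter_energies(bank, frames)


def build_vectors(
    recording: AudioClip,
    mode: str,
    params: FeatureParams = FeatureParams(),
    bank: GammatoneFilterbank | TriangularFilterbank | None = None,
) -> list[FeatureVector]:
    """Extract the feature vectors of one preprocessed recording.

    The recording must already be at the canonical rate and high-passed.
    P1/P3 return a single vocalization vector; P2/P4 return one vector per
    retained frame.  A recording shorter than one frame yields no vectors.
    A pre-designed ``bank`` may be passed to avoid repeating the filter
    design across recordings.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    frames = frame_signal(recording, params.frame_duration_ms)
    if frames.Ns_i == 0:
        return []
    if bank is None:
        bank = _design_bank(params, recording.fs, frames.NS)

    S = _frame_bank_energies(bank, frames.frames)  # (Ns_i, N)
    GC = cochlear.gc_coefficients(S, use_log_dct=mode in _LOG_DCT_MODES)
    delta = cochlear.delta_sequence(GC)

    if mode in _FRAME_MODES:
        # silence removal: per-recording min-max energy threshold
        E = frame_energies_time(frames)
        keep = E > silence_threshold(E, params.ET)
        stacked = np.hstack([GC, delta]) if params.include_deltas else GC
        return [
            FeatureVector(
                values=stacked[i].copy(), mode=mode,
                species_label=recording.label, source_id=recording.source_id,
                frame_index=int(i),
            )
            for i in np.nonzero(keep)[0]
        ]

    scalars = compute_scalar_features(
        frames, params.ET, params.ftT, duration_s=recording.duration
    )
    if params.include_deltas:
        agg = cochlear.aggregate_vocalization(GC, delta)
    else:
        agg = cochlear.VocalizationAggregate(
            AVGC=GC.mean(axis=0), STDGC=GC.std(axis=0, ddof=0)
        )
    values = np.concatenate([scalars.as_array(), agg.AVGC, agg.STDGC])
    return [
        FeatureVector(
            values=values, mode=mode,
            species_label=recording.label, source_id=recording.source_id,
        )
    ]
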