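import numpy as np
import pytest

from gammavox.preprocess import AudioClip, FrameSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone(freq, fs=11025, duration=1.0, amplitude=0.8):
    t = np.arange(int(round(duration * fs))) / fs
    return AudioClip(samples=amplitude * np.sin(2 * np.pi * freq * t), fs=fs)


def make_frames(frame_rows, fs=11025, frame_duration_ms=None):
    """Fabricate a FrameSequence directly from a (Ns_i, NS) array."""
    frames = np.atleast_2d(np.asarray(frame_rows, dtype=float))
    NS = frames.shape[1]
    if frame_duration_ms is None:
        frame_duration_ms = 1000.0 * NS / fs
    return FrameSequence(
        frames=frames, NS=NS, hop=NS // 2, fs=fs,
        frame_duration_ms=frame_duration_ms, source_id="fixture",
    )


@pytest.fixture
def tone_clip():
    return make_tone(1000.0)
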