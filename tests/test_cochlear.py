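"""Gammatone / triangular filterbank design and cochlear feature computation."""

import numpy as np
import pytest

from gammavox.cochlear import (
    aggregate_vocalization,
    delta_sequence,
    design_gammatone_bank,
    design_triangular_bank,
    erb_rate,
    filter_energies,
    gc_coefficients,
    hz_to_mel,
    invert_gc,
    triangular_energies,
)

FS = 11025


def erb_grid_oracle(n, fmin, fmax):
    """Closed-form ERB-rate-equispaced grid, computed independently."""
    lo = 21.4 * np.log10(1 + 0.00437 * fmin)
    hi = 21.4 * np.log10(1 + 0.00437 * fmax)
    pts = lo + (hi - lo) * np.arange(n) / (n - 1)
    return (10 ** (pts / 21.4) - 1) / 0.00437


class TestGammatoneDesign:
    def test_two_filters_sit_on_the_endpoints(self):
        bank = design_gammatone_bank(2, FS, 100, 1000)
        assert bank.center_freqs == pytest.approx([100.0, 1000.0], abs=0)

    def test_interior_centers_match_erb_grid_oracle(self):
        bank = design_gammatone_bank(5, FS, 200, 4000)
        assert bank.center_freqs == pytest.approx(erb_grid_oracle(5, 200, 4000), rel=1e-6)

    def test_erb_rate_spacing_uniform(self):
        bank = design_gammatone_bank(16, FS)
        steps = np.diff(erb_rate(bank.center_freqs))
        assert np.all(np.abs(steps - steps[0]) < 1e-6 * steps[0])

    def test_bandwidths_strictly_increasing(self):
        bank = design_gammatone_bank(16, FS)
        assert np.all(np.diff(bank.bandwidths) > 0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            design_gammatone_bank(8, FS, 50, 6000)
        with pytest.raises(ValueError):
            design_gammatone_bank(1, FS)

    def test_peak_response_near_center(self):
        """Each filter's magnitude response peaks within 5% of its center."""
        bank = design_gammatone_bank(12, FS, 200, 5000)
        from scipy.signal import sosfreqz

        for cf, sos in zip(bank.center_freqs, bank.sos):
            w, h = sosfreqz(sos, worN=8192)
            peak_hz = w[np.argmax(np.abs(h))] * FS / (2 * np.pi)
            assert abs(peak_hz - cf) <= 0.05 * cf


class TestFilterEnergies:
    def test_zero_frame_gives_zero_energies(self):
        bank = design_gammatone_bank(8, FS)
        assert np.all(filter_energies(bank, np.zeros(441)) == 0)

    def test_tone_energizes_its_own_filter(self):
        bank = design_gammatone_bank(20, FS, 100, 5000)
        t = np.arange(551) / FS
        for g in [2, 9, 17]:
            S = filter_energies(bank, np.sin(2 * np.pi * bank.center_freqs[g] * t))
            assert abs(int(np.argmax(S)) - g) <= 1

    def test_white_noise_excites_every_filter(self, rng):
        bank = design_gammatone_bank(10, FS)
        assert np.all(filter_energies(bank, rng.normal(size=441)) > 0)

    def test_amplitude_doubling_quadruples_energy(self, rng):
        bank = design_gammatone_bank(6, FS)
        frame = rng.normal(size=300)
        S1 = filter_energies(bank, frame)
        S2 = filter_energies(bank, 2.0 * frame)
        assert S2 == pytest.approx(4.0 * S1, rel=1e-9)


class TestGCCoefficients:
    def test_constant_energy_collapses_to_first_coefficient(self):
        n, c = 30, 2.5
        GC = gc_coefficients(np.full(n, c))
        assert GC[0] == pytest.approx(np.sqrt(n) * np.log10(c), rel=1e-12)
        assert np.allclose(GC[1:], 0.0, atol=1e-12)

    def test_identity_mode_passes_energies_through(self, rng):
        S = rng.uniform(0.1, 4.0, size=30)
        assert np.array_equal(gc_coefficients(S, use_log_dct=False), S)

    def test_log_dct_round_trip(self, rng):
        S = rng.uniform(0.1, 10.0, size=(7, 30))
        assert invert_gc(gc_coefficients(S)) == pytest.approx(S, rel=1e-9)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            gc_coefficients(np.array([1.0, -0.1]))

    def test_silent_frame_stays_finite(self):
        assert np.all(np.isfinite(gc_coefficients(np.zeros(10))))


class TestDeltas:
    def test_identical_frames_give_zero_deltas(self):
        GCs = np.tile(np.arange(5.0), (4, 1))
        assert np.all(delta_sequence(GCs) == 0)

    def test_arithmetic_progression(self):
        u = np.array([1.0, -2.0, 0.5])
        GCs = np.outer(np.arange(1, 6), u)
        d = delta_sequence(GCs)
        assert np.all(d[0] == 0)
        assert d[1:] == pytest.approx(np.tile(u, (4, 1)))

    def test_cumulative_sum_reconstructs(self, rng):
        GCs = rng.normal(size=(10, 6))
        d = delta_sequence(GCs)
        assert GCs[0] + np.cumsum(d, axis=0)[-1] == pytest.approx(GCs[-1])
        assert np.cumsum(d, axis=0) + GCs[0] == pytest.approx(GCs)


class TestAggregate:
    def test_matches_direct_statistics(self, rng):
        GCs = rng.normal(size=(10, 4))
        d = delta_sequence(GCs)
        agg = aggregate_vocalization(GCs, d)
        combined = np.hstack([GCs, d])
        assert agg.AVGC == pytest.approx(combined.mean(axis=0))
        assert agg.STDGC == pytest.approx(combined.std(axis=0, ddof=0))
        assert agg.AVGC.shape == (8,) and np.all(agg.STDGC >= 0)

    def test_two_frame_mean(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        agg = aggregate_vocalization(np.stack([a, b]), delta_sequence(np.stack([a, b])))
        assert agg.AVGC[:4] == pytest.approx((a + b) / 2)

    def test_identical_frames_zero_spread(self):
        GCs = np.tile(np.arange(3.0), (5, 1))
        agg = aggregate_vocalization(GCs, delta_sequence(GCs))
        assert np.allclose(agg.STDGC, 0.0)


class TestTriangularBank:
    def test_centers_mel_equispaced(self):
        bank = design_triangular_bank(3, FS, 50, FS / 2, NS=441)
        mels = hz_to_mel(bank.center_freqs)
        steps = np.diff(mels)
        assert np.all(np.abs(steps - steps[0]) < 1e-6 * steps[0])

    def test_tone_at_center_wins_its_triangle(self):
        NS = 512
        bank = design_triangular_bank(8, FS, 100, 5000, NS=NS)
        t = np.arange(NS) / FS
        for g in [1, 4, 6]:
            S = triangular_energies(bank, np.sin(2 * np.pi * bank.center_freqs[g] * t))
            assert int(np.argmax(S)) == g

    def test_zero_frame(self):
        bank = design_triangular_bank(5, FS, 50, 5000, NS=441)
        assert np.all(triangular_energies(bank, np.zeros(441)) == 0)

    def test_same_span_as_gammatone(self):
        gt = design_gammatone_bank(10, FS, 80, 5000)
        tri = design_triangular_bank(10, FS, 80, 5000, NS=441)
        assert tri.N == gt.N
        assert tri.center_freqs[0] == pytest.approx(gt.center_freqs[0], rel=1e-9)
        assert tri.center_freqs[-1] == pytest.approx(gt.center_freqs[-1], rel=1e-9)
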