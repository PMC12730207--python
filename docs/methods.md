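# Methods

## Problem and pipeline

`gammavox` classifies animal species from single-vocalization recordings
(one call per file, one species label per call). The front-end is a model of
cochlear frequency analysis: a bank of N gammatone filters whose center
frequencies are equally spaced on the ERB-rate scale, so that filter spacing
grows in proportion to filter bandwidth, as in the auditory periphery.
Classification uses a small feed-forward network; decisions can be fused
over frames, frame groups, whole vocalizations, or across two networks
trained at different frame durations.

The stages, in order:

1. **Conditioning.** Recordings are averaged to mono, resampled to
   11,025 Hz (polyphase, anti-aliased), and high-pass filtered at 20 Hz
   (4th-order Butterworth applied forward-backward, i.e. zero phase) to
   remove rumble and handling noise. All later stages assume this format.
2. **Framing.** Frames of `NS = round(fs · d_ms / 1000)` samples with hop
   `NS // 2` (50% overlap); a trailing partial frame is discarded.
3. **Scalar features** (per vocalization): duration `d` in seconds; the
   active-frame rate `R = |{n : E_n > TE}| / N_frames` with
   `TE = mE + ET·(ME − mE)` interpolating between the recording's min and
   max frame energy; and the active-frequency interval `[Lf, Hf]` — the
   lowest and highest DFT-bin frequencies whose magnitude strictly exceeds
   `Tft = mft + ftT·(Mft − mft)` in at least one frame. Frame spectra are
   one-sided DFTs of the unwindowed frame, DC bin excluded
   (`NF = NS // 2` bins at `j · fs / NS` Hz). All comparisons are strict
   inequalities, so a recording with all-equal energies has `R = 0` and a
   threshold fraction of 1 yields the degenerate interval at the strongest
   bin.
4. **Cochlear features** (per frame): gammatone output energies
   `S[g] = Σ y_g²`, optionally mapped to `GC = DCT(log10 S)` (orthonormal
   type-II DCT; energies floored at 1e-12 so silent frames stay finite);
   the delta vector `ΔGC(n) = GC(n) − GC(n−1)` (zero for the first frame);
   and, per vocalization, the mean `AVGC` and population standard deviation
   `STDGC` of the concatenated `[GC, ΔGC]` vectors (length 2N each).
5. **Feature formations.** P1/P3: one vector
   `[d, R, Lf, Hf, AVGC, STDGC]` per vocalization (length 4 + 4N);
   P2/P4: one `[GC, ΔGC]` vector per retained frame (length 2N).
   P1/P2 use raw energies (no log/DCT); P3/P4 the log-DCT coefficients.
   Frame modes apply energy-threshold silence removal (same `TE` rule, time
   domain energies) before emitting vectors; vocalization modes aggregate
   over all frames. The delta block can be disabled by flag.
6. **Classifier.** Two hidden layers of 50 and 25 ReLU units, softmax
   output, softmax cross-entropy loss, trained by L-BFGS (quasi-Newton).
   Training stops at 1000 iterations, or when the loss falls below 1e-6, or
   when the gradient infinity-norm falls below 1e-6. Inputs are z-scored
   with statistics from the training set only (switchable off). Training
   frames are balanced by subsampling every class to the smallest class
   count before fitting. Weights are initialized He-style from a seeded
   generator; runs are bit-reproducible for a fixed seed.
7. **Decision fusion.** Majority vote over consecutive groups of m frame
   decisions (trailing partial group voted as-is; ties go to the earliest
   appearing tied label); one modal label per vocalization; and the
   dual-network rule, where networks trained at 20 ms and 80 ms frames must
   produce the same vocalization label for the test to be accepted,
   otherwise it is rejected and excluded from the recognition rate.
8. **Protocol.** Per-class shuffle and 45 train / 5 test split (90/10),
   repeated five times with fresh seeds — repeated random splits, not
   disjoint folds, which keeps the training set large on a 50-recordings-
   per-species corpus. Metrics: confusion matrix, accuracy, and
   macro-averaged precision, recall and `F1_i = 2 P_i R_i / (P_i + R_i)`.

## Key parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `N` | 30 | filters in the bank (and DCT length) |
| `ET` | 0.005 | energy-threshold fraction for frame activity / silence removal |
| `ftT` | 0.1 | magnitude-threshold fraction for the active band |
| `frame_duration_ms` | 40 | analysis frame length (20 and 80 in the dual architecture) |
| `fmin`, `fmax` | 50 Hz, Nyquist | filterbank frequency span |
| hidden sizes | (50, 25) | network capacity |
| `max_iter`, `tol` | 1000, 1e-6 | training stopping rules |

## Numerical and design choices

- **ERB conventions.** Glasberg–Moore: `ERB(f) = 24.7(4.37 f/1000 + 1)`,
  ERB-rate `= 21.4 log10(1 + 0.00437 f)`. Filters are 4th-order all-pole
  gammatones realized as four cascaded biquads (Slaney-style) with
  bandwidth factor 1.019, each normalized to unit gain at its center
  frequency. Grid endpoints are pinned exactly to `fmin`/`fmax`.
- **Frames are unwindowed** (rectangular) both for the gammatone filtering
  (time-domain, per frame with zero initial state) and for the DFT-based
  scalar features; this makes the one-sided Parseval relation exact and is
  the plain reading of the energy definitions above.
- **Baseline bank.** The mel-spaced triangular filterbank has the same N
  and frequency interval as the gammatone bank; centers are mel-equispaced
  inclusive of the endpoints, each triangle spanning its neighbors, with
  the outer edges one mel step beyond the end centers (clipped to the
  analyzable band). Energies are triangle-weighted squared DFT magnitudes.
- **Silence-removal energy** is computed in the time domain; by Parseval it
  equals the spectral definition up to a fixed scale, which cancels in the
  min-max threshold rule.
- **Precision.** Forward/backward arithmetic runs in float32 by default
  (the optimizer state and reported loss/gradient are float64); shifted
  logits are floored at −60 before `exp` to keep softmax out of the
  subnormal range. `dtype="float64"` is available and changes end metrics
  negligibly (third decimal of the loss after 1000 iterations).
- **Determinism.** All randomness (generator, splits, balancing, weight
  init) flows from explicit integer seeds; per-clip seeds derive from a
  master seed via a seed sequence and are recorded in the dataset manifest.
- **Degenerate inputs.** Clips shorter than one frame yield empty feature
  sets (flagged, not raised); an all-equal-energy recording loses every
  frame to silence removal (strict inequality); a single-frame vocalization
  gets a zero standard-deviation block.

## The synthetic corpus

The generator emulates the statistical structure the method exploits:
species-specific active bands, harmonic stacks (fundamental drawn per
syllable from a species range, integer harmonics with geometric amplitude
decay, clipped to the band), syllable/gap alternation with species-specific
timing, optional slow amplitude modulation, truncated-normal vocalization
durations, and white background noise at a species SNR. Clips are
peak-normalized to 0.9.

The 13 default presets have graded band overlap — adjacent bands overlap
heavily (confusable), distant ones not at all — SNRs of 5–14 dB, and mean
durations from 1.45 to 4.55 s with large spreads, the dispersion typical of
field-recorded corpora (the corpus averages ≈2.8 s per clip). What the
generator does **not** model: environmental/colored noise, reverberation,
within-species individual variation beyond parameter jitter, overlapping
callers, and any real species' acoustics. Passing tests therefore show that
the pipeline recovers class structure of this kind from audio under
realistic noise and confusability — not that it attains any particular
accuracy on real field recordings.

## Problem sizes used in the shipped runs

The shipped evaluation runs (test suite and `scripts/acceptance.py`) use
the full default corpus — 13 species × 50 clips (~30 min of audio) — with
five 45/5 repeats at 40 ms and three dual-network (20/80 ms) repeats. With
frame balancing this trains on roughly 40k–60k frame vectors per network.

## Known limitations

- Gammatone filtering restarts per frame (zero state), so energies near
  frame onsets slightly underweight low frequencies relative to a
  continuous-filtering implementation.
- The active-frequency interval is a single global min/max-threshold rule;
  one loud frame can widen the interval for the whole vocalization.
- The dual-network rule reports accuracy only over accepted tests; its
  rejection rate is corpus-dependent and is reported, not targeted.
- No per-class frame-duration selection, no significance testing between
  configurations, and no MFCC variant beyond the triangular-filterbank
  energies.
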