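# Methods

## The measurement model

A nasometer headset holds one microphone at the nares and one at the mouth,
separated by a baffle plate. Perceived nasality correlates with the fraction
of acoustic energy radiated nasally, summarized per analysis frame as

```
nasalance(t) = N(t) / (N(t) + O(t)) × 100 %
```

with `N`, `O` the RMS amplitudes of the band-pass filtered nasal and oral
channels over the frame. The RMS-amplitude reading of "energy" is the
default here because it is what a frame-based real-time implementation
computes; a squared-energy variant is available via
`compute_trajectory(..., energy_mode="squared")`. The two interpretations
agree at 0, 50 and 100% and differ by at most a few points in between; the
choice is a convention that must simply be held fixed within a study.

### Pipeline stages and parameters

| Stage | Parameter | Default | Why |
|---|---|---|---|
| Band-pass | edges | 200–800 Hz | the nasalance-relevant band; energy above it is dominated by oral obstruents and below it by rumble |
| Band-pass | order | 2 (`butter` convention, 4 poles) | −3 dB at both edges and >20 dB rejection one octave outside the band |
| Framing | window | 50 ms Hann | long enough for stable RMS at speech F0, short enough to track syllables |
| Framing | overlap | 50% | halves the hop (25 ms) without changing steady-state values |
| Gate | floor | −50 dBFS | on the *combined* two-channel windowed frame RMS; below conversational speech recorded at sensible input gain, above a quiet room's floor |
| Summary | SD | sample SD (n−1) | over valid frames only |

Design notes:

- **Filter order convention.** "2nd-order Butterworth bandpass" is read as
  design order 2 in the scipy/MATLAB `butter` sense (lowpass prototype order;
  four poles after the bandpass transform). The literal one-biquad reading
  would also put −3 dB at both edges, but it attenuates only ~9 dB one
  octave outside the band (~15 dB two octaves out), too little to stop
  out-of-band energy from biasing an energy ratio — which defeats the
  purpose of band-limiting
  before an energy ratio. `order=1` gives the single-biquad variant.
- **Causal by default.** The streaming device filters forward in time, so the
  default application mode is a single causal pass; `zero_phase`
  (forward–backward) is available for offline spectral work. Because
  nasalance is a ratio of two *identically* filtered channels, the phase mode
  has almost no effect on the ratio itself.
- **Whole-signal filtering before framing** avoids per-frame edge transients
  and equals per-buffer streaming with carried state in steady state.
- **Gating and degenerate frames.** A frame is invalid when gated or when
  `N + O = 0` (the ratio is undefined there); invalid frames carry NaN and
  are excluded from summaries and correlations rather than interpolated,
  which would fabricate values. A recording with zero valid frames raises
  rather than returning an empty summary.
- **Frame timestamps are window centers**, which keeps two devices' frame
  grids alignable without a half-window bias.
- Reference-style recordings from commercial systems can be analyzed
  "as provided" through `passthrough(sample_rate)` in place of a designed
  filter.

## Electroacoustic analyses

- **LTAS** uses Welch averaging (1-s Hann segments, 50% overlap, no
  detrending), then integrates PSD power within half-open 50-Hz bands tiling
  100–1000 Hz; band centers are reported at `low + 25` Hz. Absolute levels
  are dB re digital full scale; since that reference is arbitrary, curves are
  usually compared after max-normalization (`relative` mode) or through
  differences (MAD over bands whose centers fall in 200–800 Hz).
- **Intensity gap** (isolation) is `20·log10` of the whole-recording RMS of
  each channel, oral minus nasal, optionally band-limited first. Only the
  difference is meaningful, which sidesteps absolute calibration.
- **THD** of a recorded test tone integrates Hann-windowed spectral power
  over the main lobe (peak ± 3 bins, peak searched within ±2% of each
  nominal harmonic) for the fundamental and harmonics 2..5, and reports
  `100·sqrt(ΣP_k/P_1)`. Integrating whole lobes makes the ratio insensitive
  to scalloping; harmonics at or above Nyquist are skipped.

## Agreement between non-synchronous trajectories

Two devices cannot record the same utterance simultaneously (the headset
occupies the face), so paired comparisons are made across separate
productions. Both trajectories must be computed on the same hop; invalid
frames are dropped and the sequences compacted.

- **`r_raw`**: for every integer-hop lag within ±500 ms, the overlapping
  segments are mean-centered *over the overlap* and Pearson-correlated; the
  maximum is returned with its lag. Lags leaving fewer than 10 overlapping
  frames are skipped; ties break toward the smaller |lag|. Per-overlap
  centering (rather than global means) was chosen because it makes the
  statistic exactly a Pearson correlation at each lag; the exhaustive-lag
  oracle test pins this choice.
- **DTW alignment**: classic dynamic programming with absolute-difference
  local cost, symmetric steps {(1,0),(0,1),(1,1)}, and full boundary
  conditions (no window constraint, no slope weighting). Candidate frames
  matched to one reference frame are averaged, yielding one aligned value
  per reference frame — a deterministic, order-independent resolution of
  many-to-one matches. **`r_dtw`** is the Pearson correlation of the
  reference with that aligned sequence. An exhaustive top-down DP oracle
  verifies the path cost on small inputs.

Note that DTW chooses its path from the values themselves, so `r_dtw` is not
exactly 1 for value-offset copies (the path deviates from the diagonal); it
is ≥ `r_raw` on smoothly time-warped material, which is the pattern these
statistics exist to expose.

## The synthetic generator

`generate_dual_recording` splits one source signal between the channels with
weights `w_n = p/100`, `w_o = 1 − p/100` following a prescribed nasalance
profile `p(t)`, then mixes `α·oral` into nasal and `α·nasal` into oral with
`α = 10^(−isolation_db/20)`, and adds independent Gaussian noise per channel
at `noise_floor_dbfs`. Because both channels share the source, the measured
nasalance has the closed form

```
measured = 100 · (n + α·o) / (1 + α),   n = p/100, o = 1 − n
```

(`expected_leakage_bias`), an analytic oracle for the whole pipeline: leakage
compresses readings toward 50%, monotonically in α — a leaky separator reads
oral material high and nasal material low. Source kinds: white noise, sine,
and "speech_like" (200–800 Hz band-limited noise with a 4-Hz, syllable-rate
amplitude modulation) — the latter exercises the analysis band with realistic
dynamics. `apply_time_warp` resamples a recording or trajectory along a
piecewise-linear monotone time map for agreement testing.

What the generator does **not** emulate: spectrally shaped (frequency-
dependent) leakage, room reverberation, microphone frequency response and
directivity, articulatory structure, or F0. Passing recovery tests therefore
demonstrates the correctness of the computation chain under the stated
device model, not clinical validity on real speech.

## Problem sizes and numerics

Tests and the acceptance script use 3–6 s recordings at 44.1 kHz (8 kHz for
gating recounts), 15 profile×isolation recovery cases, 5 warped agreement
pairs, and ≤12-frame DTW oracle checks — sizes at which every quantity is
stable to well under its test tolerance. All randomness flows from explicit
seeds through one `numpy` Generator per call; identical seeds give
bit-identical recordings. 16-bit quantization uses a symmetric divisor of
32768 with round-half-away, so −1.0 is exact and +1.0 saturates at
32767/32768.

## Known limitations

- Raw PCM byte order/signedness is a declared convention (16-bit signed LE);
  files from devices using another dialect need converting first.
- Only sample SD is reported as the variability measure.
- No resampling: trajectories to be compared must be computed with a common
  frame hop (the frame config, not the audio rate, sets the grid).
- Sub-hop lag interpolation is not attempted; lag resolution is one hop
  (25 ms at defaults).
- The display-only nasalance threshold of interactive systems (line vs dot
  rendering) has no numerical role here and is not modeled.
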