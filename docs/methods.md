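# Methods

This note documents the models, numerical choices and limitations behind
`phonalysis`. It is the package's own account of its science; every number it
mentions is computed by the test suite or `scripts/acceptance.py`.

## 1. The marker and its mechanism

A sustained vowel from a breathy (incompletely adducted) larynx carries
aspiration noise generated by turbulent airflow. The voiced source spectrum
rolls off steeply with frequency; turbulence noise rolls off much more
gently. Adding noise therefore raises the high-frequency part of the combined
spectrum while the low frequencies stay voice-dominated. Any low-to-high
spectral energy ratio — the explicit Energy Ratio (ER) over a 4 kHz split, or
MFCC2, whose half-cycle cosine weighting makes it a weighted log-ratio of
low- to high-frequency energy — decreases as breathiness increases.

The upper analysis bound fmax matters: with more of the noise-dominated band
included, the ratio has more contrast to work with. The package therefore
computes MFCC features at both fmax = 8 kHz and fmax = 12 kHz and exposes the
MFCC2 weighting curve remapped to Hz (`mfcc2_weighting_curve`), whose single
zero crossing — the boundary between the "low" and "high" sides of the ratio —
moves up in frequency with fmax.

## 2. Synthetic phonation model

The generator is a classical source-filter chain with cycle-level ground
truth. It is the package's test bed, not a perceptual synthesizer.

**Glottal source.** An impulse train with per-cycle Gaussian perturbations:
period T_i = T0 · (1 + jitter_fraction · ε_i) and amplitude
A_i = 10^(shimmer_db · η_i / 20), with ε, η ~ N(0, 1). The train is shaped in
the FFT domain to a spectral tilt of `source_tilt_db_per_octave`
(default −12 dB/oct) above f0. Realized periods and amplitudes are recorded
in the `truth` log so jitter/shimmer estimators can be validated by
round-trip recovery rather than against other software.

**Vocal tract.** A cascade of two-pole resonators (pole radius
exp(−πB/fs)), one per formant, each normalized to unity gain at resonance.
Defaults model /a/ with five formants, 700/1220/2600/3300/4500 Hz (male) and
×1.15 (female, shorter vocal tract), bandwidths 80/90/120/200/250 Hz.

**Lip radiation.** A first difference (~ +6 dB/oct). Without it the radiated
spectrum is dominated by the first harmonic, which is unphysical — real vowel
spectra peak near F1 — and, because the 133 Hz filterbank floor excludes a
male H1 (≈115 Hz) but not a female H1 (≈215 Hz), an H1-dominated model
produces the wrong sex ordering of MFCC2. With radiation and the F4/F5
resonances in place, male spectra are genuinely skewed toward low
frequencies, and male MFCC2 exceeds female MFCC2 among controls, as observed
in real cohorts.

**Aspiration noise.** White Gaussian noise shaped to
`noise_tilt_db_per_octave` (default −3 dB/oct, flat below 100 Hz) — by
construction shallower than the source tilt — optionally amplitude-modulated
by a raised-cosine glottal-cycle envelope (depth 0.5 by default), optionally
band-limited (used to probe fmax sensitivity), and finally scaled so
RMS(noise)/RMS(voiced) equals `noise_gain` exactly.

**Cohorts.** `simulate_cohort` draws one recording per subject over
(group × sex × replicate). Study conditions (fixed once, not tuned):

| parameter | value | rationale |
| --- | --- | --- |
| f0 | male N(115, 12²) Hz, female N(215, 18²) Hz | population-typical phonation pitch |
| noise_gain, control | LogNormal(median 0.03, σ=0.4) | mild physiological breathiness |
| noise_gain, case | LogNormal(median 0.18, σ=0.4) | audibly breathy, still voiced |
| female breathiness factor | ×1.6 on noise_gain | female phonation is breathier on average (posterior glottal gap; Klatt & Klatt 1990, Hanson 1997) |
| jitter / shimmer baseline | 0.3 % / 0.25 dB | normal-voice perturbation levels |
| age | N(65, 8²) years, both groups | elderly clinical cohort |
| sample rate / duration | 32 kHz / 4 s | supports 12 kHz analysis with margin; survives 0.75 s discard + 2.5 s keep |

The severity levels are free parameters of the simulation — no public
quantitative aspiration levels exist for these diseases — so cohort-level
results are read as directions and orderings, never as absolute effect sizes.

**What the generator does not emulate:** vowels other than /a/, running
speech, room acoustics, microphone/compression artifacts, soft-phonation
hypophonia, tremor, diplophonia, or realistic inter-speaker formant scatter.
Passing tests show the analysis chain responds correctly to the
aspiration-noise mechanism under clean recording conditions; they do not
certify performance on real clinical audio.

## 3. Segmentation

Frame-wise voicing uses the window-corrected normalized autocorrelation
(40 ms Hann frames, 10 ms hop): a frame is voiced iff its peak in the
60-500 Hz lag range is ≥ 0.45 and its RMS is within 40 dB of the loudest
frame. Unvoiced gaps ≤ 0.1 s inside a run are bridged (robustness to brief
dropouts); the longest voiced run is selected (robustness to pre-phonation
noises). The first 0.75 s of the run are discarded as onset transient and up
to 2.5 s of what follows are retained as a contiguous, unmodified sample
slice. If less than 2.5 s remains, ≥ 0.5 s is retained with a warning
(strict mode errors instead); with no voiced run the recording is excluded
from analysis. These retain/warn thresholds are configuration, recorded with
every run.

## 4. Spectral features

- **Welch PSD**: 20 ms Hann windows, 50 % overlap, density scaling
  (Parseval-consistent). Kept separate from MFCC framing.
- **Energy Ratio**: trapezoidal band integrals with exact interpolated band
  edges (0-4 kHz over 4-12 kHz), 10·log10. Errors: no coverage up to fmax →
  `InsufficientBandwidth`; zero high-band power → `DegenerateSpectrum`.
- **Mel filterbank**: triangular, area-normalized filters, centers equally
  spaced on the Slaney mel scale (linear below 1 kHz, log above; HTK variant
  available in config), fmin 133 Hz, 40 filters.
- **MFCC**: 25 ms Hann frames, 10 ms hop, n_fft the next power of two;
  mel energies → 10·log10 → orthonormal DCT-II, 13 coefficients, indexed
  1-based (MFCC1 is the constant energy term). The log floor is *relative*
  (120 dB below each frame's peak mel energy): silence stays finite and
  coefficients k ≥ 2 are exactly invariant to waveform gain, which an
  absolute floor would silently break for clean high-frequency bands. No top
  clipping, so MFCC2 lives in the ~50-150 range typical of real phonation
  analyses rather than being compressed.
- **Spectral contrast**: octave bands 100-200 … 3200-6400 Hz; per frame and
  band, 10·log10 of the ratio between the mean top-2 % and bottom-2 % of
  spectral *magnitudes* (≥ 1 bin each). Contrast uses longer 64 ms frames so
  the 100-200 Hz band spans several FFT bins; too-narrow bands merge into
  their lower neighbor with a warning.
- **Spectral flatness**: geometric/arithmetic mean of the power spectrum per
  frame (DC excluded), in [0, 1].

## 5. Voice quality

- **Pitch**: two-pass autocorrelation tracking. The first pass over the full
  60-500 Hz range fixes the median f0; the second narrows the lag range to
  ±0.7 octave around it (octave-error guard). Within the search the
  *shortest* lag within 0.01 of the maximum r is preferred, since a doubled
  period scores as high as the true one for periodic signals. Peaks are
  parabolic-interpolated for sub-bin f0. The semitone range is
  12·log2(max/min) after trimming the top/bottom 1 % of voiced frames.
- **Cycle marks**: coarse candidates are peaks of the brick-wall fundamental
  band (0.5-1.5 × median f0); each is refined to the parabolic-interpolated
  maximum of |x| within ±0.35 periods — the excitation burst, whose timing is
  much sharper than the narrowband fundamental's (the narrowband filter
  smooths cycle-to-cycle timing and would attenuate measured jitter).
  Periods are mark-to-mark intervals; cycle amplitude is the interpolated
  burst height. Duplicate refinements are dropped.
- **Jitter (localabs)** = mean |T_i − T_{i−1}| in seconds;
  **shimmer (local, dB)** = mean |20·log10(A_{i+1}/A_i)|. Both need ≥ 3
  cycles. Validated against the synthesis truth log (20 % / 25 % recovery
  tolerances at 1 % jitter and 0.5 dB shimmer).
- **HNR** per voiced frame: r = interpolated autocorrelation peak at the
  pitch lag, HNR = 10·log10(r/(1−r)), with r clamped to [1e−6, 1−1e−6]
  (±60 dB cap).
- **CPP** per 40 ms frame: real cepstrum of the dB power spectrum; peak in
  the 2-16.7 ms quefrency range; least-squares trend line fitted over that
  same range only; CPP = peak minus trend at the peak quefrency. The dB
  spectrum uses the same relative floor as the MFCCs, making CPP exactly
  gain-invariant. Absolute CPP values depend on cepstrum scaling conventions
  and are not comparable across implementations; within-package contrasts
  (clean vs breathy, trends along noise sweeps) are what the package relies
  on.

All quality metrics are scale-invariant by construction; the suite asserts
|Δ| < 1e−6 under a ×10 gain.

## 6. Cohort statistics

- **AUC** of a scalar marker is the full threshold sweep, computed exactly as
  the normalized Mann-Whitney pair count with ties worth 0.5 (rank-based
  implementation; verified against brute-force pair enumeration and, in
  tests only, scikit-learn). Direction is explicit: cases are expected
  *lower* on MFCC2/ER, so AUC > 0.5 means separation in the pathological
  direction.
- **Bootstrap CI**: percentile interval from stratified (within-class)
  resampling, 2000 replicates, seeded. Percentile rather than BCa for
  transparency; with < 5 per class a warning is emitted.
- **Correlation screen**: Pearson and Spearman both available (config
  default spearman); features whose max |r| against any MFCC feature exceeds
  0.3 are retained. Constant columns correlate 0 with a warning.
- **Model selection**: OLS over all subsets of the candidate factors
  (default {sex, age}, controls only, since group and severity are
  confounded by design); AIC = n·ln(RSS/n) + 2(p+1) with p the number of
  mean parameters; listwise deletion; rank-deficient designs error. The
  2-point penalty admits a spurious single factor ~16 % of the time — the
  calibration test asserts ≥ 80 % rejection, which is what AIC can deliver.
- **One-way ANOVA**: classical F test; the degenerate all-equal case returns
  F = 0, p = 1. Null p-values are checked for uniformity (KS test over 200
  replicates).

## 7. Problem sizes and determinism

The default analysis cohort is 120 recordings (2 groups × 2 sexes × 30) of
4 s at 32 kHz; the fmax-sensitivity cohort is 60 recordings with noise
band-limited to 8-12 kHz. These sizes give stable orderings and correlations
while keeping a full simulate→extract→analyze run around a minute on one
CPU. Every stochastic step (synthesis, bootstrap) takes an explicit seed;
fixed seeds reproduce waveforms bit-for-bit and reports byte-for-byte.

## 8. Known limitations

- Jitter/shimmer/CPP/HNR are this package's estimators, not bit-compatible
  reimplementations of Praat's; only their definitions match the named
  variants ('localabs', 'local dB').
- The noise-severity scale is synthetic; AUCs on the default cohort are far
  higher than on real clinical data because the generator contains exactly
  the mechanism the markers detect, with no nuisance variation from
  recording hardware, compression, or within-subject variability.
- Analyses above ~12 kHz are untested territory: real recordings often
  contain hardware noise there, which is one reason the default ER/MFCC
  upper bound stops at 12 kHz.
- The cycle-mark refinement assumes one dominant excitation per cycle; it
  has not been designed for diplophonic or creaky voice.
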