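# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind the `dichotic` package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Stimulus synthesis

All stimuli are stereo, 44.1 kHz (so the noise bandwidth extends to the
22.05 kHz Nyquist frequency), one second per interval, three intervals per
trial separated by silent gaps. Absolute playback level is the listener's
responsibility (a volume-calibration step outside this package), so every
interval is normalised to a common reference RMS of 0.05 full scale before
any per-test level offset; this keeps 16-bit PCM output far from clipping
even after intervals are summed with tones.

**Huggins Pitch (HP).** White noise is zero-mean Gaussian, normalised to the
reference RMS. The dichotic pair is built in the frequency domain on the
one-sided (rfft) spectrum: every bin whose centre frequency lies in
`600·(1±0.06)` Hz = [564, 636] Hz — *inclusive* at both edges, the simplest
convention — is multiplied by exactly −1 (a 180° shift; using −1 rather than
`exp(iπ)` avoids a ~1e−16 imaginary residue). The one-sided transform keeps
the output purely real, and magnitudes are untouched everywhere, so neither
channel alone carries a cue. A zero-width band (`band_fraction = 0`) is
treated as empty and returns an exact copy. Noise intervals get 5-ms
raised-cosine on/off ramps (configurable to 0): onset clicks would be an
artifactual monaural cue. The spectral invariants (equal magnitudes,
untouched out-of-band bins) are stated for the raw Huggins pair; trial
assembly then applies the common ramp to both channels, which preserves the
interaural relationships that matter but smears bin-level identities
slightly.

**Anti-Phase (AP).** A 200-Hz tone with 100-ms raised-cosine ramps,
normalised to the reference RMS, serves as the diotic standard; the diotic
target is the standard scaled by 10^(−6/20); the foil is the standard in one
channel and its negation in the other, so each foil channel's RMS equals the
standard's exactly. The target occupies the specified slot; standard and
foil are assigned to the two remaining slots uniformly at random per trial
(the original protocol fixes only the target's position statistics).

**Beat Test (BT).** One f1 per trial is drawn uniformly from
[1800, 2500] Hz; f2 = f1 + 30 Hz. Standards carry the diotic sum of both
tones; the target carries one tone per ear, with the f1-ear randomised per
trial. All tones get 5-ms raised-cosine ramps, each channel is normalised to
the reference RMS, and each interval is independently attenuated by
0–4 dB (uniform), so pairwise interval level differences never exceed 4 dB
and loudness is useless as a cue.

**Ramps.** The raised-cosine ramp follows `g(k) = (1 − cos(πk/(r−1)))/2`
over r samples, so the first and last samples are exactly zero and the ramp
midpoint sits at gain 0.5 within one sample's resolution.

**Pools and reproducibility.** A pool holds 12 trials with target positions
a seeded shuffle of four 1s, 2s and 3s. Per-trial randomness comes from the
child seed `SeedSequence((pool_seed, 1, trial_index))` (positions use stream
0), so any single trial is regenerable in isolation. All output is
byte-for-byte reproducible from (config, seed). WAV output is stereo 16-bit
PCM, channel 0 = left, with a JSON manifest as the answer key.

**Example (practice) trials** are fully diotic so they sound identical on
any equipment: HP adds a diotic 600-Hz tone to one noise interval at a
configurable tone-to-noise ratio (default 0 dB); AP presents two equal
standards and the softer diotic target. The BT example (a diotic single tone
among two beating pairs) is a synthetic extension for protocol completeness;
the deployed tests define practice examples only for HP and AP, and it is
flagged as such in the trial metadata.

## Protocol

Blocks are 6 trials drawn without replacement from a pool, order
randomised. A response is correct iff it names the target interval; chance
is 6/3 = 2 correct. Pass thresholds 3–6 of 6 are the above-chance operating
points; the conjunction ("Both") rule accepts only subjects passing two
tests at the same threshold. Block order across the four conditions uses a
cyclic 4×4 Latin square with the row given by `participant_index mod 4`
(the original study names the design but not the square). Failure to hear
the practice target is recorded as an exclusion flag, not enforced
interactively. Responses are 1-based interval indices throughout.

## Virtual listeners

The simulator exists to validate the statistics pipeline without human
data; it is not an auditory model.

*Playback* is a linear 2×2 channel-to-ear mixing matrix, optionally with a
cross-path delay: identity (headphones), `full_mix` (both ears get
(L+R)/2), `crosstalk(c)` (each ear gets 1−c of its own channel and c of the
other; c = 0.5 is the full mix), and `delayed_mix(c, d)` for off-centre
loudspeaker geometries, under which the anti-phase foil no longer cancels.

*Decision statistics* are the simplest physics-faithful detectors of each
cue, with zero-mean Gaussian internal noise added at the statistic level
(keeping behaviour analytically checkable):

- HP: power of (earL − earR) inside [564, 636] Hz divided by earL's
  broadband power; choose the maximum. Under `crosstalk(c)` the interaural
  difference scales by (1 − 2c), so the statistic scales by (1 − 2c)².
- AP: mean of the two per-ear RMS levels; choose the minimum (the
  "quietest" task). Under the full mix the foil is exactly silent, so the
  listener always picks it — accuracy 0, the below-chance signature.
- BT: Hilbert-envelope modulation depth at 30 Hz (2|E(f)|/mean envelope,
  ears averaged); choose the minimum (the "smoothest" task). The envelope is
  trimmed by the ramp duration at each end and then truncated to a whole
  number of beat periods, so a constant envelope contributes exactly zero
  rather than spectral leakage from the segment ends.

Ties within 1e−9 (relative) are treated as exact and broken uniformly from
the listener's seeded RNG: physically identical intervals can differ by
float round-off, and the tie-break — not numerical noise — should decide
them.

*Cohorts.* Each subject draws a headphone model, a loudspeaker model and an
internal-noise SD, then performs each test once per equipment condition on
shared pre-generated pools (matching deployment; per-subject pools are an
option). Statistics are deterministic per (trial, playback model) and are
cached across subjects. The packaged `mixed_equipment_cohort_spec` emulates
realistic variability: headphone channel bleed uniform on a 9-point grid
over 0–40% (bleed above ~25% makes the anti-phase foil quieter than the
−6 dB target, so AP degrades long before HP), the symmetric full mix for
loudspeakers, and internal noise uniform on [5e−4, 4e−3] — scaled to the HP
statistic, whose target value is ≈ 4 × (band width / Nyquist) ≈ 0.013, so
headphone HP performance is near ceiling with occasional 5/6 scores. These
choices reproduce the qualitative score-distribution signatures
(all-or-nothing HP over headphones, chance HP and below-chance AP over
loudspeakers) and the AUC ordering HP > AP; they make no claim to predict
human pass rates, and omit room acoustics, head shadow, reverberation and
hearing impairment entirely.

## Signal-detection analysis

ROC points are the (false-alarm, hit) pass-rate pairs at thresholds 6, 5,
4, 3, plus the degenerate accept-none (0,0) and accept-all (1,1) anchors;
AUC is the trapezoidal area over points sorted by false-alarm rate
(monotonicity is checked, and holds by construction for threshold sweeps).
d′ uses the standard-normal quantile difference; when a cohort size N is
supplied, rates of 0 and 1 are clipped to 1/(2N) and 1 − 1/(2N) before
inversion.

Bootstrap inference resamples whole subjects (all four condition scores
together) with replacement at the original cohort size and counts resampled
AUC differences strictly above and strictly below zero (exact zeros count in
neither direction); the two-sided p is twice the smaller proportion, floored
at 1/n_resamples rather than reported as 0. The permutation test swaps (or
keeps) the two tests' headphone scores independently per subject, likewise
the loudspeaker scores, and counts null differences *at least as extreme* as
the observed one in each direction — ties count as extreme, which is the
conservative convention and makes the degenerate identical-columns case
yield p = 1 rather than 0. Both default to 10,000 iterations
(CLI-overridable); the AUC resampling core is vectorised, so 10,000
iterations on a 100-subject table take well under a second.

## Mixture estimation

The unknown cohort's score histogram per test is modelled as
`p·headphone_reference + (1 − p)·loudspeaker_reference` with one p shared
across tests (the one-parameter reading that keeps distributions
normalised). p is fit by grid search over 0, 0.01, …, 1 on the summed
squared error across all tests and all 7 bins, comparing proportions (not
counts) with equal test weights. Grid ties resolve to the smallest p —
conservative about claiming headphone use — and set a tie flag. For exact
mixtures the SSE profile is a discretised parabola with its minimum at the
true proportion, so recovery is exact on the grid. An optional parametric
bootstrap (multinomial resampling of the unknown histograms) provides a
percentile interval; it is an extension and off by default.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to keep
Monte-Carlo error well inside each tolerance: 10,000 guessing blocks for
the chance level, 10,000 zero-noise decisions for the full-mix accuracy
checks, cohorts of 50–100 subjects, 40 cohort seeds for the AUC-ordering
check, 500 null tables × 1,000 permutations for type-I calibration (null
tables use the 100-subject cohort size; smaller tables make the discrete
AUC-difference null noticeably conservative), and 100–200 multinomial draws
for mixture recovery. Resampling counts are CLI-overridable up to 10⁶ for
publication-grade inference.

## Known limitations

- The virtual listeners validate the pipeline; none of their accuracies or
  AUCs are predictions of human performance, and empirical human AUC values
  cannot be reproduced here because no subject-level data are distributed
  with the tests.
- The playback models are memoryless 2×2 mixes (plus a pure delay); real
  rooms add reverberation and frequency-dependent interference.
- The mixture estimator assumes the unknown cohort is a two-component mix
  of the reference conditions; listeners in noisy environments or with
  unusual equipment violate this.
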