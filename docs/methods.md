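# Methods

## The TFS1 paradigm and what this package computes

In the TFS1 discrimination task a listener must tell a harmonic complex
tone H (components at k·f0, k = 1, 2, …) apart from an inharmonic complex I
whose components are all shifted upward by the same amount Δf (expressed in
percent of f0). Because the component *spacing* is unchanged, the envelope
of both stimuli is periodic at f0; only the temporal fine structure under
that envelope differs. Band-pass filtering around a center frequency
fc = N·f0 (harmonic rank N = 4 or 8), plus a pink-noise masker, removes
excitation-pattern and distortion-product cues, leaving fine structure as
the intended cue. The package synthesizes these stimuli, generates
auditory-nerve-like spike trains with known locking properties, measures
phase locking with vector-strength/Rayleigh statistics, estimates
behavioral thresholds from Go/No-Go sessions, and models place cues with
ERB-scaled excitation patterns.

## Stimulus synthesis

Components run from f0 up to 9 kHz, each synthesized at a per-component
level (default 60 dB SPL) with a random starting phase drawn once per trial
and shared between the H and I members of a pair (so their envelopes
match). Levels use a fixed digital calibration, RMS 1.0 ≡ 94 dB SPL (1 Pa);
no digital reference is implied by the physical quantities, so any fixed
convention reproduces all relative and dB SPL values.

The band-pass is a Butterworth design (order 3 for the neural context,
5 for the behavioral one) whose −3 dB points sit at fc ± 3.5·f0, giving a
flat region of 5·f0. The asymptotic skirt slope of an order-N Butterworth
band-pass is 20·N·log₁₀2 ≈ 6.02·N dB/octave: 18 dB/oct at third order,
30 dB/oct at fifth. Filtering is causal (forward-only, second-order
sections), matching a real-time playback chain; the digital filter's low
skirt realizes the analog slope while the high skirt is slightly steeper
from bilinear warping — slope checks are therefore made on the low skirt.
Per-component level is defined *before* the filter; the filter then
attenuates skirt components. Under this reading the 60 dB components of the
200/1600 condition sum to 68.5 dB SPL overall (power sum of the filter
gains at the component frequencies; ≈ 60 + 10·log₁₀7).

The pink masker is synthesized in the frequency domain: each retained rfft
bin between 100 and 11050 Hz receives amplitude √(2·S(f)·Δf) with
S(f) ∝ 1/f anchored at 13 dB SPL/Hz at 1 kHz, and a random phase. This
makes the PSD exact by construction rather than rescaled after estimation.
Integrated over a gerbil ERB centered at 1 kHz the masker carries ≈ 37 dB
SPL.

The Δf ladder divides the 42.5 % maximum by successive powers of two down
to 0.33 %, with optional extra values (31.87 %, 15.94 %) merged in.

### Envelope periodicity rather than envelope peak

The Hilbert envelope of a filtered complex is periodic at f0 but rich in
harmonics of f0; which harmonic carries the most envelope power depends on
the phase draw. The package therefore quantifies envelope periodicity by
the smallest autocorrelation lag reaching 95 % of the autocorrelation
maximum (`envelope_periodicity_hz`), which is f0 for every phase draw and
condition tested, instead of the raw spectral peak, which is not.

## The spike-train generator

The generator exists to provide *ground-truth locking*, not biophysics. It
is an inhomogeneous Poisson process, simulated exactly by thinning, with an
absolute dead time (default 0.7 ms, above the 0.6 ms interspike-interval
criterion used to screen recorded units). The intensity is

r(t) = max(0, SR + D·(1 + g_env·Ê(t) + g_tfs·F̂(t))),

where SR is the spontaneous rate, D the mean driven rate, and Ê/F̂ the
zero-mean unit-peak envelope and unit-peak fine structure of the stimulus
after a half-octave, fourth-order band-pass at the fiber's best frequency
(a crude cochlear filter that makes envelope/fine-structure separation
meaningful). Normalization uses the post-transient portion of the signal
(first 25 ms excluded) so the causal filter's onset does not crush the
modulation depth; g_env + g_tfs ≤ 1 keeps r non-negative before
rectification matters. A silent input yields r = SR.

Defaults mirror the study conditions the analyses expect: 40 repetitions
per stimulus, 0.4 s stimuli analyzed over the 375 ms steady state
(12.5 ms fringes excluded), spontaneous rates spanning the low/high class
boundary at 18 spikes/s (population preset draws 0–18 and 18–144 sp/s,
matching the reported 0–144 sp/s range), driven rates of tens to ~200 sp/s
(reported stimulated rates reach 223 sp/s).

What the generator does *not* emulate: adaptation, relative refractory
recovery, level-dependent envelope enhancement, across-fiber correlations,
and the phase-locking roll-off above ~1.5 kHz. Passing tests therefore
show that the *metrics* recover known locking structure from point-process
data, not that the generator reproduces auditory-nerve physiology.

## Phase-locking metrics

Vector strength is computed per repetition, V(f) = |1/N Σᵢ e^(−i2πf tᵢ)|,
averaged over repetitions with at least one spike (zero-spike repetitions
are excluded from the V average but count as zero in N_avg); the Rayleigh
statistic is z = N_avg·V_avg². For a single unlocked train z is
approximately Exp(1); averaging V across 40 repetitions concentrates z far
below the z = 13.8 significance bound, and all significance statements in
the package use the averaged form.

The vector-strength *spectrum* pools all-order interspike intervals — all
signed pairwise spike-time differences within a repetition, including the
zero-lag self pairs — into a 50 µs histogram over ±375 ms, applies a
zero-centered Gaussian window (SD 200 ms) to suppress fringe effects,
normalizes by the total pair count, and takes the square root of the FFT
magnitude. Including the self pairs is what makes the identity exact for a
single train: Σᵢⱼ e^(−i2πf(tᵢ−tⱼ)) = N²V², with N² total pairs. The
frequency resolution is 1/0.75 s = 1.333 Hz. The Gaussian window biases
spectrum VS slightly relative to the direct estimator (|bias| < 0.05 on
simulated trains; with the window disabled the spectrum equals the pooled
N²-weighted RMS of single-repetition VS values to < 0.02, the residual
being 50 µs binning).

Two contrasts summarize one fiber × one shift:

- **TFS log-z-ratio** = log₁₀(z₀ / z_Δf): z₀ at the maximal-response
  harmonic f_maxpeak from the harmonic response, z_Δf at f_maxpeak + Δf
  from the inharmonic response (default "cross" mode; a "within" mode takes
  both from the inharmonic response, since published descriptions support
  either reading). Positive = fine structure of the harmonic stimulus is
  better represented.
- **ENV/TFS log-z-ratio** = log₁₀(z(f0) / z(f_maxpeak + Δf)), both from
  the inharmonic response. Positive = envelope-dominated locking, negative
  = fine-structure-dominated.

Log base 10 is used; the base changes scale only, and every assertion on
these ratios is sign- or order-based. Zero or undefined z in a denominator
flags the ratio as undefined rather than returning ±∞. f_maxpeak is the
passband harmonic maximizing the population-average z; classes are assigned
at SR ≤ 18 sp/s and BF ≤ 1850 Hz.

The z-peak shift search evaluates z at base + Δf for every ladder entry
(ties go to the smaller shift). One caveat established during validation:
for an unlocked fiber the argmax is uniform over the ladder only when the
shifted frequencies are separated by more than the ~2.7 Hz resolution of a
375 ms window; sub-resolution neighbors share correlated z values and split
wins between them. The uniformity property is therefore tested on a
resolvable ladder (shifts ≥ 2.65 % at f0 = 400 Hz).

Tuning metrics follow the standard two-criterion rule: threshold is the
lowest level whose rate exceeds both SR + 1.2·SD(SR) and 15 spikes/s;
bandwidth is read at 50 % of the maximal driven rate by linear
interpolation, flagged one-sided when a crossing is missing. PSTH bins are
one tenth of the f0 period (0.5 ms at 200 Hz, 0.25 ms at 400 Hz); driven-
and spontaneous-rate histograms use 2.5 and 5 sp/s bins, the driven
histogram normalized to relative frequency and smoothed with a 3-bin moving
average (the histogram is padded with empty edge bins so smoothing
conserves total mass).

## Behavior

Sessions contain 10 blocks of 9 trials (6 test + 3 sham); block 0 is a
warm-up at Δf = 42.5 % excluded from analysis; sham trials never follow one
another within or across blocks; the least salient condition (200/1600)
never occupies consecutive blocks; a motivator trial follows each correct
rejection and is excluded. A session counts only if all 90 trials are
completed with a false-alarm rate ≤ 20 %.

d′ = z(hit) − z(false alarm), with 0/1 rates corrected by 1/(2n). The
false-alarm rate entering d′ is pooled per condition over accepted sessions
(a per-session option exists). The threshold cascade at d′ = 1: linear
interpolation between the first shift with d′ > 1 and its predecessor;
else a least-squares line through all (Δf, d′) points extrapolated to
d′ = 1 ("no shift exceeds 1" is the trigger, reconciling mixed wording);
if every shift exceeds 1, half the smallest measured shift; a non-positive
slope or an out-of-range extrapolation caps the threshold at 100 %.
Interpolation is exact when d′ is linear in Δf through the crossing; the
simulated observer's d′(Δf) = slope·log₂(Δf/θ) + 1 is recovered with a
small (< ~6 %) convexity bias, well inside the ±20 % recovery criterion
(median estimate 8.3 % for a true 8 % threshold over 50 seeds).

The simulated observer responds "go" on sham trials with probability equal
to its false-alarm rate and on test trials with probability
Φ(Φ⁻¹(fa) + d′(Δf)); sessions are assembled under all ordering
constraints, and trials cycle the ladder so every (condition, Δf) cell
fills evenly.

## Excitation patterns

Auditory filters are symmetric, level-independent rounded exponentials
roex(p) with p = 4·CF/ERB(CF), so the filter's equivalent rectangular
bandwidth equals the nominal ERB; the human baseline is Glasberg–Moore
ERB = 24.7·(4.37·F_kHz + 1) Hz and the gerbil scale is 1.8. Component
sources are power-summed through the filter weights; noise PSDs are
integrated against them. The CF grid is 96 points/octave from 500 Hz to
6 kHz, dense enough that the maximum-difference search error is below
0.05 dB. Discriminability compares max |E_H − E_I| against a user-supplied
intensity difference limen (the relevant gerbil limen is not built in).
Under these assumptions only the rank-4 condition (400/1600) yields an
excitation difference above a ~1 dB limen at ~10 % shifts, and the pink
masker's excitation stays within 30 dB of the complexes across the
passband, so distortion products are masked — the place-cue control the
model exists for. No compression, suppression, or level-dependent
asymmetry is modeled, and percentile bands of amplitude statistics are out
of scope.

## Pipeline, sizes and determinism

`run_pipeline` derives per-stage child seeds from one master seed via
`SeedSequence` (all below 2³¹) and writes a manifest with hashes; reruns
with the same seed are byte-identical. Default demo sizes (a few fibers
per spontaneous-rate class, 40 repetitions, 20 trials per behavioral cell)
keep a full run under a minute on one core while exercising every stage;
the statistical test suites use 100–1000 replicates per property, chosen
so the whole suite runs in well under a minute of compute per module.

## Known limitations

- The generator's locking gains are phenomenological; absolute z values
  depend on them and on driven rate, so only signs, orderings and
  significance bounds are asserted, not population means of the log-z
  ratios (which depend on real-fiber physiology).
- The "cross" vs "within" reading of the TFS log-z-ratio is configurable
  because the two published descriptions differ; defaults follow the
  methods-style (cross) reading.
- Excitation patterns are a screening model, not a fit to measured gerbil
  filters.
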