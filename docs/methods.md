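# Methods

## The measurement chain

`samph` implements the Spectral-Amplitude Modulation Phase Hierarchy (S-AMPH)
analysis of speech: a two-stage filterbank decomposition of the speech
envelope, followed by energy and phase-synchronisation measures of the nested
amplitude-modulation (AM) bands.

1. **Standardisation.** Each mono segment is z-scored to mean 0 and
   *population* standard deviation 1 (we standardise a fixed signal, we do not
   estimate a dispersion), so all downstream measures are amplitude-unit free.
2. **Spectral filterbank.** Five adjacent FIR band-passes with edge
   frequencies 100, 300, 700, 1750, 3900, 7250 Hz.  Band 1 (100–300 Hz)
   corresponds to the fundamental-frequency region of adult speech.
3. **Envelopes.** The Hilbert envelope (magnitude of the analytic signal) of
   each band at the audio rate, then polyphase-resampled to the envelope rate
   of 1050 Hz (the rate ratio is taken as the nearest rational with
   denominator ≤ 1000; ringing negatives are clipped to zero).
4. **AM decomposition.** Each envelope is band-passed into delta (0.9–2.5 Hz),
   theta (2.5–12 Hz) and beta/low-gamma (12–40 Hz) AM waveforms —
   stressed-syllable, syllable and phoneme-scale timing respectively.
5. **Modulation spectrum.** 24 channels with logarithmically spaced edges over
   0.9–40 Hz.  Per spectral band, channel power is expressed as the relative
   difference from the across-channel mean, `D_c = (P_c − P̄)/P̄`, so the
   spectrum is unitless, invariant to envelope scaling, and has exact zero
   mean over channels; the five per-band spectra are then averaged.
6. **Band energy.** The signed area under the differenced spectrum within each
   AM band, integrated against log10 frequency (channels are log-spaced, so
   log-domain integration weights octaves evenly).  Band limits falling
   between channel centers are linearly interpolated, which makes the three
   band areas partition the full-range area exactly.
7. **Phase synchronisation.** For each spectral band, the instantaneous phases
   of the AM waveforms (angle of the analytic signal) enter the n:m phase
   synchronisation index
   `PSI = |⟨exp(i(n·θ1 − θ2))⟩|`, with n = 2 for delta–theta and n = 3 for
   theta–beta/low-gamma; θ1 is always the slower band's phase (the theta rate
   sits near twice the delta rate, beta/low-gamma near three times theta).
   Computed on complex unit phasors the statistic is wrapping-invariant and
   bounded in [0, 1].  PSIs are averaged over the five spectral bands within
   a segment and over a participant's segments (per speech register), both
   unweighted.
8. **Speech rate.** Per-segment manual syllable count divided by duration;
   participant rate is the unweighted mean of segment rates per register.

## Numerical choices

* **Filters.** All band-passes are windowed-sinc (Hamming) FIRs applied
  forward–backward (via FFT convolution), hence exactly zero-phase.  This is
  load-bearing: PSI compares instantaneous phases across independently
  filtered bands, and any differential group delay would masquerade as
  (de)synchronisation.  A band-passed click cross-correlates with its input
  at lag 0 for every filter in the chain (verified in the tests).
* **Filter order.** Target transition width is 25% of the band's low edge.
  For modulation-rate bands this ideal order can exceed the signal, so the
  order is capped at one third of the signal length, with a floor of one
  cycle of the band's low edge; below the floor the input is rejected as
  degenerate (≈3.3 s for the delta band at 1050 Hz).  Realised orders adapt
  to segment length; analyses of segments shorter than ~10 s therefore use
  gentler modulation filters.
* **Edge handling.** Signals are reflect-padded by one filter length before
  filtering; phase series are additionally trimmed by 0.5 s per end
  (configurable) before the PSI average, and modulation-channel powers are
  computed after the same trim, because delta-band filters ring for hundreds
  of milliseconds.
* **Channel power normalisation.** Channel mean-square power is divided by
  the equivalent noise bandwidth of the realised (two-pass) channel filter,
  measured from its frequency response.  Log-spaced channels differ in
  bandwidth by a factor ~44 across the range; without this PSD-style
  normalisation a spectrally flat envelope would produce a strongly tilted
  "spectrum".  Raw mean-square power remains available as an option, as does
  a plain difference `P_c − P̄` in place of the relative difference.
* **MANOVA.** One-way Wilks' Λ with Rao's F approximation and
  partial η² = 1 − Λ^(1/s), computed from the within/between SSCP matrices
  directly; agreement with statsmodels' MANOVA is enforced in the tests.  For
  3 groups, 2 dependents and N = 46 this yields the familiar F(4, 84) layout.
* **Mixed repeated-measures ANOVA.** The 3 × 2 × 5 design (literacy group
  between; AM band pair and spectral band within) uses standard univariate
  mixed-model sums of squares with subjects nested in groups and uncorrected
  degrees of freedom; the decomposition reproduces R's
  `aov(... + Error(subject/(A*B)))` to six significant digits on a frozen
  unbalanced fixture.  No installed Python package offers this
  two-within-factor mixed design in one call, hence the in-house
  implementation.
* **Post-hocs and the rest.** Tukey–Kramer via the studentised-range
  distribution (cross-checked against `scipy.stats.tukey_hsd`); Pearson and
  Spearman (midranks) correlations, Kruskal–Wallis, Mann–Whitney (exact for
  small tie-free samples) and Shapiro–Wilk through scipy.  The Bonferroni
  family for the correlation matrix is the number of cells actually computed
  and is declared in the report.

## The synthetic generator

Real conversational recordings of this kind are rarely shareable, so every
stage is validated on synthetic audio whose modulation hierarchy is known
exactly.  A segment is the sum over the five spectral bands of a band-limited
noise carrier (unit variance; a tone-stack mode exists for closed-form tests)
multiplied by the product of three nonnegative modulators
`1 + depth·cos(φ_j(t))`.

* **Coupling.** Phases are chained: `φ_theta = 2·φ_delta + ε_dt(t)` and
  `φ_bg = 3·φ_theta + ε_tbg(t)`.  Each jitter process ε is slow (flat
  spectrum over 0.08–0.4 Hz) with an exactly von Mises(0, κ) marginal,
  obtained by mapping a band-limited Gaussian process (synthesised in the
  Fourier domain, exact N(0,1) marginal) through the Gaussian CDF and the von
  Mises quantile.  The expected PSI on the true phases is the Bessel ratio
  I₁(κ)/I₀(κ); κ → ∞ gives deterministic locking (PSI = 1).  The jitter is
  slow rather than i.i.d. because i.i.d. jitter at 1050 Hz is broadband noise
  no modulation filter could pass, while speech-like desynchronisation
  evolves over seconds.  The band's lower edge (0.08 Hz) exists because the
  modulus in Eq. 1 removes constant offsets entirely: jitter that does not
  mix within a segment cannot reduce the PSI, and would bias per-segment
  values above the ensemble target.
* **Independence.** κ = 0 means *independent* modulators.  Bounded jitter
  cannot express independence (it keeps the fast phase within ±π of its
  locked position, flooring the PSI at the finite-mixing level ≈ √(π/4N_eff)),
  so κ = 0 instead draws a free-running relative-phase drift — a frequency
  offset of 0.1–0.4 Hz plus a uniform start — which cycles the generalised
  phase difference through the whole circle and drives the PSI to its random
  floor.
* **Rates.** The 1:2:6 phase chain fixes the modulator rates at f_delta,
  2·f_delta and 6·f_delta.  Default f_delta = 2.3 Hz with ±8% per-segment
  jitter keeps every realised rate inside its nominal AM band
  (delta ≤ 2.5 Hz, beta/low-gamma ≥ 12 Hz); wider jitter would push
  modulators across band edges and destroy their band identity.
* **Depths** default to 0.5 in every band (clear modulation without clipping
  the nonnegative gain).
* **Cohorts.** The default cohort spec describes a three-group design: 15
  illiterate, 19 low-literate and 12 high-literate participants contributing
  89/107/90 conversational segments (3–11 each, drawn durations 4–20 s) plus
  6 rhythmic proverb segments (4–8 s; real proverbs are shorter, but
  segments under ~3.3 s cannot carry a delta-band filter, so the generator
  stays above that).  Per-participant coupling concentrations are drawn from
  group distributions — conversational κ means (1.2, 3.5, 4.5), SD 0.3, i.e.
  a weakly coupled illiterate group; rhythmic κ = 8 for every group, so
  deliberately rhythmic speech shows no group differences.  Group speech
  rates (3.2, 3.4, 4.2 syll/s) make only the high-literate group faster.
  Behavioural scores are drawn from group-level normal distributions with
  means and SDs plausible for an elderly cohort spanning zero to
  university-level literacy (they are manifest inputs, not acoustic
  measures).  There is no canonical set of quantitative PSI group means to
  reproduce, so these effect sizes are calibration choices of the generator.
* **Determinism.** Everything derives from one integer seed
  (`numpy.random.SeedSequence`); identical spec + seed reproduces the WAV
  files bit for bit.

## What the synthetic tests do and do not show

The generator emulates the *modulation structure* of speech — nested,
hierarchically coupled AM bands over speech-band carriers — not speech
itself: no formants, phones, pauses, prosodic phrase structure, or
Portuguese phonotactics, and carrier statistics are Gaussian.  Passing tests
therefore demonstrate that the measurement chain recovers known coupling,
energy distribution and group differences from signals with speech-like
temporal statistics; they do not certify effect sizes on real recordings.

Two quantitative caveats, both properties of the construction rather than of
the code:

* **Finite-segment bias.**  PSI is the modulus of a time average; over a 30 s
  segment the slow jitter yields N_eff ≈ 20–40 effective samples, so at weak
  coupling the per-segment PSI sits above the Bessel ratio (e.g. ≈0.29
  vs 0.24 at κ = 0.5).  End-to-end recovery is therefore assessed against the
  PSI computed on the generator's true phases, with the Bessel ratio as the
  long-run limit (verified separately on long modulator-only runs).
* **Intermodulation ceiling.**  The *product* of modulators creates
  sidebands; the theta × beta/gamma sideband at f_bg − f_theta (~9.2 Hz)
  falls inside the theta band and wobbles the estimated theta phase by
  ~depth/2 radians, which the n = 3 multiplier triples.  Even with noiseless
  tone carriers and deterministic locking, the recovered theta–beta/gamma
  PSI saturates near 0.74 (delta–theta: ≈0.95).  Coupling-recovery tests
  therefore quantify the delta–theta pair; theta–beta/gamma retains the same
  monotone ordering and is what the cohort-level comparisons use.

## Problem sizes used in validation

Tests and analysis drivers run at desk scale: coupling recovery uses 6
segments × 30 s per κ ∈ {0.5, 1, 2, 4, 8} with common random numbers across
the grid (the same carrier noise and jitter path transformed through each
κ's quantile — a variance-reduction choice that isolates the κ effect for the
strict-monotonicity check); the cohort-pattern check uses 3 participants per
group × 3 segments per register × 10 s; statistics calibration uses 1000
summary-level null cohorts and 100 effect cohorts at the full 15/19/12 group
sizes.  The demo analysis in `analysis/` uses the same reduced cohort; the
full-design cohort is generated as manifest + ground truth for the
book-keeping checks.

## Known limitations

* Segments shorter than ~3.3 s cannot be analysed (delta filter floor); real
  proverb repetitions of 1–3 s would need either a higher delta low edge or
  concatenation before analysis.
* The modulation spectrum of short segments (<10 s) uses length-capped
  channel filters whose transition bands exceed the narrow low channels;
  per-channel estimates below ~2 Hz are then smoothed versions of the truth.
* Between-register comparisons assume the registers were recorded with the
  same equipment and segmentation conventions; the package treats segment
  boundaries as given and performs no pause handling or speech/silence
  segmentation.
* The statistics layer validates against independent oracles and Monte-Carlo
  calibration rather than against fixed empirical values: no real recordings
  ship with the package, so its guarantees concern the correctness of the
  tests, not any particular field result.
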