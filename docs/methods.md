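# Methods

This note documents the models, estimators, parameter choices and known
limitations of the `betadyn` pipeline. It is written for a reader who wants
to know exactly what the code computes and why, and what passing tests on
synthetic data do and do not establish about real recordings.

## Signal model and the synthetic generator

The pipeline operates on trial-epoched, source-level time series from two
regions ("motor", "auditory") sampled at 300 Hz, time-locked either to
target onset (*pretarget* epochs, analysis window −700..0 ms) or to cue
onset (*precue* baseline epochs). The generator emulates the statistical
structure the analyses assume:

1. **Background**: Gaussian noise shaped in the frequency domain to an
   expected power spectrum ∝ 1/f^α (default α = 1, the DC bin zeroed),
   globally rescaled to unit SD so burst amplitudes are expressed in noise
   SD units. Frequency-domain shaping gives the exact expected spectrum at
   O(n log n) while preserving Gaussian statistics.
2. **Bursts**: per trial and channel, a Poisson(λ) number of transient
   events (default λ = 2), each a Hanning-windowed sinusoid
   A·w(t)·sin(2πft + φ) with uniform random phase (no phase-locking
   assumption), frequency uniform in 13–30 Hz for the motor channel,
   duration uniform in 2–6 cycles (converted through 1/f), amplitude
   default 5 × noise SD, and centre placed uniformly so the burst fits the
   epoch. Every injection is recorded in the ground truth. The auditory
   channel uses a single per-trial frequency drawn from a normal
   distribution centred on the band (SD = one sixth of the bandwidth,
   clipped 1 Hz inside the band edges) — a trial-level "frequency state"
   that the instantaneous-frequency analysis can recover.
3. **Coupling**: the auditory trace receives a band-passed, 20-ms-delayed
   copy of the motor trace scaled by a per-trial gain C. When the RT model
   couples behaviour to connectivity (β_C ≠ 0), C ~ Uniform(0, 2·gain)
   (default gain 0.8) so connectivity varies across trials; otherwise C is
   constant.
4. **Reaction times**: RT = β₀ + β_P·z(P) + β_F·z(F) + β_C·z(C) + ε with
   ε ~ N(0, σ). P is the *measured* mean β-band power of the generated
   motor trace in the analysis window (so the power→RT path includes
   burst-count and amplitude variability), F is the trial's auditory
   frequency state, C the coupling gain. RTs are clipped at a 100 ms floor
   (physiological plausibility; prevents nonpositive RTs).

Defaults: 600 trials (ten 60-trial blocks pooled over cue conditions),
β₀ = 500 ms, (β_P, β_F, β_C) = (30, 20, 20) ms per z-unit, σ = 50 ms.
These effect sizes give trial-level feature–RT correlations of roughly
0.45/0.30/0.28 — deliberately moderate, strong enough that a small
synthetic group (≈10 participants × ≈100 trials) recovers the effect signs
reliably, which is what the recovery harness verifies. They are generator
conventions, not estimates of any empirical effect size: real single-trial
brain–behaviour correlations are typically an order of magnitude weaker
and need the full study's trial and participant counts.

The precue epochs are generated independently from the same burst
statistics with constant coupling, so pretarget-vs-precue contrasts are
null by construction (one caveat: when β_C ≠ 0 the pretarget coupling gain
is Uniform(0, 2g) while precue coupling is constant g; the second moments
differ slightly, which can leak a small pretarget-vs-precue difference
into auditory-channel measures).

## Analysis chain

**1/f flattening.** All analyses run by default on the first temporal
derivative of the signal (scaled by fs, time axis on interval midpoints),
which multiplies the power spectrum by ≈(2πf)² and flattens a 1/f²
background; it is switchable off. Note the derivative *tilts* the β band
upward in frequency (a 30 Hz component gains (30/13)² ≈ 5.3× over a 13 Hz
component), which slightly biases burst peak frequencies upward relative
to the raw signal.

**Spectra.** Single-trial spectra use one Hanning taper over the 700-ms
window, zero-padded to 2 s, giving exactly 0.5 Hz resolution; log-power is
the natural log (the base is a convention; tests pin natural log), with
zero-power bins floored at the smallest positive float and flagged. The
same trial-wise Fourier coefficients feed the connectivity estimators.

**TFR.** Hanning-windowed short-time Fourier power, implemented as
frequency-domain multiplication (FFT of the whole epoch times the FFT of a
250-ms Hanning-windowed complex exponential per frequency), evaluated on
the exact 13–30 Hz × −750..+250 ms grid (35 × 51). Epochs must extend a
half-window (125 ms) beyond the time grid, which is why synthetic epochs
span −1.0..+0.4 s; shorter epochs raise an error rather than silently
mixing zero-padding into edge estimates. Normalization divides each
channel by one scalar — the grand mean over trials, frequencies and times
— so normalized power has grand mean 1 per channel. Computing the factor
across trials (rather than within) keeps trial-to-trial amplitude
variability, which the burst statistics need.

**Burst detection.** Thresholds are per trial and frequency row:
mean + 2 SD (sample SD, n−1) of that row's power over the *full* epoch
time axis; strict exceedance, so constant rows yield no marks. Within a
row, contiguous supra-threshold runs shorter than one cycle (1/f, rounded
up to whole 20-ms bins) are cleared before clustering. Marked points are
clustered by 4-connectivity (time or frequency adjacency, not diagonal).
Events are assigned to an analysis window by their peak point; the
maximal event is the one containing the globally highest-power marked
point, with ties broken toward earlier time then lower frequency. Design
choices flagged as genuinely open: diagonal adjacency (not used), and
whether the duration criterion precedes clustering (it does, row-wise, as
the criterion is defined through the row's own 1/f).

**Instantaneous frequency.** The band-pass is a Hamming-windowed sinc FIR
applied forward and backward (zero phase), with mirror-padded edges. The
order is 4 cycles of the low cutoff (93 taps at 300 Hz): the shortest
Hamming design whose squared response keeps the 20 Hz region within 1% of
unity while attenuating 5 Hz by >40 dB; a 3-cycle design misses the 1%
passband contract (gain 0.980 at 20 Hz). The analytic signal is built on
the mirror-padded trial; the raw estimate is the first difference of the
unwrapped phase times fs/2π. Ten median filters with kernel durations
linearly spaced 10–400 ms (odd sample counts) are applied to the raw
estimate and the pointwise median across the ten outputs is returned —
median filtering suppresses the phase-slip spikes that contaminate
derivative estimates without smearing genuine frequency steps. Samples
within the longest kernel half-width (200 ms) of either edge, or with
vanishing analytic amplitude, are invalidated. Spectral β peaks are the
largest strict local maximum inside the band (monotone spectra: no peak;
participants without a peak in either half are excluded from peak
contrasts; ties go to the lower frequency).

**Statistics.** Per time point, feature and RT are z-scored across trials,
trials with |z| > 3 on either variable dropped, and RT regressed on the
feature by OLS (on z-scored pairs the slope is the Pearson correlation;
the retained pairs are not re-z-scored, OLS re-centres internally). The
per-participant null is the mean slope timecourse over 100 random
permutations of the RT assignment. The regression core is implemented
with masked matrix products so thousands of shuffles cost three matrix
multiplications; unit tests pin it to the closed-form per-column OLS.
Group inference: pointwise paired t across participants, cluster-forming
threshold at the two-tailed t critical value for α = 0.05, clusters =
contiguous same-sign supra-threshold runs, cluster statistic = Σt, null =
max |Σt| over 1000 per-participant sign flips, Monte-Carlo p with the +1
correction. Cohen's d is the mean over participants of the cluster-
averaged difference divided by its SD (n−1). Median splits send
median-valued trials to the slow half (any fixed deterministic rule
works; this one is pinned by tests). The several β measures and regions
are *not* corrected for multiple comparisons across contrasts — each
contrast reports its own cluster p, as is conventional for this design.

**Connectivity.** PPC uses the closed form (|Σe^{iθ}|² − N)/(N(N−1)) on
trial-wise Fourier phase differences — an unbiased estimator whose null
expectation is 0 at any N. Granger causality: the trial-averaged 2×2
cross-spectral density on the full 0–Nyquist grid (the 13–30 Hz band is a
read-out, not the factorization domain) is smoothed over ±1 frequency bin
(raw 0.5 Hz trial-averaged spectra can be ill-conditioned; the radius is
config-exposed), then factorized by Wilson's iteration
S = HΣH\* with H minimum-phase and the zero-lag factor kept
lower-triangular. Convergence tolerance 1e-9 with at most 100 iterations;
on noisy estimated spectra the update typically plateaus at its numerical
floor (~1e-4 relative), which the code detects and stops at, flagging the
result as not-converged while still reporting the (accurate, ~1e-5
relative reconstruction) factorization. On analytic spectra the iteration
converges to machine precision and the reconstruction residual is <1e-12.
Directed influence uses the standard spectral decomposition with the
partial noise covariance; values below 1e-12 are clipped to 0.

## Validation harness and problem sizes

Every stage is validated by parameter recovery on synthetic data
(`betadyn.validation`, driven by `scripts/acceptance.py` and the
acceptance tests):

- grid arithmetic and estimator accuracy on closed-form signals (tone,
  linear chirp, degenerate PPC inputs);
- dual-route checks where an independent oracle exists: Welch + log-log
  fits for spectral slopes, explicit pairwise sums for PPC, brute-force
  flood fill for clustering, closed-form OLS for regression, and a pooled
  least-squares VAR(2) fit as the parametric oracle for nonparametric
  Granger (agreement within 10% at the spectral peak);
- calibration: the cluster test's family-wise type-I rate over 500 null
  simulations with 20 participants (measured ≈0.05), and per-contrast
  rejection of the full pipeline on effect-less generators. With 100 null
  runs per contrast the Monte-Carlo SE on a rejection rate is ≈0.022, so
  observed rates scatter between ≈0.03 and ≈0.09 across seed batches
  around the nominal 0.05; the calibration test therefore checks
  *binomial consistency* with α (per-contrast one-sided bound at the
  0.005 level plus a pooled bound over the three contrasts) instead of
  demanding a point match a calibrated test would often fail;
- end-to-end recovery: 100 seeded group experiments (10 participants × 80
  trials each — reduced from the study-scale 600 trials to keep the
  recovery loops proportionate, with effect sizes as above) recovering
  the three headline effect signs.

**Known shortfall (documented, not patched):** the burst-detector
recovery experiment (200 trials, amp 5 × noise SD, Poisson(1) bursts)
reaches recall ≈0.70 and precision ≈0.26–0.30 at the ±2 Hz/±100 ms
matching tolerance, short of the 0.9/0.8 targets. Three mechanisms bound
it: (a) 2-cycle bursts at the top of the band (≈67 ms at 30 Hz) are much
shorter than the 250-ms TFR window, so their detected peak wanders beyond
the matching tolerance even in isolation (single-burst recall ≈0.87);
(b) with Poisson(1) counts, ~26% of trials contain ≥2 bursts whose
smeared time–frequency blobs merge into one 4-connected event with a
single peak; (c) TFR power of Gaussian noise is approximately exponential
per bin, so the within-trial mean + 2 SD rule marks ≈5% of bins and
leaves ≈3 weak false events per trial (median normalized peak power 0.65
versus 17.6 for matched events). Raising precision would need a power
floor or duration/extent criterion beyond the stated 2-SD + one-cycle
rule, and raising recall would need longer bursts or a finer TFR — both
changes to the method or the study conditions, so the measured values are
reported as they are. Relatedly, the raw per-trial event *count* is not
monotone in burst amplitude (stronger bursts inflate the row SD and
suppress weak noise events); recovery of injected bursts is the monotone
detectability measure and is what the property test asserts.

## What synthetic success does and does not show

The generator matches the analysis assumptions by construction: stationary
1/f background, additive narrowband bursts, linear lagged coupling,
linear-Gaussian RT model, independent trials. Real MEG adds nonstationary
aperiodic activity, correlated noise between virtual channels from source
leakage, non-Poisson burst timing, and far weaker effects. Passing the
recovery harness therefore establishes *correctness of the estimators and
calibration of the inference* — not that effects of this size exist or
would be detectable in any particular recording.

Other limitations: bivariate (not conditional) Granger only; a single
band-limited component is assumed for instantaneous frequency (no
multi-component tracking); no multitaper or wavelet spectral variants; the
reverse-direction Granger contrast can show weak spurious sensitivity to
RT-dependent forward coupling at the band edges (leakage inherent to
finite-data factorization), which is worth remembering when interpreting
"no reverse effect" on small groups.
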