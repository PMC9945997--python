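# Methods

`ripplepipe` analyses ripple events — brief (~30–100 ms) high-frequency
(~100–180 Hz) oscillatory episodes of the local field potential (LFP) — in
laminar recordings from visual cortical areas V1 and V4 during a cued
covert spatial-attention task. This note documents the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Signal model and preprocessing

A session consists of one 16-contact laminar LFP matrix per area (150-µm
contact spacing, 1,017 Hz working rate) plus a trial table with the three
condition factors: cue location (RF vs. away), attentional focus
(narrow vs. wide), and stimulus size (small vs. large). All event times
live on one session clock in seconds.

Broadband conditioning band-passes 0.5–300 Hz with a zero-phase
(forward–backward) linear-phase FIR whose transition band is ≤ 10 Hz
(narrower at the sub-Hz low edge, where the transition equals the cutoff),
then decimates with anti-aliased polyphase resampling; the rational
approximation of the rate ratio handles non-integer conversions such as
32,756 → 1,017 Hz. Filtering precedes decimation so anti-aliasing margins
are set by the 300-Hz band edge.

Bipolar rereferencing computes `y_i[n] = x_{i+1}[n] − x_{i−1}[n]` for each
interior contact; the two edge contacts have no flanking neighbors and are
excluded. This cancels signal common to neighboring contacts exactly
(machine precision), which the tests verify together with linearity.

## Ripple detection

Per rereferenced channel, in order:

1. **Envelope** — zero-phase FIR band-pass at 80–250 Hz, squared, z-scored
   with mean/SD over the channel's entire recording (including intertrial
   periods). No envelope smoothing by default; an optional boxcar is
   exposed (`smooth_ms`).
2. **Candidates** — maximal runs above 3.5 SD. Event boundaries are these
   threshold crossings.
3. **Merge** — runs separated by gaps < 5 ms are merged. The squared
   band trace of even a strong burst dips below threshold twice per
   oscillation cycle; merging is what turns cycles into one event.
4. **Duration gate** — merged runs outside 30–100 ms are excluded.
   Merging precedes the duration gate.
5. **Confirm** — events whose within-event maximum does not exceed 5 SD
   are discarded; the confirmation threshold applies to the maximum only,
   never to the boundaries.
6. **Spectral validation** — the peak frequency of a 200-ms
   Hanning-tapered window of the rereferenced LFP centered on the event
   must fall in 80–200 Hz. Because a raw LFP spectrum is 1/f-dominated,
   the window spectrum is divided by a per-channel baseline spectrum (the
   median 200-ms Hanning spectrum over the session) before the argmax,
   which is searched over 30–300 Hz (`pf_search_hz`). Line-noise
   transients (< 80 Hz) and high-frequency artifacts (> 200 Hz) that trip
   the envelope are rejected here. Windows that do not fit at a recording
   edge shrink symmetrically (logged).

Z-scoring makes the detector exactly invariant to overall signal scaling.
Raising the candidate threshold never increases the event count on the
burst-on-noise signal class; it is not a theorem for arbitrary traces,
because threshold changes can split a too-long run into pieces that newly
pass the duration gate (the tests therefore check the property on the
realistic class). The threshold/merge/gate logic is verified against an
independent sample-walking run-length scan.

## Time–frequency analysis and power–power coupling

The STFT spectrogram uses 200-ms Hanning windows stepped by 5 ms, with
per-window mean subtraction and a normalization under which the power
summed over frequency bins equals the tapered window's mean square;
optional division by a baseline-interval spectrum removes the 1/f trend.
The wavelet transform uses complex Morlets with 7 cycles at every center
frequency (a common default; the width is configurable), center
frequencies logarithmically spaced 3–250 Hz in 40 steps, implemented by
frequency-domain convolution. Wavelets are unit-energy normalized so ridge
localization is unbiased across the constant-Q grid; per-frequency scaling
cancels in the correlations below.

The ripple-triggered comodulogram asks whether power at frequency f₁ in a
trigger signal covaries with power at f₂ in a target signal: for each
trigger event, wavelet power is averaged over a 200-ms window centered on
the event in both signals, and the Pearson correlation across events gives
r(f₁, f₂); z = atanh(r). The correlation runs **across events** (each
event reduced to one power value per frequency by window averaging); the
alternative — correlating across time bins within an event — is exposed by
calling the spectrogram functions directly, but across-events is the
default because it makes the correlation a statement about event-to-event
covariation rather than within-event spectral shape.

Significance against a matched control (same count of condition- and
time-matched ripple-free windows) is assessed by splitting events into
disjoint blocks (default 8), computing z per block, t-testing ripple vs.
control blocks per frequency pair, and applying Benjamini–Hochberg across
all pairs. Block-wise z values are what make a t-test well-defined when
only one contact pair is available; with many contact pairs the same
machinery can aggregate across pairs instead.

## Laminar analyses

CSD is the second spatial difference of the trial-averaged LFP,
`csd_i = −(x_{i−1} − 2x_i + x_{i+1})/h²`, in arbitrary units (conductivity
absorbed); sinks are negative. By default only interior contacts are
estimated; Vaknin edge replication (`vaknin=True`) keeps one row per
contact. CSD of any depth-linear potential is exactly zero, and halving
the spacing quadruples the magnitude.

Multiunit response latency per contact is the first post-stimulus time at
which the trial-averaged rectified high-passed signal (default 100 Hz
high-pass) exceeds its pre-stimulus baseline mean + 3 SD for ≥ 5 ms,
searched within 200 ms. The high-pass uses a short **causal** FIR whose
exact linear-phase group delay is compensated afterwards; a zero-phase
filter would leak response energy backward and bias latencies early. The
3-SD / 5-ms rule and the filter edge are this package's concretization of
a latency criterion that admits several reasonable definitions; all
constants are parameters, not claims.

Layer assignment: a contact has a qualified sink when its CSD stays below
baseline − 3 SD for ≥ 5 ms post-stimulus *and* its sink depth reaches 20%
of the deepest sink on the probe — volume conduction produces weak
curvature everywhere, so a relative depth criterion is needed to isolate
the true sink. The input layer is the contiguous run of qualified contacts
containing the earliest qualified sink (onsets within 10 ms), grown to
include the minimum-latency contact; superficial/deep labels follow by
position. If sink and latency evidence disagree by more than 2 contacts
the function raises and requires a manual override (which always wins).

Per-layer ripple rates are normalized by contact count,
`[events/(trials·duration)]/n_contacts`, because layer thickness (hence
contact count) varies across penetrations; a one-way ANOVA across layers
with Tukey post hoc is provided for layer comparisons.

## Event statistics

**Rates.** For each session, epoch, and condition cell, the rate is
`events/(n_trials · epoch_duration)` per electrode, averaged across
electrodes — one value per session per cell. The canonical epochs are
precue (200 ms after fixation), postcue (800 ms after cue offset), and
sustained (300–750 ms after stimulus onset). The task's delay is 1,000 ms
while the postcue window is 800 ms; the window is anchored at cue offset
(the literal reading), with an end-anchored variant available by defining
a different epoch.

**Paired tests.** Wilcoxon signed-rank on session-paired differences,
zero differences dropped, exact null distribution for n < 20 (verified
against full enumeration). Post hoc contrast families are declared before
testing and Benjamini–Hochberg adjusted within the family.

**RM-ANOVA.** The three-factor repeated-measures ANOVA (sessions as the
within unit) is backed by `statsmodels.AnovaRM`; sessions with incomplete
2×2×2 cells are excluded listwise. For two-level factors each effect's F
equals the squared paired t on the corresponding ±1 contrast of cell
means, which serves as the independent oracle in the tests. A constant
table is reported as F = 0, p = 1 rather than 0/0.

**Cross-area correlogram.** Same-trial V4-minus-V1 event-time differences
are histogrammed in 5-ms bins over ±200 ms (an odd bin count with a
zero-centered middle bin, so no edge sits at lag 0). The shuffle predictor
is the mean histogram over 100 random permutations of one area's trial
identities (times kept trial-relative); each permutation is accumulated
together with its inverse, which symmetrizes the predictor without
biasing it. `corrected = raw − predictor`; the AUC on either side of zero
(middle bin split evenly) quantifies lead–lag asymmetry, with a
signed-rank test across channel-pair asymmetries when channel labels are
present. Bin width, lag range and permutation count are configuration.

**Co-occurrence.** The fraction of trials with an area-A ripple (any
contact, within the epoch) that also contain an area-B ripple. Under this
any-contact definition, chance coincidences alone are substantial at
realistic sustained rates (~0.07 events/s/contact × 14 contacts × 0.45 s),
so measured values on synthetic sessions (~0.4) sit well above the
generator's 0.1 partner fraction; the quantity is reported as measured.

**Ripple-locked spiking.** Peri-event histograms of the unit(s) on the
event's own contact, over ±100 ms (or a 50-ms window for the within-ripple
estimate; both are parameters). Controls transplant each event's
within-trial offset onto a randomly drawn condition-matched ripple-free
trial, resampled with replacement 10 times and averaged.

**Trial-level models.** Reaction times (or firing rates) are fit with a
linear mixed-effects model: categorical fixed effects for cue location,
ripple occurrence, focus, and stimulus size, and a random intercept per
session, estimated by REML, followed by per-factor Wald tests. Treatment
coding uses references {cue away, no ripple, narrow focus, large
stimulus} so coefficient signs match the described effect directions. A
singular random-intercept variance triggers a logged fallback to pooled
OLS (whose coefficients equal the closed-form least-squares solution, as
tested).

## Synthetic sessions

The generator emulates the study conditions so every stage is testable
without recorded data. Defaults:

* background: 1/f noise (α = 1), 40 µV RMS, 16 contacts, 1,017 Hz, with a
  depth-weighted common component (fraction 0.6) so rereferencing has real
  common-mode signal to reject;
* trial timing: fixation → 250-ms cue → 1,000-ms delay → stimulus →
  dimming target 0.75–1.25 s later; factors balanced across trials;
* ripples: Poisson within epoch windows at per-contact rates; each event
  is a Gaussian-enveloped sinusoid, frequency uniform in 100–180 Hz,
  nominal duration uniform in 30–60 ms, amplitude 6× the channel's
  ripple-band RMS (chosen so peak z reliably exceeds the 5-SD confirmation
  threshold — a calibration of the generator, not a measured quantity).
  The envelope SD is duration/2.2 so that the width the detector sees at
  this amplitude approximately equals the nominal duration, derived from
  the threshold geometry of the squared trace;
* sustained-epoch rates: built multiplicatively from a stimulus-size base
  of 0.09 (small) vs. 0.04 (large) events/s, a cue multiplier 1.45 (RF)
  vs. 0.65 (away), and a focus multiplier 1.25 (wide) vs. 0.75 (narrow).
  Size and cue magnitudes follow the reported rate scale; the focus effect
  is reported qualitatively there, so its ratio was fixed a priori as the
  weakest of the three. Precue/postcue rates default to 0.01 events/s;
* cross-area: each V1 event spawns a V4 partner with probability 0.1 at a
  lag ~ Normal(22, 5) ms;
* spikes: inhomogeneous Poisson at 22 Hz baseline with a Gaussian rate
  bump of +8 Hz (SD 25 ms) at each injected event on the unit's contact;
* reaction times: 312 ms base, −1.5 ms for cue RF, −1.5 ms for small
  stimuli, +0.5 ms for wide focus, −3 ms on ripple trials, session random
  intercepts (SD 10 ms) and trial noise (SD 30 ms);
* evoked response (laminar ground truth): a negative alpha-function
  transient (τ = 4 ms) with a sharp dipole component centered on contact 8
  (input layer = contacts 7–9) over a broad volume-conducted floor, and a
  latency gradient of 3 ms per contact away from the center.

Bursts are injected into the *rereferenced* channels so one ground-truth
event corresponds to one detectable event on one channel; injecting into a
raw contact surfaces on two bipolar channels with opposite signs. All
randomness descends from a single integer seed through numpy's
`default_rng`/`SeedSequence` stream discipline; identical seeds reproduce
sessions exactly.

What the generator does **not** emulate: spatially structured oscillations
(gamma, alpha) and their laminar phase profiles, eye movements, electrode
drift, sharp-wave deflections accompanying ripples, spike waveform leakage
into the LFP, and non-Poisson ripple timing (refractoriness, clustering).
Passing tests therefore demonstrate correctness of the algorithms on the
stated signal model, not detector performance on recorded cortex.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: detector
benchmarks on 120-s sessions (~130 injected events), condition-rate
studies on 6 sessions × 160 trials, calibration studies with 1,000 null
simulations (12-session rate tables for the RM-ANOVA; 10 sessions × 40
trials for the mixed model), reaction-time recovery at 43 sessions × 349
trials × 100 replicates, and sign-recovery runs of two 160-trial sessions
each. Degenerate inputs are handled explicitly: zero-variance channels
raise, empty event lists are valid detector output, all-zero paired
differences give p = 1, and constant ANOVA tables give F = 0. Event
boundaries use half-open sample intervals `[start, end)`; `t_center` is
the interval midpoint.

## Known limitations

* Peak-frequency estimation has the ~5-Hz resolution of a 200-ms window.
* The comodulogram's block t-test trades events for replicates; with few
  events per block, z estimates are noisy and power is limited.
* The latency and layer-assignment constants are concretizations, tuned to
  the generator's signal model and exposed as parameters; on recorded data
  they should be revisited (and the manual override used when sink and
  latency evidence disagree).
* `AnovaRM` requires a balanced within design; unbalanced sessions are
  dropped rather than modeled.
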