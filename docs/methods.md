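# Methods

`spnsens` implements a single-neuron calcium analysis of striatal population
activity around an intraperitoneal injection: transient detection and model
fitting from 10 Hz miniscope traces, a within-neuron resampling test for
injection-responsive neurons, a time-shift test for movement-coding neurons,
fiber-photometry dF/F against an isosbestic control channel, and a synthetic
cohort generator that provides ground truth for every step.

## Time conventions

Seconds everywhere; the injection is at `t = 0`; recording windows are
half-open `[start, end)` intervals; frame indices are 0-based at 10 Hz.  The
default session records four 5-min windows at −10..−5, −5..0, 0..5 and
10..15 min around the injection.  "Recorded time" concatenates the windows
into a gap-free axis; interval shuffling and circular velocity shifts
operate there so that the gaps between windows never produce artificial
giant intervals.

## Transient model

A transient is the product of a logistic rise and an exponential decay with
a shared reference time:

    f(t) = alpha_p / (1 + exp(-(t - t0)/tau_g)) * exp(-(t - t0)/tau_d)

with `f(t0) = alpha_p/2`, a fast rise for `tau_g << tau_d`, and a peak at
`t0 + tau_g*log(tau_d/tau_g - 1)`.  The same product is sometimes written
with the opposite sign in the logistic exponent; the forms are equivalent
under a sign flip of `tau_g` and this package uses the rising orientation,
which is the one that decays in both limits for positive parameters.  The
half-rise time of the fitted curve — the earliest time the rising limb
reaches half its own maximum — is the event onset used by all downstream
inference.

## Detection chain

1. **Baseline correction.** Per frame, the mean of the lowest 20% of
   samples in a centred 30 s window is subtracted (windows truncated at the
   edges and never spanning recording gaps).  The window length is chosen
   much longer than a transient (seconds) and shorter than slow drift
   (minutes).  The estimator itself has sampling variability of a few
   per cent of the noise SD, so a second application changes the trace by
   ~4% of the noise SD on pure noise — it is idempotent only to within that
   estimator variance.
2. **Derivative thresholding.** The first difference is boxcar-smoothed at
   two scales: 0.2 s for rises and 1.0 s for falls — at 10 Hz the slow decay
   produces per-frame decrements of roughly one noise SD, invisible to any
   single-frame threshold.  The noise scale is estimated from the second
   difference (robust MAD, insensitive to the locally linear decay limbs
   that shift the first-difference distribution at high event rates) and
   propagated analytically to each smoothed stream.  The rise stream is
   additionally detrended with a running median so a rise riding the
   previous transient's decay is judged against its local slope.  Runs above
   `k = 2.5` robust SDs lasting at least 0.2 s (counted net of the boxcar
   span; shorter runs must clear a 1.2x higher peak) become rise or fall
   candidates; rise runs containing several prominent derivative peaks are
   split at the intervening minima.
3. **Pairing.** Each rise pairs with the nearest subsequent fall starting
   before the next rise; when the next transient interrupts a decay, the
   epoch is truncated at the next rise start instead of being discarded.
4. **Fitting.** A reference kernel is fitted to the peak-aligned average
   transient, then refined on a `t0`-realigned average of the largest
   events (peak-sample alignment jitter broadens the apparent rise
   severalfold; realigning on the fitted, continuous `t0` removes most of
   that smearing and with it most of the half-rise onset bias).  Each epoch
   is then fitted over its epoch plus margins (1 s before, 3 decay
   constants after, clipped at neighbouring epochs) by bounded nonlinear
   least squares with `tau_g` held at the reference value — one or two rise
   frames at 10 Hz cannot constrain it per event — and `tau_d` kept within
   a factor of 5 of the reference.  The production path is a vectorised
   Levenberg–Marquardt with a sigmoid bound-removing reparametrisation,
   batched over all events of a trace; `fit_transient` is the equivalent
   scipy reference path and the two are cross-checked in the tests.
5. **Cleaning.** Fits are flagged (never deleted) when the peak is below
   3.5 quiet-period SDs (quiet SD falls back to the second-difference noise
   estimate on dense traces), the decay is faster than the rise, `tau_d`
   leaves `[0.1, 20]` s, or the RMSE exceeds half the peak.  Accepted onsets
   closer than one frame merge, keeping the larger-area event.

**Operating point.** On synthetic neurons at SNR 10 (log-uniform rates
0.05–0.5 Hz), count recovery is essentially exact below 0.2 Hz, while
pure-noise traces yield well under one false event per 300 s.  Above
~0.3 Hz the detector undercounts by roughly `1 - exp(-0.3*rate)`: events
closer than ~0.3 s are unresolvable by derivative detection at 10 Hz with
0.8 s decays, and multi-kernel joint fitting is deliberately out of scope
(the method fits isolated transients).  Overall ~70–75% of neurons across
that rate range land within 10% count error; users analysing high-rate
units should treat absolute counts as lower bounds.

## Responsiveness classification

Per neuron, the transient-count change between the last 5 min before and
the first 5 min after injection (`delta_hz`, per-second units) is compared
to a null built by permuting the neuron's inter-transient intervals on the
recorded-time axis (10,000 shuffles by default; the first-onset latency is
part of the permuted set so null trains can cross the injection boundary;
each permutation preserves the event count and last-onset time).  A neuron
is *elevated* if the observed change strictly exceeds the nearest-rank 99th
percentile value of its null, *reduced* below the 1st; ties classify as
none, as do neurons with fewer than 5 events (they stay in denominators).
Calibration on homogeneous Poisson neurons is slightly conservative
(~0.6–1% per direction against the nominal 1%) because counts are discrete
and the comparison strict.  Power at `rate_pre = 0.1 Hz` reaches ~1.0 at a
post/pre ratio of 3.

## Movement coding

Velocity comes from the centroid track (frame-to-frame Euclidean distance
over the frame interval, 0.5 s centred moving average, linear resampling
onto the imaging frame grid).  For each neuron, speed in ±5 s around every
onset (events with incomplete windows are skipped) is baseline-subtracted
(mean of −5..−3 s per event) and averaged; the score is the mean over
±0.5 s.  The null rotates the velocity circularly within concatenated
recorded time by 10–1200 s (uniform magnitude, random sign) — rotation
preserves the speed histogram exactly — and recomputes the score.
*Heightened* above the nearest-rank 95th percentile, *lowered* below the
5th: the classification is two-sided at 5% per tail because both signs of
coupling are biologically meaningful.  Measured false-positive rates are
5–6%/4–5% per tail (within the 99% binomial CI of the nominal 5%; the
slight excess comes from the non-circularity of a finite mean-reverting
velocity process).  The locomotor sensitization index is the per-animal
ratio of total distance moved on the second versus first cocaine day.

## Photometry

dF/F is the residual fraction of the 470 nm channel against an OLS fit of
470 on 405: `(ch470 - fit)/fit`, averaged in half-open 5-min bins.  The
pipeline defaults to fitting the control regression on the pre-injection
portion of the recording: with a full-recording fit an additive dopamine
response leaks into the fitted intercept and splits across the pre/post
bins in proportion to the fraction of post-injection samples, which makes
absolute step recovery impossible by construction.  Full-recording fitting
remains available (`photometry_fit_window=None`).  A 2% relative step is
recovered in the 0–5 and 10–15 min bins within ~2–3%.

## Synthetic cohort

Event trains are homogeneous Poisson within each window (`rate_pre` before
the injection, `rate_post` after).  The real inter-transient-interval
distribution of these neurons is unknown; Poisson satisfies the
exchangeable-interval assumption of the shuffling null and is the simplest
choice consistent with it.  Traces place one kernel per event (the event
time is the kernel `t0`; the ground-truth onset adds the kernel's half-rise
offset), plus a slow sinusoidal drift (amplitude 0.3, period 120 s — long
enough to exercise the baseline correction) and white Gaussian noise.  The
default shape (`alpha_p = 2`, `tau_g = 0.06 s`, `tau_d = 0.8 s`) gives a
~0.15 s time-to-peak and ~0.55 s decay half-life, typical of a fast
genetically encoded calcium indicator in vivo; noise SD 0.153 puts the peak
SNR at 10.  Rates are drawn log-uniformly on 0.05–0.5 Hz where a
distribution is needed, reflecting the strong rate heterogeneity of these
populations.  Velocity is an exact-discretised mean-reverting process
(mean 3, SD 2, 2 s relaxation, clipped at zero) with optional Gaussian
bumps (SD 0.4 s) at event times; centroid tracks integrate the speed under
a random-walk heading.  Photometry carries a shared bleaching-plus-motion
artifact in both channels and a saturating dopamine step (5 s rise) that is
exactly zero before the injection.  Cohorts span saline and two cocaine
days with configurable responder fractions per day; responder sets are
nested across days so tracked neurons populate both the "responsive on both
days" and "last exposure only" categories; per-day locomotion scales
0.3/1.0/1.4 emulate low saline locomotion and a ~1.4x sensitization ratio.
All randomness derives from one seed; cohort outputs are byte-reproducible.

What the generator does **not** emulate: bursty or refractory event trains,
amplitude variability within a neuron, crosstalk between neighbouring
sources, non-stationary noise, or photobleaching of the calcium indicator.
Passing tests therefore demonstrate correctness of the analysis under its
own model assumptions, not robustness to every failure mode of real
recordings.

## Validation scales

The test suite runs the classifier calibrations at 1000 neurons x 1000
resamples, detector scoring at 500 neurons, fit recovery at 200 transients,
and the end-to-end cohort at 4 animals x 24 neurons x 3 sessions with 1000
shuffles.  `scripts/acceptance.py` recomputes the same quantities at
250 detector neurons, 800 calibration neurons and a 22-neuron cohort so the
whole script completes in a few minutes on one CPU; all sizes are explicit
arguments of `spnsens.validation` and can be raised.

## Known limitations

- Event counts at rates above ~0.3 Hz are lower bounds (sub-resolution
  merges; see operating point above).
- `tau_g` is reported at the per-trace reference value, not per event.
- The movement shift null is mildly anticonservative (see above).
- The Wilcoxon wrapper switches from the exact distribution to the
  continuity-corrected normal approximation above n = 25.
- The linear-mixed-model analysis of the log2 response statistic is out of
  scope; only the statistic itself is computed.
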