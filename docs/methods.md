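# Methods note

This package analyzes category-specific repetition (adaptation) effects on
visual event-related potentials (ERPs), and ships a synthetic-data generator
whose ground truth is the set of normative component parameters the analysis
pipeline is meant to recover. This note records the model, the defaults and
where they come from, what the generator does and does not emulate, and the
numerical choices.

## Experimental model

Stimuli from two categories (human faces, `F`; cat faces, `C`) are shown for
500 ms at a fixed 1000-ms onset-to-onset interval, organized in blocks of
three types: uniform-human, uniform-cat, and alternating. Crossing the probe
category with the preceding adaptor category yields four conditions, coded
probe-then-adaptor:

| code | probe | context |
| ---- | ----- | ------- |
| FF | human | uniform human block (face repeated) |
| CC | cat | uniform cat block (cat repeated) |
| FC | human | alternating block (face after cat) |
| CF | cat | alternating block (cat after face) |

Blocks hold 24 trials (infant protocol) or 120 trials (adult protocol); one
iteration is one block of each type, and the block order is counterbalanced
by rotating the initial block type across subjects. Four infant iterations
give 96 uniform trials per probe category (and 48 per alternating condition);
two adult iterations give 240 per uniform condition.

## Signal model

EEG is sampled at 250 Hz on a 128-channel montage. Every stimulus adds an
evoked kernel to the ongoing activity: a positive P1 component followed by a
negative posterior component (N290 in infants, N170 in adults), each modeled
as a raised-cosine (Hann) bump in time, weighted across the scalp by a smooth
posterior topography, on top of 1/f ("pink") background noise with optional
sinusoidal line interference and injected artifacts.

Component amplitudes are defined as **what the downstream pipeline measures**:
the baseline-referenced extremum of the conditioned, low-pass-filtered,
average-referenced epoch inside the group-specific measurement window
(maximum for P1, minimum for the N component), averaged over the twelve
occipital region-of-interest (ROI) electrodes. Because filtering, epoching,
detrending, baselining and average referencing are all linear, the generator
calibrates the injected bump amplitudes by pushing unit bumps through the
same operators and solving a 2x2 linear system at the measured extremum
samples (iterated to a fixed point over extremum locations, with cycle
detection). With all noise sources at zero the pipeline recovers the
configured amplitudes essentially exactly; note that an "N" amplitude may be
positive (the adult CC and CF conditions are), in which case the window
minimum sits at the window edge rather than at the nominal component latency.

The scalp topography is a von-Mises-style bump on the unit sphere centered on
the centroid of the 12 ROI electrodes, with two normalizations: the channel
mean is removed (so average referencing leaves the evoked signal unchanged)
and the mean weight over the 12 ROI electrodes is one (so ROI-collapsed
measures equal the configured amplitudes).

Between-subject variability decomposes into a common amplitude offset shared
by all conditions plus independent subject-by-condition offsets, and a shared
latency jitter applied to both components. The split is chosen so that, under
the realistic profile, the marginal per-condition SD and the SD of
between-condition differences both match the normative values.

## Default parameters

Per-condition amplitude/latency defaults are the published normative values
for the infant N290 and adult N170 paradigms (e.g. infant FF: N290 amplitude
-8.42 uV at 278.2 ms; adult FF: N170 -0.11 uV at 170.7 ms). P1 amplitudes are
derived from the normative peak-to-peak (N minus P1) values. Component widths
are 80/120 ms (infant P1/N) and 60/60 ms (adult). Two generation profiles
exist:

- `realistic`: normative between-subject SDs, 35 uV (infant) / 15 uV (adult)
  pink-noise RMS, 3 uV line noise, and artifact rates chosen to produce
  plausible rejection/interpolation counts;
- `validation`: the same means with nuisance sources shrunk (1 uV
  subject SD, 0.3 uV condition SD, 3 ms latency jitter, 2 uV pink noise, no
  artifacts), so parameter-recovery bias can be measured with small cohorts.

Analysis defaults follow the paradigm's printed constants: 4th-order
zero-phase Butterworth low-pass at 30 Hz; epochs from -100 to 500 ms
(half-open, 150 samples) with pre-stimulus baseline; +-150 uV amplitude
marking per channel; epochs with more than 12 bad channels rejected;
impedance > 200 marks a channel globally bad; spherical-spline interpolation
of bad channels (stiffness m = 4, series tolerance 1e-10, max 50 terms,
diagonal regularization 1e-5); average reference; component windows P1
112-148 / N 148-192 ms (adult) and P1 160-208 / N 232-324 ms (infant),
closed; minimum 20 epochs per condition average for infants (none for
adults); peak-then-average ROI reduction over the left/midline/right
occipital electrode quadruplets.

## Statistics

Planned comparisons are paired t tests on subject-level condition means
(sites collapsed), with Cohen's d for dependent means = mean(diff)/sd(diff).
The condition-by-site repeated-measures model uses the classical two-way
within-subject decomposition when the data are complete and balanced (each
effect tested against its own subject-interaction stratum); with missing
cells or a covariate, the 12-cell response is fit as a multivariate normal
with unstructured covariance by EM, effects are Wald F tests with a
fractional denominator df based on per-subject completeness, and a covariate
is removed beforehand by pooled within-cell regression. Conditions or sites
with no observations at all are dropped from the model rather than imputed.

The bootstrapped standardized measurement error (bSME) of a score is the SD
of that score across resamples (with replacement, same N) of a subject's
retained epochs; for linear scores it converges to sigma/sqrt(N), while peak
scores inherit the extremum-picking bias of the score itself.

## Stimulus matching

Image sets are equated with alternating exact rank-based histogram
specification (to the integer set-average histogram, largest-remainder
apportionment; ties broken in raster order, optionally by a blurred
structure image) and Fourier amplitude-spectrum averaging with phase
preserved (re-quantized round-half-even to [0, 255]). Diagnostics track the
histogram residual after the spectrum step and the spectrum residual after
the histogram step, per iteration.

## Numerical choices and limitations

- Zero-phase filtering is applied to the padded continuous trace before
  epoching, both in the pipeline and in the generator's calibration, so the
  two stay consistent by construction.
- The spherical-spline series uses upward Legendre recursion; the linear
  system is the standard constrained form (coefficients sum to zero) with a
  small diagonal ridge.
- The EM fit adds a 1e-10 ridge to keep the covariance positive definite;
  its Wald denominator df is an approximation, not a Satterthwaite solution.
- The montage is a deterministic golden-spiral stand-in, not digitized
  electrode positions; only the 12 ROI labels are guaranteed to form a
  coherent occipital patch.
- The generator does not emulate: ocular or movement artifacts with realistic
  morphology (artifacts are rectangular pulses designed to trip the marking
  rules predictably), non-stationary noise, drifting electrode impedance,
  trial-to-trial latency jitter (jitter is between-subject), overlapping
  responses from preceding stimuli beyond the fixed stimulation rate, or
  habituation/attention effects over the session.
- EDF export quantizes to 16 bits at 0.1 uV per bit and stores events on an
  extra status channel; EDF carries no calibrated unit metadata here, so the
  reader assumes microvolts and warns.
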