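# Methods

This note documents the models, numerical procedures, defaults and known
limitations of the synaptiq pipeline, and what its synthetic generators do
and do not emulate.

## Units and conventions

Currents are pA with inward currents negative; time is ms inside traces and
s for recording durations and rates. Charge is reported in pC with the
convention pA·s = pC, so integrating −I(t) (pA) over t (ms) and dividing by
1000 gives pC; inward synaptic currents therefore yield positive charges.
Fluorescence positions are nm along the scan line with 0 at the first
sample; intensities are arbitrary fluorescence units (AFU) and clipped
non-negative. EM distances are nm along the membrane from the
dense-projection edge, consumed as measured scalars (no image processing).

## Evoked-EPSC kinetic decomposition

The cumulative charge after the stimulus at t₀ is modelled as

Q(t) = A_fast(1 − e^−(t−t₀)/τ_fast) + A_slow(1 − e^−(t−t₀)/τ_slow).

Fitting is nonlinear least squares (scipy `curve_fit`, trust-region
reflective) on the unweighted Q(t) samples over the 50 ms window, with
A ≥ 0 and 0.1 ms ≤ τ ≤ 500 ms. Initialization is a deterministic multistart:
log-spaced candidate (τ_fast, τ_slow) pairs (default 8), each with
amplitudes initialized by non-negative linear least squares at those time
constants; the lowest-SSE solution wins, components are ordered so
τ_fast < τ_slow, and bound collisions, τ collisions, non-convergence and
clipped fractions are flagged rather than silently accepted.

The *subtraction rule* defines the reported decomposition: q50 is the
measured charge at t₀ + 50 ms (trapezoidal), the effective slow size is
a_slow_eff = q50 − A_fast (so A_fast + a_slow_eff = q50 holds exactly by
construction), and the fast fraction is f_fast = A_fast/q50. The asymptotic
A_slow of the fit is reported separately but not used for the fraction.

Identifiability: on noiseless curves the fit recovers τ_fast, τ_slow and
f_fast to well below 1% across τ_fast ∈ [2, 10] ms, τ_slow ∈ [30, 80] ms,
f_fast ∈ [0.3, 0.9]. Under realistic current noise, τ_fast and f_fast stay
tight (≈1% and ≈2% median error at 5% peak-relative noise), but τ_slow is
weakly identified — only ~1.25 of its time constants fit inside the 50 ms
window, and the integrated (random-walk) noise of the charge trace leaves a
heavy-tailed sampling distribution (median ≈ 20% high at that noise level;
a whitened increment-space fit behaves the same, so this is information,
not an optimizer artifact). Per-animal τ_slow values should therefore be
interpreted with their spread, which is what the group summaries report.

Other evoked measures: peak amplitude is the maximum inward deflection in a
search window (default 20 ms) of the baseline-subtracted trace; the 90–10%
decay time interpolates the decay-phase crossings of 90% and 10% of the
peak linearly between samples (optional moving-average smoothing, off by
default) and reports a censored flag when the trace never reaches 10%;
windowed charges integrate half-open [start, stop) windows with endpoint
interpolation so contiguous windows sum exactly to the total. An optional
stimulus-artifact blank (linear interpolation over [t₀, t₀ + 0.7 ms],
configurable, off by default) is available because real stimulation
transients are not part of the release model. Sucrose responses are
baseline-compensated with the mean of a 500 ms pre-application window and
integrated over the first 1 s and 5 s of application; truncated windows are
censored, not silently shortened. The release-probability proxy divides the
genotype mean 50 ms evoked charge by the genotype mean 5 s sucrose charge —
a per-genotype scalar, deliberately without an SEM.

## Tonic/miniature event detection

The detector operates on the median-detrended, inward-positive trace,
low-pass filtered with a Gaussian (σ = 0.3 ms) and differentiated. The
noise scale is the MAD-based robust SD of the derivative (×1.4826), so high
event rates do not inflate the threshold. Candidate onsets are the union of
(a) rising-edge crossings of threshold_sd (default 4) × that scale, (b)
derivative maxima whose prominence within a ±2 ms window exceeds the same
threshold — these recover events riding a predecessor's decay, where the
negative decay slope cancels part of the rise against an absolute
threshold — and (c) inside an above-threshold run, interior derivative
maxima at half prominence, which split near-coincident rises. A candidate
becomes an event if its amplitude — peak within 3 ms of onset minus the
median of the 0.6 ms pre-onset baseline — reaches min_amp_pA (default
10 pA) and at least half of that amplitude is an actual rise from the onset
sample (this suppresses duplicate triggers on the shoulder of an event).
Candidates closer than refractory_ms (default 0.7 ms) are reduced to the
largest. All parameters are snapshotted into every EventList.

Performance on the generator's study conditions (quantal rise 0.5 ms, decay
3 ms, amplitude SNR 10, 60 s traces, 10 kHz): recall 0.95–0.99 and
precision 0.97–1.0 for rates 10–50 Hz, and zero detections on flat noise at
5 SD. The residual misses at 50 Hz are event pairs closer than ≈1 ms —
within the rise time — which no onset-counting detector can split without
template deconvolution (deliberately out of scope). For the same reason a
detected-event frequency estimate carries a small (≈1% at 25 Hz) downward
bias from genuinely coincident events; the unbiasedness test for frequency
estimation therefore runs on ground-truth event lists, while the detector
is held to the recall/precision criteria above.

Per-event decay constants come from a single-exponential fit starting
1.5 ms after the event peak — the difference-of-exponentials waveform is
rise-contaminated immediately after its maximum, and skipping ~3 rise
constants removes a ≈7% upward bias — over a 15 ms window relative to the
local pre-event baseline; failed fits return NaN and are excluded from
means.

The CALI time course bins event times into bin_s bins (default 30 s, the
final partial bin normalized by its true width), takes the pre-light mean
frequency as count-before-light / time-before-light, and reports the
frequency in the bin starting at light_on + span (default 120 s) divided by
that mean.

## Punctum colocalization

Profiles are either read directly (position_nm, ch1_afu, ch2_afu per
animal) or extracted from a 2-channel raster by averaging bilinear samples
over a width_pixels-wide band (6 or 8, flag-selectable; the band, not just
the polyline, must stay inside the raster) perpendicular to each polyline
segment, at 1-pixel steps.

Thresholds: the lowest non-zero intensity of the trace is located, the
sample SD (ddof = 1) of all pixels — zeros included — within a 600 nm
window centred there is computed (window clipped at profile ends), and the
threshold is floor + 3.5 × SD. Both the multiplier and a manual per-profile
override are exposed (and the override is recorded), since real profiles
occasionally need the threshold adjusted to include all visible puncta.

Peaks are local maxima strictly above threshold; plateaus report their
centroid; maxima closer than min_separation_nm (default 200 nm ≈ 2 pixels,
a declared choice) are merged keeping the higher. Nearest-peak matching is
directional (reference channel → other channel): each reference peak takes
the absolute distance to its nearest other-channel peak, pairs beyond
800 nm count as unmatched and are excluded from the distance list.

Correlations are Pearson r over pixels. The default retains **all** pixels.
A retention rule keeping pixels where either channel exceeds its threshold
is available ("either", also "both"), but it is not the default because
with sparse puncta it retains pixels that are high in exactly one channel
and thereby biases the between-animal shuffled null to ≈ −0.2 independent
of sample size; with all pixels retained the shuffled null is unbiased
(mean ≈ 0.01 over 90 mismatched pairs on synthetic data) while genuinely
colocalized channels correlate at ≈ 0.8. The shuffled null correlates ch1
of animal i with ch2 of animal j ≠ i over every ordered mismatched pair
(profiles truncated to the shorter length); a seeded random-pairing scheme
exists for very large cohorts. The animal is the unit of replication in all
group summaries (mean ± SEM; SEM reported as undefined for n = 1).

## EM docked-vesicle statistics

Only profiles containing a dense projection enter any denominator; profiles
with a dense projection but no docked vesicles still count (they travel
through CSV as rows with an empty distance). Histograms use half-open
33 nm bins [k·33, (k+1)·33); per-bin counts are divided by the total
profile count, and the cumulative fraction is the normalized running sum
(undefined and flagged when there are no vesicles). Region summaries count
vesicles in [0, 165), [0, 231), [231, 330) and [330, ∞) per synapse and
divide by that synapse's profile count; the 231/232 label seam is
implemented as the half-open boundary at 231 nm so no 1 nm gap exists —
region membership changes exactly at the printed boundaries. The synapse is
the unit of replication for regions; the profile is the unit for per-profile
docked (and optional total) vesicle counts. Integer vesicle counts are kept
alongside the normalized values so conservation (Σ bins × profiles = total
vesicles; region sums = per-synapse totals) is exact rather than
floating-point approximate.

## Statistics

describe() reports mean, sample SD, SEM = SD/√n, with SEM flagged undefined
at n = 1. Two-tailed Student's t uses pooled variance by default (Welch
behind a flag), paired tests use difference scores; degenerate-variance
inputs raise instead of returning NaN. One-way ANOVA (scipy) is followed by
the Student–Newman–Keuls step-down procedure: group means are ordered, each
pair's studentized range statistic q = (m_j − m_i)/√(MSW/2·(1/n_i + 1/n_j))
is compared with the studentized-range quantile for its span and the
within-group df (computed numerically via `scipy.stats.studentized_range`,
so arbitrary and unequal group sizes are supported), and a pair is declared
different at a level only if every enclosing range is also significant.
Decisions are produced at α ∈ {0.05, 0.01, 0.001} and are consistent across
levels and invariant to group input order. No correction beyond SNK is
applied by default (a global FDR hook exists in the pipeline config but
defaults off). Replication units are fixed per stage — animal for
electrophysiology and colocalization, synapse for EM regions — and recorded
in the report.

## Synthetic generators: what they emulate, and what they don't

All generators take one explicit integer seed (numpy `default_rng`; the
pipeline spawns independent child sequences per stage/genotype/replicate)
and emit ground truth alongside the data; identical (params, seed) give
bit-identical output.

* **Evoked sweeps** are the negative derivative of the two-component charge
  model on a flat baseline with white Gaussian current noise, optionally
  passed through a first-order rise filter. The slow asymptotic amplitude
  is chosen as (1 − f_fast)·q_total / (1 − e^−50/τ_slow) so the 50 ms
  charge equals q_total by construction (to <0.1% after sampling at
  ≥10 kHz). Defaults (q_total 15 pC, f_fast 0.7721, τ 5.29/40.30 ms, 10 pA
  noise, 10 kHz) give a ≈2.3 nA peak, in the range typical for wild-type
  cholinergic NMJ recordings. Not emulated: stimulus artifacts, series
  resistance, receptor kinetics, quantal granularity of evoked release.
* **Tonic sweeps** are homogeneous (or piecewise-rate-modulated, via
  thinning) Poisson trains of difference-of-exponential quantal waveforms
  (rise 0.5 ms, decay 3 ms, gamma-distributed amplitudes with mean 50 pA
  and CV 0.3, 25 Hz, 60 s, 5 pA noise by default — the waveform and noise
  are declared choices, since mini shape is rarely published). Events may
  overlap; ground truth keeps every event. Not emulated: correlated/burst
  release, 1/f noise, baseline drift.
* **Line profiles** place n well-separated (≥3σ) Gaussian puncta
  (σ 150 nm) in channel 1 on a 100 nm grid; each gets a channel-2 partner
  with probability coloc_prob displaced by N(offset_mean, offset_sd), and
  unpartnered puncta are replaced by independent channel-2 puncta. The
  100 nm default pixel makes the 600 nm threshold window 6 samples wide.
  Not emulated: PSF anisotropy, chromatic misregistration, photobleaching,
  2-D image structure beyond the extracted line.
* **EM tables** draw per-synapse profile counts (Poisson, floored at 1),
  per-profile docked counts (Poisson, mean 4) and distances from a
  proximal-exponential (70%, scale 150 nm) + distal-Gaussian (30%,
  500 ± 50 nm) mixture, redrawn to non-negativity. Not emulated: serial-
  section correlation within a synapse, measurement quantization.

Passing parameter-recovery tests on these inputs demonstrates that the
analysis code measures what it claims on data whose generating process is
known; it does not certify performance on pathologies the generators omit
(drift, bursts, misregistration, section-to-section dependence).

## Numerical choices and degenerate inputs

Integration is trapezoidal with exact endpoint interpolation, so windowed
charges are additive to float precision. Baseline windows must be non-empty
or an error is raised; all-zero fluorescence traces, single-animal shuffles,
zero-profile EM datasets, zero pre-light event counts and degenerate
variances raise informative errors rather than emitting NaN. Fit failures
(per-event decay, charge decomposition starts) are flagged or excluded, and
every output that depends on configuration embeds the configuration (event
lists snapshot detector parameters; pipeline reports embed a config hash,
the seed, and the package version).

## Problem sizes in the verification suite

The test suite and the acceptance script are sized to run on one CPU in a
few minutes: 60 s tonic traces at 10 kHz, 100-replicate fit/frequency
simulations, 50-seed CALI recovery, 12-animal colocalization cohorts, and
20-synapse EM datasets. These sizes were chosen so that the statistical
assertions (3·SE bands, binomial bounds) are meaningful while the whole
suite stays fast; larger runs only tighten the same checks.

## Known limitations

τ_slow identifiability from a 50 ms window is intrinsic (see above). The
event detector resolves event pairs down to ≈1 ms but not closer, and its
amplitude estimate for events riding a decay subtracts a slightly elevated
local baseline. Colocalization assumes co-registered channels and a uniform
position grid (profiles are not resampled beyond truncation for shuffles).
The EM module treats distances as exact scalars; binning of distances that
sit exactly on a bin edge follows the half-open convention, which may
differ from rounding conventions used by manual measurement tools.
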