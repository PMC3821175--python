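# synaptiq

Quantification tools for synaptic physiology at the *C. elegans*
neuromuscular junction (and similar preparations): evoked-EPSC release
kinetics, miniature/tonic EPSC event statistics, immunofluorescence punctum
colocalization along the nerve cord, and docked-vesicle spatial statistics
from serial-section EM. It is written for electrophysiologists and cell
biologists who need these measurements to be reproducible, scriptable and
testable rather than spreadsheet-bound.

Every analysis stage ships with a synthetic-data generator that emits the
matching input format *with ground truth*, so the whole pipeline is
verifiable end-to-end by parameter recovery — no raw recordings required.

## The core quantities

**Evoked release kinetics.** The cumulative charge transferred during an
evoked EPSC, integrated over 50 ms after the stimulus at t₀, is decomposed
into fast and slow release components by fitting

```
Q(t) = A_fast · (1 − e^−(t−t₀)/τ_fast) + A_slow · (1 − e^−(t−t₀)/τ_slow)
```

The fitted asymptotic `A_slow` is not used directly; instead the effective
slow charge is `Q(50 ms) − A_fast` (the subtraction rule), and the fast
fraction is `A_fast / Q(50 ms)`. The package also computes peak amplitude,
the 90–10% decay time of the current (which for a pure exponential equals
τ·ln 9), windowed charges (e.g. 0–20 ms vs 25–50 ms), hypertonic-sucrose
charge transfer over the first 1 s and 5 s of application (a
readily-releasable-pool measure), and the genotype-level ratio of mean
evoked to mean sucrose charge (a release-probability proxy).

**Tonic EPSCs.** A derivative-threshold detector (robust MAD-based noise
scaling, local-baseline amplitudes, duplicate suppression) yields event
times, amplitudes and single-exponential decay constants; summaries report
frequency, means ± SEM, and the CALI time course: tEPSC frequency after a
stated illumination span normalized to the pre-light mean.

**Punctum colocalization.** Fluorescence intensities averaged over six- or
eight-pixel-wide bands along a line drawn down the nerve cord are
thresholded at the *lowest non-zero value + 3.5 × SD* of a 600 nm window
around it; peaks above threshold are punctum centers. For each reference
peak the nearest peak of the other channel within 800 nm gives the peak
distance; pixel-by-pixel Pearson correlation of paired channels is compared
with a shuffled null (channel 1 of animal i against channel 2 of animal
j ≠ i), which is nearly zero when colocalization is real rather than
chance.

**EM docked vesicles.** Distances from the dense-projection edge are sorted
into 33 nm bins and divided by the number of profiles; region summaries
(<165, <231, 231–330, >330 nm, half-open) use the synapse — a contiguous
run of profiles containing a dense projection — as the unit of replication.

**Statistics.** Mean ± SEM, two-tailed Student's t (pooled or Welch,
paired/unpaired), and one-way ANOVA with Newman–Keuls step-down post hoc
comparisons at α ∈ {0.05, 0.01, 0.001}, with studentized-range critical
values computed numerically.

## Worked example

```python
import numpy as np
from synaptiq import (EvokedParams, gen_evoked_trace, baseline_subtract,
                      peak_amplitude, cumulative_charge,
                      fit_double_exponential, decay_time_90_10)

params = EvokedParams(q_total=15.0, f_fast=0.7721, tau_fast=5.29,
                      tau_slow=40.30, noise_sd=10.0)
trace, truth = gen_evoked_trace(params, seed=42)

sweep = baseline_subtract(trace, pre_window_ms=50.0)
amp, latency = peak_amplitude(sweep, t0=100.0)
curve = cumulative_charge(sweep, t0=100.0)
decomp = fit_double_exponential(curve.time_ms, curve.charge_pc)
decay = decay_time_90_10(sweep, t0=100.0)

print(f"peak amplitude : {amp:8.1f} pA at {latency:.2f} ms")
print(f"charge (50 ms) : {curve.q50:8.2f} pC")
print(f"tau_fast       : {decomp.tau_fast:8.2f} ms")
print(f"tau_slow       : {decomp.tau_slow:8.2f} ms")
print(f"fast fraction  : {100 * decomp.f_fast:8.2f} %")
print(f"90-10% decay   : {decay.ms:8.2f} ms")
```

prints

```
peak amplitude :   2308.8 pA at 0.00 ms
charge (50 ms) :    14.98 pC
tau_fast       :     5.24 ms
tau_slow       :    36.37 ms
fast fraction  :    76.41 %
90-10% decay   :    13.39 ms
```

A single noisy sweep (10 pA current noise on a ~2.3 nA response) recovers
the generator's kinetics closely: the fast time constant within 1%, the
fast fraction within 1 percentage point, and the slow time constant within
10% — τ_slow is the least identifiable parameter because only 1.25 of its
time constants fit inside the 50 ms window. Noiseless input recovers all
three exactly (see the test suite).

The same workflow is available from the shell:

```bash
synaptiq synthgen evoked --seed 42 --out sweep.csv     # + sweep.csv.truth.json
synaptiq evoked analyze --traces sweep.csv --out results/
synaptiq synthgen em --seed 7 --out em.csv
synaptiq emdist run --data em.csv --out results/em/
synaptiq run --config examples/compare.yaml --out results/report/
```

`synaptiq run` executes a full synthetic genotype comparison (generation →
per-animal analysis → group tests) from one YAML config and writes a JSON
report plus a markdown summary with a config hash and the seed registry.

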