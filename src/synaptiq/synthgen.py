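"""Synthetic-data generators with known ground truth.

Every generator takes a parameter dataclass plus an explicit integer seed
and returns ``(data, truth)`` where ``truth`` is a JSON-serializable record
of the parameters actually realized (event times, punctum positions,
mixture specification, ...).  Identical ``(params, seed)`` give bit-identical output;
there is no hidden global random state.

What is emulated
----------------
* evoked EPSC sweeps: the current is the (negative) time derivative of a
  two-component exponential cumulative-charge curve riding on Gaussian
  current noise, so the 50 ms charge equals ``q_total`` by construction;
* tonic EPSC sweeps: homogeneous (or piecewise-rate-modulated) Poisson
  trains of quantal difference-of-exponential waveforms;
* immunofluorescence line profiles: paired Gaussian puncta in two channels
  with a controllable inter-channel displacement;
* EM docked-vesicle tables: per-profile vesicle counts with membrane
  distances drawn from a proximal/distal mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data import SweepTrace, LineProfilePair, EMDataset

__all__ = [
    "EvokedParams",
    "TonicParams",
    "ProfileParams",
    "EMGenParams",
    "gen_evoked_trace",
    "gen_tonic_trace",
    "gen_profile_pair",
    "gen_em_dataset",
    "draw_event_times",
    "quantal_kernel",
]


# ---------------------------------------------------------------------------
# evoked EPSC sweeps
# ---------------------------------------------------------------------------


@dataclass
class EvokedParams:
    """Parameters of a synthetic evoked-EPSC sweep.

    ``q_total`` is the charge transferred in the ``window_ms`` (50 ms)
    integration window after the stimulus at ``t0`` and ``f_fast`` the
    fraction of it carried by the fast component, so the slow asymptotic
    amplitude is ``(1 - f_fast) * q_total / (1 - exp(-window/tau_slow))``.
    """

    t0: float = 100.0           # stimulus time, ms
    q_total: float = 15.0       # charge over the 50 ms window, pC
    f_fast: float = 0.7721      # fast fraction of q_total
    tau_fast: float = 5.29      # ms
    tau_slow: float = 40.30     # ms
    rise_tau: float | None = None  # optional first-order rise filter, ms
    noise_sd: float = 10.0      # current noise, pA
    fs: float = 10.0            # sampling rate, kHz
    duration_ms: float = 300.0
    baseline_pA: float = 0.0
    window_ms: float = 50.0     # charge-normalization window

    def validate(self) -> None:
        if not (self.tau_fast > 0 and self.tau_slow > 0):
            raise ValueError("time constants must be positive")
        if self.tau_fast >= self.tau_slow:
            raise ValueError("tau_fast must be < tau_slow")
        if not (0.0 <= self.f_fast <= 1.0):
            raise ValueError("f_fast must be in [0, 1]")
        if self.q_total < 0:
            raise ValueError("q_total must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rise_tau is not None and self.rise_tau <= 0:
            raise ValueError("rise_tau must be positive if given")
        if not (0 <= self.t0 and self.t0 + self.window_ms <= self.duration_ms):
            raise ValueError("t0 + window must fit inside the record")


def evoked_amplitudes(p: EvokedParams) -> tuple[float, float]:
    """(A_fast, B_slow): fast charge and slow *asymptotic* amplitude."""
    a_fast = p.f_fast * p.q_total
    denom = 1.0 - np.exp(-p.window_ms / p.tau_slow)
    b_slow = (1.0 - p.f_fast) * p.q_total / denom
    return a_fast, b_slow


def evoked_charge_curve(p: EvokedParams, t_rel_ms: np.ndarray) -> np.ndarray:
    """Analytic cumulative charge Q(t) (pC) at times relative to t0."""
    a_fast, b_slow = evoked_amplitudes(p)
    t = np.asarray(t_rel_ms, dtype=float)
    return a_fast * (1.0 - np.exp(-t / p.tau_fast)) + b_slow * (
        1.0 - np.exp(-t / p.tau_slow)
    )


def gen_evoked_trace(params: EvokedParams, seed: int) -> tuple[SweepTrace, dict]:
    """Simulate an evoked-EPSC sweep; returns (trace, ground truth)."""
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_ms * params.fs)) + 1
    t = np.arange(n) / params.fs

    a_fast, b_slow = evoked_amplitudes(params)
    i_syn = np.zeros(n)
    mask = t >= params.t0
    d = t[mask] - params.t0
    # dQ/dt in pC/ms == nA; current in pA is 1000x
    rate = a_fast / params.tau_fast * np.exp(-d / params.tau_fast) + \
        b_slow / params.tau_slow * np.exp(-d / params.tau_slow)
    i_syn[mask] = 1000.0 * rate
    if params.rise_tau is not None:
        dt = 1.0 / params.fs
        alpha = dt / (params.rise_tau + dt)
        i_syn = lfilter([alpha], [1.0, alpha - 1.0], i_syn)

    current = params.baseline_pA - i_syn
    if params.noise_sd > 0:
        current = current + rng.normal(0.0, params.noise_sd, n)

    trace = SweepTrace(t, current, params.fs, {"t0_ms": params.t0})
    truth = {
        "kind": "evoked",
        "seed": int(seed),
        "params": asdict(params),
        "a_fast_pC": a_fast,
        "b_slow_pC": b_slow,
        "q50_pC": params.q_total,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# tonic EPSC sweeps
# ---------------------------------------------------------------------------


@dataclass
class TonicParams:
    """Parameters of a synthetic tonic/miniature EPSC recording.

    ``rate_profile`` is an optional piecewise-constant rate modulation given
    as a tuple of ``(t_start_s, multiplier)`` breakpoints; the multiplier is
    1 before the first breakpoint.  Used to emulate CALI time courses.
    """

    rate: float = 25.0          # Hz
    amp_mean: float = 50.0      # pA
    amp_cv: float = 0.3
    decay_tau: float = 3.0      # ms
    rise_tau: float = 0.5       # ms
    duration: float = 60.0      # s
    noise_sd: float = 5.0       # pA
    fs: float = 10.0            # kHz
    baseline_pA: float = 0.0
    rate_profile: tuple | None = None
    light_on_s: float | None = None  # optional marker passed into the trace

    def validate(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.amp_cv < 0:
            raise ValueError("amp_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rise_tau < 0 or self.decay_tau <= 0:
            raise ValueError("waveform time constants must be positive")
        if self.rise_tau >= self.decay_tau:
            raise ValueError("rise_tau must be < decay_tau")
        if self.rate_profile is not None:
            for t_start, mult in self.rate_profile:
                if mult < 0:
                    raise ValueError("rate multipliers must be >= 0")


def _rate_multiplier(times_s: np.ndarray, profile) -> np.ndarray:
    """Piecewise-constant multiplier at given times; 1 before first break."""
    starts = np.array([b[0] for b in profile])
    mults = np.array([b[1] for b in profile])
    order = np.argsort(starts)
    starts, mults = starts[order], mults[order]
    idx = np.searchsorted(starts, times_s, side="right") - 1
    out = np.ones_like(times_s, dtype=float)
    valid = idx >= 0
    out[valid] = mults[idx[valid]]
    return out


def draw_event_times(params: TonicParams, rng: np.random.Generator) -> np.ndarray:
    """Poisson event times in ms (sorted), honoring any rate profile."""
    if params.rate == 0:
        return np.empty(0)
    if params.rate_profile is None:
        n = rng.poisson(params.rate * params.duration)
        times_s = np.sort(rng.uniform(0.0, params.duration, n))
    else:
        mmax = max(1.0, max(m for _, m in params.rate_profile))
        n = rng.poisson(params.rate * mmax * params.duration)
        cand = np.sort(rng.uniform(0.0, params.duration, n))
        accept = rng.random(n) < _rate_multiplier(cand, params.rate_profile) / mmax
        times_s = cand[accept]
    return times_s * 1000.0


def quantal_kernel(fs: float, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials quantal waveform (positive)."""
    length_ms = 8.0 * decay_tau + 4.0 * max(rise_tau, 1e-9)
    tk = np.arange(int(round(length_ms * fs)) + 1) / fs
    if rise_tau <= 0:
        w = np.exp(-tk / decay_tau)
    else:
        w = np.exp(-tk / decay_tau) - np.exp(-tk / rise_tau)
        w = w / w.max()
    return w


def gen_tonic_trace(params: TonicParams, seed: int) -> tuple[SweepTrace, dict]:
    """Simulate a tonic-EPSC recording; returns (trace, ground truth)."""
    params.validate()
    rng = np.random.default_rng(seed)
    times_ms = draw_event_times(params, rng)
    n_ev = times_ms.size
    if params.amp_cv == 0:
        amps = np.full(n_ev, params.amp_mean)
    else:
        shape = 1.0 / params.amp_cv**2
        scale = params.amp_mean * params.amp_cv**2
        amps = rng.gamma(shape, scale, n_ev)

    n = int(round(params.duration * 1000.0 * params.fs)) + 1
    t = np.arange(n) / params.fs
    kernel = quantal_kernel(params.fs, params.rise_tau, params.decay_tau)
    i_syn = np.zeros(n)
    for tm, a in zip(times_ms, amps):
        i0 = int(round(tm * params.fs))
        seg = min(kernel.size, n - i0)
        if seg > 0:
            i_syn[i0:i0 + seg] += a * kernel[:seg]

    current = params.baseline_pA - i_syn
    if params.noise_sd > 0:
        current = current + rng.normal(0.0, params.noise_sd, n)

    markers = {}
    if params.light_on_s is not None:
        markers["light_on_ms"] = params.light_on_s * 1000.0
    trace = SweepTrace(t, current, params.fs, markers)
    truth = {
        "kind": "tonic",
        "seed": int(seed),
        "params": asdict(params),
        "event_times_ms": times_ms,
        "amplitudes_pA": amps,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# fluorescence line profiles
# ---------------------------------------------------------------------------


@dataclass
class ProfileParams:
    """Parameters of a paired-punctum synthetic line profile."""

    length_nm: float = 20000.0
    pixel_nm: float = 100.0
    n_puncta: int = 12
    punctum_sigma_nm: float = 150.0
    punctum_amp_range: tuple = (50.0, 200.0)  # AFU
    offset_mean_nm: float = 0.0   # ch2-vs-ch1 punctum displacement
    offset_sd_nm: float = 50.0
    baseline: float = 5.0         # AFU
    noise_sd: float = 2.0         # AFU
    coloc_prob: float = 1.0       # probability a ch1 punctum has a ch2 partner

    def validate(self) -> None:
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if self.length_nm < 10 * self.pixel_nm:
            raise ValueError("length_nm must be >= 10 pixels")
        if self.punctum_sigma_nm <= 0:
            raise ValueError("punctum_sigma_nm must be positive")
        if not (0.0 <= self.coloc_prob <= 1.0):
            raise ValueError("coloc_prob must be in [0, 1]")
        if self.n_puncta < 1:
            raise ValueError("need at least one punctum")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        spacing = 3.0 * self.punctum_sigma_nm
        usable = self.length_nm - 2 * spacing - (self.n_puncta - 1) * spacing
        if usable < 0:
            raise ValueError(
                f"{self.n_puncta} puncta cannot fit in {self.length_nm} nm "
                f"at >= {spacing} nm spacing"
            )


def gen_profile_pair(
    params: ProfileParams, seed: int, animal_id: str = "animal0"
) -> tuple[LineProfilePair, dict]:
    """Simulate a dual-channel line profile; returns (pair, ground truth)."""
    params.validate()
    rng = np.random.default_rng(seed)
    spacing = 3.0 * params.punctum_sigma_nm
    lo, hi = spacing, params.length_nm - spacing
    n = params.n_puncta
    # sorted uniforms + deterministic spacing guarantees >= 3 sigma separation
    slack = (hi - lo) - (n - 1) * spacing
    u = np.sort(rng.uniform(0.0, slack, n))
    c1 = lo + u + np.arange(n) * spacing

    partnered = rng.random(n) < params.coloc_prob
    c2 = np.empty(n)
    offsets = rng.normal(params.offset_mean_nm, params.offset_sd_nm, n)
    c2[partnered] = c1[partnered] + offsets[partnered]
    c2[~partnered] = rng.uniform(lo, hi, (~partnered).sum())
    c2 = np.clip(c2, 0.0, params.length_nm)

    a1 = rng.uniform(*params.punctum_amp_range, n)
    a2 = rng.uniform(*params.punctum_amp_range, n)

    n_pix = int(round(params.length_nm / params.pixel_nm)) + 1
    x = np.arange(n_pix) * params.pixel_nm
    sig2 = 2.0 * params.punctum_sigma_nm**2

    def render(centers, amps):
        y = np.full(n_pix, params.baseline, dtype=float)
        for c, a in zip(centers, amps):
            y += a * np.exp(-((x - c) ** 2) / sig2)
        return y

    ch1 = render(c1, a1)
    ch2 = render(c2, a2)
    if params.noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, params.noise_sd, n_pix)
        ch2 = ch2 + rng.normal(0.0, params.noise_sd, n_pix)
    ch1 = np.clip(ch1, 0.0, None)
    ch2 = np.clip(ch2, 0.0, None)

    pair = LineProfilePair(animal_id, x, ch1, ch2)
    truth = {
        "kind": "profile",
        "seed": int(seed),
        "animal_id": animal_id,
        "params": {**asdict(params),
                   "punctum_amp_range": list(params.punctum_amp_range)},
        "ch1_centers_nm": c1,
        "ch2_centers_nm": c2,
        "partnered": partnered,
        "pair_offsets_nm": np.where(partnered, c2 - c1, np.nan),
    }
    return pair, truth


# ---------------------------------------------------------------------------
# EM docked-vesicle tables
# ---------------------------------------------------------------------------


@dataclass
class EMGenParams:
    """Parameters of a synthetic docked-vesicle EM dataset.

    ``distance_mixture`` is a tuple of ``(weight, kind, loc, scale)``
    components with kind in {"expon", "norm"}; distances are redrawn until
    non-negative (a zero scale gives the point mass at ``loc``).
    """

    n_synapses: int = 20
    mean_profiles_per_synapse: float = 6.0   # Poisson, floored at 1
    vesicles_per_profile: float = 4.0        # Poisson mean
    distance_mixture: tuple = (
        (0.7, "expon", 0.0, 150.0),
        (0.3, "norm", 500.0, 50.0),
    )
    n_animals: int = 5

    def validate(self) -> None:
        if self.n_synapses < 1 or self.n_animals < 1:
            raise ValueError("counts must be >= 1")
        if self.mean_profiles_per_synapse < 1:
            raise ValueError("mean_profiles_per_synapse must be >= 1")
        if self.vesicles_per_profile < 0:
            raise ValueError("vesicles_per_profile must be >= 0")
        w = sum(c[0] for c in self.distance_mixture)
        if not np.isclose(w, 1.0):
            raise ValueError("mixture weights must sum to 1")
        for _, kind, _, scale in self.distance_mixture:
            if kind not in ("expon", "norm"):
                raise ValueError(f"unknown mixture kind {kind!r}")
            if scale < 0:
                raise ValueError("mixture scales must be >= 0")


def sample_distances(
    mixture, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n non-negative distances (nm) from the component mixture."""
    weights = np.array([c[0] for c in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for k, (_, kind, loc, scale) in enumerate(mixture):
        m = comp == k
        cnt = int(m.sum())
        if cnt == 0:
            continue
        if scale == 0:
            out[m] = loc
        elif kind == "expon":
            out[m] = loc + rng.exponential(scale, cnt)
        else:
            d = rng.normal(loc, scale, cnt)
            for _ in range(100):
                neg = d < 0
                if not neg.any():
                    break
                d[neg] = rng.normal(loc, scale, int(neg.sum()))
            out[m] = np.abs(d)
    return out


def gen_em_dataset(
    params: EMGenParams, seed: int, genotype: str = "wt"
) -> tuple[EMDataset, dict]:
    """Simulate a docked-vesicle distance table; returns (dataset, truth)."""
    params.validate()
    rng = np.random.default_rng(seed)
    rows = []
    profile_counts = []
    total_vesicles = 0
    for s in range(params.n_synapses):
        animal = f"an{s % params.n_animals:02d}"
        syn = f"{genotype}_syn{s:03d}"
        n_prof = max(1, int(rng.poisson(params.mean_profiles_per_synapse)))
        profile_counts.append(n_prof)
        for p in range(n_prof):
            prof = f"{syn}_p{p:02d}"
            n_ves = int(rng.poisson(params.vesicles_per_profile))
            if n_ves == 0:
                rows.append((animal, genotype, syn, prof, np.nan, True))
            else:
                dists = sample_distances(params.distance_mixture, n_ves, rng)
                total_vesicles += n_ves
                for d in dists:
                    rows.append((animal, genotype, syn, prof, float(d), True))
    df = pd.DataFrame(
        rows,
        columns=["animal", "genotype", "synapse_id", "profile_id",
                 "distance_nm", "has_dense_projection"],
    )
    dataset = EMDataset(df)
    truth = {
        "kind": "em",
        "seed": int(seed),
        "genotype": genotype,
        "params": {**asdict(params),
                   "distance_mixture": [list(c) for c in params.distance_mixture]},
        "profiles_per_synapse": profile_counts,
        "total_vesicles": int(total_vesicles),
    }
    return dataset, truth
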