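"""Evoked-EPSC and sucrose-response analysis.

Charge convention: currents are pA with inward negative; integrating
``-current`` over time in ms and dividing by 1000 gives charge in pC
(pA*s = pC).  Reported charges are therefore positive for inward synaptic
currents.  The kinetic decomposition fits

    Q(t) = A_fast * (1 - exp(-(t - t0)/tau_fast))
         + A_slow * (1 - exp(-(t - t0)/tau_slow))

to the cumulative charge, then applies the subtraction rule: the effective
slow size is the total 50 ms charge minus A_fast, and the fast fraction is
A_fast / Q(50 ms) — the asymptotic A_slow of the fit is reported but not
used for the fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls
from sklearn.base import BaseEstimator

from .data import SweepTrace

__all__ = [
    "ChargeDecomposition",
    "CumulativeCharge",
    "SucroseCharges",
    "DecayTime",
    "DoubleExponentialChargeFit",
    "baseline_subtract",
    "blank_artifact",
    "peak_amplitude",
    "cumulative_charge",
    "fit_double_exponential",
    "decay_time_90_10",
    "windowed_charge",
    "sucrose_charges",
    "release_ratio",
    "analyze_sweep",
]


# ---------------------------------------------------------------------------
# pre-processing and integration
# ---------------------------------------------------------------------------


def baseline_subtract(
    trace: SweepTrace, pre_window_ms: float, marker: str = "t0_ms"
) -> SweepTrace:
    """Subtract the mean current of the window just before a marker."""
    if marker not in trace.markers:
        raise ValueError(f"trace has no marker {marker!r}")
    ref = trace.markers[marker]
    mask = (trace.time_ms >= ref - pre_window_ms) & (trace.time_ms < ref)
    if not mask.any():
        raise ValueError("empty baseline window")
    out = trace.copy()
    out.current_pA = out.current_pA - trace.current_pA[mask].mean()
    return out


def blank_artifact(trace: SweepTrace, t0: float, width_ms: float = 0.7) -> SweepTrace:
    """Replace the stimulus-artifact window [t0, t0+width] by linear interpolation."""
    out = trace.copy()
    mask = (out.time_ms >= t0) & (out.time_ms <= t0 + width_ms)
    if mask.sum() < 1:
        return out
    idx = np.where(mask)[0]
    i0 = max(idx[0] - 1, 0)
    i1 = min(idx[-1] + 1, out.n_samples - 1)
    out.current_pA[idx] = np.interp(
        out.time_ms[idx],
        [out.time_ms[i0], out.time_ms[i1]],
        [out.current_pA[i0], out.current_pA[i1]],
    )
    return out


def peak_amplitude(
    trace: SweepTrace, t0: float, search_ms: float = 20.0
) -> tuple[float, float]:
    """Peak inward deflection (pA, magnitude) and its latency (ms) after t0."""
    mask = (trace.time_ms >= t0) & (trace.time_ms <= t0 + search_ms)
    if not mask.any():
        raise ValueError("empty search window")
    y = -trace.current_pA[mask]
    i = int(np.argmax(y))
    amp = max(float(y[i]), 0.0)
    latency = float(trace.time_ms[mask][i] - t0)
    if amp == 0.0:
        latency = 0.0
    return amp, latency


@dataclass
class CumulativeCharge:
    """Cumulative charge transfer from t0, time relative to t0 in ms."""

    time_ms: np.ndarray   # relative to t0, starts at 0
    charge_pc: np.ndarray
    q_final: float        # charge at the end of the window (pC)

    @property
    def q50(self) -> float:
        return self.q_final


def _integrate(trace: SweepTrace, t_start: float, t_stop: float) -> float:
    """Trapezoidal integral of -current over [t_start, t_stop], in pC."""
    t, i = trace.time_ms, trace.current_pA
    if t_start < t[0] - 1e-9 or t_stop > t[-1] + 1e-9:
        raise ValueError("integration window outside record")
    inner = (t > t_start) & (t < t_stop)
    tt = np.concatenate(([t_start], t[inner], [t_stop]))
    yy = np.concatenate(
        ([np.interp(t_start, t, i)], i[inner], [np.interp(t_stop, t, i)])
    )
    return float(np.trapezoid(-yy, tt)) / 1000.0


def cumulative_charge(
    trace: SweepTrace, t0: float, duration_ms: float = 50.0
) -> CumulativeCharge:
    """Cumulative trapezoidal charge (pC) over ``duration_ms`` after t0."""
    from scipy.integrate import cumulative_trapezoid

    t, i = trace.time_ms, trace.current_pA
    if t0 < t[0] - 1e-9 or t0 + duration_ms > t[-1] + 1e-9:
        raise ValueError("t0 + duration beyond record")
    inner = (t > t0) & (t < t0 + duration_ms)
    tt = np.concatenate(([t0], t[inner], [t0 + duration_ms]))
    yy = np.concatenate(
        ([np.interp(t0, t, i)], i[inner], [np.interp(t0 + duration_ms, t, i)])
    )
    q = cumulative_trapezoid(-yy, tt, initial=0.0) / 1000.0
    return CumulativeCharge(tt - t0, q, float(q[-1]))


def windowed_charge(
    trace: SweepTrace, t0: float, windows: list[tuple[float, float]]
) -> list[float]:
    """Charge (pC) per [start, stop) window, offsets in ms relative to t0."""
    ws = sorted(windows)
    for (a, b) in ws:
        if b <= a:
            raise ValueError(f"window ({a}, {b}) is empty or reversed")
    for (a0, b0), (a1, b1) in zip(ws, ws[1:]):
        if a1 < b0:
            raise ValueError(f"windows ({a0},{b0}) and ({a1},{b1}) overlap")
    return [_integrate(trace, t0 + a, t0 + b) for (a, b) in windows]


# ---------------------------------------------------------------------------
# double-exponential charge decomposition
# ---------------------------------------------------------------------------


@dataclass
class ChargeDecomposition:
    """Result of the two-component cumulative-charge fit."""

    q50: float            # total transferred charge over the window (pC)
    a_fast: float         # fast component size (pC)
    tau_fast: float       # ms
    tau_slow: float       # ms
    a_slow_eff: float     # q50 - a_fast, per the subtraction rule (pC)
    f_fast: float         # a_fast / q50
    a_slow_asymptotic: float  # fitted A_slow (not used for f_fast)
    residual_norm: float
    converged: bool
    flags: list = field(default_factory=list)


def _biexp_q(t, a_f, a_s, tau_f, tau_s):
    return a_f * (1.0 - np.exp(-t / tau_f)) + a_s * (1.0 - np.exp(-t / tau_s))


class DoubleExponentialChargeFit(BaseEstimator):
    """Two-component exponential fit of a cumulative-charge curve.

    scikit-learn style estimator: ``fit(t_ms, q_pc)`` expects time relative
    to the stimulus (starting at 0) and the cumulative charge in pC.  After
    fitting, the kinetic parameters are available as trailing-underscore
    attributes and as ``decomposition_``.

    Parameters
    ----------
    window_ms : float
        Charge-integration window defining q50 (default 50 ms).
    tau_min, tau_max : float
        Bounds on both time constants (ms).
    n_starts : int
        Number of deterministic log-spaced (tau_fast, tau_slow) starts.
    """

    def __init__(self, window_ms: float = 50.0, tau_min: float = 0.1,
                 tau_max: float = 500.0, n_starts: int = 8):
        self.window_ms = window_ms
        self.tau_min = tau_min
        self.tau_max = tau_max
        self.n_starts = n_starts

    def _starts(self):
        base = np.geomspace(self.tau_min * 5, self.tau_max / 10.0,
                            max(self.n_starts // 2, 1))
        pairs = []
        for tf in base:
            for k in (4.0, 16.0):
                ts = min(tf * k, self.tau_max * 0.99)
                pairs.append((tf, ts))
        return pairs[: self.n_starts]

    def fit(self, t_ms, q_pc):
        t = np.asarray(t_ms, dtype=float)
        q = np.asarray(q_pc, dtype=float)
        if t.size != q.size:
            raise ValueError("t and q must have equal length")
        if t.size < 20:
            raise ValueError("need at least 20 samples to fit")
        if t[0] > 1e-6:
            raise ValueError("time must be relative to the stimulus (start at 0)")

        q50 = float(np.interp(self.window_ms, t, q))
        lb = [0.0, 0.0, self.tau_min, self.tau_min]
        ub = [np.inf, np.inf, self.tau_max, self.tau_max]

        best = None
        flags: list[str] = []
        for tf0, ts0 in self._starts():
            # amplitudes initialized by NNLS at the candidate time constants
            design = np.column_stack(
                [1.0 - np.exp(-t / tf0), 1.0 - np.exp(-t / ts0)]
            )
            try:
                amps0, _ = nnls(design, q)
            except Exception:
                amps0 = np.array([q50 / 2, q50 / 2])
            p0 = [max(amps0[0], 1e-12), max(amps0[1], 1e-12), tf0, ts0]
            try:
                popt, _ = curve_fit(
                    _biexp_q, t, q, p0=p0, bounds=(lb, ub), maxfev=20000
                )
            except Exception:
                continue
            resid = _biexp_q(t, *popt) - q
            sse = float(resid @ resid)
            if best is None or sse < best[1]:
                best = (popt, sse)

        if best is None:
            self.converged_ = False
            self.decomposition_ = ChargeDecomposition(
                q50, math.nan, math.nan, math.nan, math.nan, math.nan,
                math.nan, math.inf, False, ["no start converged"],
            )
            self._expose()
            return self

        (a_f, a_s, tau_f, tau_s), sse = best
        if tau_f > tau_s:  # order components: fast = smaller tau
            a_f, a_s, tau_f, tau_s = a_s, a_f, tau_s, tau_f
        for tau, name in ((tau_f, "tau_fast"), (tau_s, "tau_slow")):
            if tau < self.tau_min * (1 + 1e-6) or tau > self.tau_max * (1 - 1e-6):
                flags.append(f"{name} at bound")
        if np.isclose(tau_f, tau_s, rtol=1e-3):
            flags.append("tau collision")

        a_slow_eff = q50 - a_f
        f_fast = a_f / q50 if q50 > 0 else math.nan
        if not (0.0 <= f_fast <= 1.0):
            flags.append("f_fast clipped")
            f_fast = min(max(f_fast, 0.0), 1.0)

        self.converged_ = True
        self.decomposition_ = ChargeDecomposition(
            q50=q50, a_fast=float(a_f), tau_fast=float(tau_f),
            tau_slow=float(tau_s), a_slow_eff=float(a_slow_eff),
            f_fast=float(f_fast), a_slow_asymptotic=float(a_s),
            residual_norm=math.sqrt(sse), converged=True, flags=flags,
        )
        self._expose()
        return self

    def _expose(self):
        d = self.decomposition_
        self.q50_ = d.q50
        self.a_fast_ = d.a_fast
        self.tau_fast_ = d.tau_fast
        self.tau_slow_ = d.tau_slow
        self.a_slow_eff_ = d.a_slow_eff
        self.f_fast_ = d.f_fast
        self.flags_ = d.flags


def fit_double_exponential(
    t_ms, q_pc, t0: float = 0.0, window_ms: float = 50.0
) -> ChargeDecomposition:
    """Fit the two-component charge model; ``t0`` shifts absolute times."""
    t = np.asarray(t_ms, dtype=float) - t0
    est = DoubleExponentialChargeFit(window_ms=window_ms)
    est.fit(t, q_pc)
    return est.decomposition_


# ---------------------------------------------------------------------------
# decay time and sucrose responses
# ---------------------------------------------------------------------------


@dataclass
class DecayTime:
    """90-10% decay interval; ``censored`` if the trace never reaches 10%."""

    ms: float
    censored: bool
    t90_ms: float
    t10_ms: float


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First downward crossing of ``level`` (linear interpolation)."""
    below = y <= level
    if not below.any():
        return None
    k = int(np.argmax(below))
    if k == 0:
        return float(t[0])
    y0, y1 = y[k - 1], y[k]
    frac = (y0 - level) / (y0 - y1) if y0 != y1 else 1.0
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def decay_time_90_10(
    trace: SweepTrace, t0: float, smooth_ms: float = 0.0
) -> DecayTime:
    """Time between the decay-phase 90% and 10% crossings of the peak."""
    mask = trace.time_ms >= t0
    t = trace.time_ms[mask]
    y = -trace.current_pA[mask]
    if smooth_ms > 0:
        w = max(int(round(smooth_ms * trace.fs_khz)), 1)
        y = np.convolve(y, np.ones(w) / w, mode="same")
    ip = int(np.argmax(y))
    peak = y[ip]
    if peak <= 0:
        raise ValueError("no inward peak after t0")
    td, yd = t[ip:], y[ip:]
    t90 = _crossing_time(td, yd, 0.9 * peak)
    t10 = _crossing_time(td, yd, 0.1 * peak)
    if t90 is None:
        raise ValueError("trace never decays below 90% of peak")
    if t10 is None:
        return DecayTime(float(td[-1] - t90), True, t90, math.nan)
    return DecayTime(t10 - t90, False, t90, t10)


@dataclass
class SucroseCharges:
    """Baseline-compensated charge in the first 1 s / 5 s of application."""

    q_1s: float
    q_5s: float
    censored: bool = False


def sucrose_charges(
    trace: SweepTrace,
    app_start_ms: float | None = None,
    windows_s: tuple[float, float] = (1.0, 5.0),
    baseline_window_ms: float = 500.0,
) -> SucroseCharges:
    """Charge transfer (pC) in the stated windows of sucrose application."""
    if app_start_ms is None:
        app_start_ms = trace.markers.get("app_start_ms")
        if app_start_ms is None:
            raise ValueError("no app_start_ms marker and none given")
    if app_start_ms >= trace.time_ms[-1]:
        raise ValueError("application start beyond record")
    comp = baseline_subtract(
        SweepTrace(trace.time_ms, trace.current_pA, trace.fs_khz,
                   {**trace.markers, "app_start_ms": app_start_ms}),
        baseline_window_ms, marker="app_start_ms",
    )
    qs = []
    censored = False
    for w in windows_s:
        stop = app_start_ms + w * 1000.0
        if stop > comp.time_ms[-1]:
            stop = comp.time_ms[-1]
            censored = True
        qs.append(_integrate(comp, app_start_ms, stop))
    return SucroseCharges(qs[0], qs[1], censored)


def release_ratio(mean_eepsc_q50: float, mean_sucrose_q5s: float) -> float:
    """Genotype-level release-probability proxy: eEPSC charge / RRP charge."""
    if mean_sucrose_q5s <= 0:
        raise ValueError("sucrose charge must be positive")
    if mean_eepsc_q50 <= 0:
        raise ValueError("eEPSC charge must be positive")
    return mean_eepsc_q50 / mean_sucrose_q5s


# ---------------------------------------------------------------------------
# per-sweep convenience pipeline
# ---------------------------------------------------------------------------


def analyze_sweep(
    trace: SweepTrace,
    t0: float | None = None,
    duration_ms: float = 50.0,
    pre_window_ms: float = 50.0,
    artifact_blank_ms: float = 0.0,
    windows: list[tuple[float, float]] | None = None,
) -> dict:
    """Full evoked analysis of one sweep: amplitude, q50, fit, decay, windows."""
    if t0 is None:
        t0 = trace.markers.get("t0_ms")
        if t0 is None:
            raise ValueError("no t0 marker and none given")
    sub = baseline_subtract(trace, pre_window_ms, marker="t0_ms") \
        if "t0_ms" in trace.markers else trace
    if artifact_blank_ms > 0:
        sub = blank_artifact(sub, t0, artifact_blank_ms)
    amp, latency = peak_amplitude(sub, t0)
    curve = cumulative_charge(sub, t0, duration_ms)
    decomp = fit_double_exponential(curve.time_ms, curve.charge_pc,
                                    window_ms=duration_ms)
    decay = decay_time_90_10(sub, t0)
    out = {
        "peak_amplitude_pA": amp,
        "peak_latency_ms": latency,
        "q50_pC": curve.q_final,
        "tau_fast_ms": decomp.tau_fast,
        "tau_slow_ms": decomp.tau_slow,
        "a_fast_pC": decomp.a_fast,
        "a_slow_eff_pC": decomp.a_slow_eff,
        "f_fast": decomp.f_fast,
        "fit_converged": decomp.converged,
        "fit_flags": decomp.flags,
        "decay_90_10_ms": decay.ms,
        "decay_censored": decay.censored,
    }
    if windows:
        out["windowed_charge_pC"] = windowed_charge(sub, t0, windows)
    return out
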