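"""Tonic/miniature EPSC event detection and statistics.

The detector is derivative-threshold based: the trace is median-detrended,
low-pass filtered, and differentiated; onsets are rising-edge crossings of
``threshold_sd`` times a robust (MAD-based) estimate of the derivative
noise SD.  Event amplitude is the local peak minus the median of a short
pre-event baseline; events below ``min_amp_pA`` or within ``refractory_ms``
of a larger event are dropped.  All detection parameters are snapshotted
into the resulting :class:`EventList`.

Also provides the CALI illumination time-course: per-bin event frequencies
and the post-illumination frequency normalized to the pre-light mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .data import SweepTrace

__all__ = [
    "EventList",
    "EventDetector",
    "CaliTimecourse",
    "detect_events",
    "event_decay_time",
    "measure_decay_times",
    "event_summary",
    "cali_timecourse",
]


@dataclass
class EventList:
    """Detected (or ground-truth) quantal events in one trace."""

    times_ms: np.ndarray
    amplitudes_pA: np.ndarray
    duration_s: float
    decay_ms: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=float)
        if self.times_ms.size != self.amplitudes_pA.size:
            raise ValueError("times and amplitudes must have equal length")
        if self.times_ms.size > 1 and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.amplitudes_pA <= 0):
            raise ValueError("amplitudes must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")

    @property
    def n(self) -> int:
        return self.times_ms.size

    @property
    def frequency_hz(self) -> float:
        return self.n / self.duration_s


class EventDetector(BaseEstimator):
    """Derivative-threshold miniature-event detector.

    ``fit(trace)`` sets ``events_`` (an :class:`EventList`).

    Candidate onsets come from three derivative criteria, merged: rising-edge
    crossings of the absolute threshold; local derivative maxima whose
    locally-windowed prominence exceeds the threshold (these catch events
    riding the decay of a predecessor, where the decay slope cancels part of
    the rise); and, inside an above-threshold run, interior maxima at
    ``split_fraction`` of the threshold (these split near-coincident rises).
    A candidate is kept if its amplitude (peak minus the local pre-event
    baseline median) reaches ``min_amp_pA`` and at least half of that
    amplitude is an actual rise from the onset sample (suppresses duplicate
    triggers on the shoulder of an already-detected event).

    Parameters
    ----------
    threshold_sd : float
        Onset threshold in robust (MAD-based) SDs of the smoothed-derivative
        noise.
    min_amp_pA : float
        Minimum event amplitude (peak minus local pre-event baseline).
    refractory_ms : float
        Duplicate-suppression window: of two candidates closer than this,
        only the larger is kept.
    smooth_sigma_ms : float
        Gaussian low-pass sigma applied before differentiation.
    peak_window_ms : float
        Window after onset searched for the event peak.
    baseline_window_ms : float
        Pre-onset window whose median defines the local baseline.
    prominence_wlen_ms : float
        Window limiting the prominence bases of derivative peaks.
    split_fraction : float
        Prominence fraction for splitting merged rises inside a run.
    """

    def __init__(self, threshold_sd: float = 4.0, min_amp_pA: float = 10.0,
                 refractory_ms: float = 0.7, smooth_sigma_ms: float = 0.3,
                 peak_window_ms: float = 3.0, baseline_window_ms: float = 0.6,
                 prominence_wlen_ms: float = 4.0, split_fraction: float = 0.5):
        self.threshold_sd = threshold_sd
        self.min_amp_pA = min_amp_pA
        self.refractory_ms = refractory_ms
        self.smooth_sigma_ms = smooth_sigma_ms
        self.peak_window_ms = peak_window_ms
        self.baseline_window_ms = baseline_window_ms
        self.prominence_wlen_ms = prominence_wlen_ms
        self.split_fraction = split_fraction

    def fit(self, trace: SweepTrace):
        from scipy.signal import find_peaks

        if not np.all(np.isfinite(trace.current_pA)):
            raise ValueError("trace contains non-finite samples")
        fs = trace.fs_khz
        y = -(trace.current_pA - np.median(trace.current_pA))  # inward positive
        ys = gaussian_filter1d(y, max(self.smooth_sigma_ms * fs, 1e-9))
        d = np.diff(ys) * fs  # pA/ms
        mad = np.median(np.abs(d - np.median(d)))
        sd = 1.4826 * mad
        if sd == 0:
            sd = max(float(np.std(d)), 1e-12)
        thr = self.threshold_sd * sd
        merge = max(int(round(self.refractory_ms * fs)), 1)
        wlen = max(int(round(self.prominence_wlen_ms * fs)), 3)

        above = d > thr
        onsets = set(np.where(above & ~np.roll(above, 1))[0].tolist())
        pk, _ = find_peaks(d, prominence=thr, wlen=wlen)
        ons = np.array(sorted(onsets))
        for i in pk:
            if ons.size == 0 or np.min(np.abs(ons - i)) > merge:
                onsets.add(int(i))
        pk2, _ = find_peaks(d, prominence=self.split_fraction * thr, wlen=wlen)
        ons = np.array(sorted(onsets))
        for i in pk2:
            if above[i] and (ons.size == 0 or np.min(np.abs(ons - i)) > merge):
                onsets.add(int(i))

        n = ys.size
        pk_w = max(int(round(self.peak_window_ms * fs)), 1)
        bl_w = max(int(round(self.baseline_window_ms * fs)), 1)
        cands = []
        for i in sorted(onsets):
            if i <= 0:
                continue
            stop = min(i + pk_w, n)
            pk_idx = i + int(np.argmax(ys[i:stop]))
            base = np.median(ys[max(i - bl_w, 0):i])
            amp = ys[pk_idx] - base
            rise = ys[pk_idx] - ys[i]
            if amp >= self.min_amp_pA and rise >= 0.5 * amp:
                cands.append((trace.time_ms[i], float(amp)))

        # refractory: greedy by amplitude, drop smaller neighbours
        cands.sort(key=lambda c: -c[1])
        kept: list[tuple[float, float]] = []
        for t, a in cands:
            if all(abs(t - tk) >= self.refractory_ms for tk, _ in kept):
                kept.append((t, a))
        kept.sort()

        times = np.array([t for t, _ in kept])
        amps = np.array([a for _, a in kept])
        self.events_ = EventList(
            times, amps, trace.duration_ms / 1000.0,
            config=self.get_params(),
        )
        return self


def detect_events(
    trace: SweepTrace,
    threshold_sd: float = 4.0,
    min_amp_pA: float = 10.0,
    refractory_ms: float = 0.7,
    **kwargs,
) -> EventList:
    """Detect miniature events; see :class:`EventDetector`."""
    det = EventDetector(threshold_sd=threshold_sd, min_amp_pA=min_amp_pA,
                        refractory_ms=refractory_ms, **kwargs)
    return det.fit(trace).events_


# ---------------------------------------------------------------------------
# per-event decay
# ---------------------------------------------------------------------------


def event_decay_time(
    trace: SweepTrace,
    event_time_ms: float,
    fit_window_ms: float = 15.0,
    peak_search_ms: float = 5.0,
    baseline_window_ms: float = 2.0,
    skip_ms: float = 1.5,
) -> float:
    """Single-exponential decay constant (ms) of one event; NaN on failure.

    The fit starts ``skip_ms`` after the peak so the (faster) rise component
    of the quantal waveform does not bias the decay estimate.
    """
    fs = trace.fs_khz
    y = -(trace.current_pA - np.median(trace.current_pA))
    i0 = trace.index_at(event_time_ms)
    i0 = min(max(i0, 0), y.size - 2)
    stop = min(i0 + int(round(peak_search_ms * fs)), y.size)
    pk = i0 + int(np.argmax(y[i0:stop]))
    bl_w = max(int(round(baseline_window_ms * fs)), 1)
    base = np.median(y[max(i0 - bl_w, 0):i0]) if i0 > 0 else 0.0
    amp = y[pk] - base
    if amp <= 0:
        return math.nan
    start = pk + int(round(skip_ms * fs))
    end = min(pk + int(round(fit_window_ms * fs)) + 1, y.size)
    td = (np.arange(start, end) - pk) / fs
    yd = y[start:end] - base
    if td.size < 5:
        return math.nan
    try:
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            td, yd, p0=[amp, max(fit_window_ms / 5.0, 0.5)],
            bounds=([0.0, 1e-3], [np.inf, 1e3]), maxfev=5000,
        )
    except Exception:
        return math.nan
    return float(popt[1])


def measure_decay_times(trace: SweepTrace, events: EventList, **kwargs) -> EventList:
    """Attach per-event decay constants to an EventList (NaN where fit fails)."""
    decays = np.array(
        [event_decay_time(trace, t, **kwargs) for t in events.times_ms]
    )
    return EventList(events.times_ms, events.amplitudes_pA, events.duration_s,
                     decay_ms=decays, config=events.config)


# ---------------------------------------------------------------------------
# summaries and CALI time course
# ---------------------------------------------------------------------------


def event_summary(events: EventList) -> dict:
    """Frequency (Hz), mean amplitude and decay +- SEM over detected events."""
    out = {"n_events": events.n, "frequency_hz": events.frequency_hz}
    for name, vals in (
        ("amplitude_pA", events.amplitudes_pA),
        ("decay_ms", events.decay_ms if events.decay_ms is not None else None),
    ):
        if vals is None:
            continue
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[f"mean_{name}"] = math.nan
            out[f"sem_{name}"] = math.nan
        else:
            out[f"mean_{name}"] = float(vals.mean())
            out[f"sem_{name}"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1 else math.nan
            )
    return out


@dataclass
class CaliTimecourse:
    """Binned tEPSC frequencies around a light-on marker."""

    bin_edges_s: np.ndarray
    frequency_hz: np.ndarray
    light_on_ms: float
    span_s: float
    pre_mean_hz: float
    normalized_post: float


def cali_timecourse(
    events_or_trace,
    light_on_ms: float | None = None,
    span_s: float = 120.0,
    bin_s: float = 30.0,
    detector: EventDetector | None = None,
) -> CaliTimecourse:
    """CALI normalization: frequency in the bin starting at light_on + span,
    divided by the mean pre-light frequency.

    Accepts either a :class:`SweepTrace` (events are detected) or an
    :class:`EventList`.
    """
    if isinstance(events_or_trace, SweepTrace):
        trace = events_or_trace
        if light_on_ms is None:
            light_on_ms = trace.markers.get("light_on_ms")
        events = (detector or EventDetector()).fit(trace).events_
    else:
        events = events_or_trace
    if light_on_ms is None:
        raise ValueError("light_on_ms required (no marker found)")
    duration_s = events.duration_s
    light_s = light_on_ms / 1000.0
    if not (0 < light_s < duration_s):
        raise ValueError("light_on must lie inside the record")

    t_s = events.times_ms / 1000.0
    edges = np.arange(0.0, duration_s + 1e-9, bin_s)
    if edges[-1] < duration_s:  # trailing partial bin
        edges = np.append(edges, duration_s)
    counts, _ = np.histogram(t_s, bins=edges)
    widths = np.diff(edges)
    freq = counts / widths

    n_pre = int((t_s < light_s).sum())
    pre_mean = n_pre / light_s
    if pre_mean == 0:
        raise ValueError("zero pre-light frequency")
    post_start = light_s + span_s
    post_stop = min(post_start + bin_s, duration_s)
    if post_stop <= post_start:
        raise ValueError("post-illumination bin lies beyond the record")
    n_post = int(((t_s >= post_start) & (t_s < post_stop)).sum())
    post_freq = n_post / (post_stop - post_start)

    return CaliTimecourse(
        bin_edges_s=edges, frequency_hz=freq, light_on_ms=float(light_on_ms),
        span_s=span_s, pre_mean_hz=float(pre_mean),
        normalized_post=float(post_freq / pre_mean),
    )
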