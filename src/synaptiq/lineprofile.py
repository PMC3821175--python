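"""Dual-channel line-profile colocalization along a nerve cord.

Implements the punctum-colocalization workflow: per-channel intensity
thresholds from the lowest non-zero value plus a multiple of the local SD,
peak calling above threshold, nearest-peak distances between channels with
an 800 nm matching cutoff, pixel-by-pixel Pearson correlation of paired
channels, and a shuffled (between-animal) null correlation.

The animal is the unit of replication throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.base import BaseEstimator

from .data import LineProfilePair

__all__ = [
    "PeakSet",
    "ColocResult",
    "NearestPeakResult",
    "PeakCaller",
    "extract_line_profile",
    "estimate_threshold",
    "detect_peaks",
    "nearest_peak_distances",
    "paired_correlation",
    "shuffled_correlation",
    "analyze_pair",
    "summarize_coloc",
]


# ---------------------------------------------------------------------------
# thresholding and peak calling
# ---------------------------------------------------------------------------


def estimate_threshold(
    position_nm: np.ndarray,
    intensity: np.ndarray,
    sd_multiplier: float = 3.5,
    window_nm: float = 600.0,
) -> float:
    """Detection threshold: lowest non-zero intensity + multiplier x local SD.

    The SD is the sample SD (ddof=1) of the trace within +-window_nm/2 of the
    lowest non-zero sample, window clipped at the profile ends; zero-valued
    pixels inside the window are included.
    """
    x = np.asarray(position_nm, dtype=float)
    y = np.asarray(intensity, dtype=float)
    nz = y > 0
    if not nz.any():
        raise ValueError("no non-zero floor: trace is all zero")
    idx_nz = np.where(nz)[0]
    floor_idx = idx_nz[np.argmin(y[idx_nz])]
    floor = float(y[floor_idx])
    half = window_nm / 2.0
    win = np.abs(x - x[floor_idx]) <= half + 1e-9
    if win.sum() < 3:
        raise ValueError("fewer than 3 samples in the SD window")
    sd = float(np.std(y[win], ddof=1))
    return floor + sd_multiplier * sd


@dataclass
class PeakSet:
    """Called peaks of one channel: positions, heights, threshold used."""

    channel: str
    positions_nm: np.ndarray
    heights: np.ndarray
    threshold: float

    def __post_init__(self):
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if np.any(self.heights <= self.threshold):
            raise ValueError("every peak height must exceed the threshold")

    @property
    def n(self) -> int:
        return self.positions_nm.size


def detect_peaks(
    position_nm: np.ndarray,
    intensity: np.ndarray,
    threshold: float,
    min_separation_nm: float = 200.0,
) -> PeakSet:
    """Local maxima strictly above ``threshold``.

    Plateau maxima report their centroid position; maxima closer than
    ``min_separation_nm`` are merged keeping the higher.
    """
    x = np.asarray(position_nm, dtype=float)
    y = np.asarray(intensity, dtype=float)
    idx, props = signal.find_peaks(y, plateau_size=1)
    if idx.size == 0:
        return PeakSet("", np.empty(0), np.empty(0), threshold)
    centroids = (props["left_edges"] + props["right_edges"]) / 2.0
    heights = y[idx]
    keep = heights > threshold
    centroids, heights = centroids[keep], heights[keep]
    pos = np.interp(centroids, np.arange(x.size), x)

    # greedy merge: highest first, drop anything within min_separation
    order = np.argsort(heights)[::-1]
    kept: list[int] = []
    for k in order:
        if all(abs(pos[k] - pos[j]) >= min_separation_nm for j in kept):
            kept.append(k)
    kept = sorted(kept, key=lambda k: pos[k])
    return PeakSet("", pos[kept], heights[kept], threshold)


class PeakCaller(BaseEstimator):
    """Threshold estimation + peak calling for one profile channel.

    ``fit(position_nm, intensity)`` sets ``threshold_`` (estimated by the
    lowest-nonzero + sd_multiplier x SD rule unless ``threshold`` overrides
    it) and ``peaks_`` (a :class:`PeakSet`).
    """

    def __init__(self, sd_multiplier: float = 3.5, window_nm: float = 600.0,
                 min_separation_nm: float = 200.0,
                 threshold: float | None = None, channel: str = ""):
        self.sd_multiplier = sd_multiplier
        self.window_nm = window_nm
        self.min_separation_nm = min_separation_nm
        self.threshold = threshold
        self.channel = channel

    def fit(self, position_nm, intensity):
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            self.threshold_overridden_ = True
        else:
            self.threshold_ = estimate_threshold(
                position_nm, intensity, self.sd_multiplier, self.window_nm
            )
            self.threshold_overridden_ = False
        peaks = detect_peaks(
            position_nm, intensity, self.threshold_, self.min_separation_nm
        )
        peaks.channel = self.channel
        self.peaks_ = peaks
        return self


# ---------------------------------------------------------------------------
# nearest-peak distances
# ---------------------------------------------------------------------------


@dataclass
class NearestPeakResult:
    """Directional ref -> other nearest-peak matching within ``max_nm``."""

    distances_nm: np.ndarray         # matched distances only
    matched_ref_idx: np.ndarray
    matched_other_idx: np.ndarray
    unmatched_ref_idx: np.ndarray
    max_nm: float

    @property
    def n_matched(self) -> int:
        return self.distances_nm.size

    @property
    def n_unmatched(self) -> int:
        return self.unmatched_ref_idx.size

    @property
    def mean_distance_nm(self) -> float:
        return float(self.distances_nm.mean()) if self.n_matched else math.nan


def nearest_peak_distances(
    ref: PeakSet, other: PeakSet, max_nm: float = 800.0
) -> NearestPeakResult:
    """For each ref peak, distance to the nearest other-channel peak.

    Pairs farther than ``max_nm`` are recorded as unmatched and excluded
    from the distance list.
    """
    if ref.n == 0 or other.n == 0:
        return NearestPeakResult(
            np.empty(0), np.empty(0, int), np.empty(0, int),
            np.arange(ref.n), max_nm,
        )
    diff = np.abs(ref.positions_nm[:, None] - other.positions_nm[None, :])
    nearest = np.argmin(diff, axis=1)
    dist = diff[np.arange(ref.n), nearest]
    ok = dist <= max_nm
    return NearestPeakResult(
        dist[ok], np.where(ok)[0], nearest[ok], np.where(~ok)[0], max_nm
    )


# ---------------------------------------------------------------------------
# pixel correlations
# ---------------------------------------------------------------------------


def _retained_mask(ch1, ch2, thr1, thr2, retain: str) -> np.ndarray:
    if retain == "either":
        return (ch1 > thr1) | (ch2 > thr2)
    if retain == "both":
        return (ch1 > thr1) & (ch2 > thr2)
    if retain == "all":
        return np.ones(ch1.size, dtype=bool)
    raise ValueError(f"unknown retention rule {retain!r}")


def paired_correlation(
    pair: LineProfilePair,
    threshold1: float = 0.0,
    threshold2: float = 0.0,
    retain: str = "all",
) -> float:
    """Pixel-by-pixel Pearson correlation of the two channels.

    Pixels are retained by the threshold rule: ``either`` (default) keeps
    pixels where at least one channel exceeds its threshold; ``both``
    requires both; ``all`` keeps everything.
    """
    mask = _retained_mask(pair.ch1, pair.ch2, threshold1, threshold2, retain)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 retained pixels")
    a, b = pair.ch1[mask], pair.ch2[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a retained channel")
    return float(stats.pearsonr(a, b).statistic)


def shuffled_correlation(
    pairs: list[LineProfilePair],
    scheme: str = "all_pairs",
    seed: int | None = None,
    retain: str = "all",
    sd_multiplier: float = 3.5,
    window_nm: float = 600.0,
    n_random: int | None = None,
) -> tuple[list[float], float]:
    """Between-animal null correlations: ch1 of animal i vs ch2 of animal j != i.

    Profiles are truncated to the shorter length of each pair; per-profile
    thresholds follow the same rule as the paired correlation.  Returns
    (list of r, mean r).  ``scheme='all_pairs'`` uses every ordered
    mismatched pair; ``scheme='random'`` draws ``n_random`` mismatched pairs
    with the given seed.
    """
    if len(pairs) < 2:
        raise ValueError("shuffled correlation requires >= 2 animals")
    thr1 = [estimate_threshold(p.position_nm, p.ch1, sd_multiplier, window_nm)
            for p in pairs]
    thr2 = [estimate_threshold(p.position_nm, p.ch2, sd_multiplier, window_nm)
            for p in pairs]

    if scheme == "all_pairs":
        combos = [(i, j) for i in range(len(pairs)) for j in range(len(pairs))
                  if i != j]
    elif scheme == "random":
        if n_random is None:
            n_random = 2 * len(pairs)
        rng = np.random.default_rng(seed)
        combos = []
        while len(combos) < n_random:
            i, j = rng.integers(0, len(pairs), 2)
            if i != j:
                combos.append((int(i), int(j)))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rs = []
    for i, j in combos:
        n = min(pairs[i].n_pixels, pairs[j].n_pixels)
        a = pairs[i].ch1[:n]
        b = pairs[j].ch2[:n]
        mask = _retained_mask(a, b, thr1[i], thr2[j], retain)
        if mask.sum() < 3 or np.ptp(a[mask]) == 0 or np.ptp(b[mask]) == 0:
            continue
        rs.append(float(stats.pearsonr(a[mask], b[mask]).statistic))
    if not rs:
        raise ValueError("no valid shuffled pair had enough retained pixels")
    return rs, float(np.mean(rs))


# ---------------------------------------------------------------------------
# per-animal analysis and group summary
# ---------------------------------------------------------------------------


@dataclass
class ColocResult:
    """Per-animal colocalization metrics."""

    animal_id: str
    label: str
    paired_r: float
    peak_distances_nm: np.ndarray
    mean_distance_nm: float
    n_matched: int
    n_unmatched: int
    threshold_ch1: float
    threshold_ch2: float
    shuffled_r: list = field(default_factory=list)


def analyze_pair(
    pair: LineProfilePair,
    label: str = "all",
    sd_multiplier: float = 3.5,
    window_nm: float = 600.0,
    min_separation_nm: float = 200.0,
    max_dist_nm: float = 800.0,
    retain: str = "all",
    threshold_ch1: float | None = None,
    threshold_ch2: float | None = None,
) -> ColocResult:
    """Threshold, call peaks, match ch1 peaks to ch2, correlate pixels."""
    c1 = PeakCaller(sd_multiplier, window_nm, min_separation_nm,
                    threshold_ch1, "ch1").fit(pair.position_nm, pair.ch1)
    c2 = PeakCaller(sd_multiplier, window_nm, min_separation_nm,
                    threshold_ch2, "ch2").fit(pair.position_nm, pair.ch2)
    match = nearest_peak_distances(c1.peaks_, c2.peaks_, max_dist_nm)
    r = paired_correlation(pair, c1.threshold_, c2.threshold_, retain)
    return ColocResult(
        animal_id=pair.animal_id, label=label, paired_r=r,
        peak_distances_nm=match.distances_nm,
        mean_distance_nm=match.mean_distance_nm,
        n_matched=match.n_matched, n_unmatched=match.n_unmatched,
        threshold_ch1=c1.threshold_, threshold_ch2=c2.threshold_,
    )


def summarize_coloc(results: list[ColocResult]):
    """Group means +- SEM of paired r and mean peak distance, animal as unit."""
    import pandas as pd

    if not results:
        raise ValueError("no results to summarize")
    rows = []
    df = pd.DataFrame(
        {
            "label": [r.label for r in results],
            "animal_id": [r.animal_id for r in results],
            "paired_r": [r.paired_r for r in results],
            "mean_distance_nm": [r.mean_distance_nm for r in results],
        }
    )
    for label, sub in df.groupby("label", sort=False):
        n = len(sub)
        row = {"label": label, "n_animals": n}
        for col in ("paired_r", "mean_distance_nm"):
            vals = sub[col].to_numpy()
            row[f"{col}_mean"] = float(np.nanmean(vals))
            row[f"{col}_sem"] = (
                float(np.nanstd(vals, ddof=1) / np.sqrt(n)) if n > 1 else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raster extraction
# ---------------------------------------------------------------------------


def extract_line_profile(
    raster: np.ndarray,
    polyline: np.ndarray,
    width_pixels: int = 6,
    pixel_nm: float = 100.0,
    animal_id: str = "animal0",
) -> LineProfilePair:
    """Average a 2-channel raster over a band along a polyline.

    ``raster`` has shape (2, H, W); ``polyline`` is an (n, 2) array of
    (row, col) vertices in pixel units.  At each unit step along the line
    the intensity is averaged over ``width_pixels`` samples placed
    perpendicular to the local direction (bilinear interpolation).
    """
    from scipy.ndimage import map_coordinates

    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 3 or raster.shape[0] != 2:
        raise ValueError("raster must have shape (2, H, W)")
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
        raise ValueError("polyline must be an (n>=2, 2) array of (row, col)")
    if width_pixels < 2 or width_pixels % 2:
        raise ValueError("width_pixels must be even and >= 2")
    H, W = raster.shape[1:]
    for k, (r, c) in enumerate(poly):
        if not (0 <= r <= H - 1 and 0 <= c <= W - 1):
            raise ValueError(f"polyline vertex {k} at ({r}, {c}) exits the raster")

    offsets = np.arange(width_pixels) - (width_pixels - 1) / 2.0
    rows_all, cols_all = [], []
    for k in range(poly.shape[0] - 1):
        p0, p1 = poly[k], poly[k + 1]
        seg = p1 - p0
        length = float(np.hypot(*seg))
        if length == 0:
            continue
        direction = seg / length
        normal = np.array([-direction[1], direction[0]])
        n_steps = int(np.floor(length)) + 1
        ts = np.arange(n_steps, dtype=float)
        if k > 0:  # avoid duplicating the shared vertex
            ts = ts[1:]
        centers = p0[None, :] + ts[:, None] * direction[None, :]
        pts = centers[:, None, :] + offsets[None, :, None] * normal[None, None, :]
        rr, cc = pts[..., 0], pts[..., 1]
        if (rr < -1e-9).any() or (rr > H - 1 + 1e-9).any() or \
           (cc < -1e-9).any() or (cc > W - 1 + 1e-9).any():
            raise ValueError(
                f"averaging band around segment starting at vertex {k} exits the raster"
            )
        rows_all.append(rr)
        cols_all.append(cc)

    rr = np.concatenate(rows_all, axis=0)
    cc = np.concatenate(cols_all, axis=0)
    channels = []
    for ch in range(2):
        vals = map_coordinates(raster[ch], [rr.ravel(), cc.ravel()], order=1)
        channels.append(vals.reshape(rr.shape).mean(axis=1))
    positions = np.arange(rr.shape[0]) * pixel_nm
    return LineProfilePair(
        animal_id, positions,
        np.clip(channels[0], 0, None), np.clip(channels[1], 0, None),
    )
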