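"""Docked-vesicle spatial statistics from serial-section EM.

Distances are consumed as measured scalars (nm along the membrane from the
dense-projection edge).  Histograms use half-open 33 nm bins normalized per
profile; only profiles containing a dense projection are counted.  Region
summaries use the synapse (a contiguous run of profiles with a dense
projection) as the replication unit; per-profile totals use the profile.

Boundary convention: all bins and regions are half-open [lo, hi); "<231 nm"
means [0, 231) and "232-330 nm" is implemented as [231, 330) so the printed
231/232 seam leaves no gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import EMDataset

__all__ = [
    "DockedHistogram",
    "build_histogram",
    "region_summary",
    "totals",
]


@dataclass
class DockedHistogram:
    """Per-profile-normalized docked-vesicle distance histogram."""

    bin_edges_nm: np.ndarray
    counts: np.ndarray            # integer vesicle counts per bin
    vesicles_per_profile: np.ndarray
    n_profiles: int
    cumulative_fraction: np.ndarray | None  # None when no vesicles

    @property
    def total_vesicles(self) -> int:
        return int(self.counts.sum())


def build_histogram(dataset: EMDataset, bin_nm: float = 33.0) -> DockedHistogram:
    """Sort distances into half-open ``bin_nm`` bins, divide by profile count."""
    if bin_nm <= 0:
        raise ValueError("bin width must be positive")
    n_prof = dataset.n_profiles
    if n_prof == 0:
        raise ValueError("dataset has no profiles with a dense projection")
    d = dataset.vesicles["distance_nm"].to_numpy(dtype=float)
    if d.size == 0:
        edges = np.array([0.0, bin_nm])
        counts = np.zeros(1, dtype=int)
        return DockedHistogram(edges, counts, counts / n_prof, n_prof, None)
    n_bins = int(np.floor(d.max() / bin_nm)) + 1
    edges = np.arange(n_bins + 1) * bin_nm
    # np.histogram's last bin is closed; the extra bin above max keeps all
    # interior bins half-open [lo, hi)
    counts, _ = np.histogram(d, bins=edges)
    counts = counts.astype(int)
    cum = np.cumsum(counts) / counts.sum()
    return DockedHistogram(edges, counts, counts / n_prof, n_prof, cum)


def _region_counts(d: np.ndarray, regions: tuple[float, float, float]) -> dict:
    a, b, c = regions
    return {
        f"lt{int(a)}": int((d < a).sum()),
        f"lt{int(b)}": int((d < b).sum()),
        f"r{int(b)}_{int(c)}": int(((d >= b) & (d < c)).sum()),
        f"gt{int(c)}": int((d >= c).sum()),
    }


def region_summary(
    dataset: EMDataset, regions: tuple[float, float, float] = (165.0, 231.0, 330.0)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Docked vesicles per profile in distance regions, synapse as data point.

    Returns ``(per_synapse, per_genotype)``: per-synapse region counts
    divided by that synapse's profile count, and genotype means +- SEM over
    synapses.
    """
    profiles = dataset.profiles
    if profiles.empty:
        raise ValueError("dataset has no profiles with a dense projection")
    ves = dataset.vesicles
    rows = []
    for (genotype, animal, syn), prof_sub in profiles.groupby(
        ["genotype", "animal", "synapse_id"], sort=False
    ):
        n_prof = len(prof_sub)
        if n_prof == 0:
            raise ValueError(f"synapse {syn} has zero profiles")
        d = ves[ves["synapse_id"] == syn]["distance_nm"].to_numpy(dtype=float)
        counts = _region_counts(d, regions)
        row = {"genotype": genotype, "animal": animal, "synapse_id": syn,
               "n_profiles": n_prof, "n_vesicles": int(d.size)}
        row.update({f"count_{k}": v for k, v in counts.items()})
        row.update({f"per_profile_{k}": v / n_prof for k, v in counts.items()})
        rows.append(row)
    per_syn = pd.DataFrame(rows)

    metric_cols = [c for c in per_syn.columns if c.startswith("per_profile_")]
    summary_rows = []
    for genotype, sub in per_syn.groupby("genotype", sort=False):
        n = len(sub)
        row = {"genotype": genotype, "n_synapses": n}
        for col in metric_cols:
            vals = sub[col].to_numpy()
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else math.nan
            )
        summary_rows.append(row)
    return per_syn, pd.DataFrame(summary_rows)


def totals(dataset: EMDataset) -> pd.DataFrame:
    """Per-profile docked (and optional total) vesicle counts per genotype.

    The profile is the replication unit.  ``n_total_vesicles`` is used when
    the dataset carries that per-profile column; otherwise the total column
    is NaN.
    """
    profiles = dataset.profiles
    if profiles.empty:
        raise ValueError("dataset has no profiles with a dense projection")
    ves = dataset.vesicles
    docked = (
        ves.groupby(["genotype", "animal", "synapse_id", "profile_id"])
        .size()
        .rename("docked")
    )
    per_prof = profiles.set_index(
        ["genotype", "animal", "synapse_id", "profile_id"]
    ).join(docked).fillna({"docked": 0}).reset_index()

    has_total = "n_total_vesicles" in dataset.df.columns
    if has_total:
        tot = (
            dataset.included.dropna(subset=["n_total_vesicles"])
            .groupby(["genotype", "animal", "synapse_id", "profile_id"])[
                "n_total_vesicles"
            ]
            .first()
        )
        per_prof = per_prof.set_index(
            ["genotype", "animal", "synapse_id", "profile_id"]
        ).join(tot).reset_index()

    rows = []
    for genotype, sub in per_prof.groupby("genotype", sort=False):
        n = len(sub)
        row = {"genotype": genotype, "n_profiles": n}
        for col, label in (("docked", "docked"),
                           ("n_total_vesicles", "total")):
            if col not in sub.columns:
                row[f"{label}_mean"] = math.nan
                row[f"{label}_sem"] = math.nan
                continue
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[f"{label}_mean"] = math.nan
                row[f"{label}_sem"] = math.nan
            else:
                row[f"{label}_mean"] = float(vals.mean())
                row[f"{label}_sem"] = (
                    float(vals.std(ddof=1) / np.sqrt(vals.size))
                    if vals.size > 1 else math.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)
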