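"""End-to-end report pipeline over synthetic genotype comparisons.

A single config (dict or YAML file) names the stages to run, the genotype
labels, and per-genotype generator parameter overrides.  Each stage
generates its synthetic inputs (seeded via ``numpy.random.SeedSequence``
spawning so every replicate is independent yet reproducible), runs the
corresponding analysis with the correct replication unit (animal for
electrophysiology and colocalization, synapse for EM regions), and feeds
group tables into the configured tests (two-tailed t for two groups, ANOVA
with SNK for three or more).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .data import _NumpyJSONEncoder
from .synthgen import (
    EvokedParams, TonicParams, ProfileParams, EMGenParams,
    gen_evoked_trace, gen_tonic_trace, gen_profile_pair, gen_em_dataset,
)
from .evoked import analyze_sweep
from .tonic import detect_events, event_summary
from .lineprofile import analyze_pair, shuffled_correlation
from .emdist import region_summary
from .stats import describe, t_test, anova_snk

__all__ = ["run_pipeline", "config_hash"]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, cls=_NumpyJSONEncoder)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _mk_params(cls, overrides: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**overrides)


def _group_tests(tables: dict) -> dict:
    """Apply t test (2 groups) or ANOVA+SNK (>=3) per metric."""
    out = {}
    metrics = next(iter(tables.values())).keys()
    labels = list(tables)
    for metric in metrics:
        groups = {g: np.asarray(tables[g][metric], dtype=float) for g in labels}
        groups = {g: v[np.isfinite(v)] for g, v in groups.items()}
        if any(v.size < 2 for v in groups.values()):
            continue
        try:
            if len(labels) == 2:
                res = t_test(groups[labels[0]], groups[labels[1]])
                out[metric] = {"test": res.test, "statistic": res.statistic,
                               "df": res.df, "p_value": res.p_value}
            else:
                res = anova_snk(groups)
                out[metric] = {
                    "test": res.test, "statistic": res.statistic,
                    "p_value": res.p_value,
                    "pairwise": {f"{a}|{b}": dec
                                 for (a, b), dec in res.pairwise.items()},
                }
        except ValueError as exc:
            out[metric] = {"error": str(exc)}
    return out


def _describe_tables(tables: dict) -> dict:
    out = {}
    for label, metrics in tables.items():
        out[label] = {}
        for metric, vals in metrics.items():
            vals = np.asarray(vals, dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            d = describe(vals)
            out[label][metric] = {"mean": d.mean, "sem": d.sem, "n": d.n}
    return out


def _stage_evoked(cfg: dict, ss: np.random.SeedSequence) -> dict:
    n = int(cfg.get("n_per_group", 10))
    tables: dict = {}
    per_sweep: dict = {}
    for label, overrides in cfg["genotypes"].items():
        params = _mk_params(EvokedParams, overrides or {})
        seeds = ss.spawn(1)[0].generate_state(n) % (2**31)
        rows = []
        for s in seeds:
            trace, _ = gen_evoked_trace(params, int(s))
            rows.append(analyze_sweep(trace))
        per_sweep[label] = rows
        tables[label] = {
            "q50_pC": [r["q50_pC"] for r in rows],
            "f_fast_pct": [100.0 * r["f_fast"] for r in rows],
            "tau_fast_ms": [r["tau_fast_ms"] for r in rows],
            "tau_slow_ms": [r["tau_slow_ms"] for r in rows],
            "decay_90_10_ms": [r["decay_90_10_ms"] for r in rows],
            "peak_amplitude_pA": [r["peak_amplitude_pA"] for r in rows],
        }
    return {"unit": "animal", "groups": _describe_tables(tables),
            "tests": _group_tests(tables), "per_sweep": per_sweep}


def _stage_tonic(cfg: dict, ss: np.random.SeedSequence) -> dict:
    n = int(cfg.get("n_per_group", 10))
    det_cfg = cfg.get("detector", {})
    tables: dict = {}
    for label, overrides in cfg["genotypes"].items():
        params = _mk_params(TonicParams, overrides or {})
        seeds = ss.spawn(1)[0].generate_state(n) % (2**31)
        freqs, amps = [], []
        for s in seeds:
            trace, _ = gen_tonic_trace(params, int(s))
            events = detect_events(trace, **det_cfg)
            summ = event_summary(events)
            freqs.append(summ["frequency_hz"])
            amps.append(summ.get("mean_amplitude_pA", np.nan))
        tables[label] = {"frequency_hz": freqs, "amplitude_pA": amps}
    return {"unit": "animal", "groups": _describe_tables(tables),
            "tests": _group_tests(tables)}


def _stage_lineprofile(cfg: dict, ss: np.random.SeedSequence) -> dict:
    n = int(cfg.get("n_animals", 10))
    tables: dict = {}
    shuffled: dict = {}
    for label, overrides in cfg["genotypes"].items():
        params = _mk_params(ProfileParams, overrides or {})
        child = ss.spawn(1)[0]
        seeds = child.generate_state(n) % (2**31)
        pairs, dists, rs = [], [], []
        for i, s in enumerate(seeds):
            pair, _ = gen_profile_pair(params, int(s), f"{label}_an{i:02d}")
            pairs.append(pair)
            res = analyze_pair(pair, label)
            dists.append(res.mean_distance_nm)
            rs.append(res.paired_r)
        tables[label] = {"mean_distance_nm": dists, "paired_r": rs}
        _, mean_shuf = shuffled_correlation(pairs)
        shuffled[label] = mean_shuf
    return {"unit": "animal", "groups": _describe_tables(tables),
            "tests": _group_tests(tables), "shuffled_mean_r": shuffled}


def _stage_emdist(cfg: dict, ss: np.random.SeedSequence) -> dict:
    tables: dict = {}
    for label, overrides in cfg["genotypes"].items():
        params = _mk_params(EMGenParams, overrides or {})
        seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        dataset, _ = gen_em_dataset(params, seed, genotype=label)
        per_syn, _ = region_summary(dataset)
        tables[label] = {
            col: per_syn[col].tolist()
            for col in per_syn.columns if col.startswith("per_profile_")
        }
    return {"unit": "synapse", "groups": _describe_tables(tables),
            "tests": _group_tests(tables)}


_STAGES = {
    "evoked": _stage_evoked,
    "tonic": _stage_tonic,
    "lineprofile": _stage_lineprofile,
    "emdist": _stage_emdist,
}


def run_pipeline(config, out_dir=None, seed: int | None = None) -> dict:
    """Run the configured stages and return (and optionally write) a report."""
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    if "stages" not in config or not config["stages"]:
        raise ValueError("config must name at least one stage under 'stages'")
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    ss = np.random.SeedSequence(seed)

    report = {
        "software": {"name": "synaptiq", "version": __version__},
        "config_hash": config_hash(config),
        "seed": seed,
        "stages": {},
    }
    for name, stage_cfg in config["stages"].items():
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        if not stage_cfg or "genotypes" not in stage_cfg:
            raise ValueError(f"stage {name!r} missing 'genotypes'")
        report["stages"][name] = _STAGES[name](stage_cfg, ss.spawn(1)[0])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, cls=_NumpyJSONEncoder, indent=1)
        _write_markdown(report, out_dir / "summary.md")
    return report


def _write_markdown(report: dict, path) -> None:
    lines = [f"# synaptiq report (config {report['config_hash']}, "
             f"seed {report['seed']})", ""]
    for stage, res in report["stages"].items():
        lines.append(f"## {stage} (unit: {res['unit']})")
        for label, metrics in res["groups"].items():
            lines.append(f"- **{label}**")
            for metric, d in metrics.items():
                lines.append(
                    f"  - {metric}: {d['mean']:.4g} ± {d['sem']:.2g} (n={d['n']})"
                )
        if res.get("tests"):
            lines.append("- tests:")
            for metric, t in res["tests"].items():
                if "p_value" in t:
                    lines.append(f"  - {metric}: {t['test']}, p={t['p_value']:.3g}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
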