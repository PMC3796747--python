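"""Flat-file input/output: configs, trajectory CSVs, histograms, manifests.

All artifacts are plain text: comma-separated CSV with a header row,
tab-separated edge lists, and JSON manifests recording the config echo and
every seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .coevolution import RunResult, SimulationConfig
from .experiments import (
    PAIR_TYPE_NAMES,
    RELABELED_STRATEGIES,
    SweepResult,
    relabeled_fractions,
    relabeled_pair_stats,
)

__all__ = [
    "read_config",
    "write_config",
    "write_trajectory_csv",
    "write_sweep_csv",
    "write_payoff_histograms_csv",
    "write_degree_histogram_csv",
    "write_manifest",
]

_CONFIG_FIELDS = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}


def read_config(path: str | Path) -> SimulationConfig:
    """Load a flat key/value config file (keys = SimulationConfig fields)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a flat key/value mapping")
    unknown = set(data) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = SimulationConfig(**data)
    cfg.validate()
    return cfg


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def write_trajectory_csv(run: RunResult, path: str | Path) -> None:
    """One row per step: t, strategy fractions, edge count, then the 10
    pair-type fractions and mean weights (relabeled order)."""
    cols = (
        ["t"]
        + [f"frac_{s}" for s in RELABELED_STRATEGIES]
        + ["edge_count"]
        + [f"pair_frac_{p}" for p in PAIR_TYPE_NAMES]
        + [f"pair_weight_{p}" for p in PAIR_TYPE_NAMES]
    )
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for rec in run.records:
            frac = relabeled_fractions(run, rec)
            pf, pw = relabeled_pair_stats(run, rec)
            row = (
                [str(rec.t)]
                + [f"{x:.10g}" for x in frac]
                + [str(rec.edge_count)]
                + [f"{x:.10g}" for x in pf]
                + [("" if np.isnan(x) else f"{x:.10g}") for x in pw]
            )
            fh.write(",".join(row) + "\n")


def write_sweep_csv(result: SweepResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("b,variant,n_runs," + ",".join(f"mean_frac_{s}" for s in RELABELED_STRATEGIES) + "\n")
        for i, b in enumerate(result.b_values):
            vals = ",".join(f"{x:.10g}" for x in result.mean_frac[i])
            fh.write(f"{b:.10g},{result.variant},{result.n_runs},{vals}\n")


def write_payoff_histograms_csv(
    report: dict[float, dict[str, tuple[np.ndarray, np.ndarray]]], path: str | Path
) -> None:
    """Long-format histogram CSV: b, profile_type, bin_left, bin_right, count."""
    with open(path, "w") as fh:
        fh.write("b,profile_type,bin_left,bin_right,count\n")
        for b in sorted(report):
            for profile in sorted(report[b]):
                edges, counts = report[b][profile]
                for k, c in enumerate(counts):
                    fh.write(f"{b:.10g},{profile},{edges[k]:.10g},{edges[k + 1]:.10g},{int(c)}\n")


def write_degree_histogram_csv(hists: dict[str, np.ndarray], path: str | Path) -> None:
    """Columns: series, degree, mean_count (series = overall/initial or a strategy)."""
    with open(path, "w") as fh:
        fh.write("series,degree,mean_count\n")
        for series in sorted(hists):
            for d, c in enumerate(hists[series]):
                fh.write(f"{series},{d},{c:.10g}\n")


def write_manifest(
    path: str | Path,
    config: SimulationConfig | None,
    master_seed: int,
    run_seeds: list[int],
    artifacts: list[str],
    extra: dict | None = None,
) -> None:
    manifest = {
        "config": dataclasses.asdict(config) if config else None,
        "master_seed": master_seed,
        "run_seeds": run_seeds,
        "artifacts": artifacts,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
        fh.write("\n")
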