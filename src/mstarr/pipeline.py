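"""End-to-end orchestration: simulate, filter, normalize, test, report.

``run_pipeline`` drives the whole analysis from a single configuration
mapping (YAML-friendly), with one master seed feeding every stage's
labelled random stream, and returns a plain-dict report with per-stage row
counts and headline results. When the input is simulated, the report also
contains truth-based diagnostics (realized false-discovery proportion,
direction split).
"""
from __future__ import annotations

import json
import time

import numpy as np
import pandas as pd

from . import __version__
from .activity import ActivityModel
from .core import DNA, ConfigurationError
from .normalize import normalize_counts
from .simulate import SimConfig, simulate_counts, simulate_library
from .windows import filter_detected, filter_stable


def run_simulated(sim_config: SimConfig, q_threshold: float = 0.10,
                  min_fraction: float = 0.5, use_weights: bool = True,
                  stability_central: float = 0.90,
                  stability_max_outside: float = 0.25) -> dict:
    """Simulate a library and run the full calling pipeline on it.

    Returns a report dict with stage row counts, enhancer/MD calls, the
    direction split, and truth-based diagnostics (MD false-discovery
    proportion and sensitivity at the chosen q threshold).
    """
    t0 = time.time()
    windows, truth = simulate_library(sim_config)
    counts = simulate_counts(truth, sim_config)

    detected = filter_detected(counts, min_fraction=min_fraction)
    kept = counts.counts.index[detected]
    filtered = counts.subset_windows(kept)

    normalized = normalize_counts(filtered)
    dna_cols = normalized.samples.index[normalized.samples["type"] == DNA]
    stable = filter_stable(normalized.values[list(dna_cols)],
                           central=stability_central,
                           max_outside=stability_max_outside)
    analysis_ids = filtered.counts.index[stable]
    normalized = type(normalized)(
        values=normalized.values.loc[analysis_ids],
        obs_weights=normalized.obs_weights.loc[analysis_ids],
        sample_weights=normalized.sample_weights,
        trend=normalized.trend,
        samples=normalized.samples,
    )

    model = ActivityModel(normalized, use_weights=use_weights)
    results = model.fit(q_threshold=q_threshold)

    frame = results.frame
    truth_sub = truth.frame.loc[frame.index]
    called_md = frame["is_md"].to_numpy(dtype=bool)
    true_md = truth_sub["is_md"].to_numpy(dtype=bool)
    n_called = int(called_md.sum())
    fdp = float((called_md & ~true_md).sum() / n_called) if n_called else float("nan")
    sens = float((called_md & true_md).sum() / true_md.sum()) if true_md.sum() else float("nan")

    called_enh = frame["is_enhancer"].to_numpy(dtype=bool)
    true_enh = truth_sub["is_enhancer"].to_numpy(dtype=bool)
    enh_fdp = (float((called_enh & ~true_enh).sum() / called_enh.sum())
               if called_enh.sum() else float("nan"))

    return {
        "version": __version__,
        "seed": sim_config.seed,
        "n_windows_simulated": sim_config.n_windows,
        "n_windows_detected": int(detected.sum()),
        "n_windows_analysis": int(len(analysis_ids)),
        "n_enhancers": results.n_enhancers,
        "n_md": results.n_md,
        "direction_split": results.direction_split,
        "md_fdp": fdp,
        "md_sensitivity": sens,
        "enhancer_fdp": enh_fdp,
        "elapsed_s": round(time.time() - t0, 2),
        "_results": results,
        "_truth": truth,
    }


def run_pipeline(config: dict) -> dict:
    """Run the pipeline from a plain configuration mapping.

    Currently drives the simulation-backed analysis; file-backed stages are
    exposed individually through the library and CLI. Unknown simulation
    keys raise a configuration error naming the key.
    """
    sim_keys = config.get("simulate", {})
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(sim_keys) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulate option(s): {sorted(unknown)}")
    if "dropped_reps" in sim_keys:
        sim_keys = dict(sim_keys)
        sim_keys["dropped_reps"] = [tuple(x) for x in sim_keys["dropped_reps"]]
    sim = SimConfig(**sim_keys)
    if "seed" in config:
        sim.seed = int(config["seed"])
    report = run_simulated(
        sim,
        q_threshold=float(config.get("q_threshold", 0.10)),
        min_fraction=float(config.get("min_fraction", 0.5)),
        use_weights=bool(config.get("use_weights", True)),
    )
    return report


def write_report(report: dict, path) -> None:
    """Serialize a report (dropping in-memory objects) as JSON."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, default=_default)
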