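"""Experiment sweep driver: repetition batches over config-axis grids.

Each sweep cell is an :class:`ExperimentConfig` override; within a cell
``n_repetitions`` independent training runs execute with child seeds
spawned deterministically from the master seed (counter-based via
``np.random.SeedSequence``), so results are independent of execution
order. Outputs are a per-repetition CSV, a JSON summary with
median/quartiles and two-sample t-tests against the first (control)
cell, and the config hash + seed for exact replay.
"""

from __future__ import annotations

import itertools
import json
import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import ExperimentConfig, config_hash, dump_config
from .patterns import gen_task1, gen_task2_nested, gen_task4_poisson
from .protocol import run_training

__all__ = ["generate_patterns", "run_cell", "run_sweep"]


def generate_patterns(task_id: int, task_cfg, rng: np.random.Generator):
    """Draw one pattern set for a repetition of the given task family."""
    if task_id in (1, 3):
        return gen_task1(task_cfg, rng)
    if task_id == 2:
        base, assignments = gen_task2_nested(
            task_cfg.P, task_cfg.t_delay, task_cfg.t_offset, task_cfg.t_duration
        )
        assign = assignments[int(rng.integers(len(assignments)))]
        return [replace(p, rewarded=r) for p, r in zip(base, assign)]
    if task_id == 4:
        return gen_task4_poisson(task_cfg, rng)
    raise ValueError(f"unknown task id {task_id}")


def run_cell(cfg: ExperimentConfig, seeds) -> pd.DataFrame:
    """All repetitions of one cell; one row per repetition."""
    task_cfg = cfg.task.to_runtime()
    net = cfg.network.to_runtime()
    stdp, reward = cfg.plasticity.to_runtime()
    train = cfg.training.to_runtime()
    rows = []
    for rep, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        patterns = generate_patterns(cfg.task.id, task_cfg, rng)
        result = run_training(patterns, task_cfg, net, stdp, reward, train, rng)
        rows.append(
            {
                "repetition": rep,
                "final_accuracy": result.final_accuracy,
                "final_max_accuracy": result.final_max_accuracy,
            }
        )
    return pd.DataFrame(rows)


def _summary(values: np.ndarray) -> dict:
    return {
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "mean": float(np.mean(values)),
        "n": int(len(values)),
    }


def run_sweep(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full sweep grid and write CSV/JSON artifacts.

    With no sweep axes the grid is the single base cell and the result
    reduces to a plain repetition batch of ``run_training``.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    axes = cfg.sweep
    if axes:
        grids = list(itertools.product(*(ax.values for ax in axes)))
    else:
        grids = [()]

    master = np.random.SeedSequence(cfg.seed)
    summary: dict = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "cells": [],
    }
    frames = []
    control_values = None
    for cell_idx, combo in enumerate(grids):
        cell_cfg = cfg
        label = {}
        for ax, value in zip(axes, combo):
            cell_cfg = cell_cfg.with_override(ax.path, value)
            label[ax.path] = value
        n_rep = cell_cfg.training.n_repetitions
        seeds = np.random.SeedSequence(
            cfg.seed, spawn_key=(cell_idx,)
        ).spawn(n_rep)
        print(f"[striatoseq] cell {cell_idx + 1}/{len(grids)} {label}", file=sys.stderr)
        df = run_cell(cell_cfg, seeds)
        for key, value in label.items():
            df[key] = value
        df["cell"] = cell_idx
        frames.append(df)
        values = df["final_max_accuracy"].to_numpy()
        cell_summary = {"cell": cell_idx, "label": label, **_summary(values)}
        if control_values is None:
            control_values = values
        else:
            t, p = stats.ttest_ind(values, control_values)
            cell_summary["p_vs_control"] = float(p)
        summary["cells"].append(cell_summary)

    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "results.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    (out / "config.yaml").write_text(dump_config(cfg))
    return summary
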