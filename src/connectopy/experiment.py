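"""End-to-end seeded experiments on synthetic cohorts.

``run_experiment`` reproduces the full benchmark grid on simulated data:
per subject and task it simulates ROI + non-ROI timeseries, runs the
split / fingerprint / optimize / embed / score pipeline for every
requested algorithm and connectivity source, then produces the group
statistics (one-sample t-tests with Holm correction, repeated-measures
ANOVA) and split-half / cross-task reliability tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    ALGORITHMS,
    GroundTruthMaps,
    cross_task_reliability,
    run_subject,
    split_half_reliability,
)
from .io import records_to_frame
from .simulate import (
    RetinotopicGrid,
    SimulationConfig,
    make_retinotopic_grid,
    simulate_nonroi_timeseries,
    simulate_roi_timeseries,
)
from .stats import holm_bonferroni, one_sample_t, rm_anova

__all__ = ["ExperimentConfig", "run_experiment"]

logger = logging.getLogger("connectopy")

_VALID_TASKS = ("rest", "movie")


@dataclass
class ExperimentConfig:
    """Declarative description of one synthetic benchmark experiment."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    subjects: int = 2
    algorithms: list[str] = field(default_factory=lambda: ["spectral_knn_unweighted"])
    source_modes: list[str] = field(default_factory=lambda: ["all"])
    tasks: list[str] = field(default_factory=lambda: ["movie"])
    optimizer_budget: int | None = 20
    seed: int = 0

    def validate(self) -> None:
        if self.subjects < 1:
            raise ValueError("config.subjects must be >= 1")
        if not self.algorithms:
            raise ValueError("config.algorithms must be non-empty")
        for name in self.algorithms:
            if name not in ALGORITHMS:
                raise ValueError(f"config.algorithms: unknown algorithm {name!r}")
        for task in self.tasks:
            if task not in _VALID_TASKS:
                raise ValueError(f"config.tasks: unknown task {task!r}")
        if not self.tasks:
            raise ValueError("config.tasks must be non-empty")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            if "grid_shape" in sim:
                sim["grid_shape"] = tuple(sim["grid_shape"])
            sim = SimulationConfig(**sim)
        cfg = cls(simulation=sim, **d)
        cfg.validate()
        return cfg


def simulate_subject(
    config: SimulationConfig,
    grid: RetinotopicGrid,
    tasks: list[str],
    subject_seed: int,
):
    """Simulate (ROI, source blocks) for each task of one subject.

    Tasks differ only through their random draw: the generative model has
    no rest-vs-movie structure, it only provides independent sessions.
    """
    data = {}
    for i, task in enumerate(tasks):
        cfg = SimulationConfig(**{**config.to_dict(), "seed": subject_seed + i})
        roi_ts, latents = simulate_roi_timeseries(grid, cfg, return_latents=True)
        sources = {
            "cortex": simulate_nonroi_timeseries(latents, cfg, "cortex"),
            "subcortex": simulate_nonroi_timeseries(latents, cfg, "subcortex"),
        }
        data[task] = (roi_ts, sources)
    return data


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Run the benchmark grid; optionally write the results bundle to disk.

    Returns a dict with the tidy accuracy table, group statistics,
    reliability tables and optimizer traces.  Deterministic given the
    config (including its seed).
    """
    config.validate()
    grid = make_retinotopic_grid(config.simulation.grid_shape)
    truth = GroundTruthMaps(grid.ecc, grid.polar)
    rng = np.random.default_rng(config.seed)

    all_records = []
    reliability_rows = []
    traces_out = {}
    for s in range(config.subjects):
        subject = f"sub-{s + 1:02d}"
        subject_seed = int(rng.integers(2**31 - 10))
        data = simulate_subject(config.simulation, grid, config.tasks, subject_seed)
        logger.info("running %s (seed %d)", subject, subject_seed)
        records, embeddings, traces = run_subject(
            data,
            truth,
            config.algorithms,
            source_modes=config.source_modes,
            subject=subject,
            seed=subject_seed,
            budget=config.optimizer_budget,
        )
        all_records.extend(records)
        for key, trials in traces.items():
            traces_out[(subject, *key)] = [
                {"params": t.params, "score": t.score, "valid": t.valid}
                for t in trials
            ]
        for task in config.tasks:
            for name in config.algorithms:
                for mode in config.source_modes:
                    odd = embeddings.get((task, name, mode, "odd"))
                    even = embeddings.get((task, name, mode, "even"))
                    if odd is None or even is None:
                        continue
                    rel = split_half_reliability(odd, even)
                    reliability_rows.append(
                        {
                            "subject": subject,
                            "kind": "split_half",
                            "task": task,
                            "algorithm": name,
                            "source_mode": mode,
                            **rel,
                        }
                    )
        if len(config.tasks) == 2:
            t1, t2 = config.tasks
            for name in config.algorithms:
                for mode in config.source_modes:
                    a = embeddings.get((t1, name, mode, "odd"))
                    b = embeddings.get((t2, name, mode, "even"))
                    if a is None or b is None:
                        continue
                    rel = cross_task_reliability(a, b)
                    reliability_rows.append(
                        {
                            "subject": subject,
                            "kind": "cross_task",
                            "task": f"{t1}-{t2}",
                            "algorithm": name,
                            "source_mode": mode,
                            **rel,
                        }
                    )

    records_df = records_to_frame(all_records)
    results = {
        "records": records_df,
        "reliability": pd.DataFrame(reliability_rows),
        "ttests": _group_ttests(records_df),
        "anova": _group_anova(records_df, config),
        "traces": traces_out,
    }
    if out_dir is not None:
        _write_bundle(results, config, out_dir)
    return results


def _group_ttests(records: pd.DataFrame) -> pd.DataFrame:
    """One-sample t-tests of |r| against zero, Holm-corrected within algorithm."""
    rows = []
    for (alg, variant), sub in records.groupby(["algorithm", "variant"]):
        cells = []
        for (task, mode, map_type), cell in sub.groupby(
            ["task", "source_mode", "map_type"]
        ):
            x = cell.groupby("subject")["abs_r"].mean()
            if len(x) < 2 or x.std(ddof=1) == 0:
                continue
            res = one_sample_t(x.to_numpy())
            cells.append((task, mode, map_type, res))
        if not cells:
            continue
        _, p_adj = holm_bonferroni([c[3].p for c in cells])
        for (task, mode, map_type, res), p in zip(cells, p_adj):
            rows.append(
                {
                    "algorithm": alg,
                    "variant": variant,
                    "task": task,
                    "source_mode": mode,
                    "map_type": map_type,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "p_holm": p,
                    "d_z": res.d_z,
                }
            )
    return pd.DataFrame(rows)


def _group_anova(records: pd.DataFrame, config: ExperimentConfig):
    """Map-type x algorithm (x task) repeated-measures ANOVA, where the
    design has enough subjects and more than one algorithm."""
    if records.empty:
        return None
    df = records.copy()
    df["alg"] = df["algorithm"] + np.where(
        df["variant"] != "", ":" + df["variant"], ""
    )
    cell = (
        df.groupby(["subject", "task", "alg", "map_type"])["abs_r"]
        .mean()
        .reset_index()
    )
    within = ["map_type", "alg"] + (["task"] if len(config.tasks) > 1 else [])
    n_cells = int(np.prod([cell[f].nunique() for f in within]))
    n_subj = cell["subject"].nunique()
    if n_subj < 3 or cell["alg"].nunique() < 2:
        return None
    if len(cell) != n_subj * n_cells:
        return None
    try:
        return rm_anova(cell, "abs_r", within, "subject")
    except ValueError:
        return None


def _write_bundle(results: dict, config: ExperimentConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["records"].to_csv(out / "accuracy_records.csv", index=False)
    results["reliability"].to_csv(out / "reliability.csv", index=False)
    results["ttests"].to_csv(out / "ttests.csv", index=False)
    if results["anova"] is not None:
        results["anova"].to_csv(out / "anova.csv")
    with open(out / "optimizer_traces.json", "w") as f:
        json.dump({"|".join(k): v for k, v in results["traces"].items()}, f, indent=1)
    with open(out / "config.json", "w") as f:
        cfg = {
            "simulation": config.simulation.to_dict(),
            "subjects": config.subjects,
            "algorithms": config.algorithms,
            "source_modes": config.source_modes,
            "tasks": config.tasks,
            "optimizer_budget": config.optimizer_budget,
            "seed": config.seed,
        }
        json.dump(cfg, f, indent=1)
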