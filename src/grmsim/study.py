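"""Orchestration of the Monte Carlo condition grid.

One *condition* cell fixes (n, J, K); its population (theta pool + item
bank) is generated once from the hierarchical seed and shared by all R
replications.  Each replication draws a fresh sample without replacement,
generates responses, fits the GRM by MML-EM, scores respondents by EAP and
computes the full set of recovery metrics.  Per-condition aggregation uses
arithmetic means for all RMSE metrics and the Fisher-z mean for the
theta correlation.

Because every stream is keyed by (base_seed, n, J, K, replication), a grid
run is deterministic regardless of execution order or worker count;
parallelism is over condition cells only (replications stay serial inside a
cell).  With an output directory set, each completed condition is
checkpointed to CSV together with a manifest, and a rerun resumes from the
checkpoints.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .estimation import DegenerateItemError, em_fit, make_quadrature
from .grm_model import DEFAULT_D
from .metrics import ReplicationMetrics, compute_replication_metrics, fisher_mean_r
from .population import (
    GRID_BASE_SEED,
    GRID_J_VALUES,
    GRID_K_VALUES,
    GRID_N_VALUES,
    GRID_REPLICATIONS,
    Condition,
    Population,
    draw_sample,
    generate_population,
)

logger = logging.getLogger("grmsim")

METRIC_COLUMNS = [
    "rmse_a", "fpc_a", "rmse_a_fpc", "rmse_a_std", "rmse_a_std_fpc",
    "rmse_theta", "fpc_theta", "rmse_theta_fpc", "r",
]

MEAN_COLUMNS = [c for c in METRIC_COLUMNS if c not in ("fpc_a", "fpc_theta", "r")]


@dataclass(frozen=True)
class FitSettings:
    """Estimation controls shared by every replication."""

    quad_points: int = 61
    quad_half_width: float = 6.0
    tol: float = 1e-4
    max_cycles: int = 500
    D: float = DEFAULT_D
    slope_rescaled: bool = False
    sqrt_fpc: bool = True

    def quadrature(self):
        return make_quadrature(self.quad_points, self.quad_half_width)


@dataclass(frozen=True)
class StudyConfig:
    """Full description of a grid run; defaults reproduce the reference design."""

    n_values: tuple[int, ...] = GRID_N_VALUES
    J_values: tuple[int, ...] = GRID_J_VALUES
    K_values: tuple[int, ...] = GRID_K_VALUES
    R: int = GRID_REPLICATIONS
    base_seed: int = GRID_BASE_SEED
    fit: FitSettings = field(default_factory=FitSettings)
    out_dir: str | None = None
    workers: int = 1

    def __post_init__(self) -> None:
        if not (self.n_values and self.J_values and self.K_values):
            raise ValueError("n_values, J_values and K_values must be non-empty")
        object.__setattr__(self, "n_values", tuple(int(v) for v in self.n_values))
        object.__setattr__(self, "J_values", tuple(int(v) for v in self.J_values))
        object.__setattr__(self, "K_values", tuple(int(v) for v in self.K_values))

    def conditions(self) -> list[Condition]:
        return [
            Condition(n=n, J=J, K=K, R=self.R, base_seed=self.base_seed)
            for n, J, K in product(self.n_values, self.J_values, self.K_values)
        ]


@dataclass
class StudyResult:
    """Long per-replication table plus per-condition aggregates."""

    per_replication: pd.DataFrame
    per_condition: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_replication(pop: Population, rep_index: int, settings: FitSettings | None = None) -> dict:
    """Draw, fit, score and summarize one replication of a condition.

    Returns a flat record (dict) suitable for the long results table; a
    degenerate-item failure is recorded with ``status='failed'`` rather than
    raised, so a grid run survives pathological samples.
    """
    settings = settings or FitSettings()
    cond = pop.condition
    rng = cond.rng(rep_index)
    record: dict = {"n": cond.n, "J": cond.J, "K": cond.K, "rep": rep_index}
    sample = draw_sample(pop, rng)
    try:
        fit = em_fit(
            sample.responses,
            cond.K,
            quad=settings.quadrature(),
            tol=settings.tol,
            max_cycles=settings.max_cycles,
            D=settings.D,
            slope_rescaled=settings.slope_rescaled,
        )
    except DegenerateItemError as exc:
        logger.warning("replication %s of %s failed: %s", rep_index, cond, exc)
        record.update({c: np.nan for c in METRIC_COLUMNS})
        record.update(converged=False, n_warnings=0, status="failed", reason=str(exc))
        return record
    m: ReplicationMetrics = compute_replication_metrics(
        a_true=pop.bank.a,
        a_hat=fit.a_hat,
        theta_true=sample.theta_true,
        theta_hat=fit.theta_eap,
        N_pop=pop.N_pop,
        converged=fit.converged,
        n_warnings=len(fit.warnings),
        sqrt_fpc=settings.sqrt_fpc,
    )
    record.update(dataclasses.asdict(m))
    record.update(status="ok", reason="")
    return record


def aggregate_condition(rep_df: pd.DataFrame) -> dict:
    """Condition-level aggregates from that cell's replication records.

    Arithmetic means of the RMSE metrics, Fisher-z mean of the theta
    correlation, convergence rate over successful replications; failed
    replications are counted but excluded from the metric means.
    """
    n, J, K = (int(rep_df[c].iloc[0]) for c in ("n", "J", "K"))
    ok = rep_df[rep_df["status"] == "ok"]
    out: dict = {
        "n": n, "J": J, "K": K,
        "n_reps": len(rep_df),
        "n_failed": int((rep_df["status"] != "ok").sum()),
    }
    if len(ok) == 0:
        out.update({c: np.nan for c in MEAN_COLUMNS})
        out.update(r_fisher=np.nan, convergence_rate=np.nan, status="failed")
        return out
    for c in MEAN_COLUMNS:
        out[c] = float(ok[c].mean())
    out["r_fisher"] = fisher_mean_r(ok["r"].to_numpy())
    out["convergence_rate"] = float(ok["converged"].mean())
    out["status"] = "ok"
    return out


def run_condition(
    condition: Condition, settings: FitSettings | None = None
) -> tuple[dict, pd.DataFrame]:
    """Build the condition's population once and run its R replications."""
    settings = settings or FitSettings()
    t0 = time.time()
    pop = generate_population(condition, D=settings.D,
                              slope_rescaled=settings.slope_rescaled)
    records = [run_replication(pop, rep, settings) for rep in range(condition.R)]
    rep_df = pd.DataFrame.from_records(records)
    agg = aggregate_condition(rep_df)
    logger.info(
        "condition n=%d J=%d K=%d: R=%d done in %.1fs (mean rmse_a=%.3f, r_fisher=%.4f)",
        condition.n, condition.J, condition.K, condition.R,
        time.time() - t0, agg.get("rmse_a", float("nan")), agg.get("r_fisher", float("nan")),
    )
    return agg, rep_df


def _condition_tag(c: Condition) -> str:
    return f"n{c.n}_J{c.J}_K{c.K}"


def run_grid(config: StudyConfig) -> StudyResult:
    """Run the full Cartesian grid of a study configuration.

    With ``config.out_dir`` set, per-replication records for each finished
    condition are checkpointed to ``conditions/<tag>.csv`` and a manifest is
    maintained; rerunning the same config resumes from the checkpoints.
    Worker count affects only wall time, never the result.
    """
    conditions = config.conditions()
    out_dir = Path(config.out_dir) if config.out_dir else None
    cond_dir = None
    done: dict[str, pd.DataFrame] = {}
    if out_dir is not None:
        cond_dir = out_dir / "conditions"
        cond_dir.mkdir(parents=True, exist_ok=True)
        for c in conditions:
            f = cond_dir / f"{_condition_tag(c)}.csv"
            if f.exists():
                df = pd.read_csv(f)
                if "reason" in df.columns:  # empty strings survive the round trip
                    df["reason"] = df["reason"].fillna("").astype(object)
                if len(df) == c.R:
                    done[_condition_tag(c)] = df

    todo = [c for c in conditions if _condition_tag(c) not in done]
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    def _one(c: Condition) -> tuple[str, pd.DataFrame]:
        _, rep_df = run_condition(c, config.fit)
        if cond_dir is not None:
            rep_df.to_csv(cond_dir / f"{_condition_tag(c)}.csv", index=False)
        return _condition_tag(c), rep_df

    if config.workers > 1 and len(todo) > 1:
        results = Parallel(n_jobs=config.workers)(delayed(_one)(c) for c in todo)
    else:
        results = [_one(c) for c in todo]
    done.update(dict(results))

    rep_frames = [done[_condition_tag(c)] for c in conditions]
    per_replication = pd.concat(rep_frames, ignore_index=True)
    per_condition = pd.DataFrame.from_records(
        [aggregate_condition(df) for df in rep_frames]
    )

    manifest = {
        "config": config_to_dict(config),
        "base_seed": config.base_seed,
        "grid": {
            "n_values": list(config.n_values),
            "J_values": list(config.J_values),
            "K_values": list(config.K_values),
            "R": config.R,
            "cells": len(conditions),
        },
        "conditions": {
            _condition_tag(c): str(per_condition.iloc[i]["status"])
            for i, c in enumerate(conditions)
        },
        "version": __version__,
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if out_dir is not None:
        per_replication.to_csv(out_dir / "per_replication.csv", index=False)
        per_condition.to_csv(out_dir / "per_condition.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return StudyResult(per_replication=per_replication, per_condition=per_condition,
                       manifest=manifest)


def summarize_saturation(
    result: StudyResult, metric: str = "rmse_theta_fpc", tol: float = 0.01
) -> pd.DataFrame:
    """Smallest J beyond which a metric stops improving meaningfully.

    For each (n, K), scans the condition means across ascending J and
    reports the first J at which the improvement from the previous J drops
    below ``tol`` (NaN if the metric keeps improving through the whole
    range).  Requires at least 3 J values.
    """
    pc = result.per_condition
    if metric not in pc.columns:
        raise ValueError(f"unknown metric {metric!r}")
    if pc["J"].nunique() < 3:
        raise ValueError("saturation summary needs results for at least 3 J values")
    rows = []
    for (n, K), grp in pc.groupby(["n", "K"]):
        grp = grp.sort_values("J")
        J_vals = grp["J"].to_numpy()
        means = grp[metric].to_numpy()
        improvements = means[:-1] - means[1:]
        sat = np.nan
        for i, imp in enumerate(improvements):
            if imp < tol:
                sat = int(J_vals[i + 1])
                break
        rows.append({"n": int(n), "K": int(K), "metric": metric, "saturation_J": sat})
    return pd.DataFrame(rows)


def config_to_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["n_values"] = list(config.n_values)
    d["J_values"] = list(config.J_values)
    d["K_values"] = list(config.K_values)
    return d
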