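"""Config parsing, command-line interface, logging and plain-text reporting.

The configuration format is YAML with the exact field names of
:class:`~grmsim.study.StudyConfig` (estimation controls nested under
``fit:``).  An empty file means "the reference design": the full grid
(n 500-1500 by 100, J 5-50 by 5, K 4-7), R = 100 replications, base seed
123.  Unknown keys are rejected by name rather than ignored, since a typo
in a simulation config silently changes the study.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from .estimation import em_fit, make_quadrature, eap_scores
from .grm_model import ItemBank
from .metrics import EvaluationCriteria, classify_agreement
from .population import (
    Condition,
    draw_sample,
    generate_population,
    read_sample_csv,
    write_sample_csv,
    write_theta_csv,
)
from .study import (
    FitSettings,
    StudyConfig,
    StudyResult,
    config_to_dict,
    run_grid,
    summarize_saturation,
)

logger = logging.getLogger("grmsim")

#: Reduced-scale preset for desk-top runs: corner subset of the grid, R = 20.
DESK_PRESET = StudyConfig(
    n_values=(500, 1500), J_values=(10, 50), K_values=(4, 7), R=20
)


def setup_logging(verbose: int = 0) -> None:
    level = logging.DEBUG if verbose >= 2 else logging.INFO if verbose == 1 else logging.WARNING
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")
    logging.getLogger("grmsim").setLevel(max(level, logging.INFO) if verbose == 0 else level)


# ---------------------------------------------------------------------------
# Config round-trip
# ---------------------------------------------------------------------------

_TOP_KEYS = {f.name for f in dataclasses.fields(StudyConfig)}
_FIT_KEYS = {f.name for f in dataclasses.fields(FitSettings)}


def load_config(path) -> StudyConfig:
    """Parse a YAML study config; unspecified fields take the reference defaults."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        return StudyConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    fit_raw = data.pop("fit", {}) or {}
    unknown_fit = set(fit_raw) - _FIT_KEYS
    if unknown_fit:
        raise ValueError(f"unknown config keys under fit: {sorted(unknown_fit)}")
    for key in ("n_values", "J_values", "K_values"):
        if key in data:
            vals = data[key]
            if not isinstance(vals, (list, tuple)) or not vals:
                raise ValueError(f"{key} must be a non-empty list")
            if any(int(v) < 1 for v in vals):
                raise ValueError(f"{key} contains a non-positive value")
    if "K_values" in data and any(int(v) < 2 for v in data["K_values"]):
        raise ValueError("K_values: every K must be >= 2")
    if "J_values" in data and any(int(v) < 2 for v in data["J_values"]):
        raise ValueError("J_values: every J must be >= 2")
    try:
        return StudyConfig(fit=FitSettings(**fit_raw), **data)
    except TypeError as exc:
        raise ValueError(str(exc)) from exc


def write_config(config: StudyConfig, path) -> None:
    """Canonical YAML serialization (sorted keys, full precision) — round-trip stable."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=True, default_flow_style=False)
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def render_report(result: StudyResult, criteria: EvaluationCriteria | None = None) -> str:
    """Human-readable study summary.

    One row per condition with the metric means, the Fisher-mean correlation
    with its Cohen agreement band, and a flag marking cells whose
    FPC-corrected theta RMSE meets the accuracy reference (default 0.30);
    followed by the item-count saturation summary when the run covers
    enough J values.
    """
    criteria = criteria or EvaluationCriteria()
    pc = result.per_condition.copy()
    if pc.empty:
        raise ValueError("cannot render a report for an empty result")

    def _label(row):
        if row["status"] != "ok" or not np.isfinite(row["r_fisher"]):
            return "failed"
        return classify_agreement(float(row["r_fisher"]), criteria)

    pc["agreement"] = pc.apply(_label, axis=1)
    pc["meets_rmse_ref"] = np.where(
        pc["status"].eq("ok") & (pc["rmse_theta_fpc"] < criteria.rmse_reference), "yes", "no"
    )
    cols = [
        "n", "J", "K", "n_reps", "n_failed", "convergence_rate",
        "rmse_a", "rmse_a_fpc", "rmse_a_std", "rmse_a_std_fpc",
        "rmse_theta", "rmse_theta_fpc", "r_fisher", "agreement", "meets_rmse_ref",
    ]
    lines = [
        "GRM parameter-recovery study report",
        "===================================",
        f"conditions: {len(pc)}; replications per condition: {int(pc['n_reps'].iloc[0])}",
        f"theta-RMSE reference: {criteria.rmse_reference:.2f}; "
        f"agreement bands: high > {criteria.high_cut:.2f}, "
        f"moderate {criteria.low_cut:.2f}-{criteria.high_cut:.2f}, "
        f"low < {criteria.low_cut:.2f}",
        "",
        pc[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"),
    ]
    if pc["J"].nunique() >= 3:
        sat = summarize_saturation(result)
        lines += ["", "Item-count saturation (first J with improvement < 0.01):",
                  sat.to_string(index=False)]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _parse_subset(subset: tuple[str, ...]) -> dict:
    out: dict = {}
    for chunk in subset:
        if "=" not in chunk:
            raise ValueError(f"subset must look like key=v1,v2 — got {chunk!r}")
        key, vals = chunk.split("=", 1)
        key = key.strip()
        if key not in ("n", "J", "K"):
            raise ValueError(f"subset key must be n, J or K — got {key!r}")
        out[f"{key}_values"] = tuple(int(v) for v in vals.split(",") if v.strip())
    return out


@click.group()
@click.option("-v", "--verbose", count=True, help="-v progress, -vv per-replication detail.")
def cli(verbose: int) -> None:
    """Monte Carlo parameter-recovery studies for the graded response model."""
    setup_logging(verbose)


@cli.command()
@click.option("--n", type=int, required=True, help="Sample size.")
@click.option("--j", "J", type=int, required=True, help="Item count.")
@click.option("--k", "K", type=int, required=True, help="Response categories per item.")
@click.option("--seed", type=int, default=123, show_default=True)
@click.option("--out-dir", type=click.Path(file_okay=False), required=True)
def generate(n: int, J: int, K: int, seed: int, out_dir: str) -> None:
    """Generate a condition's item bank, theta pool and one sample to CSV."""
    cond = Condition(n=n, J=J, K=K, R=1, base_seed=seed)
    pop = generate_population(cond)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop.bank.to_csv(out / "item_bank.csv")
    write_theta_csv(out / "population_thetas.csv", pop)
    sample = draw_sample(pop, cond.rng(0))
    write_sample_csv(out / "sample.csv", sample, cond, replication=0)
    click.echo(f"wrote item_bank.csv, population_thetas.csv, sample.csv to {out}")


@cli.command("fit")
@click.option("--responses", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--k", "K", type=int, required=True)
@click.option("--out", type=click.Path(dir_okay=False), required=True,
              help="Output CSV of estimated item parameters (JSON sidecar alongside).")
def fit_cmd(responses: str, K: int, out: str) -> None:
    """Fit the GRM to a response CSV by marginal maximum likelihood EM."""
    sample, _ = read_sample_csv(responses)
    model = em_fit(sample.responses, K)
    ItemBank.from_intercepts(model.a_hat, model.d_hat, D=model.D).to_csv(out)
    sidecar = Path(out).with_suffix(".diagnostics.json")
    sidecar.write_text(json.dumps({
        "n_cycles": model.n_cycles,
        "converged": model.converged,
        "loglik_trace": model.loglik_trace.tolist(),
        "warnings": model.warnings,
    }, indent=2))
    click.echo(f"fit {'converged' if model.converged else 'did NOT converge'} "
               f"after {model.n_cycles} cycles; wrote {out} and {sidecar.name}")


@cli.command()
@click.option("--responses", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--params", type=click.Path(exists=True, dir_okay=False), required=True,
              help="Item-parameter CSV (item bank schema).")
@click.option("--out", type=click.Path(dir_okay=False), required=True)
def score(responses: str, params: str, out: str) -> None:
    """EAP-score respondents given fitted item parameters."""
    sample, _ = read_sample_csv(responses)
    bank = ItemBank.from_csv(params)
    eap, psd = eap_scores(sample.responses, bank.a1, bank.d, make_quadrature())
    pd.DataFrame({"theta_eap": eap, "theta_psd": psd}).to_csv(out, index=False)
    click.echo(f"wrote {len(eap)} EAP scores to {out}")


@cli.command("run-study")
@click.option("--config", "config_path", type=click.Path(exists=True, dir_okay=False))
@click.option("--preset", type=click.Choice(["full", "desk"]), default=None,
              help="full: complete reference grid, R=100; desk: corner subset, R=20.")
@click.option("--seed", type=int, default=None, help="Override the base seed.")
@click.option("--reps", type=int, default=None, help="Override the replication count.")
@click.option("--subset", multiple=True,
              help="Restrict grid values, e.g. --subset n=500,1500 --subset J=10.")
@click.option("--out-dir", type=click.Path(file_okay=False), default=None)
@click.option("--workers", type=int, default=None)
def run_study(config_path, preset, seed, reps, subset, out_dir, workers) -> None:
    """Run a study grid and write the result tables and manifest."""
    if config_path:
        config = load_config(config_path)
    elif preset == "desk":
        config = DESK_PRESET
    else:
        config = StudyConfig()
    overrides = _parse_subset(subset)
    if seed is not None:
        overrides["base_seed"] = seed
    if reps is not None:
        overrides["R"] = reps
    if out_dir is not None:
        overrides["out_dir"] = out_dir
    if workers is not None:
        overrides["workers"] = workers
    if overrides:
        config = dataclasses.replace(config, **overrides)
    result = run_grid(config)
    click.echo(render_report(result))


@cli.command()
@click.option("--results", "results_dir", type=click.Path(exists=True, file_okay=False),
              required=True, help="Directory holding per_replication.csv.")
def summarize(results_dir: str) -> None:
    """Re-aggregate saved per-replication results and print the text report."""
    from .study import aggregate_condition

    rep = pd.read_csv(Path(results_dir) / "per_replication.csv")
    groups = [g for _, g in rep.groupby(["n", "J", "K"], sort=True)]
    pc = pd.DataFrame.from_records([aggregate_condition(g) for g in groups])
    click.echo(render_report(StudyResult(per_replication=rep, per_condition=pc)))


def main() -> int:
    """Entry point with the documented exit-code contract."""
    try:
        cli.main(standalone_mode=False)
    except click.ClickException as exc:
        exc.show()
        return 1
    except click.Abort:
        return 1
    except ValueError as exc:
        click.echo(f"error: {exc}", err=True)
        return 1
    except Exception as exc:  # runtime failure; partial results remain on disk
        click.echo(f"runtime failure: {exc}", err=True)
        return 2
    return 0


if __name__ == "__main__":
    sys.exit(main())
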