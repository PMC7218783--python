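"""End-to-end pipeline: simulate -> design -> fit -> reduce -> optimize -> validate.

One YAML configuration drives the whole study: the current staffing, the
daily workload, per-activity service-time distributions, the factorial
bounds, analysis settings (interaction order, significance level, forced
terms) and the optimization costs/budget.  ``run_pipeline`` writes every
intermediate artifact (design CSV, experiment CSV, ANOVA CSV, fit JSON,
optimization JSON, a patient-level event log and the current-vs-proposed
comparison) into an output directory, and is deterministic for a fixed
master seed: rerunning with the same configuration reproduces every
artifact byte for byte (wall-clock timings go to a separate
``timings.json`` kept outside the deterministic set).

The validation step re-simulates the recommended staffing with fresh
seeds and reports the gap between the simulated mean wait and the
surface's prediction — the standard check that the surrogate is trusted
only as far as the simulator confirms it.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .design import (
    FactorSpec,
    cell_seed,
    default_factors,
    full_factorial,
    run_experiments,
)
from .metamodel import (
    ResponseSurfaceRegressor,
    TermKey,
    fit_experiment_table,
    term_label,
)
from .models import FACTOR_NAMES, ResourceConfig, ServiceModel, WorkloadModel, DistSpec
from .optimize import OptimizationProblem, optimize, total_cost
from .reference import reference_model  # re-exported pipeline fixture
from .simulator import simulate_day

__all__ = [
    "PipelineConfig",
    "ScenarioComparison",
    "PipelineRun",
    "percent_improvement",
    "parse_term_label",
    "run_pipeline",
    "load_config",
    "write_report",
    "reference_model",
]


def percent_improvement(before: float, after: float) -> float:
    """Relative reduction, ``100 * (before - after) / before``."""
    if before <= 0:
        raise ValueError("baseline value must be > 0")
    return 100.0 * (before - after) / before


def parse_term_label(label: str) -> TermKey:
    """``'X1X5'`` -> ``(0, 4)``; ``'Intercept'`` -> ``()``."""
    if label == "Intercept":
        return ()
    parts = [p for p in label.split("X") if p]
    try:
        idx = tuple(sorted(int(p) - 1 for p in parts))
    except ValueError:
        raise ValueError(f"cannot parse term label {label!r}") from None
    if any(i < 0 for i in idx) or len(set(idx)) != len(idx):
        raise ValueError(f"cannot parse term label {label!r}")
    return idx


@dataclass
class PipelineConfig:
    current: ResourceConfig
    workload: WorkloadModel
    service: ServiceModel
    factors: list[FactorSpec]
    unit_costs: tuple[float, ...]
    budget: float | None = None  # None -> cost of the current staffing
    replications: int = 10
    common_random_numbers: bool = False
    max_order: int = 3
    alpha: float = 0.05
    forced_terms: list[TermKey] = field(default_factory=list)
    validation_replications: int = 10
    master_seed: int = 12345

    def resolved_budget(self) -> float:
        if self.budget is None:
            return total_cost(self.current, self.unit_costs)
        return float(self.budget)


@dataclass
class ScenarioComparison:
    """Current vs proposed staffing: simulated waits and resource costs."""

    current_config: ResourceConfig
    proposed_config: ResourceConfig
    current_wait: float
    proposed_wait: float
    current_cost: float
    proposed_cost: float

    @property
    def wait_improvement_pct(self) -> float:
        return percent_improvement(self.current_wait, self.proposed_wait)

    @property
    def cost_reduction_pct(self) -> float:
        return percent_improvement(self.current_cost, self.proposed_cost)


@dataclass
class PipelineRun:
    comparison: ScenarioComparison
    fit: ResponseSurfaceRegressor
    reduced_fit: ResponseSurfaceRegressor
    validation: dict[str, float]
    out_dir: Path
    artifacts: dict[str, Path]


def _dist_from_dict(d: dict) -> DistSpec:
    return DistSpec(family=d["family"], params=tuple(d["params"]))


def load_config(path) -> PipelineConfig:
    """Read the pipeline configuration from an annotated YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    res = raw["resources"]
    current = ResourceConfig(**{n: res[n] for n in FACTOR_NAMES})
    wl = raw.get("workload", {})
    workload = WorkloadModel(
        arrival_rate=wl.get("arrival_rate", 145.0),
        esi_mix=tuple(wl.get("esi_mix", (0.05, 0.15, 0.30, 0.30, 0.20))),
        cardiac_fraction=wl.get("cardiac_fraction", 0.40),
        day_length=wl.get("day_length", 1440.0),
    )
    sv = raw.get("service", {})
    service = ServiceModel(
        distributions={
            name: _dist_from_dict(spec)
            for name, spec in sv.get("distributions", {}).items()
        }
        or ServiceModel().distributions,
        cpr_success_prob=sv.get("cpr_success_prob", 0.7),
    )
    dz = raw.get("design", {})
    bounds = dz.get("bounds")
    factors = (
        [FactorSpec(n, *bounds[n]) for n in FACTOR_NAMES] if bounds else default_factors()
    )
    an = raw.get("analysis", {})
    opt = raw.get("optimization", {})
    costs = opt.get("unit_costs")
    unit_costs = (
        tuple(costs[n] for n in FACTOR_NAMES) if costs else (0.6, 0.5, 0.8, 0.7, 2.0)
    )
    budget = opt.get("budget")
    if isinstance(budget, str):
        budget = np.inf if budget in ("inf", "infinite") else float(budget)
    return PipelineConfig(
        current=current,
        workload=workload,
        service=service,
        factors=factors,
        unit_costs=unit_costs,
        budget=budget,
        replications=dz.get("replications", 10),
        common_random_numbers=dz.get("common_random_numbers", False),
        max_order=an.get("max_order", 3),
        alpha=an.get("alpha", 0.05),
        forced_terms=[parse_term_label(t) for t in an.get("forced_terms", [])],
        validation_replications=an.get("validation_replications", 10),
        master_seed=raw.get("seed", 12345),
    )


def _simulate_mean(config, workload, service, seeds, collect_first_log=False,
                   simulator=None):
    sim = simulator or simulate_day
    waits, records = [], None
    for i, s in enumerate(seeds):
        r = sim(config, workload, service, s, keep_records=(i == 0))
        waits.append(r.mean_wait)
        if i == 0 and collect_first_log:
            records = getattr(r, "records", [])
    return float(np.mean(waits)), records


def _fit_to_dict(fit: ResponseSurfaceRegressor) -> dict:
    return {
        "terms": [term_label(t) for t in fit.terms_],
        "coefficients": {term_label(t): b for t, b in fit.coefficients().items()},
        "r2": fit.r2_,
        "residual_ss": fit.residual_ss_,
        "total_ss": fit.total_ss_,
        "n_obs": int(len(fit.y_)),
    }


def fit_from_dict(d: dict, n_factors: int = 5) -> ResponseSurfaceRegressor:
    """Rebuild a fitted surface from its JSON form by exact interpolation."""
    terms = [parse_term_label(t) for t in d["terms"]]
    coef = {parse_term_label(t): v for t, v in d["coefficients"].items()}
    X = full_factorial(n_factors).rows
    y = np.full(X.shape[0], coef.get((), 0.0))
    for t in terms:
        y += coef[t] * np.prod(X[:, list(t)], axis=1)
    return ResponseSurfaceRegressor(terms=terms).fit(X, y)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig, out_dir, *, simulator=None) -> PipelineRun:
    """Execute every stage and write all artifacts under ``out_dir``.

    ``simulator`` substitutes the day simulator in every stage (same
    call signature); used to verify the pipeline plumbing against a
    response generator with known coefficients.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage_t0 = time.perf_counter()

    def clock(stage: str) -> None:
        nonlocal stage_t0
        timings[stage] = round(time.perf_counter() - stage_t0, 4)
        stage_t0 = time.perf_counter()

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- stage: baseline simulation of the current staffing ---------------
    try:
        base_seeds = [cell_seed(config.master_seed, 10_000, j)
                      for j in range(config.replications)]
        current_wait, log = _simulate_mean(
            config.current, config.workload, config.service, base_seeds,
            collect_first_log=True, simulator=simulator,
        )
        log_path = out / "current_patient_log.jsonl"
        with open(log_path, "w") as fh:
            for rec in log or []:
                fh.write(json.dumps({
                    "patient_id": rec.patient_id,
                    "esi_level": rec.esi_level,
                    "cardiac": rec.cardiac,
                    "arrival_time": rec.arrival_time,
                    "stages": [dataclasses.asdict(s) for s in rec.stages],
                    "disposition": rec.disposition,
                    "total_wait": rec.total_wait,
                }, sort_keys=True) + "\n")
        artifacts["patient_log"] = log_path
    except Exception as exc:  # pragma: no cover - defensive
        fail("baseline_simulation", exc)
    clock("baseline_simulation")

    # -- stage: factorial design ------------------------------------------
    try:
        design = full_factorial(len(config.factors), config.factors)
        p = out / "design.csv"
        design.to_frame().to_csv(p, index=False)
        artifacts["design"] = p
    except Exception as exc:
        fail("design", exc)
    clock("design")

    # -- stage: run experiments -------------------------------------------
    try:
        table = run_experiments(
            design, config.workload, config.service,
            replications=config.replications,
            master_seed=config.master_seed,
            common_random_numbers=config.common_random_numbers,
            simulator=simulator,
        )
        p = out / "experiments.csv"
        table.to_frame().to_csv(p, index=False)
        artifacts["experiments"] = p
    except Exception as exc:
        fail("experiments", exc)
    clock("experiments")

    # -- stage: fit + ANOVA -----------------------------------------------
    try:
        fit = fit_experiment_table(table, max_order=config.max_order)
        anova = fit.anova()
        p = out / "anova.csv"
        anova.to_csv(p)
        artifacts["anova"] = p
        p = out / "fit.json"
        _write_json(p, _fit_to_dict(fit))
        artifacts["fit"] = p
    except Exception as exc:
        fail("fit", exc)
    clock("fit")

    # -- stage: reduce ------------------------------------------------------
    try:
        reduced = fit.reduce(alpha=config.alpha, forced_terms=config.forced_terms)
        p = out / "reduced_fit.json"
        _write_json(p, _fit_to_dict(reduced))
        artifacts["reduced_fit"] = p
    except Exception as exc:
        fail("reduce", exc)
    clock("reduce")

    # -- stage: optimize ----------------------------------------------------
    try:
        problem = OptimizationProblem(
            factors=tuple(config.factors),
            unit_costs=config.unit_costs,
            fit=reduced,
            budget=config.resolved_budget(),
        )
        result = optimize(problem)
        p = out / "optimization.json"
        _write_json(p, {
            "argmin": dict(zip(FACTOR_NAMES, result.argmin.as_tuple())),
            "predicted_wait": result.predicted_wait,
            "total_cost": result.total_cost,
            "budget": config.resolved_budget(),
            "n_feasible": result.n_feasible,
            "ties": [dict(zip(FACTOR_NAMES, t.as_tuple())) for t in result.ties],
        })
        artifacts["optimization"] = p
    except Exception as exc:
        fail("optimize", exc)
    clock("optimize")

    # -- stage: validate ----------------------------------------------------
    try:
        val_seeds = [cell_seed(config.master_seed, 20_000, j)
                     for j in range(config.validation_replications)]
        simulated_opt, _ = _simulate_mean(
            result.argmin, config.workload, config.service, val_seeds,
            simulator=simulator)
        validation = {
            "simulated_wait": simulated_opt,
            "predicted_wait": result.predicted_wait,
            "gap": simulated_opt - result.predicted_wait,
        }
        p = out / "validation.json"
        _write_json(p, validation)
        artifacts["validation"] = p
    except Exception as exc:
        fail("validate", exc)
    clock("validate")

    # -- stage: comparison --------------------------------------------------
    try:
        comparison = ScenarioComparison(
            current_config=config.current,
            proposed_config=result.argmin,
            current_wait=current_wait,
            proposed_wait=simulated_opt,
            current_cost=total_cost(config.current, config.unit_costs),
            proposed_cost=total_cost(result.argmin, config.unit_costs),
        )
        p = out / "comparison.json"
        _write_json(p, {
            "current": {
                "config": dict(zip(FACTOR_NAMES, config.current.as_tuple())),
                "wait_min": comparison.current_wait,
                "cost": comparison.current_cost,
            },
            "proposed": {
                "config": dict(zip(FACTOR_NAMES, result.argmin.as_tuple())),
                "wait_min": comparison.proposed_wait,
                "cost": comparison.proposed_cost,
            },
            "wait_improvement_pct": comparison.wait_improvement_pct,
            "cost_reduction_pct": comparison.cost_reduction_pct,
        })
        artifacts["comparison"] = p
    except Exception as exc:
        fail("comparison", exc)
    clock("comparison")

    manifest = {
        "master_seed": config.master_seed,
        "replications": config.replications,
        "common_random_numbers": config.common_random_numbers,
        "baseline_seeds": base_seeds,
        "validation_seeds": val_seeds,
        "artifacts": {k: v.name for k, v in artifacts.items()},
    }
    _write_json(out / "manifest.json", manifest)
    artifacts["manifest"] = out / "manifest.json"
    # wall-clock log; intentionally outside the deterministic artifact set
    _write_json(out / "timings.json", timings)

    return PipelineRun(
        comparison=comparison,
        fit=fit,
        reduced_fit=reduced,
        validation=validation,
        out_dir=out,
        artifacts=artifacts,
    )


def write_report(run_dir, stream=None) -> str:
    """Render the comparison table from a completed run directory."""
    import io
    import sys

    with open(Path(run_dir) / "comparison.json") as fh:
        comp = json.load(fh)
    cols = ("CHW", "Recep.", "Nurse", "Cardio.", "Beds")
    lines = [
        "Status    " + "  ".join(f"{c:>7}" for c in cols)
        + f"  {'Wait (min)':>11}  {'Cost':>8}",
    ]
    for name in ("current", "proposed"):
        row = comp[name]
        levels = [row["config"][n] for n in FACTOR_NAMES]
        lines.append(
            f"{name.capitalize():<10}"
            + "  ".join(f"{v:>7d}" for v in levels)
            + f"  {row['wait_min']:>11.0f}  {row['cost']:>8.1f}"
        )
    lines.append(f"Wait-time improvement: {comp['wait_improvement_pct']:.1f}%")
    lines.append(f"Cost reduction:        {comp['cost_reduction_pct']:.1f}%")
    text = "\n".join(lines)
    print(text, file=stream or sys.stdout)
    return text
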