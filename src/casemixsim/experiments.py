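"""Experiment drivers: develop everywhere, validate everywhere, sweep.

These orchestrate the study design: one cohort and one fitted risk model
per population under a master seed, a full cross-population validation
matrix of transported-model AUCs, and correlation sweeps tracing how the
AUC and the SD of the linear predictor respond to the correlation
structure in either simulation approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .approach1 import simulate_population_a1
from .approach2 import simulate_population_a2
from .cohort import Cohort
from .evaluation import EvaluationReport, auc_mann_whitney, evaluate
from .risk_model import RiskModel, fit_logistic
from .specs import GaussianGroup, PopulationSpecA1, PopulationSpecA2

__all__ = [
    "population_seed",
    "simulate_population",
    "DevelopmentResult",
    "develop_all",
    "ValidationMatrix",
    "cross_validate",
    "SweepResult",
    "correlation_sweep_a1",
    "correlation_sweep_a2",
    "fig3_scenario_specs",
]

SAME_DIRECTION_ORS = (1.5, 1.5)
OPPOSITE_DIRECTION_ORS = (1.5, 0.8)


def population_seed(master_seed: int, population_id: str, approach: int = 0) -> int:
    """Deterministic per-population seed derived from the master seed.

    Mixing goes through a SeedSequence keyed on (master seed, approach,
    population id bytes); the result is reduced below 2**31 so it can be
    stored and replayed anywhere an integer seed is accepted.
    """
    entropy = [int(master_seed), int(approach), *population_id.encode()]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def simulate_population(spec, seed: int) -> Cohort:
    """Dispatch to the approach-1 or approach-2 simulator."""
    if isinstance(spec, PopulationSpecA1):
        return simulate_population_a1(spec, seed)
    if isinstance(spec, PopulationSpecA2):
        return simulate_population_a2(spec, seed)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


@dataclass
class DevelopmentResult:
    """One cohort, fitted model and development report per population."""

    cohorts: dict[str, Cohort]
    models: dict[str, RiskModel]
    reports: dict[str, EvaluationReport]

    @property
    def population_ids(self) -> list[str]:
        return list(self.cohorts)


def develop_all(specs: Sequence, master_seed: int) -> DevelopmentResult:
    """Simulate, fit and evaluate every population under one master seed."""
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"population ids must be unique, got {ids}")
    cohorts: dict[str, Cohort] = {}
    models: dict[str, RiskModel] = {}
    reports: dict[str, EvaluationReport] = {}
    for spec in specs:
        seed = population_seed(master_seed, spec.id, spec.approach)
        cohort = simulate_population(spec, seed)
        model = fit_logistic(cohort)
        cohorts[spec.id] = cohort
        models[spec.id] = model
        reports[spec.id] = evaluate(model, cohort, direction="fixed")
    return DevelopmentResult(cohorts=cohorts, models=models, reports=reports)


@dataclass
class ValidationMatrix:
    """Cross-population AUC matrix.

    Rows index the population a model is validated in; columns index the
    population it was developed in.  ``flipped`` marks entries where the
    auto-orientation reversed the transported score's direction.
    """

    population_ids: list[str]
    auc: pd.DataFrame
    flipped: pd.DataFrame

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.auc), index=self.population_ids)

    def is_diagonally_dominant(self, tol: float = 0.01) -> bool:
        """Every development AUC within ``tol`` of its validation row's max."""
        row_max = self.auc.max(axis=1)
        return bool((self.diagonal() >= row_max - tol).all())


def cross_validate(
    models: dict[str, RiskModel],
    cohorts: dict[str, Cohort],
    direction: Literal["fixed", "auto"] = "auto",
) -> ValidationMatrix:
    """Validate every model in every cohort (transported coefficients,
    no refitting).  Diagonal entries are the development AUCs."""
    if set(models) != set(cohorts):
        raise ValueError("models and cohorts must cover the same population ids")
    ids = list(cohorts)
    auc = pd.DataFrame(index=ids, columns=ids, dtype=float)
    flipped = pd.DataFrame(False, index=ids, columns=ids)
    for validated_in, cohort in cohorts.items():
        lp_cache = {dev: m.linear_predictor(cohort.x) for dev, m in models.items()}
        for developed_in, lp in lp_cache.items():
            a, f = auc_mann_whitney(lp, cohort.y, direction=direction)
            auc.loc[validated_in, developed_in] = a
            flipped.loc[validated_in, developed_in] = f
    return ValidationMatrix(population_ids=ids, auc=auc, flipped=flipped)


@dataclass
class SweepResult:
    """AUC and SD-of-LP traced over a grid of correlation values."""

    grid: np.ndarray
    auc: np.ndarray
    sd_lp: np.ndarray
    scenario: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rho": self.grid, "auc": self.auc, "sd_lp": self.sd_lp, "scenario": self.scenario}
        )


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size and (np.abs(grid) >= 1).any():
        raise ValueError("correlation grid values must lie in (-1, 1)")
    if grid.size > 1 and not (np.diff(grid) > 0).all():
        raise ValueError("correlation grid must be strictly increasing")
    return grid


def correlation_sweep_a1(
    base: PopulationSpecA1,
    rho_grid: Iterable[float],
    or_mode: Literal["same", "opposite"] = "same",
    seed: int = 0,
) -> SweepResult:
    """Development AUC and SD of LP as the total-population correlation varies.

    ``or_mode="same"`` fixes adjusted ORs (1.5, 1.5); ``"opposite"`` uses
    (1.5, 0.8).  Each grid point is an independent fresh simulation, so
    the curves carry Monte-Carlo jitter.
    """
    grid = _check_grid(np.asarray(list(rho_grid), dtype=float))
    ors = {"same": SAME_DIRECTION_ORS, "opposite": OPPOSITE_DIRECTION_ORS}[or_mode]
    aucs, sds = [], []
    for i, rho in enumerate(grid):
        spec = PopulationSpecA1(
            id=f"{base.id}~rho{rho:+.3f}",
            n=base.n,
            prevalence=base.prevalence,
            mu=base.mu,
            sigma=base.sigma,
            rho=float(rho),
            adjusted_or=ors,
        )
        cohort = simulate_population_a1(spec, population_seed(seed, spec.id, 1))
        model = fit_logistic(cohort)
        report = evaluate(model, cohort, direction="fixed")
        aucs.append(report.auc)
        sds.append(report.sd_lp)
    return SweepResult(
        grid=grid,
        auc=np.asarray(aucs),
        sd_lp=np.asarray(sds),
        scenario=f"approach1 ORs {ors} mu={base.mu} sigma={base.sigma}",
    )


def correlation_sweep_a2(
    base: PopulationSpecA2,
    rho_case_levels: Iterable[float],
    rho_control_grid: Iterable[float],
    seed: int = 0,
) -> list[SweepResult]:
    """One AUC curve per fixed case correlation, over a control-correlation grid."""
    control_grid = _check_grid(np.asarray(list(rho_control_grid), dtype=float))
    results = []
    for rho_case in rho_case_levels:
        if not -1 < rho_case < 1:
            raise ValueError(f"case correlation must lie in (-1, 1), got {rho_case}")
        aucs, sds = [], []
        for rho_control in control_grid:
            spec = base.with_correlations(rho_case, float(rho_control))
            spec_id = f"{base.id}~case{rho_case:+.3f}~ctrl{rho_control:+.3f}"
            cohort = simulate_population_a2(spec, population_seed(seed, spec_id, 2))
            model = fit_logistic(cohort)
            report = evaluate(model, cohort, direction="fixed")
            aucs.append(report.auc)
            sds.append(report.sd_lp)
        results.append(
            SweepResult(
                grid=control_grid,
                auc=np.asarray(aucs),
                sd_lp=np.asarray(sds),
                scenario=(
                    f"approach2 rho_case={rho_case} mu_case={base.case.mu} "
                    f"mu_control={base.control.mu} sigma_case={base.case.sigma} "
                    f"sigma_control={base.control.sigma}"
                ),
            )
        )
    return results


def fig3_scenario_specs(n: int = 100_000, prevalence: float = 0.2) -> dict[str, PopulationSpecA2]:
    """The four case/control parameter scenarios used for the
    control-correlation sweeps (labels a–d).

    All share control means (0, 0) except where noted; correlations are
    placeholders overwritten by the sweep.
    """
    layouts = {
        "a": ((1.0, 2.0), (2.0, 2.0), (2.0, 2.0)),
        "b": ((1.0, 3.0), (2.0, 2.0), (2.0, 2.0)),
        "c": ((1.0, 2.0), (2.0, 3.0), (2.0, 3.0)),
        "d": ((1.0, 2.0), (2.0, 1.0), (2.0, 1.0)),
    }
    specs = {}
    for label, (mu_case, sigma_case, sigma_control) in layouts.items():
        specs[label] = PopulationSpecA2(
            id=f"scenario-{label}",
            n=n,
            prevalence=prevalence,
            case=GaussianGroup(mu=mu_case, sigma=sigma_case, rho=0.0),
            control=GaussianGroup(mu=(0.0, 0.0), sigma=sigma_control, rho=0.0),
        )
    return specs
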