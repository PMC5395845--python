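"""Two-predictor logistic risk models: fitting, transport, prediction.

A fitted model is a frozen triple (intercept, beta1, beta2) with fit
diagnostics.  Transporting a model to an external cohort means applying
these coefficients unchanged — no recalibration or refitting — which is
how external validity is assessed throughout the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import Cohort

__all__ = ["RiskModel", "FitMetadata", "fit_logistic", "FitError", "SeparationError"]

SCORE_TOL = 1e-8  # max |mean score| at the reported optimum
SEPARATION_BOUND = 50.0  # |coefficient| beyond this is treated as separation


class FitError(RuntimeError):
    """Logistic fit failed to converge; carries diagnostics."""


class SeparationError(FitError):
    """Outcome classes are (quasi-)separable; ML estimates diverge."""


@dataclass(frozen=True)
class FitMetadata:
    iterations: int
    converged: bool
    score_norm: float  # max absolute component of the mean score vector


@dataclass(frozen=True)
class RiskModel:
    intercept: float
    coefficients: tuple[float, float]
    development_population: str = ""
    seed: int | None = None
    fit: FitMetadata | None = None

    @property
    def adjusted_or(self) -> tuple[float, float]:
        """Exponentiated slopes: per-unit adjusted odds ratios."""
        return (float(np.exp(self.coefficients[0])), float(np.exp(self.coefficients[1])))

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        """b0 + b1*x1 + b2*x2 per row."""
        x = np.asarray(x, dtype=float)
        return self.intercept + x @ np.asarray(self.coefficients)

    def predicted_risk(self, x: np.ndarray) -> np.ndarray:
        """Inverse-logit of the linear predictor, elementwise in (0, 1)."""
        return expit(self.linear_predictor(x))

    def scaled(self, factor: float) -> "RiskModel":
        """Model with coefficient vector (and intercept) scaled; used to
        check that validation AUC depends only on coefficient direction."""
        return RiskModel(
            intercept=self.intercept * factor,
            coefficients=(self.coefficients[0] * factor, self.coefficients[1] * factor),
            development_population=self.development_population,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": list(self.coefficients),
            "development_population": self.development_population,
            "seed": self.seed,
            "fit": None
            if self.fit is None
            else {
                "iterations": self.fit.iterations,
                "converged": self.fit.converged,
                "score_norm": self.fit.score_norm,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, obj: dict) -> "RiskModel":
        fit = obj.get("fit")
        return cls(
            intercept=float(obj["intercept"]),
            coefficients=tuple(float(c) for c in obj["coefficients"]),  # type: ignore[arg-type]
            development_population=str(obj.get("development_population", "")),
            seed=obj.get("seed"),
            fit=None
            if fit is None
            else FitMetadata(
                iterations=int(fit["iterations"]),
                converged=bool(fit["converged"]),
                score_norm=float(fit["score_norm"]),
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_logistic(cohort: Cohort, maxiter: int = 100) -> RiskModel:
    """Maximum-likelihood logistic fit of outcome on the two predictors.

    Newton iterations on the (concave) log-likelihood; convergence is
    accepted only if the mean score vector vanishes to ``SCORE_TOL``.
    Diverging coefficients (|b| > 50) are reported as separation.
    """
    if not cohort.has_both_classes():
        raise ValueError(
            f"cohort {cohort.population_id!r} needs both outcome classes "
            f"({cohort.n_cases} cases / {cohort.n_controls} controls)"
        )
    if abs(np.corrcoef(cohort.x[:, 0], cohort.x[:, 1])[0, 1]) > 1 - 1e-12:
        raise ValueError("predictors are perfectly collinear")

    design = sm.add_constant(cohort.x, has_constant="add")
    logit_model = sm.Logit(cohort.y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = logit_model.fit(method="newton", maxiter=maxiter, tol=1e-10, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from exc

    params = np.asarray(res.params, dtype=float)
    if np.abs(params).max() > SEPARATION_BOUND:
        raise SeparationError(
            f"coefficients diverged beyond {SEPARATION_BOUND}: {params.tolist()}"
        )
    score_norm = float(np.abs(logit_model.score(params)).max() / cohort.n)
    iterations = int(res.mle_retvals.get("iterations", -1))
    converged = bool(res.mle_retvals.get("converged", False)) and score_norm < SCORE_TOL
    if not converged:
        raise FitError(
            f"logistic fit did not converge after {iterations} iterations "
            f"(mean-score norm {score_norm:.3e}, params {params.tolist()})"
        )
    return RiskModel(
        intercept=float(params[0]),
        coefficients=(float(params[1]), float(params[2])),
        development_population=cohort.population_id,
        seed=cohort.seed,
        fit=FitMetadata(iterations=iterations, converged=converged, score_norm=score_norm),
    )
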