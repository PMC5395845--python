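"""Discrimination and case-mix descriptors.

The AUC is computed by the midrank Mann–Whitney formula (ties count
one-half), optionally auto-oriented: a transported model whose score
ranks inversely to the outcome is reported as max(A, 1 - A) with a flag
recording the flip.  Case-mix heterogeneity is summarised by the sample
SD of the linear predictor and by outcome-stratified predictor moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort
from .risk_model import RiskModel

__all__ = [
    "auc_mann_whitney",
    "sd_linear_predictor",
    "group_summaries",
    "evaluate",
    "GroupSummary",
    "EvaluationReport",
    "reports_to_frame",
]

Direction = Literal["fixed", "auto"]


def auc_mann_whitney(
    scores: np.ndarray, y: np.ndarray, direction: Direction = "fixed"
) -> tuple[float, bool]:
    """Concordance probability of ``scores`` for the binary outcome ``y``.

    Midrank formula: (sum of case ranks - n1(n1+1)/2) / (n1 n0), with
    tied scores contributing 1/2.  Under ``direction="auto"`` the result
    is max(A, 1 - A) and the returned flag records whether the flip was
    taken; under ``"fixed"`` the raw value is returned.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if scores.shape != y.shape:
        raise ValueError("scores and y must have the same length")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes to be present")
    ranks = rankdata(scores)  # midranks
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    auc = float(auc)
    if direction == "auto" and auc < 0.5:
        return 1.0 - auc, True
    if direction not in ("fixed", "auto"):
        raise ValueError(f"direction must be 'fixed' or 'auto', got {direction!r}")
    return auc, False


def sd_linear_predictor(model: RiskModel, cohort: Cohort) -> float:
    """Sample SD (denominator n-1) of the model's linear predictor."""
    return float(np.std(model.linear_predictor(cohort.x), ddof=1))


@dataclass(frozen=True)
class GroupSummary:
    """Predictor moments within one outcome group."""

    mu: tuple[float, float]
    sigma: tuple[float, float]
    rho: float
    n: int


def _summarise(x: np.ndarray) -> GroupSummary:
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    rho = float(np.corrcoef(x[:, 0], x[:, 1])[0, 1])
    return GroupSummary(
        mu=(float(mu[0]), float(mu[1])),
        sigma=(float(sigma[0]), float(sigma[1])),
        rho=rho,
        n=x.shape[0],
    )


def group_summaries(cohort: Cohort) -> tuple[GroupSummary, GroupSummary]:
    """(case, control) means, SDs and Pearson correlation of the predictors."""
    if cohort.n_cases < 3 or cohort.n_controls < 3:
        raise ValueError(
            "each outcome group needs at least 3 members for a correlation "
            f"({cohort.n_cases} cases / {cohort.n_controls} controls)"
        )
    return _summarise(cohort.x[cohort.y == 1]), _summarise(cohort.x[cohort.y == 0])


@dataclass(frozen=True)
class EvaluationReport:
    """One (model, cohort) evaluation: discrimination plus case-mix."""

    model_population: str
    cohort_population: str
    auc: float
    auc_direction_flipped: bool
    sd_lp: float
    case_summary: GroupSummary
    control_summary: GroupSummary
    n_cases: int
    n_controls: int

    def to_row(self) -> dict:
        c, ct = self.case_summary, self.control_summary
        return {
            "model": self.model_population,
            "cohort": self.cohort_population,
            "auc": self.auc,
            "flipped": self.auc_direction_flipped,
            "sd_lp": self.sd_lp,
            "case_mu1": c.mu[0],
            "case_mu2": c.mu[1],
            "case_sigma1": c.sigma[0],
            "case_sigma2": c.sigma[1],
            "case_rho": c.rho,
            "control_mu1": ct.mu[0],
            "control_mu2": ct.mu[1],
            "control_sigma1": ct.sigma[0],
            "control_sigma2": ct.sigma[1],
            "control_rho": ct.rho,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


def evaluate(model: RiskModel, cohort: Cohort, direction: Direction = "fixed") -> EvaluationReport:
    """Evaluate a (possibly transported) model in a cohort.

    Development-sample evaluations conventionally use ``direction="fixed"``
    (in-sample ML fits are concordant by construction); external
    validations default to "auto" in the experiment drivers, with the
    flip surfaced rather than hidden.
    """
    lp = model.linear_predictor(cohort.x)
    auc, flipped = auc_mann_whitney(lp, cohort.y, direction=direction)
    case, control = group_summaries(cohort)
    return EvaluationReport(
        model_population=model.development_population,
        cohort_population=cohort.population_id,
        auc=auc,
        auc_direction_flipped=flipped,
        sd_lp=float(np.std(lp, ddof=1)),
        case_summary=case,
        control_summary=control,
        n_cases=cohort.n_cases,
        n_controls=cohort.n_controls,
    )


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack evaluation reports into a DataFrame, one row per report.

    By the study's reporting convention, moments are meant to be read at
    two decimals and AUCs at three; values are stored unrounded.
    """
    return pd.DataFrame([r.to_row() for r in reports])
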