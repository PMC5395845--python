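"""Approach-1 population simulation.

Predictors are drawn for the whole population from a bivariate Gaussian;
the logistic slopes are fixed a priori as log adjusted odds ratios; the
intercept is calibrated on the realized sample so that the mean predicted
risk equals the target prevalence; outcomes are independent Bernoulli
draws from the individual risks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort
from .specs import PopulationSpecA1

__all__ = [
    "draw_predictors_a1",
    "calibrate_intercept",
    "assign_outcomes",
    "simulate_population_a1",
]

CALIBRATION_TOL = 1e-8


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_predictors_a1(spec: PopulationSpecA1, seed) -> np.ndarray:
    """Draw ``spec.n`` i.i.d. rows from the spec's bivariate Gaussian.

    Sampling applies the Cholesky factor of the covariance matrix to
    independent standard normals, so results are exactly reproducible
    for a given seed.
    """
    rng = _rng(seed)
    chol = np.linalg.cholesky(spec.covariance())
    z = rng.standard_normal((spec.n, 2))
    return np.asarray(spec.mu) + z @ chol.T


def calibrate_intercept(x: np.ndarray, betas, target_prevalence: float) -> float:
    """Intercept b0 such that mean(expit(b0 + x @ betas)) hits the target.

    The mean risk is strictly increasing in b0, so the root is unique;
    Brent's method is run on an auto-expanded bracket around
    logit(target) and the result is accurate to 1e-8 in mean risk.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError(f"target_prevalence must lie in (0, 1), got {target_prevalence}")
    eta = np.asarray(x, dtype=float) @ np.asarray(betas, dtype=float)

    def mean_risk_gap(b0: float) -> float:
        return float(expit(b0 + eta).mean() - target_prevalence)

    center = float(logit(target_prevalence))
    half_width = 1.0 + float(np.ptp(eta)) if eta.size else 1.0
    lo, hi = center - half_width, center + half_width
    while mean_risk_gap(lo) > 0:
        lo -= half_width
    while mean_risk_gap(hi) < 0:
        hi += half_width
    b0 = float(brentq(mean_risk_gap, lo, hi, xtol=1e-13))
    assert abs(mean_risk_gap(b0)) <= CALIBRATION_TOL
    return b0


def assign_outcomes(risks: np.ndarray, seed) -> np.ndarray:
    """Independent Bernoulli outcome per individual risk."""
    risks = np.asarray(risks, dtype=float)
    if risks.size and (risks.min() < 0 or risks.max() > 1):
        raise ValueError("risks must lie in [0, 1]")
    rng = _rng(seed)
    return (rng.random(risks.shape) < risks).astype(int)


def simulate_population_a1(spec: PopulationSpecA1, seed: int) -> Cohort:
    """Full approach-1 simulation: draw, calibrate, assign.

    The master seed is split into independent sub-streams for the
    predictor draw and the outcome draw, so the two stages never share
    random state.
    """
    ss = np.random.SeedSequence(seed)
    predictor_ss, outcome_ss = ss.spawn(2)
    x = draw_predictors_a1(spec, np.random.default_rng(predictor_ss))
    betas = spec.betas
    b0 = calibrate_intercept(x, betas, spec.prevalence)
    risks = expit(b0 + x @ np.asarray(betas))
    y = assign_outcomes(risks, np.random.default_rng(outcome_ss))
    return Cohort(
        population_id=spec.id,
        x=x,
        y=y,
        seed=int(seed),
        metadata={
            "approach": 1,
            "true_intercept": b0,
            "true_betas": list(betas),
            "target_prevalence": spec.prevalence,
        },
    )
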