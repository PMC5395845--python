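"""Approach-2 population simulation and closed-form mixture summaries.

Here the predictor distribution is specified conditional on disease
status: cases and controls are sampled from separate bivariate Gaussians
and concatenated, with the case count fixed exactly at
round(n * prevalence).  The whole-population moments of the implied
two-component mixture, and the closed-form unadjusted odds ratio under
a common within-group SD, are available analytically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .specs import GaussianGroup, PopulationSpecA2

__all__ = [
    "simulate_population_a2",
    "mixture_moments",
    "unadjusted_or",
    "MixtureSummary",
    "CommonVarianceWarning",
]


class CommonVarianceWarning(UserWarning):
    """The closed-form unadjusted OR assumes equal case/control SDs."""


@dataclass(frozen=True)
class MixtureSummary:
    """Whole-population parameters implied by the case/control mixture."""

    mu_total: tuple[float, float]
    sigma_total: tuple[float, float]
    rho_total: float
    unadjusted_or: tuple[float, float]


def _draw_group(group: GaussianGroup, n: int, rng: np.random.Generator) -> np.ndarray:
    chol = np.linalg.cholesky(group.covariance())
    z = rng.standard_normal((n, 2))
    return np.asarray(group.mu) + z @ chol.T


def simulate_population_a2(spec: PopulationSpecA2, seed: int) -> Cohort:
    """Sample cases and controls separately and combine.

    Exactly ``spec.n_cases`` rows come from the case Gaussian; rows are
    then shuffled with a seed-derived permutation so that downstream
    code cannot rely on block ordering.
    """
    ss = np.random.SeedSequence(seed)
    case_ss, control_ss, shuffle_ss = ss.spawn(3)
    x_case = _draw_group(spec.case, spec.n_cases, np.random.default_rng(case_ss))
    x_control = _draw_group(spec.control, spec.n_controls, np.random.default_rng(control_ss))
    x = np.vstack([x_case, x_control])
    y = np.concatenate([np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)])
    perm = np.random.default_rng(shuffle_ss).permutation(spec.n)
    return Cohort(
        population_id=spec.id,
        x=x[perm],
        y=y[perm],
        seed=int(seed),
        metadata={"approach": 2, "n_cases": spec.n_cases},
    )


def unadjusted_or(spec: PopulationSpecA2, component: int) -> float:
    """Closed-form single-predictor odds ratio exp((mu_case - mu_control) / SD^2).

    Valid when the predictor shares a common SD in cases and controls;
    if the SDs differ, the control-group SD is used and a
    ``CommonVarianceWarning`` is emitted.
    """
    if component not in (1, 2):
        raise ValueError(f"component must be 1 or 2, got {component}")
    i = component - 1
    sd_case, sd_control = spec.case.sigma[i], spec.control.sigma[i]
    if sd_case != sd_control:
        warnings.warn(
            f"component {component}: case SD {sd_case} != control SD {sd_control}; "
            "the closed-form unadjusted OR assumes a common variance — using the control SD",
            CommonVarianceWarning,
            stacklevel=2,
        )
    return float(np.exp((spec.case.mu[i] - spec.control.mu[i]) / sd_control**2))


def mixture_moments(spec: PopulationSpecA2) -> MixtureSummary:
    """Exact whole-population moments of the case/control Gaussian mixture.

    With case fraction pi, per component:
        mu_t     = pi mu_c + (1-pi) mu_ct
        sigma_t² = pi sigma_c² + (1-pi) sigma_ct² + pi(1-pi)(mu_c - mu_ct)²
    and the total covariance adds the analogous between-group term to the
    prevalence-weighted within-group covariances.
    """
    pi = spec.prevalence
    mu_c, mu_ct = np.asarray(spec.case.mu), np.asarray(spec.control.mu)
    s_c, s_ct = np.asarray(spec.case.sigma), np.asarray(spec.control.sigma)

    mu_t = pi * mu_c + (1 - pi) * mu_ct
    var_t = pi * s_c**2 + (1 - pi) * s_ct**2 + pi * (1 - pi) * (mu_c - mu_ct) ** 2
    sigma_t = np.sqrt(var_t)
    cov_t = (
        pi * spec.case.rho * s_c[0] * s_c[1]
        + (1 - pi) * spec.control.rho * s_ct[0] * s_ct[1]
        + pi * (1 - pi) * (mu_c[0] - mu_ct[0]) * (mu_c[1] - mu_ct[1])
    )
    rho_t = float(cov_t / (sigma_t[0] * sigma_t[1]))
    return MixtureSummary(
        mu_total=(float(mu_t[0]), float(mu_t[1])),
        sigma_total=(float(sigma_t[0]), float(sigma_t[1])),
        rho_total=rho_t,
        unadjusted_or=(unadjusted_or(spec, 1), unadjusted_or(spec, 2)),
    )
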