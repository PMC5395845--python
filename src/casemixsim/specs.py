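"""Population specifications for the two simulation approaches.

A population is described either by total-population Gaussian parameters
plus fixed adjusted odds ratios (approach 1) or by case- and
control-conditional Gaussian parameters (approach 2).  Both carry the
cohort size ``n`` and the disease prevalence.  Specs are immutable and
validated on construction; they round-trip through plain JSON objects.

Two bundled spec collections encode the study's standard populations:
16 approach-1 populations "A"–"P" and 9 approach-2 populations "A"–"I",
all with n = 100,000 and 20% prevalence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SpecValidationError",
    "PopulationSpecA1",
    "GaussianGroup",
    "PopulationSpecA2",
    "load_table1_specs",
    "load_table2_specs",
    "load_specs",
]

Pair = tuple[float, float]


class SpecValidationError(ValueError):
    """Raised when a population spec violates its invariants."""


def _as_pair(value: Sequence[float], name: str) -> Pair:
    vals = tuple(float(v) for v in value)
    if len(vals) != 2:
        raise SpecValidationError(f"{name} must have exactly 2 components, got {len(vals)}")
    return vals  # type: ignore[return-value]


def _check_gaussian(sigma: Pair, rho: float, where: str) -> None:
    if sigma[0] <= 0 or sigma[1] <= 0:
        raise SpecValidationError(f"{where}: sigma must be positive, got {sigma}")
    if not -1.0 < rho < 1.0:
        raise SpecValidationError(f"{where}: correlation must lie in (-1, 1), got {rho}")
    # With positive SDs and |rho| < 1 the 2x2 covariance is positive
    # definite; a Cholesky attempt guards against numerical edge cases.
    cov = _covariance(sigma, rho)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SpecValidationError(
            f"{where}: covariance for sigma={sigma}, rho={rho} is not positive definite"
        ) from exc


def _covariance(sigma: Pair, rho: float) -> np.ndarray:
    s1, s2 = sigma
    return np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])


@dataclass(frozen=True)
class PopulationSpecA1:
    """Total-population generative spec (approach 1).

    Predictors are bivariate Gaussian in the whole population with means
    ``mu``, standard deviations ``sigma`` and Pearson correlation ``rho``.
    Disease is assigned from a logistic model whose per-unit adjusted odds
    ratios ``adjusted_or`` are fixed a priori; the intercept is calibrated
    so that the mean predicted risk equals ``prevalence``.
    """

    id: str
    n: int
    prevalence: float
    mu: Pair
    sigma: Pair
    rho: float
    adjusted_or: Pair

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", _as_pair(self.mu, "mu"))
        object.__setattr__(self, "sigma", _as_pair(self.sigma, "sigma"))
        object.__setattr__(self, "adjusted_or", _as_pair(self.adjusted_or, "adjusted_or"))
        if self.n < 2:
            raise SpecValidationError(f"n must be >= 2, got {self.n}")
        if not 0.0 < self.prevalence < 1.0:
            raise SpecValidationError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.adjusted_or[0] <= 0 or self.adjusted_or[1] <= 0:
            raise SpecValidationError(f"adjusted ORs must be positive, got {self.adjusted_or}")
        _check_gaussian(self.sigma, self.rho, f"population {self.id}")

    @property
    def approach(self) -> int:
        return 1

    @property
    def betas(self) -> Pair:
        """Log odds ratios, the fixed logistic slopes."""
        return (math.log(self.adjusted_or[0]), math.log(self.adjusted_or[1]))

    def covariance(self) -> np.ndarray:
        return _covariance(self.sigma, self.rho)

    def sd_linear_predictor(self) -> float:
        """Closed-form SD of b1*x1 + b2*x2 under the spec's Gaussian law."""
        b1, b2 = self.betas
        s1, s2 = self.sigma
        return math.sqrt(b1**2 * s1**2 + b2**2 * s2**2 + 2 * self.rho * b1 * b2 * s1 * s2)

    def with_rho(self, rho: float) -> "PopulationSpecA1":
        return replace(self, rho=float(rho))

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "approach": 1,
            "n": self.n,
            "prevalence": self.prevalence,
            "mu": list(self.mu),
            "sigma": list(self.sigma),
            "rho": self.rho,
            "adjusted_or": list(self.adjusted_or),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "PopulationSpecA1":
        if obj.get("approach", 1) != 1:
            raise SpecValidationError(f"expected approach 1 spec, got {obj.get('approach')}")
        return cls(
            id=str(obj["id"]),
            n=int(obj["n"]),
            prevalence=float(obj["prevalence"]),
            mu=obj["mu"],
            sigma=obj["sigma"],
            rho=float(obj["rho"]),
            adjusted_or=obj["adjusted_or"],
        )


@dataclass(frozen=True)
class GaussianGroup:
    """Bivariate Gaussian parameters for one outcome group."""

    mu: Pair
    sigma: Pair
    rho: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", _as_pair(self.mu, "mu"))
        object.__setattr__(self, "sigma", _as_pair(self.sigma, "sigma"))
        _check_gaussian(self.sigma, self.rho, "group")

    def covariance(self) -> np.ndarray:
        return _covariance(self.sigma, self.rho)

    def to_dict(self) -> dict:
        return {"mu": list(self.mu), "sigma": list(self.sigma), "rho": self.rho}

    @classmethod
    def from_dict(cls, obj: dict) -> "GaussianGroup":
        return cls(mu=obj["mu"], sigma=obj["sigma"], rho=float(obj["rho"]))


@dataclass(frozen=True)
class PopulationSpecA2:
    """Outcome-conditional generative spec (approach 2).

    Cases and controls are sampled from separate bivariate Gaussians;
    exactly ``round(n * prevalence)`` individuals are cases.  Adjusted
    predictor effects are not inputs here — they emerge from the logistic
    fit on the combined cohort.
    """

    id: str
    n: int
    prevalence: float
    case: GaussianGroup
    control: GaussianGroup

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise SpecValidationError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise SpecValidationError(
                f"population {self.id}: n={self.n}, prevalence={self.prevalence} "
                "implies an empty outcome group"
            )

    @property
    def approach(self) -> int:
        return 2

    @property
    def n_cases(self) -> int:
        return int(round(self.n * self.prevalence))

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    def with_correlations(self, rho_case: float, rho_control: float) -> "PopulationSpecA2":
        return replace(
            self,
            case=replace(self.case, rho=float(rho_case)),
            control=replace(self.control, rho=float(rho_control)),
        )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "approach": 2,
            "n": self.n,
            "prevalence": self.prevalence,
            "case": self.case.to_dict(),
            "control": self.control.to_dict(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "PopulationSpecA2":
        if obj.get("approach", 2) != 2:
            raise SpecValidationError(f"expected approach 2 spec, got {obj.get('approach')}")
        return cls(
            id=str(obj["id"]),
            n=int(obj["n"]),
            prevalence=float(obj["prevalence"]),
            case=GaussianGroup.from_dict(obj["case"]),
            control=GaussianGroup.from_dict(obj["control"]),
        )


PopulationSpec = PopulationSpecA1 | PopulationSpecA2


def spec_from_dict(obj: dict) -> PopulationSpec:
    """Dispatch a JSON object to the right spec class via its "approach" key."""
    approach = int(obj.get("approach", 1))
    if approach == 1:
        return PopulationSpecA1.from_dict(obj)
    if approach == 2:
        return PopulationSpecA2.from_dict(obj)
    raise SpecValidationError(f"unknown approach {approach}")


def load_specs(path) -> list[PopulationSpec]:
    """Load a JSON list of population specs from a file path."""
    with open(path) as fh:
        objs = json.load(fh)
    return [spec_from_dict(o) for o in objs]


def _load_bundled(name: str) -> list[dict]:
    text = resources.files("casemixsim.data").joinpath(name).read_text()
    return json.loads(text)


def load_table1_specs() -> list[PopulationSpecA1]:
    """The 16 standard approach-1 populations "A"–"P"."""
    return [PopulationSpecA1.from_dict(o) for o in _load_bundled("table1_populations.json")]


def load_table2_specs() -> list[PopulationSpecA2]:
    """The 9 standard approach-2 populations "A"–"I"."""
    return [PopulationSpecA2.from_dict(o) for o in _load_bundled("table2_populations.json")]
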