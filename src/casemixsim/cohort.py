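"""Simulated cohorts: two predictor columns and a binary outcome."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Cohort"]


@dataclass
class Cohort:
    """One simulated population: predictor matrix ``x`` (n rows, 2 columns),
    outcome vector ``y`` in {0, 1}, and the seed it was generated from."""

    population_id: str
    x: np.ndarray
    y: np.ndarray
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.x.ndim != 2 or self.x.shape[1] != 2:
            raise ValueError(f"x must be n-by-2, got shape {self.x.shape}")
        if self.y.shape != (self.x.shape[0],):
            raise ValueError(
                f"y length {self.y.shape} does not match x rows {self.x.shape[0]}"
            )
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must contain only 0/1 outcomes")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @property
    def prevalence(self) -> float:
        """Realized (not target) case fraction."""
        return self.n_cases / self.n

    def has_both_classes(self) -> bool:
        return 0 < self.n_cases < self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x1": self.x[:, 0], "x2": self.x[:, 1], "y": self.y})

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write `x1,x2,y` rows; metadata goes to a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "population_id": self.population_id,
                "seed": self.seed,
                "realized_prevalence": self.prevalence,
                **self.metadata,
            }
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            population_id=str(meta.get("population_id", path.stem)),
            x=df[["x1", "x2"]].to_numpy(),
            y=df["y"].to_numpy(),
            seed=int(meta.get("seed", -1)),
            metadata={
                k: v
                for k, v in meta.items()
                if k not in ("population_id", "seed")
            },
        )
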