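"""Prevalence/recovery time series shared by the dynamics engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Per-step prevalences and recovery probabilities of both layers.

    All four series have length ``n_steps + 1`` (the initial condition is
    recorded at index 0).  ``converged`` is False when the iteration stopped
    at ``max_steps`` without meeting the tolerance.
    """

    rho1_series: np.ndarray
    rho2_series: np.ndarray
    mu1_series: np.ndarray
    mu2_series: np.ndarray
    converged: bool
    n_steps: int
    clamp_events: int = field(default=0)

    def __post_init__(self) -> None:
        for name in ("rho1_series", "rho2_series", "mu1_series", "mu2_series"):
            series = np.asarray(getattr(self, name), dtype=float)
            if series.shape != (self.n_steps + 1,):
                raise ValueError(
                    f"{name} must have length n_steps + 1 = {self.n_steps + 1}"
                )
            setattr(self, name, series)

    @property
    def final(self) -> tuple[float, float]:
        return float(self.rho1_series[-1]), float(self.rho2_series[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(self.n_steps + 1),
                "rho1": self.rho1_series,
                "rho2": self.rho2_series,
                "mu1": self.mu1_series,
                "mu2": self.mu2_series,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
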