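"""Agent-based Monte-Carlo simulation of the two-layer process.

Serves as an independent check on the deterministic probability dynamics:
every node holds a binary infection state per layer, updates are
synchronous, and exposures combine as independent Bernoulli trials.  A
susceptible node of layer A with ``m`` infected layer-A neighbours and an
infected layer-B counterpart escapes infection with probability
``(1 - beta1)**m * (1 - gamma1)``; recovery uses the layer's realised
prevalence at the current step through the shared resource law.  (The
deterministic engines use an additive counterpart term; at small coupling
the two agree to first order in gamma.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .networks import MultiplexNetwork
from .params import EpidemicParams, recovery_probability

__all__ = ["AgentState", "EnsembleSummary", "simulate"]


@dataclass
class AgentState:
    """Binary infection indicators for both layers at one step."""

    s1: np.ndarray
    s2: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1)
        self.s2 = np.asarray(self.s2)
        if self.s1.shape != self.s2.shape or self.s1.ndim != 1:
            raise ValueError("s1 and s2 must be 1-d arrays of equal length")
        for name, vec in (("s1", self.s1), ("s2", self.s2)):
            if not np.isin(vec, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0 or 1")


@dataclass
class EnsembleSummary:
    """Across-realisation statistics of the final prevalences."""

    rho1_mean: float
    rho2_mean: float
    rho1_sd: float
    rho2_sd: float
    n_realizations: int
    survival_fraction: float
    rho1_finals: np.ndarray = field(repr=False)
    rho2_finals: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "rho1_mean": self.rho1_mean,
            "rho2_mean": self.rho2_mean,
            "rho1_sd": self.rho1_sd,
            "rho2_sd": self.rho2_sd,
            "n_realizations": self.n_realizations,
            "survival_fraction": self.survival_fraction,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")


def _run_realization(
    network: MultiplexNetwork,
    params: EpidemicParams,
    initial_fraction: float,
    t_max: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    n = network.n_nodes
    n0 = max(1, round(n * initial_fraction))
    s1 = np.zeros(n, dtype=np.int64)
    s2 = np.zeros(n, dtype=np.int64)
    s1[rng.choice(n, size=n0, replace=False)] = 1
    s2[rng.choice(n, size=n0, replace=False)] = 1
    adj_a = network.layer_a.adjacency
    adj_b = network.layer_b.adjacency
    for _ in range(t_max):
        rho1 = s1.mean()
        rho2 = s2.mean()
        if rho1 == 0.0 and rho2 == 0.0:
            break
        m1 = adj_a @ s1
        m2 = adj_b @ s2
        p_inf1 = 1.0 - (1.0 - params.beta1) ** m1 * (1.0 - params.gamma1 * s2)
        p_inf2 = 1.0 - (1.0 - params.beta2) ** m2 * (1.0 - params.gamma2 * s1)
        mu1 = recovery_probability(rho1, params.resource, params.c)
        mu2 = recovery_probability(rho2, params.resource, params.c)
        u1 = rng.random(n)
        u2 = rng.random(n)
        v1 = rng.random(n)
        v2 = rng.random(n)
        new1 = np.where(s1 == 1, (v1 >= mu1).astype(np.int64), (u1 < p_inf1).astype(np.int64))
        new2 = np.where(s2 == 1, (v2 >= mu2).astype(np.int64), (u2 < p_inf2).astype(np.int64))
        s1, s2 = new1, new2
    return float(s1.mean()), float(s2.mean())


def simulate(
    network: MultiplexNetwork,
    params: EpidemicParams,
    initial_fraction: float = 0.1,
    t_max: int = 300,
    seed: int = 0,
    n_realizations: int = 10,
) -> EnsembleSummary:
    """Ensemble of stochastic realisations, reporting final prevalences.

    One master seed drives the whole ensemble; per-realisation generators
    are spawned deterministically, so results are reproducible.  A
    realisation that hits the absorbing all-susceptible state stays there
    (the loop stops early).  Requires at least one initially infected node.
    """
    if network.n_nodes * initial_fraction < 1:
        raise ValueError("initial_fraction must seed at least one infected node")
    if t_max < 1:
        raise ValueError("t_max must be at least 1")
    if n_realizations < 1:
        raise ValueError("n_realizations must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n_realizations)
    finals1 = np.empty(n_realizations)
    finals2 = np.empty(n_realizations)
    for i, child in enumerate(children):
        finals1[i], finals2[i] = _run_realization(
            network, params, initial_fraction, t_max, np.random.default_rng(child)
        )
    survived = (finals1 > 0) | (finals2 > 0)
    return EnsembleSummary(
        rho1_mean=float(finals1.mean()),
        rho2_mean=float(finals2.mean()),
        rho1_sd=float(finals1.std(ddof=1)) if n_realizations > 1 else 0.0,
        rho2_sd=float(finals2.std(ddof=1)) if n_realizations > 1 else 0.0,
        n_realizations=n_realizations,
        survival_fraction=float(survived.mean()),
        rho1_finals=finals1,
        rho2_finals=finals2,
    )
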