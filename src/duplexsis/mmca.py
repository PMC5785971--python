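"""Node-level discrete-time probability dynamics on arbitrary two-layer graphs.

This is the microscopic Markov-chain approximation (MMCA) of the stochastic
process: each node carries a probability of being infected in each layer,
and all nodes update synchronously.  Writing ``p1[i]`` for the probability
that node ``i`` is infected in layer A at time ``t``, the update is

    p1[i](t+1) = (1 - p1[i]) * (1 - q1[i])        # intra-layer infection
               + (1 - mu1) * p1[i]                # failure to recover
               + gamma1 * p2[i] * (1 - p1[i])     # counterpart infection

with ``q1[i] = prod_j (1 - beta1 * a_ij * p1[j])`` the probability of
escaping infection from every layer-A neighbour, and ``mu1`` the recovery
probability computed from the layer's current prevalence through the
resource law.  Layer B is symmetric.  The three terms are not a partition
of probability, so for large coupling the raw sum can exceed one; entries
are clamped to [0, 1] after each update and clamp events are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .networks import MultiplexNetwork
from .params import EpidemicParams, recovery_probability
from .trajectory import Trajectory

__all__ = ["NodeProbabilityState", "InfectionPressure", "infection_pressure", "step", "run"]

logger = logging.getLogger(__name__)


@dataclass
class NodeProbabilityState:
    """Per-node infection probabilities for both layers at one time step."""

    p1: np.ndarray
    p2: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        if self.p1.shape != self.p2.shape or self.p1.ndim != 1:
            raise ValueError("p1 and p2 must be 1-d arrays of equal length")
        for name, vec in (("p1", self.p1), ("p2", self.p2)):
            if np.any(vec < 0) or np.any(vec > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")

    @classmethod
    def uniform(cls, n_nodes: int, rho1: float, rho2: float) -> "NodeProbabilityState":
        return cls(p1=np.full(n_nodes, float(rho1)), p2=np.full(n_nodes, float(rho2)))

    @property
    def prevalence(self) -> tuple[float, float]:
        """Population prevalences (rho1, rho2): the means of p1 and p2."""
        return float(self.p1.mean()), float(self.p2.mean())


@dataclass
class InfectionPressure:
    """Per-node probabilities of escaping intra-layer infection (q1, q2)."""

    q1: np.ndarray
    q2: np.ndarray


def _escape_probability(adjacency, beta: float, p: np.ndarray) -> np.ndarray:
    """q[i] = prod over neighbours j of (1 - beta * p[j]).

    Computed through logarithms so that a row product reduces to a sparse
    matrix-vector product; a factor of exactly zero (beta * p[j] == 1)
    propagates as -inf and exponentiates back to zero.
    """
    if beta == 0.0:
        return np.ones(p.shape[0])
    with np.errstate(divide="ignore"):
        log_terms = np.log1p(-beta * p)
    return np.exp(adjacency @ log_terms)


def infection_pressure(
    state: NodeProbabilityState, network: MultiplexNetwork, params: EpidemicParams
) -> InfectionPressure:
    """Escape probabilities of both layers for the current state."""
    if state.p1.shape[0] != network.n_nodes:
        raise ValueError(
            f"state has {state.p1.shape[0]} nodes but network has {network.n_nodes}"
        )
    q1 = _escape_probability(network.layer_a.adjacency, params.beta1, state.p1)
    q2 = _escape_probability(network.layer_b.adjacency, params.beta2, state.p2)
    return InfectionPressure(q1=q1, q2=q2)


def step(
    state: NodeProbabilityState, network: MultiplexNetwork, params: EpidemicParams
) -> NodeProbabilityState:
    """One synchronous update of every node in both layers.

    Recovery probabilities are evaluated from the population prevalences at
    the current step (the resource is shared globally), infection pressures
    from the current per-node probabilities.  The result is clamped to
    [0, 1]; clamp events are counted on the returned state as
    ``_clamp_events`` and logged at debug level.
    """
    pressure = infection_pressure(state, network, params)
    rho1, rho2 = state.prevalence
    mu1 = recovery_probability(rho1, params.resource, params.c)
    mu2 = recovery_probability(rho2, params.resource, params.c)
    raw1 = (1 - state.p1) * (1 - pressure.q1) + (1 - mu1) * state.p1 \
        + params.gamma1 * state.p2 * (1 - state.p1)
    raw2 = (1 - state.p2) * (1 - pressure.q2) + (1 - mu2) * state.p2 \
        + params.gamma2 * state.p1 * (1 - state.p2)
    clamped = int(np.count_nonzero((raw1 < 0) | (raw1 > 1))
                  + np.count_nonzero((raw2 < 0) | (raw2 > 1)))
    if clamped:
        logger.debug("clamped %d node probabilities at t=%d", clamped, state.t)
    new = NodeProbabilityState(
        p1=np.clip(raw1, 0.0, 1.0), p2=np.clip(raw2, 0.0, 1.0), t=state.t + 1
    )
    new._clamp_events = clamped  # type: ignore[attr-defined]
    return new


def run(
    network: MultiplexNetwork,
    params: EpidemicParams,
    p0_1,
    p0_2,
    tol: float = 1e-9,
    max_steps: int = 10**6,
) -> tuple[Trajectory, NodeProbabilityState]:
    """Iterate the node-level map until no probability moves more than tol.

    ``p0_1`` and ``p0_2`` may be scalars (broadcast uniformly) or per-node
    vectors.  Non-convergence within ``max_steps`` is reported through the
    trajectory's ``converged`` flag, not as an error.  Returns the recorded
    trajectory and the final node-level state.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    if max_steps < 1:
        raise ValueError("max_steps must be at least 1")
    n = network.n_nodes
    p1 = np.broadcast_to(np.asarray(p0_1, dtype=float), (n,)).copy()
    p2 = np.broadcast_to(np.asarray(p0_2, dtype=float), (n,)).copy()
    state = NodeProbabilityState(p1=p1, p2=p2, t=0)

    rho1, rho2 = state.prevalence
    rho1_s, rho2_s = [rho1], [rho2]
    mu1_s = [recovery_probability(rho1, params.resource, params.c)]
    mu2_s = [recovery_probability(rho2, params.resource, params.c)]
    clamp_total = 0
    converged = False
    for _ in range(max_steps):
        new = step(state, network, params)
        clamp_total += getattr(new, "_clamp_events", 0)
        delta = max(
            np.max(np.abs(new.p1 - state.p1)), np.max(np.abs(new.p2 - state.p2))
        )
        state = new
        rho1, rho2 = state.prevalence
        rho1_s.append(rho1)
        rho2_s.append(rho2)
        mu1_s.append(recovery_probability(rho1, params.resource, params.c))
        mu2_s.append(recovery_probability(rho2, params.resource, params.c))
        if delta < tol:
            converged = True
            break
    trajectory = Trajectory(
        rho1_series=np.array(rho1_s),
        rho2_series=np.array(rho2_s),
        mu1_series=np.array(mu1_s),
        mu2_series=np.array(mu2_s),
        converged=converged,
        n_steps=state.t,
        clamp_events=clamp_total,
    )
    return trajectory, state
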