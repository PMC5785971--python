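"""Model parameters and the resource-dependent recovery law.

The model couples two SIS processes running on two network layers (A and B)
that share one node set.  Within a layer, infection passes along links with
probability ``beta``; across layers, an infected counterpart transmits with
probability ``gamma``.  Recovery is not a constant: each infected node
receives an average resource amount ``R`` (a fraction of total capacity,
between 0 and 1), and the per-step recovery probability of a layer with
prevalence ``rho`` is ``exp(-c * rho / R)`` — the more widespread the
disease, the thinner the resource is spread and the slower recovery becomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["EpidemicParams", "recovery_probability"]


@dataclass(frozen=True)
class EpidemicParams:
    """Transmission, coupling and resource parameters.

    Parameters
    ----------
    beta1, beta2
        Intra-layer transmission probabilities in layers A and B.
    gamma1
        Inter-layer transmission probability from a node's counterpart in
        layer B to the node in layer A.
    gamma2
        Same, from layer A to layer B.
    resource
        Average resource amount R available per infected node, expressed as
        a fraction in [0, 1].
    c
        Control coefficient weighing prevalence against resource in the
        recovery law; must be positive.  Default 1.
    """

    beta1: float
    beta2: float
    gamma1: float
    gamma2: float
    resource: float
    c: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "gamma1", "gamma2", "resource"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if not self.c > 0.0:
            raise ValueError(f"c must be positive, got {self.c!r}")

    def swap_layers(self) -> "EpidemicParams":
        """Parameters with the roles of layers A and B exchanged."""
        return replace(
            self,
            beta1=self.beta2,
            beta2=self.beta1,
            gamma1=self.gamma2,
            gamma2=self.gamma1,
        )


def recovery_probability(prevalence, resource, c: float = 1.0):
    """Per-step recovery probability ``exp(-c * prevalence / resource)``.

    Resource is shared among the infected, so recovery slows as prevalence
    rises and speeds up as resource grows.  Two limits need a convention:

    * ``resource == 0`` with ``prevalence > 0`` gives 0 (no recovery: the
      dynamics degenerate to an SI process);
    * ``prevalence == 0`` gives 1 for any resource, the limit of the
      expression as prevalence vanishes at fixed positive resource.  It is
      dynamically irrelevant because nobody is infected.

    Accepts scalars or arrays for ``prevalence`` and ``resource``; returns
    a scalar for scalar input.
    """
    rho = np.asarray(prevalence, dtype=float)
    res = np.asarray(resource, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("prevalence must lie in [0, 1]")
    if np.any(res < 0) or np.any(res > 1):
        raise ValueError("resource must lie in [0, 1]")
    if not c > 0:
        raise ValueError("c must be positive")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.divide(
            c * rho, res, out=np.full(np.broadcast(rho, res).shape, np.inf), where=res > 0
        )
    # exp(-inf) = 0 covers resource == 0 with prevalence > 0; the
    # prevalence == 0 branch (ratio 0/0 -> set to 0) yields exp(0) = 1.
    ratio = np.where(rho == 0, 0.0, ratio)
    out = np.exp(-ratio)
    if out.ndim == 0:
        return float(out)
    return out
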