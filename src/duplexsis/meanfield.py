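"""Homogeneous mean-field reduction on random-regular layers.

On a random-regular layer every node is statistically equivalent, so the
per-node probabilities collapse to a single prevalence per layer and the
escape probability becomes ``q = (1 - beta * rho)**k``.  The two-layer map
reads

    rho1' = (1 - rho1) * (1 - (1 - beta1*rho1)**k1)
          + (1 - mu1) * rho1 + gamma1 * rho2 * (1 - rho1)

with ``mu1 = exp(-c * rho1 / R)`` and the symmetric update for layer B.
A fixed point (rho1*, rho2*) satisfies the steady-state balance

    (1 - rho1)[1 - (1 - beta1*rho1)**k1 + gamma1*rho2] - rho1 * mu1 = 0

and its layer-B twin.  Solving the layer-A balance for rho2 yields the
inter-layer consistency map ``rho2 = A(rho1)``; substituting it into the
layer-B balance gives one scalar equation in rho1 whose roots are the
steady states.  Both the dynamical route (iterating from a fixed initial
prevalence, which selects one attractor) and the algebraic route (scanning
for every root, which exposes coexisting branches in bistable regimes) are
provided, because first-order transitions make them disagree.

The fixed-point iterator optionally applies safeguarded geometric
extrapolation: once the per-step displacement shrinks with a stable ratio
(the asymptotic linear regime of the map), the limit is extrapolated and
accepted only if it reduces the residual.  This leaves the attained branch
untouched while removing the critical slowing down near continuous
transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import bisect as _bisect

from .params import EpidemicParams, recovery_probability
from .trajectory import Trajectory

__all__ = [
    "MeanFieldConfig",
    "MeanFieldState",
    "SteadyStateRoot",
    "step_mf",
    "run_mf",
    "batch_steady_state",
    "steady_state_residuals",
    "rho2_of_rho1",
    "scalar_steady_residual",
    "scalar_equation_roots",
    "find_roots",
    "small_resource_residual",
    "small_resource_roots",
    "roots_to_dataframe",
]

_FIELDS = ("beta1", "beta2", "gamma1", "gamma2", "resource", "c", "k1", "k2")


@dataclass(frozen=True)
class MeanFieldConfig:
    """Epidemic parameters plus the uniform degrees of the two layers."""

    params: EpidemicParams
    k1: int
    k2: int

    def __post_init__(self) -> None:
        for name in ("k1", "k2"):
            k = getattr(self, name)
            if int(k) != k or k < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {k!r}")


@dataclass(frozen=True)
class MeanFieldState:
    """Prevalences (rho1, rho2) of the two layers."""

    rho1: float
    rho2: float

    def __post_init__(self) -> None:
        for name in ("rho1", "rho2"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SteadyStateRoot:
    """A steady state with its residual diagnostics.

    ``branch_label`` is "trivial" for the disease-free state and "endemic"
    otherwise (including the saturated all-infected branch).
    """

    rho1_star: float
    rho2_star: float
    residual1: float
    residual2: float
    branch_label: str


def _resolve(config: MeanFieldConfig, overrides: dict | None = None) -> dict:
    values = {
        "beta1": config.params.beta1,
        "beta2": config.params.beta2,
        "gamma1": config.params.gamma1,
        "gamma2": config.params.gamma2,
        "resource": config.params.resource,
        "c": config.params.c,
        "k1": config.k1,
        "k2": config.k2,
    }
    for name, value in (overrides or {}).items():
        if name not in _FIELDS:
            raise ValueError(f"unknown parameter {name!r}; expected one of {_FIELDS}")
        values[name] = value
    return values


def _mu_arrays(rho, resource, c):
    """Recovery probability exp(-c*rho/R), elementwise with the two limit
    conventions (rho == 0 -> 1; R == 0 with rho > 0 -> 0)."""
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.divide(
            c * rho,
            resource,
            out=np.full(np.broadcast(rho, resource).shape, np.inf),
            where=np.asarray(resource) > 0,
        )
    return np.exp(-np.where(np.asarray(rho) == 0, 0.0, ratio))


def _map(r1, r2, v: dict):
    """The two-layer mean-field map, elementwise over broadcast arrays."""
    mu1 = _mu_arrays(r1, v["resource"], v["c"])
    mu2 = _mu_arrays(r2, v["resource"], v["c"])
    n1 = (1 - r1) * (1 - (1 - v["beta1"] * r1) ** v["k1"]) + (1 - mu1) * r1 \
        + v["gamma1"] * r2 * (1 - r1)
    n2 = (1 - r2) * (1 - (1 - v["beta2"] * r2) ** v["k2"]) + (1 - mu2) * r2 \
        + v["gamma2"] * r1 * (1 - r2)
    return np.clip(n1, 0.0, 1.0), np.clip(n2, 0.0, 1.0)


def step_mf(state: MeanFieldState, config: MeanFieldConfig) -> MeanFieldState:
    """One synchronous mean-field update (clamped to [0, 1])."""
    v = _resolve(config)
    n1, n2 = _map(np.float64(state.rho1), np.float64(state.rho2), v)
    return MeanFieldState(rho1=float(n1), rho2=float(n2))


def run_mf(
    config: MeanFieldConfig,
    rho0_1: float = 0.1,
    rho0_2: float = 0.1,
    tol: float = 1e-9,
    max_steps: int = 10**6,
) -> tuple[Trajectory, SteadyStateRoot]:
    """Iterate the mean-field map from a fixed initial prevalence.

    Follows the plain synchronous orbit (no acceleration), so on uniform
    regular systems the recorded series coincide with the node-level engine.
    Returns the trajectory and the reached steady state with its residuals.
    """
    if not 0.0 <= rho0_1 <= 1.0 or not 0.0 <= rho0_2 <= 1.0:
        raise ValueError("initial prevalences must lie in [0, 1]")
    if not tol > 0:
        raise ValueError("tol must be positive")
    v = _resolve(config)
    c = v["c"]
    r1, r2 = float(rho0_1), float(rho0_2)
    rho1_s, rho2_s = [r1], [r2]
    mu1_s = [recovery_probability(r1, v["resource"], c)]
    mu2_s = [recovery_probability(r2, v["resource"], c)]
    converged = False
    steps = 0
    for _ in range(max_steps):
        n1, n2 = _map(np.float64(r1), np.float64(r2), v)
        n1, n2 = float(n1), float(n2)
        delta = max(abs(n1 - r1), abs(n2 - r2))
        r1, r2 = n1, n2
        steps += 1
        rho1_s.append(r1)
        rho2_s.append(r2)
        mu1_s.append(recovery_probability(r1, v["resource"], c))
        mu2_s.append(recovery_probability(r2, v["resource"], c))
        if delta < tol:
            converged = True
            break
    trajectory = Trajectory(
        rho1_series=np.array(rho1_s),
        rho2_series=np.array(rho2_s),
        mu1_series=np.array(mu1_s),
        mu2_series=np.array(mu2_s),
        converged=converged,
        n_steps=steps,
    )
    res1, res2 = steady_state_residuals(r1, r2, config)
    label = "trivial" if max(r1, r2) < 1e-8 else "endemic"
    root = SteadyStateRoot(
        rho1_star=r1,
        rho2_star=r2,
        residual1=float(res1),
        residual2=float(res2),
        branch_label=label,
    )
    return trajectory, root


def batch_steady_state(
    config: MeanFieldConfig,
    rho0_1=0.1,
    rho0_2=0.1,
    *,
    overrides: dict | None = None,
    tol: float = 1e-9,
    max_steps: int = 10**6,
    accelerate: bool = True,
):
    """Steady states of the mean-field map for many parameter values at once.

    ``overrides`` maps parameter names (``beta1``, ``beta2``, ``gamma1``,
    ``gamma2``, ``resource``, ``c``, ``k1``, ``k2``) to scalars or arrays;
    arrays broadcast against each other and against the initial prevalences.
    Returns ``(rho1, rho2, converged, n_steps)`` where the first three are
    arrays of the broadcast shape.

    With ``accelerate=True`` a safeguarded geometric extrapolation shortcuts
    the tail of the iteration once the convergence ratio stabilises.  Three
    safeguards keep the reached branch the one selected by the plain orbit:
    the extrapolation is attempted only after the step-size ratio has been
    stable for several consecutive steps, it is accepted only if it reduces
    the fixed-point residual, and after acceptance the iteration is
    monitored — if the step size later grows above its acceptance level or
    the state drifts visibly away from the accepted point (both signatures
    of having been dropped into the wrong basin near a saddle), the
    pre-extrapolation state is restored and the element falls back to the
    plain orbit.
    """
    v = _resolve(config, overrides)
    shape = np.broadcast(
        *[np.asarray(v[f], dtype=float) for f in _FIELDS],
        np.asarray(rho0_1, dtype=float),
        np.asarray(rho0_2, dtype=float),
    ).shape
    v = {f: np.broadcast_to(np.asarray(v[f], dtype=float), shape) for f in _FIELDS}
    r1 = np.broadcast_to(np.asarray(rho0_1, dtype=float), shape).copy()
    r2 = np.broadcast_to(np.asarray(rho0_2, dtype=float), shape).copy()
    if shape == ():
        r1, r2 = r1.reshape(1), r2.reshape(1)
        v = {f: v[f].reshape(1) for f in _FIELDS}
    active = np.ones(r1.shape, dtype=bool)
    d_prev = np.full(r1.shape, np.nan)
    ratio_prev = np.full(r1.shape, np.nan)
    stable_count = np.zeros(r1.shape, dtype=int)
    cooldown = np.zeros(r1.shape, dtype=int)
    saved1 = np.empty_like(r1)
    saved2 = np.empty_like(r2)
    acc1 = np.empty_like(r1)
    acc2 = np.empty_like(r2)
    d_accept = np.full(r1.shape, np.nan)
    drift_max = 1e-3
    steps = 0
    while active.any() and steps < max_steps:
        n1, n2 = _map(r1, r2, v)
        d = np.maximum(np.abs(n1 - r1), np.abs(n2 - r2))
        if accelerate:
            # rollback: a monitored element whose step size grew past its
            # acceptance level, or which drifted away from the accepted
            # point, was extrapolated into the wrong basin
            monitored = active & np.isfinite(d_accept)
            drift = np.maximum(np.abs(n1 - acc1), np.abs(n2 - acc2))
            bad = monitored & ((d > d_accept) | (drift > drift_max))
            if bad.any():
                # restore the plain-orbit state saved at the episode start
                # and run plainly for a while before allowing a new episode
                n1 = np.where(bad, saved1, n1)
                n2 = np.where(bad, saved2, n2)
                d = np.where(bad, np.inf, d)
                cooldown = np.where(bad, 2000, cooldown)
                d_accept = np.where(bad, np.nan, d_accept)
            cooldown = np.maximum(cooldown - 1, 0)
            accel_ok = cooldown == 0
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.minimum(d / d_prev, 1.0 - 1e-12)
                stable = (
                    active
                    & accel_ok
                    & (np.abs(ratio - ratio_prev) < 1e-3)
                    & (ratio > 0)
                    & (d > 0)
                )
            stable_count = np.where(stable, stable_count + 1, 0)
            # extrapolate only deep in the asymptotic phase (small steps,
            # persistently stable ratio) so transients near a saddle are
            # never mistaken for convergence to an attractor
            attempt = stable & (stable_count >= 3) & (steps >= 10) & (d < 1e-5)
            if attempt.any():
                factor = np.where(attempt, ratio / (1.0 - ratio), 0.0)
                e1 = np.clip(n1 + (n1 - r1) * factor, 0.0, 1.0)
                e2 = np.clip(n2 + (n2 - r2) * factor, 0.0, 1.0)
                f1, f2 = _map(e1, e2, v)
                residual = np.maximum(np.abs(f1 - e1), np.abs(f2 - e2))
                take = attempt & (residual < d)
                # a chain of extrapolations forms one monitored episode:
                # the rollback state and the drift reference stay at the
                # first acceptance, so a slow slide into another basin
                # accumulates drift instead of resetting it
                fresh = take & ~np.isfinite(d_accept)
                saved1 = np.where(fresh, n1, saved1)
                saved2 = np.where(fresh, n2, saved2)
                acc1 = np.where(fresh, e1, acc1)
                acc2 = np.where(fresh, e2, acc2)
                d_accept = np.where(take, np.maximum(2 * residual, 100 * tol), d_accept)
                n1 = np.where(take, e1, n1)
                n2 = np.where(take, e2, n2)
                stable_count = np.where(take, 0, stable_count)
                ratio_prev = np.where(take, np.nan, ratio)
                d_prev = np.where(take, np.nan, d)
            else:
                ratio_prev = np.where(active, ratio, ratio_prev)
                d_prev = np.where(active, d, d_prev)
        r1 = np.where(active, n1, r1)
        r2 = np.where(active, n2, r2)
        active = active & (d >= tol)
        steps += 1
    converged = ~active
    if shape == ():
        return float(r1[0]), float(r2[0]), bool(converged[0]), steps
    return r1, r2, converged, steps


def steady_state_residuals(rho1, rho2, config: MeanFieldConfig):
    """Left-hand sides of the two steady-state balance equations.

    Both vanish at a fixed point of the mean-field map.  The recovery term
    keeps the control coefficient c explicit in the exponent.  Vectorised
    over ``rho1`` and ``rho2``.
    """
    v = _resolve(config)
    rho1 = np.asarray(rho1, dtype=float)
    rho2 = np.asarray(rho2, dtype=float)
    mu1 = recovery_probability(rho1, v["resource"], v["c"])
    mu2 = recovery_probability(rho2, v["resource"], v["c"])
    res_a = (1 - rho1) * (1 - (1 - v["beta1"] * rho1) ** v["k1"] + v["gamma1"] * rho2) \
        - rho1 * mu1
    res_b = (1 - rho2) * (1 - (1 - v["beta2"] * rho2) ** v["k2"] + v["gamma2"] * rho1) \
        - rho2 * mu2
    if res_a.ndim == 0:
        return float(res_a), float(res_b)
    return res_a, res_b


def rho2_of_rho1(rho1, config: MeanFieldConfig):
    """Layer-B prevalence consistent with the layer-A balance at ``rho1``.

    This is the inter-layer consistency map A(rho1): solving the layer-A
    steady-state balance for rho2.  Undefined for ``gamma1 == 0`` (the
    layers decouple) and at ``rho1 == 1`` (division by zero).  The result
    is not clipped: values outside [0, 1] mean no admissible layer-B
    prevalence balances layer A at that rho1.
    """
    v = _resolve(config)
    if v["gamma1"] == 0:
        raise ValueError("rho2_of_rho1 is undefined for gamma1 == 0 (layers decouple)")
    rho1 = np.asarray(rho1, dtype=float)
    if np.any(rho1 < 0) or np.any(rho1 >= 1):
        raise ValueError("rho1 must lie in [0, 1)")
    mu1 = recovery_probability(rho1, v["resource"], v["c"])
    out = rho1 * mu1 / (v["gamma1"] * (1 - rho1)) \
        - (1 - (1 - v["beta1"] * rho1) ** v["k1"]) / v["gamma1"]
    if out.ndim == 0:
        return float(out)
    return out


def scalar_steady_residual(rho1, config: MeanFieldConfig):
    """Scalar steady-state equation in rho1 alone.

    Obtained by substituting ``rho2 = A(rho1)`` into the layer-B balance
    and dividing by ``A(rho1)``:

        mu(A) - [1 + gamma2*rho1 - (1 - beta2*A)**k2] * (1/A - 1) = 0

    with ``mu(A) = exp(-c*A/R)``.  Points where ``A(rho1)`` falls outside
    (0, 1) are out of the equation's domain and return NaN; root scans skip
    them.  Vectorised over ``rho1``.
    """
    v = _resolve(config)
    rho1 = np.asarray(rho1, dtype=float)
    a = np.asarray(rho2_of_rho1(rho1, config), dtype=float)
    in_domain = (a > 0) & (a < 1)
    a_safe = np.where(in_domain, a, 0.5)
    mu_a = recovery_probability(a_safe, v["resource"], v["c"])
    residual = mu_a - (1 + v["gamma2"] * rho1 - (1 - v["beta2"] * a_safe) ** v["k2"]) \
        * (1.0 / a_safe - 1.0)
    residual = np.where(in_domain, residual, np.nan)
    if residual.ndim == 0:
        return float(residual)
    return residual


def scalar_equation_roots(
    config: MeanFieldConfig,
    grid=None,
    grid_size: int = 2000,
    tol: float = 1e-10,
) -> list[float]:
    """Roots of the scalar steady-state equation on a grid over (0, 1).

    Brackets every sign change between consecutive in-domain grid points
    and refines each bracket by bisection to ``tol``.  A custom ``grid``
    (for example log-spaced, to resolve roots that scale with R) may be
    supplied; by default the grid is uniform with ``grid_size`` interior
    points.
    """
    if grid is None:
        if grid_size < 100:
            raise ValueError("grid_size must be at least 100")
        grid = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    grid = np.asarray(grid, dtype=float)
    values = scalar_steady_residual(grid, config)
    roots: list[float] = []
    fn = lambda x: scalar_steady_residual(float(x), config)  # noqa: E731
    finite = np.isfinite(values)
    for i in range(len(grid) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        lo, hi = values[i], values[i + 1]
        if lo == 0.0:
            roots.append(float(grid[i]))
        elif lo * hi < 0:
            roots.append(float(_bisect(fn, grid[i], grid[i + 1], xtol=tol)))
    if finite[-1] and values[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def find_roots(
    config: MeanFieldConfig,
    grid_size: int = 2000,
    tol: float = 1e-10,
    residual_tol: float = 1e-8,
) -> list[SteadyStateRoot]:
    """All steady states: trivial, interior endemic, and saturated branches.

    Interior roots come from the bracketed scan of the scalar equation
    (duplicates closer than ``10 * tol`` merge); with ``gamma1 == 0`` the
    scalar equation is undefined (the layers decouple) and the interior
    scan is skipped.  The disease-free state (0, 0) is always appended.  The saturated corner (1, 1) — where the
    inter-layer map A(rho1) is singular and at small R numerically
    underflows out of the scan's domain — is included whenever its balance
    residuals fall below ``residual_tol``.  Roots are sorted by rho1.
    """
    if config.params.gamma1 == 0:
        interior = []
    else:
        interior = scalar_equation_roots(config, grid_size=grid_size, tol=tol)
    merged: list[float] = []
    for root in sorted(interior):
        if not merged or root - merged[-1] > 10 * tol:
            merged.append(root)
    roots = [SteadyStateRoot(0.0, 0.0, 0.0, 0.0, "trivial")]
    for rho1 in merged:
        rho2 = float(np.clip(rho2_of_rho1(rho1, config), 0.0, 1.0))
        res1, res2 = steady_state_residuals(rho1, rho2, config)
        roots.append(SteadyStateRoot(rho1, rho2, float(res1), float(res2), "endemic"))
    res1, res2 = steady_state_residuals(1.0, 1.0, config)
    if max(abs(res1), abs(res2)) < residual_tol:
        roots.append(SteadyStateRoot(1.0, 1.0, float(res1), float(res2), "endemic"))
    return sorted(roots, key=lambda r: r.rho1_star)


def small_resource_residual(rho1, config: MeanFieldConfig):
    """Residual of the vanishing-resource reduction of the scalar equation.

        (1 + gamma2*rho1)**(1/k2) - 1 - (beta2/gamma1) * [1 - (1 - beta1*rho1)**k1]

    ``rho1 = 0`` is always a root.  Requires ``gamma1 > 0`` and ``k2 >= 1``.
    Vectorised over ``rho1``.
    """
    v = _resolve(config)
    if not v["gamma1"] > 0:
        raise ValueError("small-resource reduction requires gamma1 > 0")
    if v["k2"] < 1:
        raise ValueError("small-resource reduction requires k2 >= 1")
    rho1 = np.asarray(rho1, dtype=float)
    out = (1 + v["gamma2"] * rho1) ** (1.0 / v["k2"]) - 1.0 \
        - v["beta2"] / v["gamma1"] * (1 - (1 - v["beta1"] * rho1) ** v["k1"])
    if out.ndim == 0:
        return float(out)
    return out


def small_resource_roots(
    config: MeanFieldConfig, grid_size: int = 2000, tol: float = 1e-10
) -> list[float]:
    """Roots of the vanishing-resource equation in [0, 1), including 0."""
    if grid_size < 100:
        raise ValueError("grid_size must be at least 100")
    grid = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    values = small_resource_residual(grid, config)
    fn = lambda x: small_resource_residual(float(x), config)  # noqa: E731
    roots = [0.0]
    for i in range(len(grid) - 1):
        if values[i] == 0.0:
            roots.append(float(grid[i]))
        elif values[i] * values[i + 1] < 0:
            roots.append(float(_bisect(fn, grid[i], grid[i + 1], xtol=tol)))
    return roots


def roots_to_dataframe(roots: list[SteadyStateRoot]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rho1": [r.rho1_star for r in roots],
            "rho2": [r.rho2_star for r in roots],
            "residual1": [r.residual1 for r in roots],
            "residual2": [r.residual2 for r in roots],
            "branch_label": [r.branch_label for r in roots],
        }
    )
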