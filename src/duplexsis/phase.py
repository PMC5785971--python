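"""Parameter sweeps, transition classification and critical thresholds.

The central experiment of the model is a resource sweep: fix the network
and transmission parameters, iterate the mean-field map to its steady state
from the same initial prevalence (0.1 in both layers) at every resource
value R on a grid, and inspect the steady prevalence curve rho1*(R).  Three
shapes occur:

* first-order — rho1* drops discontinuously from a finite value to
  (numerically) zero at a critical resource R_c;
* hybrid — rho1* drops discontinuously but lands on a small non-zero
  branch that then varies continuously;
* continuous — rho1* decreases without any discontinuity.

Classification detects the largest adjacent-point gap of the curve,
re-solves a ten-fold finer grid around it (so a steep continuous segment is
not mistaken for a jump), and applies two thresholds: a gap larger than
``jump_threshold`` is a discontinuity, and a post-jump level below
``zero_threshold`` makes it a jump to extinction.  Critical parameter
values are refined by bisection on the underlying model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meanfield import MeanFieldConfig, batch_steady_state

__all__ = [
    "SweepResult",
    "TransitionClassification",
    "PhaseDiagram",
    "sweep",
    "classify",
    "find_critical_R",
    "phase_boundary",
    "refine_phase_boundary",
    "phase_diagram",
]

logger = logging.getLogger(__name__)

_ALIASES = {
    "R": "resource",
    "resource": "resource",
    "gamma1": "gamma1",
    "gamma2": "gamma2",
    "beta1": "beta1",
    "beta2": "beta2",
    "k1": "k1",
    "k2": "k2",
}


def _canon(name: str) -> str:
    try:
        return _ALIASES[name]
    except KeyError:
        raise ValueError(
            f"unknown sweep parameter {name!r}; expected one of {sorted(set(_ALIASES))}"
        ) from None


def _steady_rho1(
    base_config: MeanFieldConfig,
    overrides: dict,
    rho0: float,
    tol: float,
    max_steps: int,
) -> float:
    rho1, _, _, _ = batch_steady_state(
        base_config, rho0, rho0, overrides=overrides, tol=tol, max_steps=max_steps
    )
    return float(rho1)


@dataclass
class SweepResult:
    """Steady prevalences along one parameter grid (fixed-initial protocol)."""

    parameter_name: str
    grid: np.ndarray
    rho1_curve: np.ndarray
    rho2_curve: np.ndarray
    converged: np.ndarray
    base_config: MeanFieldConfig
    rho0: float = 0.1
    tol: float = 1e-9
    max_steps: int = 10**6
    forward_curve: np.ndarray | None = field(default=None, repr=False)
    backward_curve: np.ndarray | None = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                self.parameter_name: self.grid,
                "rho1": self.rho1_curve,
                "rho2": self.rho2_curve,
                "converged": self.converged,
            }
        )
        if self.forward_curve is not None:
            frame["rho1_forward"] = self.forward_curve
        if self.backward_curve is not None:
            frame["rho1_backward"] = self.backward_curve
        return frame

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class TransitionClassification:
    """Detected transition type of one sweep.

    ``kind`` is one of ``first_order``, ``hybrid``, ``continuous``,
    ``none``.  ``critical_value`` locates the discontinuity (or, for a
    continuous transition, the point where the curve crosses the zero
    threshold); it is NaN when no such point exists.  ``jump_size`` is the
    largest gap found, ``post_jump_level`` the curve value on the low side
    of the discontinuity (NaN for continuous/none).
    """

    kind: str
    critical_value: float
    jump_size: float
    post_jump_level: float


def sweep(
    parameter_name: str,
    grid,
    base_config: MeanFieldConfig,
    rho0: float = 0.1,
    tol: float = 1e-9,
    max_steps: int = 10**6,
    continuation: bool = False,
) -> SweepResult:
    """Steady prevalence at every grid value, each from the same rho0.

    The protocol deliberately restarts from ``rho0`` at every grid point;
    with ``continuation=True``, forward and backward warm-started branches
    are recorded as well, as a hysteresis diagnostic (in bistable regimes
    the two branches disagree over the coexistence interval).
    """
    name = _canon(parameter_name)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("grid must be a 1-d array with at least two values")
    diffs = np.diff(grid)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("grid must be strictly monotone")
    rho1, rho2, converged, _ = batch_steady_state(
        base_config, rho0, rho0, overrides={name: grid}, tol=tol, max_steps=max_steps
    )
    if not np.all(converged):
        logger.warning(
            "%d of %d sweep points did not converge within %d steps",
            int(np.sum(~converged)), len(grid), max_steps,
        )
    result = SweepResult(
        parameter_name=name,
        grid=grid,
        rho1_curve=rho1,
        rho2_curve=rho2,
        converged=converged,
        base_config=base_config,
        rho0=rho0,
        tol=tol,
        max_steps=max_steps,
    )
    if continuation:
        for direction in ("forward", "backward"):
            order = range(len(grid)) if direction == "forward" else range(len(grid) - 1, -1, -1)
            warm1 = warm2 = rho0
            curve = np.empty(len(grid))
            for i in order:
                warm1, warm2, _, _ = batch_steady_state(
                    base_config,
                    max(warm1, 1e-4),  # keep a seed of infection when warm state died out
                    max(warm2, 1e-4),
                    overrides={name: float(grid[i])},
                    tol=tol,
                    max_steps=max_steps,
                )
                curve[i] = warm1
            setattr(result, f"{direction}_curve", curve)
    return result


def classify(
    sweep_result: SweepResult,
    jump_threshold: float = 0.05,
    zero_threshold: float = 1e-3,
    refine: bool = True,
    refine_points: int = 31,
    critical_tol: float = 1e-4,
) -> TransitionClassification:
    """Transition type of a sweep curve.

    The largest adjacent-point gaps of rho1 are located on the sweep grid
    and, when ``refine`` is set, re-measured on a ten-fold finer sub-grid
    spanning the neighbouring intervals; this separates a genuine
    discontinuity from a steep continuous segment.  Several candidate gaps
    are examined in decreasing order, because a curve can carry a steep
    continuous shoulder that dwarfs a genuine (smaller) jump elsewhere —
    the first candidate whose refined gap survives the threshold is the
    discontinuity.  The decision rules are:

    * gap > ``jump_threshold`` and low side < ``zero_threshold``  -> first_order
    * gap > ``jump_threshold`` and low side >= ``zero_threshold`` -> hybrid
    * otherwise, curve spanning more than ``zero_threshold``      -> continuous
    * otherwise                                                   -> none

    For discontinuous kinds the critical value is refined by bisection of
    the steady state between the bracketing grid points, to ``critical_tol``.
    """
    if len(sweep_result.grid) < 20:
        raise ValueError("classification needs a sweep with at least 20 points")
    if not 0 < jump_threshold < 1 or not 0 < zero_threshold < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    grid = sweep_result.grid
    curve = sweep_result.rho1_curve
    name = sweep_result.parameter_name
    if name == "resource":
        rises = np.diff(curve) > 1e-6
        if rises.any():
            logger.warning(
                "rho1 increased along a resource sweep at %d points (max rise %.3g)",
                int(rises.sum()), float(np.diff(curve)[rises].max()),
            )

    gaps = np.abs(np.diff(curve))

    def refine_gap(idx: int):
        """Re-measure the gap at base interval ``idx`` on a finer sub-grid."""
        lo_idx, hi_idx = max(idx - 1, 0), min(idx + 2, len(grid) - 1)
        sub = np.linspace(grid[lo_idx], grid[hi_idx], refine_points)
        rho1, _, _, _ = batch_steady_state(
            sweep_result.base_config,
            sweep_result.rho0,
            sweep_result.rho0,
            overrides={name: sub},
            tol=sweep_result.tol,
            max_steps=sweep_result.max_steps,
        )
        sub_gaps = np.abs(np.diff(rho1))
        j = int(np.argmax(sub_gaps))
        return (
            float(sub_gaps[j]),
            float(min(rho1[j], rho1[j + 1])),
            float(max(rho1[j], rho1[j + 1])),
            (float(sub[j]), float(sub[j + 1])),
        )

    i = int(np.argmax(gaps))
    jump = float(gaps[i])
    side_lo = float(min(curve[i], curve[i + 1]))
    side_hi = float(max(curve[i], curve[i + 1]))
    bracket = (float(grid[i]), float(grid[i + 1]))
    if refine and jump > 0:
        jump = 0.0
        examined: list[int] = []
        for idx in np.argsort(gaps)[::-1][:4]:
            idx = int(idx)
            if gaps[idx] <= jump_threshold:
                break
            if any(abs(idx - seen) <= 1 for seen in examined):
                continue
            examined.append(idx)
            cand_jump, cand_lo, cand_hi, cand_bracket = refine_gap(idx)
            if cand_jump > jump:
                jump, side_lo, side_hi, bracket = (
                    cand_jump, cand_lo, cand_hi, cand_bracket,
                )
            if cand_jump > jump_threshold:
                break
        if not examined:
            # every base gap is below the jump threshold, so no refined
            # sub-interval can hide a discontinuity above it: keep the
            # base-grid measurement
            jump = float(gaps[i])

    if jump > jump_threshold:
        kind = "first_order" if side_lo < zero_threshold else "hybrid"
        level = 0.5 * (side_lo + side_hi)
        critical = _bisect_indicator(
            sweep_result, bracket, lambda r: r > level, critical_tol
        )
        return TransitionClassification(kind, critical, jump, side_lo)

    if curve.max() > zero_threshold and curve.max() - curve.min() > zero_threshold:
        critical = float("nan")
        above = curve > zero_threshold
        if above.any() and not above.all():
            k = int(np.argmax(above[:-1] != above[1:]))
            critical = _bisect_indicator(
                sweep_result,
                (float(grid[k]), float(grid[k + 1])),
                lambda r: r > zero_threshold,
                critical_tol,
            )
        return TransitionClassification("continuous", critical, jump, float("nan"))

    return TransitionClassification("none", float("nan"), jump, float("nan"))


def _bisect_indicator(sweep_result: SweepResult, bracket, predicate, tol) -> float:
    """Bisection of a boolean predicate of the steady rho1 over one parameter."""
    lo, hi = bracket
    cfg = sweep_result.base_config
    name = sweep_result.parameter_name

    def flag(value: float) -> bool:
        return predicate(
            _steady_rho1(
                cfg, {name: value}, sweep_result.rho0, sweep_result.tol,
                sweep_result.max_steps,
            )
        )

    f_lo = flag(lo)
    if f_lo == flag(hi):
        return 0.5 * (lo + hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if flag(mid) == f_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_critical_R(
    base_config: MeanFieldConfig,
    rho0: float = 0.1,
    bracket: tuple[float, float] = (0.0, 1.0),
    tol: float = 1e-4,
    zero_threshold: float = 1e-3,
    solver_tol: float = 1e-9,
    max_steps: int = 10**6,
) -> float:
    """Critical resource amount R_c where the steady prevalence vanishes.

    Bisects R on the indicator "steady rho1 from the fixed initial
    prevalence exceeds ``zero_threshold``".  The bracket must straddle the
    transition: endemic at its low end, extinct at its high end.
    """
    lo, hi = bracket
    rho_lo = _steady_rho1(base_config, {"resource": lo}, rho0, solver_tol, max_steps)
    rho_hi = _steady_rho1(base_config, {"resource": hi}, rho0, solver_tol, max_steps)
    if not (rho_lo > zero_threshold and rho_hi < zero_threshold):
        raise ValueError(
            "bracket does not straddle the transition: "
            f"steady rho1 is {rho_lo:.3g} at R={lo} and {rho_hi:.3g} at R={hi}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        rho_mid = _steady_rho1(
            base_config, {"resource": mid}, rho0, solver_tol, max_steps
        )
        if rho_mid > zero_threshold:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def phase_boundary(
    axis_name: str,
    axis_grid,
    base_config: MeanFieldConfig,
    sweep_grid=None,
    rho0: float = 0.1,
    jump_threshold: float = 0.05,
    zero_threshold: float = 1e-3,
    tol: float = 1e-9,
    max_steps: int = 10**6,
) -> list[tuple[float, TransitionClassification]]:
    """Classify the resource sweep at every value of one other parameter."""
    axis = _canon(axis_name)
    if axis == "resource":
        raise ValueError("phase_boundary varies a parameter other than the resource")
    if sweep_grid is None:
        sweep_grid = np.linspace(0.0, 1.0, 201)
    out = []
    for value in np.asarray(axis_grid, dtype=float):
        overridden = _override_config(base_config, axis, value)
        result = sweep("resource", sweep_grid, overridden, rho0=rho0, tol=tol,
                       max_steps=max_steps)
        out.append(
            (float(value), classify(result, jump_threshold, zero_threshold))
        )
    return out


def refine_phase_boundary(
    axis_name: str,
    lo: float,
    hi: float,
    base_config: MeanFieldConfig,
    tol: float = 5e-3,
    sweep_grid=None,
    rho0: float = 0.1,
    jump_threshold: float = 0.05,
    zero_threshold: float = 1e-3,
) -> float:
    """Bisect one parameter for the point where the sweep classification flips.

    ``lo`` and ``hi`` must classify differently; returns the midpoint of the
    final bracket.
    """
    axis = _canon(axis_name)
    if sweep_grid is None:
        sweep_grid = np.linspace(0.0, 1.0, 201)

    def kind_at(value: float) -> str:
        overridden = _override_config(base_config, axis, value)
        result = sweep("resource", sweep_grid, overridden, rho0=rho0)
        return classify(result, jump_threshold, zero_threshold).kind

    kind_lo, kind_hi = kind_at(lo), kind_at(hi)
    if kind_lo == kind_hi:
        raise ValueError(
            f"classification is {kind_lo!r} at both ends of [{lo}, {hi}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if kind_at(mid) == kind_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _override_config(config: MeanFieldConfig, name: str, value: float) -> MeanFieldConfig:
    from dataclasses import replace

    if name in ("k1", "k2"):
        return replace(config, **{name: int(round(value))})
    return replace(config, params=replace(config.params, **{name: float(value)}))


@dataclass
class PhaseDiagram:
    """Transition kind of the resource sweep over a 2-D parameter plane."""

    axis1_name: str
    axis2_name: str
    axis1_grid: np.ndarray
    axis2_grid: np.ndarray
    classification_grid: np.ndarray  # kind strings, shape (len(axis1), len(axis2))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                self.axis1_name: self.axis1_grid[i],
                self.axis2_name: self.axis2_grid[j],
                "kind": self.classification_grid[i, j],
            }
            for i in range(len(self.axis1_grid))
            for j in range(len(self.axis2_grid))
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def kinds_present(self) -> set[str]:
        return set(self.classification_grid.ravel())


def phase_diagram(
    axis1_name: str,
    axis1_grid,
    axis2_name: str,
    axis2_grid,
    base_config: MeanFieldConfig,
    sweep_grid=None,
    rho0: float = 0.1,
    jump_threshold: float = 0.05,
    zero_threshold: float = 1e-3,
) -> PhaseDiagram:
    """Classify the resource sweep on every cell of a 2-D parameter grid."""
    a1 = _canon(axis1_name)
    a2 = _canon(axis2_name)
    grid1 = np.asarray(axis1_grid, dtype=float)
    grid2 = np.asarray(axis2_grid, dtype=float)
    kinds = np.empty((len(grid1), len(grid2)), dtype=object)
    for i, v1 in enumerate(grid1):
        cfg1 = _override_config(base_config, a1, v1)
        results = phase_boundary(
            a2, grid2, cfg1, sweep_grid=sweep_grid, rho0=rho0,
            jump_threshold=jump_threshold, zero_threshold=zero_threshold,
        )
        for j, (_, classification) in enumerate(results):
            kinds[i, j] = classification.kind
    return PhaseDiagram(
        axis1_name=a1,
        axis2_name=a2,
        axis1_grid=grid1,
        axis2_grid=grid2,
        classification_grid=kinds,
    )
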