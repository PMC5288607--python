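"""Accuracy experiments: reference solutions, error tables, convergence.

The harness compares fixed-step classical and exponential RK runs
against a tight adaptive reference.  The headline quantity is the
*average error* of one monitored concentration component (the mean
absolute deviation from the reference over all grid points), the
trajectories of which each model's benchmark configuration monitors:
protein for the one-gene circuit, protein 1 for the two-gene circuit,
and inactive p53 for the p53-mdm2 module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.integrate import solve_ivp

from .integrators import (
    AutonomousSystem,
    SteadyStateSystem,
    Trajectory,
    integrate,
    parse_method,
    method_label,
)
from .models import get_model

__all__ = [
    "BENCHMARKS",
    "benchmark_config",
    "ErrorSummary",
    "ConvergenceReport",
    "reference_solution",
    "average_error",
    "error_table",
    "error_growth_series",
    "convergence_order",
    "qualitative_failure_check",
    "make_random_stable_linear_system",
    "DEFAULT_SEED",
]

#: fixture seed; all experiment commands are otherwise deterministic
DEFAULT_SEED = 20170119

#: step-size windows for order studies on the benchmark models, chosen
#: inside the asymptotic regime but above the reference error floor
ORDER_STUDY_STEPS = {
    1: (0.2, 0.1, 0.05, 0.025, 0.0125),
    2: (0.2, 0.1, 0.05, 0.025, 0.0125),
    4: (0.4, 0.2, 0.1, 0.05),
}


def default_order_study_steps(order: int) -> tuple[float, ...]:
    """Step sizes recommended for fitting a method of the given order."""
    if order not in ORDER_STUDY_STEPS:
        raise ValueError(f"no preset step window for order {order}")
    return ORDER_STUDY_STEPS[order]

#: per-model benchmark configuration: initial state, horizon, and the
#: monitored component used in the error tables
BENCHMARKS = {
    "one-gene": {
        "y0": (0.6, 0.8),
        "t_end": 100.0,
        "component": 1,
        "component_name": "p",
        "step_sizes": (1 / 4, 1 / 8, 1 / 16, 1 / 32),
    },
    "two-gene": {
        "y0": (0.6, 0.8, 0.0, 0.0),
        "t_end": 100.0,
        "component": 2,
        "component_name": "p1",
        "step_sizes": (1.0, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32),
    },
    "p53": {
        "y0": (10.0, 0.1, 3.0, 0.8),
        "t_end": 50.0,
        "component": 0,
        "component_name": "P_I",
        "step_sizes": (1 / 16, 1 / 32, 1 / 64, 1 / 128),
    },
}


def benchmark_config(model_name: str) -> dict:
    """Benchmark settings (initial state, horizon, monitored component)."""
    key = model_name.strip().lower().replace("_", "-")
    if key == "p53-mdm2":
        key = "p53"
    if key not in BENCHMARKS:
        raise ValueError(f"no benchmark configuration for model {model_name!r}")
    return dict(BENCHMARKS[key])


# ---------------------------------------------------------------------
# Reference solutions


def reference_solution(
    target: SteadyStateSystem | AutonomousSystem,
    y0: Sequence[float],
    t_end: float,
    grid: np.ndarray | None = None,
    rtol: float = 1e-12,
    atol: float = 1e-13,
) -> Trajectory:
    """High-accuracy adaptive reference sampled on a uniform grid.

    Uses DOP853 at rtol 1e-12 / atol 1e-13.  The grid defaults to 1000
    uniform intervals on [0, t_end].
    """
    system = target.system if isinstance(target, SteadyStateSystem) else target
    y0 = np.asarray(y0, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, t_end, 1001)
    grid = np.asarray(grid, dtype=float)
    if t_end == 0.0 or grid.shape[0] == 1:
        return Trajectory(
            times=grid[:1],
            states=y0[None, :].copy(),
            method="reference",
            h=0.0,
            names=system.names,
        )
    sol = solve_ivp(
        lambda t, y: system.rhs(y),
        (0.0, float(grid[-1])),
        y0,
        method="DOP853",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    h = float(grid[1] - grid[0]) if grid.shape[0] > 1 else 0.0
    return Trajectory(
        times=sol.t, states=sol.y.T, method="reference", h=h, names=system.names
    )


def _dense_reference(target, y0, t_end, rtol=1e-12, atol=1e-13):
    """Adaptive reference with dense output, reusable across step grids."""
    system = target.system if isinstance(target, SteadyStateSystem) else target
    sol = solve_ivp(
        lambda t, y: system.rhs(y),
        (0.0, float(t_end)),
        np.asarray(y0, dtype=float),
        method="DOP853",
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    return sol


# ---------------------------------------------------------------------
# Error metrics


def average_error(traj: Trajectory, ref: Trajectory, component: int) -> float:
    """Mean absolute error of one component over the common grid.

    Divergent (truncated) trajectories score ``+inf``: they failed to
    reach the end of the interval, and dropping them would hide the
    instability the comparison is meant to expose.
    """
    if traj.diverged or traj.states.shape[0] < ref.states.shape[0]:
        return math.inf
    if traj.states.shape[0] != ref.states.shape[0] or not np.allclose(
        traj.times, ref.times, rtol=0, atol=1e-9 * max(1.0, abs(traj.times[-1]))
    ):
        raise ValueError("trajectory and reference grids do not match")
    return float(np.mean(np.abs(traj.states[:, component] - ref.states[:, component])))


@dataclass
class ErrorSummary:
    """Average errors per (method, step size), one monitored component."""

    model: str
    component: int
    component_name: str
    t_end: float
    methods: list[str]
    step_sizes: list[float]
    rows: dict = field(default_factory=dict)  # (method, h) -> float
    diverged: dict = field(default_factory=dict)  # (method, h) -> bool

    def error(self, method: str, h: float) -> float:
        return self.rows[(method, h)]

    def to_dataframe(self) -> pd.DataFrame:
        """Rows = step sizes, columns = methods (the tables' layout)."""
        data = {
            m: [self.rows.get((m, h), math.nan) for h in self.step_sizes]
            for m in self.methods
        }
        return pd.DataFrame(data, index=pd.Index(self.step_sizes, name="h"))

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        # divergent cells print as "unstable" rather than inf
        out = df.map(lambda v: "unstable" if math.isinf(v) else f"{v:.17g}")
        out.to_csv(path)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "component": self.component,
            "component_name": self.component_name,
            "t_end": self.t_end,
            "methods": self.methods,
            "step_sizes": self.step_sizes,
            "errors": {
                f"{m}@{h:g}": (None if math.isinf(v) else v)
                for (m, h), v in self.rows.items()
            },
            "unstable": [f"{m}@{h:g}" for (m, h), d in self.diverged.items() if d],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def error_table(
    model: str | SteadyStateSystem,
    methods: Sequence[str],
    step_sizes: Sequence[float],
    y0: Sequence[float] | None = None,
    t_end: float | None = None,
    component: int | None = None,
) -> ErrorSummary:
    """Average-error comparison over a grid of methods and step sizes.

    ``model`` may be a benchmark name (configuration filled in from
    :data:`BENCHMARKS`) or a :class:`SteadyStateSystem` with explicit
    ``y0``/``t_end``/``component``.  The reference is integrated once
    (dense output) and evaluated on each step grid.  Per-cell failures
    are recorded as ``+inf``, never raised.
    """
    if isinstance(model, str):
        cfg = benchmark_config(model)
        sss = get_model(model)
        model_name = model
    else:
        sss = model
        cfg = {}
        model_name = sss.meta.get("name", "custom")
    y0 = np.asarray(y0 if y0 is not None else cfg["y0"], dtype=float)
    t_end = float(t_end if t_end is not None else cfg["t_end"])
    component = int(component if component is not None else cfg["component"])
    comp_name = cfg.get("component_name") or (
        sss.system.names[component] if sss.system.names else f"y{component + 1}"
    )

    method_labels = [method_label(*parse_method(m)) for m in methods]
    dense = _dense_reference(sss, y0, t_end)
    summary = ErrorSummary(
        model=model_name,
        component=component,
        component_name=comp_name,
        t_end=t_end,
        methods=method_labels,
        step_sizes=[float(h) for h in step_sizes],
    )
    for m, label in zip(methods, method_labels):
        for h in summary.step_sizes:
            traj = integrate(m, sss, y0, h, t_end)
            ref_states = dense.sol(traj.times).T
            # a truncated final partial step still counts as complete
            if traj.diverged or traj.times[-1] < t_end - h * (1 + 1e-9):
                err = math.inf
            else:
                err = float(
                    np.mean(np.abs(traj.states[:, component] - ref_states[:, component]))
                )
            summary.rows[(label, h)] = err
            summary.diverged[(label, h)] = traj.diverged
    return summary


def error_growth_series(
    model: str | SteadyStateSystem,
    method: str,
    h: float,
    window: tuple[float, float] | None = None,
    y0: Sequence[float] | None = None,
    t_end: float | None = None,
    component: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """|numerical - reference| of the monitored component inside a window.

    Returns ``(times, abs_errors)`` restricted to grid points with
    ``t_a <= t <= t_b`` (default window: the full interval).
    """
    if isinstance(model, str):
        cfg = benchmark_config(model)
        sss = get_model(model)
    else:
        sss = model
        cfg = {}
    y0 = np.asarray(y0 if y0 is not None else cfg["y0"], dtype=float)
    t_end = float(t_end if t_end is not None else cfg["t_end"])
    component = int(component if component is not None else cfg["component"])
    if window is None:
        window = (0.0, t_end)
    t_a, t_b = window
    if not (t_a <= t_b <= t_end + 1e-12):
        raise ValueError("window must satisfy t_a <= t_b <= t_end")
    traj = integrate(method, sss, y0, h, t_end)
    dense = _dense_reference(sss, y0, t_end)
    ref = dense.sol(traj.times).T
    err = np.abs(traj.states[:, component] - ref[:, component])
    mask = (traj.times >= t_a - 1e-12) & (traj.times <= t_b + 1e-12)
    return traj.times[mask], err[mask]


# ---------------------------------------------------------------------
# Convergence order


@dataclass
class ConvergenceReport:
    """Empirical order from a log-log fit of error against step size."""

    method: str
    step_sizes: list[float]
    errors: list[float]
    fitted_order: float | None
    declared_order: int
    inconclusive: bool = False

    @property
    def consistent(self) -> bool:
        return (
            self.fitted_order is not None
            and abs(self.fitted_order - self.declared_order) <= 0.25
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "step_sizes": self.step_sizes,
            "errors": self.errors,
            "fitted_order": self.fitted_order,
            "declared_order": self.declared_order,
            "inconclusive": self.inconclusive,
            "consistent": self.consistent,
        }


def convergence_order(
    model: str | SteadyStateSystem,
    method: str,
    step_sizes: Sequence[float],
    y0: Sequence[float] | None = None,
    t_end: float = 10.0,
    component: int | None = None,
    error_floor: float = 1e-9,
) -> ConvergenceReport:
    """Fit the empirical order of a method on one model.

    ``step_sizes`` must be at least three values in geometric
    progression.  Errors at or below ``error_floor`` (100x the reference
    accuracy) are excluded from the fit; if fewer than two points
    survive the report is flagged inconclusive rather than returning a
    meaningless slope.
    """
    hs = [float(h) for h in step_sizes]
    if len(hs) < 3:
        raise ValueError("need at least three step sizes")
    ratios = [hs[i] / hs[i + 1] for i in range(len(hs) - 1)]
    if max(ratios) / min(ratios) > 1.001:
        raise ValueError("step sizes must form a geometric progression")
    if isinstance(model, str):
        cfg = benchmark_config(model)
        sss = get_model(model)
    else:
        sss = model
        cfg = {}
    y0 = np.asarray(y0 if y0 is not None else cfg["y0"], dtype=float)
    component = int(component if component is not None else cfg.get("component", 0))

    kind, tableau = parse_method(method)
    dense = _dense_reference(sss, y0, t_end)
    errors = []
    for h in hs:
        traj = integrate(method, sss, y0, h, t_end)
        ref = dense.sol(traj.times).T
        errors.append(
            float(np.mean(np.abs(traj.states[:, component] - ref[:, component])))
        )
    usable = [(h, e) for h, e in zip(hs, errors) if e > error_floor]
    if len(usable) < 2:
        return ConvergenceReport(
            method=method_label(kind, tableau),
            step_sizes=hs,
            errors=errors,
            fitted_order=None,
            declared_order=tableau.order,
            inconclusive=True,
        )
    lh = np.log([h for h, _ in usable])
    le = np.log([e for _, e in usable])
    slope = float(np.polyfit(lh, le, 1)[0])
    return ConvergenceReport(
        method=method_label(kind, tableau),
        step_sizes=hs,
        errors=errors,
        fitted_order=slope,
        declared_order=tableau.order,
    )


# ---------------------------------------------------------------------
# Qualitative steady-state check


def qualitative_failure_check(
    model: str | SteadyStateSystem,
    method: str,
    h: float,
    t_end: float = 200.0,
    y0: Sequence[float] | None = None,
    settle_tol: float = 1e-2,
) -> dict:
    """Does a fixed-step run settle onto the stable steady state?

    ``settles`` is true iff the trajectory reaches ``t_end`` and the sup
    over the second half of the run of ``||z(t) - z*||`` is at most
    ``settle_tol``.  Large steps can make a classical method miss the
    steady state entirely (sustained spurious oscillation) while the
    exponential method built from the same tableau still settles.
    """
    if isinstance(model, str):
        cfg = benchmark_config(model)
        sss = get_model(model)
    else:
        sss = model
        cfg = {}
    y0 = np.asarray(y0 if y0 is not None else cfg["y0"], dtype=float)
    traj = integrate(method, sss, y0, h, t_end)
    if traj.diverged or traj.times[-1] < t_end - h * (1 + 1e-9):
        return {"settles": False, "terminal_distance": math.inf, "diverged": True}
    mask = traj.times >= t_end / 2
    dist = np.linalg.norm(traj.states[mask] - sss.z_star, axis=1)
    return {
        "settles": bool(np.max(dist) <= settle_tol),
        "terminal_distance": float(dist[-1]),
        "diverged": False,
    }


# ---------------------------------------------------------------------
# Random stable linear fixtures


def make_random_stable_linear_system(
    d: int,
    seed: int,
    real_range: tuple[float, float] = (-2.0, -0.1),
    imag_max: float = 2.0,
) -> SteadyStateSystem:
    """Random linear system ``y' = Omega y`` with a stable spectrum.

    ``Omega`` is built as an orthogonal similarity of a real block
    Schur form whose 1x1/2x2 blocks carry eigenvalue real parts drawn
    uniformly from ``real_range`` (strictly negative) and imaginary
    parts from ``[0, imag_max]``.  Deterministic in ``seed``; the steady
    state is the origin.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    lo, hi = real_range
    if not (lo < 0 and hi < 0):
        raise ValueError("real_range must be strictly negative")
    rng = np.random.default_rng(seed)
    B = np.zeros((d, d))
    i = 0
    while i < d:
        re = rng.uniform(lo, hi)
        if i + 1 < d and rng.random() < 0.5:
            im = rng.uniform(0.0, imag_max)
            B[i : i + 2, i : i + 2] = [[re, im], [-im, re]]
            i += 2
        else:
            B[i, i] = re
            i += 1
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    omega = Q @ B @ Q.T

    system = AutonomousSystem(
        dim=d, rhs=lambda y: omega @ y, jac=lambda y: omega
    )
    return SteadyStateSystem(
        system=system,
        z_star=np.zeros(d),
        omega=omega,
        meta={"name": f"linear-{d}d-seed{seed}", "seed": seed},
    )
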