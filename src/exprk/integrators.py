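"""Fixed-step classical and exponential Runge-Kutta integration.

The exponential Runge-Kutta (expRK) scheme generated from a classical
tableau (c, A, b) advances ``y' = f(y)`` near an asymptotically stable
steady state at the origin.  With ``V = h * Omega`` (``Omega`` the
Jacobian of ``f`` at the steady state) the stages and update read

    Y_i     = exp(c_i V) y_n + sum_j a_ij exp((c_i - c_j) V) (h f(Y_j) - V Y_j)
    y_{n+1} = exp(V) y_n     + sum_i b_i  exp((1 - c_i)  V) (h f(Y_i) - V Y_i)

Because ``h f(Y) - V Y`` vanishes identically when ``f`` is linear with
matrix ``Omega``, the scheme integrates the linearization exactly and
preserves the steady state as a fixed point.  As ``Omega -> 0`` every
exponential factor tends to the identity and the scheme collapses to the
classical prototype, whose algebraic order it inherits.

Systems with a nonzero steady state ``z*`` are handled by the shifted
variant: translate ``y_n = z_n - z*``, step with ``f(y) = psi(y + z*)``,
translate back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .tableaux import ButcherTableau, builtin_tableau

__all__ = [
    "AutonomousSystem",
    "SteadyStateSystem",
    "StageExponentialCache",
    "Trajectory",
    "ImplicitSolveError",
    "DivergenceError",
    "matrix_exponential",
    "rk_step",
    "exprk_step",
    "exprk_step_shifted",
    "solve_implicit_stages",
    "integrate",
    "parse_method",
    "METHOD_ALIASES",
]

logger = logging.getLogger(__name__)

#: state-norm threshold beyond which a trajectory is declared divergent
DIVERGENCE_NORM = 1e12


class ImplicitSolveError(RuntimeError):
    """Newton iteration on the implicit stage equations failed to converge."""


class DivergenceError(RuntimeError):
    """Raised only when a caller asks for strict divergence handling."""


@dataclass
class AutonomousSystem:
    """An autonomous ODE ``y' = f(y)`` with analytic Jacobian.

    ``rhs`` and ``jac`` must accept any finite state vector of length
    ``dim`` and return a length-``dim`` vector / ``dim x dim`` matrix.
    ``names`` optionally labels the state components for file output.
    """

    dim: int
    rhs: Callable[[np.ndarray], np.ndarray]
    jac: Callable[[np.ndarray], np.ndarray]
    names: tuple[str, ...] | None = None


@dataclass
class SteadyStateSystem:
    """An autonomous system together with a stable steady state.

    ``omega`` is the rate matrix, i.e. the Jacobian of the right-hand
    side evaluated at ``z_star``.  If omitted it is computed from
    ``system.jac``.  The steady-state residual ``||rhs(z_star)||`` must
    not exceed ``residual_tol``.
    """

    system: AutonomousSystem
    z_star: np.ndarray
    omega: np.ndarray | None = None
    residual_tol: float = 1e-8
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_star = np.asarray(self.z_star, dtype=float)
        jac_at_star = np.asarray(self.system.jac(self.z_star), dtype=float)
        if self.omega is None:
            self.omega = jac_at_star
        else:
            self.omega = np.asarray(self.omega, dtype=float)
            if not np.allclose(self.omega, jac_at_star, rtol=1e-8, atol=1e-10):
                raise ValueError("omega does not match jac(z_star)")
        res = float(np.linalg.norm(self.system.rhs(self.z_star)))
        if res > self.residual_tol:
            raise ValueError(
                f"steady-state residual {res:.3e} exceeds tolerance "
                f"{self.residual_tol:.1e}"
            )
        self.residual = res

    @property
    def dim(self) -> int:
        return self.system.dim


def matrix_exponential(M: np.ndarray) -> np.ndarray:
    """Matrix exponential by scaling-and-squaring (scipy's Pade-based expm).

    Raises ``ValueError`` on non-finite input.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix_exponential: non-finite entries in input")
    return scipy.linalg.expm(M)


class StageExponentialCache:
    """Precomputed exponential factors of an expRK method.

    For fixed tableau, step size ``h`` and rate matrix ``Omega`` the
    scheme needs ``exp(c_i V)``, ``exp((c_i - c_j) V)`` for every nonzero
    ``a_ij``, ``exp((1 - c_i) V)`` and ``exp(V)``, with ``V = h Omega``.
    They are computed once here and reused at every step, which is what
    makes fixed-step expRK integration cost-competitive with classical
    RK.  Factors with coefficient zero are the identity exactly;
    negative coefficients (possible for implicit tableaux) are
    exponentials of the negated matrix, never matrix inverses.
    """

    def __init__(self, tableau: ButcherTableau, h: float, omega: np.ndarray):
        omega = np.asarray(omega, dtype=float)
        d = omega.shape[0]
        self.tableau = tableau
        self.h = float(h)
        self.omega = omega
        self.V = self.h * omega
        self._eye = np.eye(d)
        c = tableau.c
        self.exp_stage = [self._factor(ci) for ci in c]
        self.exp_update = [self._factor(1.0 - ci) for ci in c]
        self.exp_V = self._factor(1.0)
        self.exp_pair: dict[tuple[int, int], np.ndarray] = {}
        for i in range(tableau.s):
            for j in range(tableau.s):
                if tableau.A[i, j] != 0.0:
                    self.exp_pair[(i, j)] = self._factor(c[i] - c[j])
        logger.info(
            "stage-exponential cache built: tableau=%s h=%g dim=%d factors=%d",
            tableau.name,
            h,
            d,
            2 * tableau.s + 1 + len(self.exp_pair),
        )

    def _factor(self, coeff: float) -> np.ndarray:
        if coeff == 0.0:
            return self._eye
        return matrix_exponential(coeff * self.V)

    def matches(self, tableau: ButcherTableau, h: float, omega: np.ndarray) -> bool:
        return (
            tableau is self.tableau
            and h == self.h
            and omega is self.omega
        )


class _IdentityCache:
    """Degenerate cache for classical RK: every factor is the identity."""

    def __init__(self, tableau: ButcherTableau, h: float, dim: int):
        eye = np.eye(dim)
        self.tableau = tableau
        self.h = float(h)
        self.V = np.zeros((dim, dim))
        self.exp_stage = [eye] * tableau.s
        self.exp_update = [eye] * tableau.s
        self.exp_V = eye
        self.exp_pair = {
            (i, j): eye
            for i in range(tableau.s)
            for j in range(tableau.s)
            if tableau.A[i, j] != 0.0
        }


def solve_implicit_stages(
    tableau: ButcherTableau,
    residual: Callable[[np.ndarray], np.ndarray],
    jacobian: Callable[[np.ndarray], np.ndarray],
    guess: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> tuple[np.ndarray, int]:
    """Newton iteration on the stacked implicit stage system.

    ``residual`` maps the stacked stage vector (length ``s*d``) to the
    stacked stage residuals; ``jacobian`` returns its ``s*d x s*d``
    Jacobian.  Returns ``(stages, iterations)`` once the residual
    max-norm falls below ``tol`` (absolute).
    """
    Y = np.array(guess, dtype=float)
    for it in range(max_iter):
        r = residual(Y)
        rnorm = float(np.max(np.abs(r)))
        if rnorm <= tol:
            logger.debug(
                "implicit stages converged: tableau=%s iters=%d residual=%.2e",
                tableau.name,
                it,
                rnorm,
            )
            return Y, it
        J = jacobian(Y)
        Y = Y - np.linalg.solve(J, r)
    rnorm = float(np.max(np.abs(residual(Y))))
    if rnorm <= tol:
        return Y, max_iter
    raise ImplicitSolveError(
        f"implicit stages of tableau {tableau.name!r} did not converge "
        f"within {max_iter} Newton iterations (residual {rnorm:.3e})"
    )


def _generic_step(
    tableau: ButcherTableau,
    f: Callable[[np.ndarray], np.ndarray],
    jac: Callable[[np.ndarray], np.ndarray] | None,
    cache,
    y_n: np.ndarray,
    h: float,
    newton_tol: float = 1e-12,
    newton_max_iter: int = 50,
) -> np.ndarray:
    """One step of the (exp)RK scheme defined by ``tableau`` and ``cache``.

    With an identity cache this is the classical method; with a
    stage-exponential cache it is the expRK method.  ``g(Y) = h f(Y) - V Y``
    is the nonlinear remainder fed through the exponential factors.
    """
    s = tableau.s
    A, b = tableau.A, tableau.b
    V = cache.V
    y_n = np.asarray(y_n, dtype=float)
    d = y_n.shape[0]

    def g(Y: np.ndarray) -> np.ndarray:
        return h * f(Y) - V @ Y

    if tableau.explicit:
        gs: list[np.ndarray] = []
        Ys: list[np.ndarray] = []
        for i in range(s):
            Yi = cache.exp_stage[i] @ y_n
            for j in range(i):
                aij = A[i, j]
                if aij != 0.0:
                    Yi = Yi + aij * (cache.exp_pair[(i, j)] @ gs[j])
            Ys.append(Yi)
            gs.append(g(Yi))
    else:
        if jac is None:
            raise ValueError("implicit tableau requires an analytic Jacobian")
        base = [cache.exp_stage[i] @ y_n for i in range(s)]

        def residual(Ystack: np.ndarray) -> np.ndarray:
            Y = Ystack.reshape(s, d)
            gvals = [g(Y[j]) for j in range(s)]
            out = np.empty((s, d))
            for i in range(s):
                acc = base[i].copy()
                for j in range(s):
                    aij = A[i, j]
                    if aij != 0.0:
                        acc += aij * (cache.exp_pair[(i, j)] @ gvals[j])
                out[i] = Y[i] - acc
            return out.ravel()

        def jacobian(Ystack: np.ndarray) -> np.ndarray:
            Y = Ystack.reshape(s, d)
            dg = [h * jac(Y[j]) - V for j in range(s)]
            J = np.eye(s * d)
            for i in range(s):
                for j in range(s):
                    aij = A[i, j]
                    if aij != 0.0:
                        J[i * d : (i + 1) * d, j * d : (j + 1) * d] -= aij * (
                            cache.exp_pair[(i, j)] @ dg[j]
                        )
            return J

        guess = np.concatenate(base)
        Ystack, _ = solve_implicit_stages(
            tableau, residual, jacobian, guess, tol=newton_tol, max_iter=newton_max_iter
        )
        Ys = list(Ystack.reshape(s, d))
        gs = [g(Yi) for Yi in Ys]

    y_next = cache.exp_V @ y_n
    for i in range(s):
        if b[i] != 0.0:
            y_next = y_next + b[i] * (cache.exp_update[i] @ gs[i])
    return y_next


def rk_step(
    tableau: ButcherTableau,
    system: AutonomousSystem,
    y_n: np.ndarray,
    h: float,
    newton_tol: float = 1e-12,
    newton_max_iter: int = 50,
) -> np.ndarray:
    """One step of the classical RK method defined by ``tableau``."""
    cache = _IdentityCache(tableau, h, system.dim)
    return _generic_step(
        tableau, system.rhs, system.jac, cache, y_n, h, newton_tol, newton_max_iter
    )


def exprk_step(
    tableau: ButcherTableau,
    system: AutonomousSystem,
    omega: np.ndarray,
    cache: StageExponentialCache,
    y_n: np.ndarray,
    h: float,
    newton_tol: float = 1e-12,
    newton_max_iter: int = 50,
) -> np.ndarray:
    """One expRK step for a system whose steady state is the origin."""
    if not cache.matches(tableau, h, omega):
        cache = StageExponentialCache(tableau, h, omega)
    return _generic_step(
        tableau, system.rhs, system.jac, cache, y_n, h, newton_tol, newton_max_iter
    )


def exprk_step_shifted(
    tableau: ButcherTableau,
    sss: SteadyStateSystem,
    cache: StageExponentialCache,
    z_n: np.ndarray,
    h: float,
    newton_tol: float = 1e-12,
    newton_max_iter: int = 50,
) -> np.ndarray:
    """One expRK step for a system with steady state ``z* != 0``.

    Translates ``y_n = z_n - z*``, steps the translated system (whose
    steady state is the origin), and shifts back.
    """
    z_star = sss.z_star

    def f(y: np.ndarray) -> np.ndarray:
        return sss.system.rhs(y + z_star)

    def jac(y: np.ndarray) -> np.ndarray:
        return sss.system.jac(y + z_star)

    y_n = np.asarray(z_n, dtype=float) - z_star
    y_next = _generic_step(
        tableau, f, jac, cache, y_n, h, newton_tol, newton_max_iter
    )
    return y_next + z_star


@dataclass
class Trajectory:
    """Uniform-grid output of a fixed-step integrator run.

    ``states`` holds one row per time point.  If the run blew up the
    trajectory is truncated at the last finite state and ``diverged`` is
    set instead of raising, so instability experiments remain expressible.
    """

    times: np.ndarray
    states: np.ndarray
    method: str
    h: float
    diverged: bool = False
    names: tuple[str, ...] | None = None

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def write_csv(self, path) -> None:
        """Write ``t,<name_1>,...,<name_d>`` rows (RFC-4180, 17 sig. digits)."""
        d = self.states.shape[1]
        names = self.names or tuple(f"y{i + 1}" for i in range(d))
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("t," + ",".join(names) + "\n")
            for t, row in zip(self.times, self.states):
                fh.write(
                    ",".join(f"{v:.17g}" for v in (t, *row)) + "\n"
                )

    def metadata(self) -> dict:
        return {
            "method": self.method,
            "h": self.h,
            "t_end": float(self.times[-1]),
            "n_points": int(self.times.shape[0]),
            "diverged": self.diverged,
            "names": list(self.names) if self.names else None,
        }


#: aliases for the exponential methods as they are usually written
METHOD_ALIASES = {
    "expeuler": ("exprk", "euler"),
    "expimeuler": ("exprk", "implicit_euler"),
    "exptrap": ("exprk", "trapezoid"),
    "expheun": ("exprk", "heun"),
    "expmid": ("exprk", "midpoint"),
    "exprk3/8": ("exprk", "rk38"),
    "exprk38": ("exprk", "rk38"),
    "exprk4": ("exprk", "rk4"),
}


def parse_method(spec: str | tuple) -> tuple[str, ButcherTableau]:
    """Resolve a method spec to ``(kind, tableau)``.

    Accepts ``"rk:<tableau>"``, ``"exprk:<tableau>"``, bare tableau
    names (classical), the usual aliases (``expEuler``, ``expHeun``,
    ``expRK3/8``, ``expRK4``, ...), or an explicit ``(kind, tableau)``
    pair with a :class:`ButcherTableau` instance.
    """
    if isinstance(spec, tuple):
        kind, tab = spec
        if isinstance(tab, str):
            tab = builtin_tableau(tab)
        return kind, tab
    key = spec.strip()
    low = key.lower()
    if low in METHOD_ALIASES:
        kind, name = METHOD_ALIASES[low]
        return kind, builtin_tableau(name)
    if ":" in key:
        kind, _, name = key.partition(":")
        kind = kind.strip().lower()
        if kind not in ("rk", "exprk"):
            raise ValueError(
                f"unknown method family {kind!r}; use 'rk' or 'exprk'"
            )
        return kind, builtin_tableau(name.strip().lower())
    return "rk", builtin_tableau(low)


def method_label(kind: str, tableau: ButcherTableau) -> str:
    return f"{kind}:{tableau.name}"


def integrate(
    method: str | tuple,
    target: SteadyStateSystem | AutonomousSystem,
    y0: Sequence[float],
    h: float,
    t_end: float,
    newton_tol: float = 1e-12,
    newton_max_iter: int = 50,
) -> Trajectory:
    """Integrate with a fixed step from ``t = 0`` to ``t = t_end``.

    ``method`` selects the family and prototype tableau (see
    :func:`parse_method`).  Exponential methods require a
    :class:`SteadyStateSystem`; classical methods accept either.  The
    stage-exponential cache is built once per run.  Non-finite blow-up
    (or state norm beyond ``DIVERGENCE_NORM``) truncates the trajectory
    and sets its ``diverged`` flag rather than raising.
    """
    if h <= 0:
        raise ValueError("step size h must be positive")
    kind, tableau = parse_method(method)
    if isinstance(target, SteadyStateSystem):
        sss: SteadyStateSystem | None = target
        system = target.system
    else:
        sss = None
        system = target
    if kind == "exprk" and sss is None:
        raise ValueError("exponential methods require a SteadyStateSystem")

    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (system.dim,):
        raise ValueError(f"y0 has shape {y0.shape}, expected ({system.dim},)")
    n_steps = int(np.floor(t_end / h + 1e-9))
    times = np.arange(n_steps + 1) * h
    states = np.empty((n_steps + 1, system.dim))
    states[0] = y0

    if kind == "exprk":
        cache = StageExponentialCache(tableau, h, sss.omega)
        z_star = sss.z_star

        def f(y: np.ndarray) -> np.ndarray:
            return system.rhs(y + z_star)

        def jacf(y: np.ndarray) -> np.ndarray:
            return system.jac(y + z_star)

        def step(z: np.ndarray) -> np.ndarray:
            y = _generic_step(
                tableau, f, jacf, cache, z - z_star, h, newton_tol, newton_max_iter
            )
            return y + z_star

    else:
        id_cache = _IdentityCache(tableau, h, system.dim)

        def step(y: np.ndarray) -> np.ndarray:
            return _generic_step(
                tableau,
                system.rhs,
                system.jac,
                id_cache,
                y,
                h,
                newton_tol,
                newton_max_iter,
            )

    diverged = False
    n_done = n_steps
    for n in range(n_steps):
        try:
            y_next = step(states[n])
        except ImplicitSolveError as exc:
            raise ImplicitSolveError(f"{exc} at step {n} (t={times[n]:g})") from exc
        if not np.all(np.isfinite(y_next)):
            logger.info(
                "divergence (non-finite state) at step %d, t=%g; truncating", n + 1, times[n + 1]
            )
            diverged = True
            n_done = n
            break
        states[n + 1] = y_next
        if np.linalg.norm(y_next) > DIVERGENCE_NORM:
            logger.info(
                "divergence (norm > %g) at step %d, t=%g; truncating",
                DIVERGENCE_NORM,
                n + 1,
                times[n + 1],
            )
            diverged = True
            n_done = n + 1
            break

    return Trajectory(
        times=times[: n_done + 1],
        states=states[: n_done + 1],
        method=method_label(kind, tableau),
        h=h,
        diverged=diverged,
        names=system.names,
    )
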