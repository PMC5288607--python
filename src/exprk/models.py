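"""Benchmark genetic regulatory systems and their steady-state analysis.

Three ODE models of transcription/translation with a stable steady
state:

* a one-gene negative self-regulation loop (the protein represses its
  own gene as a dimer),
* a two-gene cross-regulation circuit (protein 2 activates gene 1,
  protein 1 represses gene 2, Hill kinetics),
* the p53-mdm2 core module with complex formation (damped oscillations
  toward a stable steady state).

The first two fit the generic mRNA/protein form

    r' = -Gamma r + F(p),      p' = K r - M p

with diagonal degradation/translation matrices; their rate matrix at a
steady state is the block matrix

    Omega = [[-Gamma, F'(p*)], [K, -M]].

The p53-mdm2 system has a saturating synthesis term and a bilinear
complex-formation term, so its Jacobian is derived directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .integrators import AutonomousSystem, SteadyStateSystem

__all__ = [
    "hill_activation",
    "hill_repression",
    "hill_activation_deriv",
    "hill_repression_deriv",
    "GRNModel",
    "grn_assemble",
    "grn_system",
    "SteadyStateReport",
    "CharacteristicReport",
    "one_gene_model",
    "two_gene_model",
    "two_gene_characteristic",
    "p53_model",
    "stability_report",
    "finite_difference_jacobian",
    "get_model",
    "MODEL_NAMES",
    "ONE_GENE_PARAMS",
    "TWO_GENE_PARAMS",
    "P53_PARAMS",
]


# ---------------------------------------------------------------------
# Hill kinetics


def hill_activation(p, theta: float, n: float):
    """Activating Hill function ``p^n / (theta^n + p^n)``."""
    pn = p**n
    return pn / (theta**n + pn)


def hill_repression(p, theta: float, n: float):
    """Repressing Hill function ``theta^n / (theta^n + p^n)``."""
    tn = theta**n
    return tn / (tn + p**n)


def hill_activation_deriv(p, theta: float, n: float):
    tn = theta**n
    return n * tn * p ** (n - 1) / (tn + p**n) ** 2


def hill_repression_deriv(p, theta: float, n: float):
    return -hill_activation_deriv(p, theta, n)


# ---------------------------------------------------------------------
# Generic N-gene transcription/translation machinery


@dataclass
class GRNModel:
    """An N-gene transcription/translation network.

    ``gamma``/``mu`` are mRNA/protein degradation rates (1/time),
    ``kappa`` translation rates (1/time), all strictly positive.  ``F``
    maps the protein vector to transcription rates and ``F_jac`` is its
    analytic N x N Jacobian.  The state is ordered
    ``(r_1..r_N, p_1..p_N)``.
    """

    N: int
    gamma: np.ndarray
    mu: np.ndarray
    kappa: np.ndarray
    F: Callable[[np.ndarray], np.ndarray]
    F_jac: Callable[[np.ndarray], np.ndarray]
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        for label, v in (("gamma", self.gamma), ("mu", self.mu), ("kappa", self.kappa)):
            if v.shape != (self.N,):
                raise ValueError(f"{label} must have length N={self.N}")
            if np.any(v <= 0):
                raise ValueError(f"{label} must be strictly positive")

    def rhs(self, y: np.ndarray) -> np.ndarray:
        r, p = y[: self.N], y[self.N :]
        return np.concatenate(
            [-self.gamma * r + self.F(p), self.kappa * r - self.mu * p]
        )

    def jac(self, y: np.ndarray) -> np.ndarray:
        return grn_assemble(self, y[self.N :])


def grn_assemble(model: GRNModel, p_star: np.ndarray) -> np.ndarray:
    """Rate matrix ``[[-Gamma, F'(p*)], [K, -M]]`` at protein levels ``p_star``."""
    p_star = np.atleast_1d(np.asarray(p_star, dtype=float))
    if p_star.shape != (model.N,):
        raise ValueError(f"p_star must have length N={model.N}")
    N = model.N
    omega = np.zeros((2 * N, 2 * N))
    omega[:N, :N] = -np.diag(model.gamma)
    omega[:N, N:] = np.asarray(model.F_jac(p_star), dtype=float).reshape(N, N)
    omega[N:, :N] = np.diag(model.kappa)
    omega[N:, N:] = -np.diag(model.mu)
    return omega


def grn_system(model: GRNModel, z_star: np.ndarray, **kwargs) -> SteadyStateSystem:
    """Wrap a :class:`GRNModel` and its steady state as a SteadyStateSystem."""
    system = AutonomousSystem(
        dim=2 * model.N, rhs=model.rhs, jac=model.jac, names=model.names
    )
    return SteadyStateSystem(system=system, z_star=np.asarray(z_star, float), **kwargs)


def finite_difference_jacobian(
    f: Callable[[np.ndarray], np.ndarray], x: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian, used to cross-check analytic ones."""
    x = np.asarray(x, dtype=float)
    fx = np.asarray(f(x))
    J = np.empty((fx.shape[0], x.shape[0]))
    for j in range(x.shape[0]):
        step = eps * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        J[:, j] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * step)
    return J


# ---------------------------------------------------------------------
# Reports


@dataclass
class SteadyStateReport:
    """Steady state with its spectrum and stability verdict."""

    z_star: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stable: bool

    def to_dict(self) -> dict:
        return {
            "z_star": [float(v) for v in self.z_star],
            "residual": float(self.residual),
            "eigenvalues": [[float(ev.real), float(ev.imag)] for ev in self.eigenvalues],
            "stable": bool(self.stable),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class CharacteristicReport:
    """Quartic characteristic data of the two-gene rate matrix."""

    D: float
    D_hopf: float
    roots: np.ndarray
    stable: bool


def stability_report(sss: SteadyStateSystem) -> SteadyStateReport:
    """Spectrum of the rate matrix, sorted by real part descending.

    Ties in the real part are broken by imaginary part descending, so
    the report is deterministic.
    """
    ev = np.linalg.eigvals(sss.omega)
    order = np.lexsort((-ev.imag, -ev.real))
    ev = ev[order]
    return SteadyStateReport(
        z_star=sss.z_star.copy(),
        residual=sss.residual,
        eigenvalues=ev,
        stable=bool(np.max(ev.real) < 0),
    )


# ---------------------------------------------------------------------
# One-gene negative self-regulation

ONE_GENE_PARAMS = {"alpha": 3.0, "gamma": 1.0, "mu": 1.5, "kappa": 5.0, "theta": 1.0}


def one_gene_model(
    alpha: float = 3.0,
    gamma: float = 1.0,
    mu: float = 1.5,
    kappa: float = 5.0,
    theta: float = 1.0,
) -> SteadyStateSystem:
    """One gene repressed by its own protein acting as a dimer.

        r' = -gamma r + alpha / (1 + p^2/theta^2)
        p' = kappa r - mu p

    The protein steady state is the unique positive root of the cubic
    ``p^3/theta^2 + p - alpha*kappa/(gamma*mu) = 0`` and
    ``r* = (mu/kappa) p*``.
    """
    for label, v in (("alpha", alpha), ("gamma", gamma), ("mu", mu), ("kappa", kappa), ("theta", theta)):
        if v <= 0:
            raise ValueError(f"{label} must be positive")

    th2 = theta**2

    def F(p: np.ndarray) -> np.ndarray:
        return np.atleast_1d(alpha / (1.0 + p[0] ** 2 / th2))

    def F_jac(p: np.ndarray) -> np.ndarray:
        return np.array([[-2.0 * alpha * p[0] / th2 / (1.0 + p[0] ** 2 / th2) ** 2]])

    model = GRNModel(
        N=1, gamma=[gamma], mu=[mu], kappa=[kappa], F=F, F_jac=F_jac, names=("r", "p")
    )

    # unique positive real root of p^3/theta^2 + p - alpha*kappa/(gamma*mu)
    rho = alpha * kappa / (gamma * mu)
    roots = np.roots([1.0 / th2, 0.0, 1.0, -rho])
    real_pos = [z.real for z in roots if abs(z.imag) < 1e-9 and z.real > 0]
    assert len(real_pos) == 1, "cubic must have a unique positive root"
    p_star = real_pos[0]
    for _ in range(3):  # Newton polish to full double precision
        cval = p_star**3 / th2 + p_star - rho
        p_star -= cval / (3.0 * p_star**2 / th2 + 1.0)
    r_star = mu / kappa * p_star

    return grn_system(
        model,
        [r_star, p_star],
        residual_tol=1e-12,
        meta={
            "name": "one-gene",
            "params": {"alpha": alpha, "gamma": gamma, "mu": mu, "kappa": kappa, "theta": theta},
            "grn": model,
        },
    )


# ---------------------------------------------------------------------
# Two-gene cross-regulation

TWO_GENE_PARAMS = {
    "n1": 3,
    "n2": 3,
    "m1": 1.8,
    "m2": 1.8,
    "k1": 1.0,
    "k2": 1.0,
    "gamma1": 1.0,
    "gamma2": 1.0,
    "mu1": 1.0,
    "mu2": 1.0,
    "theta1": 0.6542,
    "theta2": 0.6542,
}


def two_gene_model(
    n1: int = 3,
    n2: int = 3,
    m1: float = 1.8,
    m2: float = 1.8,
    k1: float = 1.0,
    k2: float = 1.0,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
    mu1: float = 1.0,
    mu2: float = 1.0,
    theta1: float = 0.6542,
    theta2: float = 0.6542,
) -> SteadyStateSystem:
    """Two-gene activation-inhibition circuit with Hill kinetics.

        r1' = m1 H+(p2; theta2, n2) - gamma1 r1
        r2' = m2 H-(p1; theta1, n1) - gamma2 r2
        p1' = k1 r1 - mu1 p1
        p2' = k2 r2 - mu2 p2

    Protein 2 activates gene 1; protein 1 represses gene 2.  The
    steady state is reduced to a scalar equation for ``p1*`` (damped
    Newton from ``p1 = theta1``, bisection fallback), the remaining
    components following from the linear balances.
    """
    if n1 < 1 or n2 < 1 or int(n1) != n1 or int(n2) != n2:
        raise ValueError("Hill coefficients must be integers >= 1")
    pars = dict(
        n1=int(n1), n2=int(n2), m1=m1, m2=m2, k1=k1, k2=k2,
        gamma1=gamma1, gamma2=gamma2, mu1=mu1, mu2=mu2, theta1=theta1, theta2=theta2,
    )
    if any(v <= 0 for v in pars.values()):
        raise ValueError("all parameters must be positive")

    A = m1 * k1 / (gamma1 * mu1)  # max attainable p1
    B = m2 * k2 / (gamma2 * mu2)  # max attainable p2

    def p2_of_p1(p1: float) -> float:
        return B * hill_repression(p1, theta1, n1)

    def scalar_eq(p1: float) -> float:
        return p1 - A * hill_activation(p2_of_p1(p1), theta2, n2)

    def scalar_eq_deriv(p1: float) -> float:
        p2 = p2_of_p1(p1)
        return 1.0 - A * hill_activation_deriv(p2, theta2, n2) * B * hill_repression_deriv(
            p1, theta1, n1
        )

    # damped Newton from p1 = theta1; fall back to bisection on (0, A)
    p1 = theta1
    converged = False
    for _ in range(100):
        fval = scalar_eq(p1)
        if abs(fval) <= 1e-14:
            converged = True
            break
        step = fval / scalar_eq_deriv(p1)
        new = p1 - step
        halvings = 0
        while (new <= 0 or abs(scalar_eq(new)) > abs(fval)) and halvings < 60:
            step *= 0.5
            new = p1 - step
            halvings += 1
        if halvings >= 60:
            break
        p1 = new
    if not converged and abs(scalar_eq(p1)) > 1e-12:
        lo, hi = 1e-14, A * (1 + 1e-12)
        if scalar_eq(lo) * scalar_eq(hi) > 0:
            raise RuntimeError(
                "two-gene steady-state solve failed from the default start; "
                "try different initial brackets"
            )
        p1 = brentq(scalar_eq, lo, hi, xtol=1e-15, rtol=8.9e-16)
    p1_star = p1
    p2_star = p2_of_p1(p1_star)
    r1_star = mu1 / k1 * p1_star
    r2_star = mu2 / k2 * p2_star

    def F(p: np.ndarray) -> np.ndarray:
        return np.array(
            [
                m1 * hill_activation(p[1], theta2, n2),
                m2 * hill_repression(p[0], theta1, n1),
            ]
        )

    def F_jac(p: np.ndarray) -> np.ndarray:
        return np.array(
            [
                [0.0, m1 * hill_activation_deriv(p[1], theta2, n2)],
                [m2 * hill_repression_deriv(p[0], theta1, n1), 0.0],
            ]
        )

    model = GRNModel(
        N=2,
        gamma=[gamma1, gamma2],
        mu=[mu1, mu2],
        kappa=[k1, k2],
        F=F,
        F_jac=F_jac,
        names=("r1", "r2", "p1", "p2"),
    )
    return grn_system(
        model,
        [r1_star, r2_star, p1_star, p2_star],
        residual_tol=1e-12,
        meta={"name": "two-gene", "params": pars, "grn": model},
    )


def two_gene_characteristic(sss: SteadyStateSystem) -> CharacteristicReport:
    """Quartic characteristic equation of the two-gene rate matrix.

    The spectrum solves ``(l+g1)(l+g2)(l+mu1)(l+mu2) + D = 0`` where the
    coupling constant D collects the product of the two Hill-function
    slopes at the steady state.  The steady state is stable iff
    ``D < D_hopf``; at ``D = D_hopf`` a complex pair crosses the
    imaginary axis (Hopf bifurcation).
    """
    pars = sss.meta["params"]
    n1, n2 = pars["n1"], pars["n2"]
    t1n, t2n = pars["theta1"] ** n1, pars["theta2"] ** n2
    _, _, p1, p2 = sss.z_star
    D = (
        pars["m1"] * pars["m2"] * pars["k1"] * pars["k2"] * n1 * n2
        * p1 ** (n1 - 1) * p2 ** (n2 - 1) * t1n * t2n
        / ((p1**n1 + t1n) ** 2 * (p2**n2 + t2n) ** 2)
    )
    g1, g2, mu1, mu2 = pars["gamma1"], pars["gamma2"], pars["mu1"], pars["mu2"]
    D_hopf = (
        (g1 + g2) * (g1 + mu1) * (g2 + mu1) * (g1 + mu2) * (g2 + mu2) * (mu1 + mu2)
        / (g1 + g2 + mu1 + mu2) ** 2
    )
    poly = np.array([1.0])
    for rate in (g1, g2, mu1, mu2):
        poly = np.convolve(poly, [1.0, rate])
    poly[-1] += D
    roots = np.roots(poly)
    roots = roots[np.lexsort((-roots.imag, -roots.real))]
    return CharacteristicReport(
        D=float(D), D_hopf=float(D_hopf), roots=roots, stable=bool(D < D_hopf)
    )


# ---------------------------------------------------------------------
# p53-mdm2 core module

#: rates in 1/min, concentrations in nM; the stress input is held at zero
P53_PARAMS = {
    "s_p": 1.4,      # p53 synthesis (nM/min)
    "s_m0": 2e-3,    # basal mdm2 synthesis (nM/min)
    "s_m1": 0.15,    # p53-induced mdm2 synthesis (nM/min)
    "s_m2": 0.2,     # active-p53-induced mdm2 synthesis (nM/min)
    "k_a": 20.0,     # p53 activation (1/min); idle while the stress input is zero
    "k_c": 4.0,      # complex formation (1/(min nM))
    "k_u": 0.4,      # ubiquitination-driven release (1/min)
    "j_a": 0.2,      # deactivation of active p53 (1/min)
    "j_c": 2e-3,     # complex dissociation (1/min)
    "d_p": 2e-4,     # p53 degradation (1/min)
    "d_m": 0.4,      # mdm2 degradation (1/min)
    "K_m": 100.0,    # saturation constant of induced mdm2 synthesis (nM)
}


def p53_model(**overrides) -> SteadyStateSystem:
    """The p53-mdm2 module with complex formation and zero stress input.

    State ``(P_I, M, C, P_A)``: inactive p53, mdm2, p53-mdm2 complex,
    and active p53.

        P_I' = s_p + j_a P_A - d_p P_I - k_c P_I M + j_c C
        M'   = s_m0 + (s_m1 P_I + s_m2 P_A)/(P_I + P_A + K_m)
               + (k_u + j_c) C - (d_m + k_c P_I) M
        C'   = k_c P_I M - (j_c + k_u) C
        P_A' = -(j_a + d_p) P_A

    With zero stress the active form decays, so ``P_A* = 0``; ``M*`` and
    ``C*`` have closed forms in ``P_I*``, which itself solves a scalar
    balance found by bracketed root finding on ``(0, s_p/d_p)``.
    """
    pars = dict(P53_PARAMS)
    unknown = set(overrides) - set(pars)
    if unknown:
        raise ValueError(f"unknown p53 parameters: {sorted(unknown)}")
    pars.update(overrides)
    if any(v < 0 for v in pars.values()) or any(
        pars[k] <= 0 for k in ("s_p", "d_p", "d_m", "K_m", "k_u", "j_a")
    ):
        raise ValueError("p53 parameters must be positive (rates may not vanish)")
    s_p, s_m0, s_m1, s_m2 = pars["s_p"], pars["s_m0"], pars["s_m1"], pars["s_m2"]
    k_c, k_u, j_a, j_c = pars["k_c"], pars["k_u"], pars["j_a"], pars["j_c"]
    d_p, d_m, K_m = pars["d_p"], pars["d_m"], pars["K_m"]

    def rhs(y: np.ndarray) -> np.ndarray:
        P_I, M, C, P_A = y
        synth = (s_m1 * P_I + s_m2 * P_A) / (P_I + P_A + K_m)
        return np.array(
            [
                s_p + j_a * P_A - d_p * P_I - k_c * P_I * M + j_c * C,
                s_m0 + synth + (k_u + j_c) * C - (d_m + k_c * P_I) * M,
                k_c * P_I * M - (j_c + k_u) * C,
                -(j_a + d_p) * P_A,
            ]
        )

    def jac(y: np.ndarray) -> np.ndarray:
        P_I, M, C, P_A = y
        den = P_I + P_A + K_m
        # quotient rule on the saturating synthesis term
        dsynth_dPI = (s_m1 * (P_A + K_m) - s_m2 * P_A) / den**2
        dsynth_dPA = (s_m2 * (P_I + K_m) - s_m1 * P_I) / den**2
        return np.array(
            [
                [-d_p - k_c * M, -k_c * P_I, j_c, j_a],
                [dsynth_dPI - k_c * M, -(d_m + k_c * P_I), k_u + j_c, dsynth_dPA],
                [k_c * M, k_c * P_I, -(j_c + k_u), 0.0],
                [0.0, 0.0, 0.0, -(j_a + d_p)],
            ]
        )

    # steady state: P_A* = 0; eliminate M*, C* and solve the P_I balance
    def m_star(P_I: float) -> float:
        return (s_m0 + s_m1 * P_I / (P_I + K_m)) / d_m

    def balance(P_I: float) -> float:
        return s_p - d_p * P_I - k_c * k_u / (j_c + k_u) * P_I * m_star(P_I)

    hi = s_p / d_p
    lo = 1e-12
    if balance(lo) * balance(hi) > 0:
        raise RuntimeError("p53 steady-state bracket (0, s_p/d_p) does not change sign")
    P_I_star = brentq(balance, lo, hi, xtol=1e-13, rtol=8.9e-16)
    M_star = m_star(P_I_star)
    C_star = k_c * P_I_star * M_star / (j_c + k_u)
    z_star = np.array([P_I_star, M_star, C_star, 0.0])

    system = AutonomousSystem(dim=4, rhs=rhs, jac=jac, names=("P_I", "M", "C", "P_A"))
    return SteadyStateSystem(
        system=system,
        z_star=z_star,
        residual_tol=1e-10,
        meta={"name": "p53", "params": pars},
    )


# ---------------------------------------------------------------------
# Registry

MODEL_NAMES = ("one-gene", "two-gene", "p53")

_FACTORIES = {
    "one-gene": one_gene_model,
    "one_gene": one_gene_model,
    "two-gene": two_gene_model,
    "two_gene": two_gene_model,
    "p53": p53_model,
    "p53-mdm2": p53_model,
}


def get_model(name: str, **overrides) -> SteadyStateSystem:
    """Build a benchmark model by name, optionally overriding parameters."""
    key = name.strip().lower()
    if key not in _FACTORIES:
        raise ValueError(
            f"unknown model {name!r}; available: " + ", ".join(MODEL_NAMES)
        )
    return _FACTORIES[key](**overrides)
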