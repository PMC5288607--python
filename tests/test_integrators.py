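"""Stepper correctness: classical RK, expRK, implicit stages, trajectories.

The exponential schemes are cross-checked against three independent
oracles: an eigendecomposition-based matrix exponential, the matrix
exponential of the exact linear flow, and direct transcriptions of the
one- and two-stage exponential formulas (exponential Euler, backward
Euler, trapezoid, Heun and midpoint rules) written out by hand.
"""

import numpy as np
import pytest
import scipy.linalg


from exprk.integrators import (
    AutonomousSystem,
    ImplicitSolveError,
    StageExponentialCache,
    Trajectory,
    exprk_step,
    exprk_step_shifted,
    integrate,
    matrix_exponential,
    parse_method,
    rk_step,
)
from exprk.experiments import make_random_stable_linear_system
from exprk.tableaux import BUILTIN_TABLEAUX, builtin_tableau


def scalar_system(f, df):
    return AutonomousSystem(
        dim=1,
        rhs=lambda y: np.array([f(y[0])]),
        jac=lambda y: np.array([[df(y[0])]]),
    )


DECAY = scalar_system(lambda y: -y, lambda y: -1.0)


# ---------------------------------------------------------------------
# matrix exponential


def test_expm_zero_is_identity():
    np.testing.assert_array_equal(matrix_exponential(np.zeros((3, 3))), np.eye(3))


def test_expm_diagonal():
    out = matrix_exponential(np.diag([-1.0, -2.0]))
    np.testing.assert_allclose(out, np.diag([np.exp(-1), np.exp(-2)]), rtol=1e-14)


def test_expm_matches_eigendecomposition_oracle(rng):
    """Random 4x4 with moderate spectral radius vs an eigenbasis oracle."""
    for _ in range(5):
        M = rng.uniform(-1.5, 1.5, size=(4, 4))
        w, V = np.linalg.eig(M)
        oracle = (V @ np.diag(np.exp(w)) @ np.linalg.inv(V)).real
        np.testing.assert_allclose(matrix_exponential(M), oracle, atol=1e-10)


def test_expm_rejects_non_finite():
    with pytest.raises(ValueError):
        matrix_exponential(np.array([[np.nan, 0], [0, 0]]))


# ---------------------------------------------------------------------
# classical RK steps on y' = -y (closed forms)


@pytest.mark.parametrize(
    "name,h,expected",
    [
        ("rk4", 0.1, 1 - 0.1 + 0.005 - 0.1**3 / 6 + 0.1**4 / 24),  # degree-4 Taylor
        ("euler", 0.5, 0.5),
        ("heun", 0.5, 1 - 0.5 + 0.125),
        ("implicit_euler", 0.5, 1 / 1.5),
        ("trapezoid", 0.5, (1 - 0.25) / (1 + 0.25)),
        ("midpoint", 0.5, (1 - 0.25) / (1 + 0.25)),
    ],
)
def test_rk_step_linear_closed_forms(name, h, expected):
    y1 = rk_step(builtin_tableau(name), DECAY, np.array([1.0]), h)
    assert abs(y1[0] - expected) < 1e-13


def test_implicit_midpoint_matches_bisection_oracle():
    """y' = -y^2: the scalar stage equation solved by bisection."""
    h, y0 = 0.1, 1.0
    tab = builtin_tableau("midpoint")

    # stage equation Y = y0 - (h/2) Y^2, take the root near y0
    def stage_eq(Y):
        return Y - y0 + 0.5 * h * Y**2

    lo, hi = 0.0, 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if stage_eq(lo) * stage_eq(mid) <= 0:
            hi = mid
        else:
            lo = mid
    Y = 0.5 * (lo + hi)
    expected = y0 - h * Y**2
    sys2 = scalar_system(lambda y: -(y**2), lambda y: -2 * y)
    y1 = rk_step(tab, sys2, np.array([y0]), h)
    assert abs(y1[0] - expected) < 1e-12


def test_implicit_nonconvergence_raises():
    # Newton cannot track a step far beyond the blow-up of y' = y^2
    sys2 = scalar_system(lambda y: y**2, lambda y: 2 * y)
    with pytest.raises(ImplicitSolveError, match="implicit_euler"):
        rk_step(builtin_tableau("implicit_euler"), sys2, np.array([1.0]), 10.0)


# ---------------------------------------------------------------------
# expRK steps


@pytest.mark.parametrize("name", sorted(BUILTIN_TABLEAUX))
def test_exprk_reduces_to_rk_for_zero_rate_matrix(name, one_gene):
    """With Omega = 0 the exponential scheme is the classical prototype."""
    tab = builtin_tableau(name)
    system = one_gene.system
    omega = np.zeros((2, 2))
    cache = StageExponentialCache(tab, 0.25, omega)
    y = np.array([0.6, 0.8])
    y_rk = y.copy()
    for _ in range(100):
        y = exprk_step(tab, system, omega, cache, y, 0.25)
        y_rk = rk_step(tab, system, y_rk, 0.25)
        np.testing.assert_allclose(y, y_rk, rtol=1e-13, atol=1e-15)


@pytest.mark.parametrize("name", sorted(BUILTIN_TABLEAUX))
def test_exprk_exact_on_linear_system(name):
    """On y' = Omega y every expRK method reproduces the matrix exponential flow."""
    lin = make_random_stable_linear_system(4, seed=7)
    tab = builtin_tableau(name)
    h = 0.5
    cache = StageExponentialCache(tab, h, lin.omega)
    y = np.array([0.4, -0.2, 1.0, 0.3])
    for n in range(1, 21):
        y = exprk_step(tab, lin.system, lin.omega, cache, y, h)
        exact = scipy.linalg.expm(n * h * lin.omega) @ np.array([0.4, -0.2, 1.0, 0.3])
        np.testing.assert_allclose(y, exact, rtol=1e-11, atol=1e-13)


def test_exprk_exact_on_one_gene_rate_matrix():
    """Exponential Euler on the one-gene linearization equals exp(h*Omega)y0."""
    omega = np.array([[-1.0, -0.48], [5.0, -1.5]])
    system = AutonomousSystem(dim=2, rhs=lambda y: omega @ y, jac=lambda y: omega)
    tab = builtin_tableau("euler")
    h = 0.5
    cache = StageExponentialCache(tab, h, omega)
    y0 = np.array([0.1, 0.1])
    y1 = exprk_step(tab, system, omega, cache, y0, h)
    np.testing.assert_allclose(y1, scipy.linalg.expm(h * omega) @ y0, atol=1e-12)


def test_origin_is_fixed_point(one_gene):
    """f(0) = 0 implies the expRK update leaves the origin exactly."""
    z_star = one_gene.z_star

    def f(y):
        return one_gene.system.rhs(y + z_star)

    shifted = AutonomousSystem(
        dim=2, rhs=f, jac=lambda y: one_gene.system.jac(y + z_star)
    )
    tab = builtin_tableau("rk4")
    cache = StageExponentialCache(tab, 0.3, one_gene.omega)
    y1 = exprk_step(tab, shifted, one_gene.omega, cache, np.zeros(2), 0.3)
    # only the tiny steady-state residual of z* can enter
    assert np.max(np.abs(y1)) < 1e-13


@pytest.mark.parametrize("name", sorted(BUILTIN_TABLEAUX))
def test_shifted_step_preserves_steady_state(name, all_models):
    for sss in all_models.values():
        tab = builtin_tableau(name)
        h = 0.2
        cache = StageExponentialCache(tab, h, sss.omega)
        z1 = exprk_step_shifted(tab, sss, cache, sss.z_star, h)
        assert np.max(np.abs(z1 - sss.z_star)) < 1e-13


def test_shifted_step_on_linear_system():
    """psi(z) = Omega (z - z*) gives z* + exp(h Omega)(z0 - z*) exactly."""
    lin = make_random_stable_linear_system(3, seed=11)
    omega = lin.omega
    z_star = np.array([1.0, 2.0, -0.5])
    system = AutonomousSystem(
        dim=3, rhs=lambda z: omega @ (z - z_star), jac=lambda z: omega
    )
    from exprk.integrators import SteadyStateSystem

    sss = SteadyStateSystem(system=system, z_star=z_star)
    tab = builtin_tableau("heun")
    h = 0.7
    cache = StageExponentialCache(tab, h, omega)
    z0 = z_star + np.array([0.3, -0.1, 0.2])
    z1 = exprk_step_shifted(tab, sss, cache, z0, h)
    expected = z_star + scipy.linalg.expm(h * omega) @ (z0 - z_star)
    np.testing.assert_allclose(z1, expected, atol=1e-12)


# ---------------------------------------------------------------------
# equivalence with the hand-written one/two-stage exponential formulas


def _shifted_f(sss):
    z_star = sss.z_star
    return lambda y: sss.system.rhs(y + z_star)


def _direct_exp_euler(f, V, y, h):
    E = scipy.linalg.expm(V)
    return E @ y + E @ (h * f(y) - V @ y)


def _fixed_point(update, start, tol=1e-14, max_iter=500):
    y = np.array(start, dtype=float)
    for _ in range(max_iter):
        y_new = update(y)
        if np.max(np.abs(y_new - y)) <= tol:
            return y_new
        y = y_new
    raise AssertionError("direct-form fixed-point iteration did not converge")


def _direct_exp_implicit_euler(f, V, y, h):
    E = scipy.linalg.expm(V)
    return _fixed_point(lambda y1: E @ y + h * f(y1) - V @ y1, E @ y)


def _direct_exp_trapezoid(f, V, y, h):
    E = scipy.linalg.expm(V)
    explicit_part = E @ y + E @ (0.5 * (h * f(y) - V @ y))
    return _fixed_point(
        lambda y1: explicit_part + 0.5 * (h * f(y1) - V @ y1), E @ y
    )


def _direct_exp_heun(f, V, y, h):
    E = scipy.linalg.expm(V)
    yp = E @ y + E @ (h * f(y) - V @ y)
    yc = E @ y + (h * f(yp) - V @ yp)
    return 0.5 * (yp + yc)


def _direct_exp_midpoint(f, V, y, h):
    E = scipy.linalg.expm(V)
    Eh = scipy.linalg.expm(0.5 * V)
    Emh = scipy.linalg.expm(-0.5 * V)

    def update(y1):
        mid = 0.5 * (Eh @ y + Emh @ y1)
        return E @ y + Eh @ (h * f(mid) - V @ mid)

    return _fixed_point(update, E @ y)


DIRECT_FORMS = {
    "euler": _direct_exp_euler,
    "implicit_euler": _direct_exp_implicit_euler,
    "trapezoid": _direct_exp_trapezoid,
    "heun": _direct_exp_heun,
    "midpoint": _direct_exp_midpoint,
}


@pytest.mark.parametrize("name", sorted(DIRECT_FORMS))
def test_generic_construction_matches_direct_formulas(name, one_gene, rng):
    """The tableau-generated scheme equals the written-out exponential rules."""
    tab = builtin_tableau(name)
    h = 0.1
    cache = StageExponentialCache(tab, h, one_gene.omega)
    f = _shifted_f(one_gene)
    jac = lambda y: one_gene.system.jac(y + one_gene.z_star)
    shifted = AutonomousSystem(dim=2, rhs=f, jac=jac)
    for _ in range(10):
        y = rng.uniform(-0.5, 0.5, size=2)
        got = exprk_step(tab, shifted, one_gene.omega, cache, y, h)
        want = DIRECT_FORMS[name](f, cache.V, y, h)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-13)


# ---------------------------------------------------------------------
# integrate & trajectories


def test_integrate_zero_horizon(one_gene):
    traj = integrate("exprk:rk4", one_gene, [0.6, 0.8], 0.25, 0.0)
    assert traj.states.shape == (1, 2)
    np.testing.assert_array_equal(traj.states[0], [0.6, 0.8])


def test_integrate_truncates_partial_final_step(two_gene):
    traj = integrate("exprk:rk4", two_gene, [0.6, 0.8, 0, 0], 1.32, 200.0)
    assert not traj.diverged
    assert traj.times[-1] == pytest.approx(1.32 * 151)
    dt = np.diff(traj.times)
    np.testing.assert_allclose(dt, dt[0])


def test_integrate_converges_to_two_gene_steady_state(two_gene):
    """The slow pair decays as exp(-0.0509 t): close at t=100, settled by t=300."""
    traj = integrate("exprk:rk4", two_gene, [0.6, 0.8, 0, 0], 0.5, 100.0)
    assert np.linalg.norm(traj.final_state - two_gene.z_star) < 1e-2
    traj = integrate("exprk:rk4", two_gene, [0.6, 0.8, 0, 0], 0.5, 300.0)
    assert np.linalg.norm(traj.final_state - two_gene.z_star) < 1e-4


def test_divergence_flagged_not_raised():
    growth = AutonomousSystem(
        dim=1, rhs=lambda y: np.array([y[0] ** 2]), jac=lambda y: np.array([[2 * y[0]]])
    )
    traj = integrate("rk:euler", growth, [1.0], 1.0, 100.0)
    assert traj.diverged
    assert traj.times.shape[0] < 101
    assert np.all(np.isfinite(traj.states))


def test_trajectory_csv_round_trip(tmp_path, one_gene):
    traj = integrate("exprk:euler", one_gene, [0.6, 0.8], 0.5, 5.0)
    path = tmp_path / "traj.csv"
    traj.write_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "t,r,p"
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    np.testing.assert_allclose(data[:, 0], traj.times)
    np.testing.assert_allclose(data[:, 1:], traj.states)


def test_parse_method_aliases():
    assert parse_method("expRK4") == ("exprk", builtin_tableau("rk4"))
    assert parse_method("expRK3/8")[1].name == "rk38"
    assert parse_method("rk:heun") == ("rk", builtin_tableau("heun"))
    assert parse_method("euler") == ("rk", builtin_tableau("euler"))
    with pytest.raises(ValueError):
        parse_method("spectral:rk4")
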