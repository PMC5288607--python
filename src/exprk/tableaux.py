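"""Butcher tableaux of classical Runge-Kutta methods.

A Butcher tableau collects the coefficients (c, A, b) of an s-stage
Runge-Kutta scheme.  In this package every tableau doubles as the
*prototype* of an exponential Runge-Kutta method: the exponential scheme
is generated mechanically from the classical coefficients (see
:mod:`exprk.integrators`), and reduces back to the classical method when
the rate matrix vanishes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "ButcherTableau",
    "builtin_tableau",
    "validate_tableau",
    "BUILTIN_TABLEAUX",
]

_TOL = 1e-12


@dataclass(frozen=True)
class ButcherTableau:
    """Coefficients (c, A, b) of an s-stage Runge-Kutta method.

    Parameters
    ----------
    name:
        Human-readable label, e.g. ``"rk4"``.
    c:
        Abscissae, length ``s``.
    A:
        Stage-coefficient matrix, shape ``(s, s)``.
    b:
        Quadrature weights, length ``s``.
    order:
        Declared algebraic order of the method.
    explicit:
        True iff ``A`` is strictly lower triangular, so the stages can be
        evaluated sequentially without solving nonlinear equations.
    """

    name: str
    c: np.ndarray
    A: np.ndarray
    b: np.ndarray
    order: int
    explicit: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))

    @property
    def s(self) -> int:
        """Number of stages."""
        return self.b.shape[0]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "c": self.c.tolist(),
            "A": self.A.tolist(),
            "b": self.b.tolist(),
            "order": self.order,
            "explicit": self.explicit,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ButcherTableau":
        return cls(
            name=str(d["name"]),
            c=np.asarray(d["c"], dtype=float),
            A=np.asarray(d["A"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            order=int(d["order"]),
            explicit=bool(d["explicit"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "ButcherTableau":
        return cls.from_dict(json.loads(s))


def _f(num: int, den: int = 1) -> float:
    # exact rational -> nearest double
    return float(Fraction(num, den))


def _make_builtins() -> dict[str, ButcherTableau]:
    z = 0.0
    half = _f(1, 2)
    t: dict[str, ButcherTableau] = {}
    t["euler"] = ButcherTableau(
        "euler", [z], [[z]], [1.0], order=1, explicit=True
    )
    t["implicit_euler"] = ButcherTableau(
        "implicit_euler", [1.0], [[1.0]], [1.0], order=1, explicit=False
    )
    t["heun"] = ButcherTableau(
        "heun", [z, 1.0], [[z, z], [1.0, z]], [half, half], order=2, explicit=True
    )
    t["trapezoid"] = ButcherTableau(
        "trapezoid",
        [z, 1.0],
        [[z, z], [half, half]],
        [half, half],
        order=2,
        explicit=False,
    )
    t["midpoint"] = ButcherTableau(
        "midpoint", [half], [[half]], [1.0], order=2, explicit=False
    )
    t["rk38"] = ButcherTableau(
        "rk38",
        [z, _f(1, 3), _f(2, 3), 1.0],
        [
            [z, z, z, z],
            [_f(1, 3), z, z, z],
            [_f(-1, 3), 1.0, z, z],
            [1.0, -1.0, 1.0, z],
        ],
        [_f(1, 8), _f(3, 8), _f(3, 8), _f(1, 8)],
        order=4,
        explicit=True,
    )
    t["rk4"] = ButcherTableau(
        "rk4",
        [z, half, half, 1.0],
        [
            [z, z, z, z],
            [half, z, z, z],
            [z, half, z, z],
            [z, z, 1.0, z],
        ],
        [_f(1, 6), _f(1, 3), _f(1, 3), _f(1, 6)],
        order=4,
        explicit=True,
    )
    return t


BUILTIN_TABLEAUX: dict[str, ButcherTableau] = _make_builtins()


def builtin_tableau(name: str) -> ButcherTableau:
    """Return one of the built-in classical tableaux.

    Recognized names: ``euler``, ``heun``, ``rk38``, ``rk4``,
    ``implicit_euler``, ``trapezoid``, ``midpoint``.
    """
    try:
        return BUILTIN_TABLEAUX[name]
    except KeyError:
        raise ValueError(
            f"unknown tableau {name!r}; available: "
            + ", ".join(sorted(BUILTIN_TABLEAUX))
        ) from None


def _strictly_lower_triangular(A: np.ndarray, tol: float) -> bool:
    return bool(np.all(np.abs(np.triu(A)) <= tol))


def validate_tableau(t: ButcherTableau, tol: float = _TOL) -> list[str]:
    """Check a tableau against its structural invariants.

    Returns a list of human-readable violation descriptions; an empty
    list means the tableau is valid.  Never raises.
    """
    violations: list[str] = []
    s = t.s
    if t.c.shape != (s,):
        violations.append(f"c has shape {t.c.shape}, expected ({s},)")
    if t.A.shape != (s, s):
        violations.append(f"A has shape {t.A.shape}, expected ({s}, {s})")
    if not (
        np.all(np.isfinite(t.c))
        and np.all(np.isfinite(t.A))
        and np.all(np.isfinite(t.b))
    ):
        violations.append("non-finite coefficient")
        return violations
    if abs(t.b.sum() - 1.0) > tol:
        violations.append(f"weights sum != 1 (sum b = {t.b.sum()!r})")
    if t.A.shape == (s, s) and t.c.shape == (s,):
        row_sums = t.A.sum(axis=1)
        if np.max(np.abs(row_sums - t.c)) > tol:
            violations.append("row-sum condition c_i = sum_j a_ij violated")
        if t.explicit != _strictly_lower_triangular(t.A, tol):
            violations.append("explicitness flag inconsistent with A")
    if t.order < 1:
        violations.append(f"declared order {t.order} is not a positive integer")
    return violations
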