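"""Delayed difference-equation model of nightly drinking and desire.

The model couples two state variables observed once per evening: the number
of standard drinks consumed, ``A_n``, and the desire (craving) to drink on a
0-12 composite scale, ``D_n``.  Both respond linearly to the previous night's
levels and to the recent *trend* in drinking::

    D_n = d1*A_{n-1} + d2*D_{n-1} + d3*(A_{n-1} - A_{n-2})
    A_n = a1*(D_n - D_{n-1}) + a2*A_{n-1} + a3*(A_{n-1} - A_{n-2})

Desire is updated first each evening: the drinking equation references the
*same-day* desire change ``D_n - D_{n-1}``, and computing ``D_n`` first is
the only evaluation order that makes the system explicit rather than
simultaneous.

The two-night delay in alcohol means three initial conditions are needed:
``A0`` (the pre-study baseline drinking level, e.g. a 30-day Timeline
Followback average), and ``A1``/``D1`` (the first diary observations).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "InitialConditions",
    "Trajectory",
    "EquilibriumReport",
    "step",
    "simulate",
    "companion_matrix",
    "dominant_eigenvalue_modulus",
    "classify_equilibrium",
    "classify_behavior",
]

PARAM_NAMES = ("a1", "a2", "a3", "d1", "d2", "d3")


@dataclass(frozen=True)
class ModelParameters:
    """The six coefficients of the drinking-desire recursion.

    a1 : drinks tonight per unit same-day change in desire (>= 0)
    a2 : drinks tonight per drink last night (>= 0)
    a3 : drinks tonight per unit change in drinks over two nights (any sign)
    d1 : desire units tonight per drink last night (>= 0)
    d2 : desire units tonight per desire unit last night (>= 0)
    d3 : desire units tonight per unit change in drinks over two nights (any sign)
    """

    a1: float
    a2: float
    a3: float
    d1: float
    d2: float
    d3: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        for name in ("a1", "a2", "d1", "d2"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be nonnegative")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.a1, self.a2, self.a3, self.d1, self.d2, self.d3)

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kwargs: float) -> "ModelParameters":
        d = self.as_dict()
        d.update(kwargs)
        return ModelParameters(**d)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        return cls(**{k: float(d[k]) for k in PARAM_NAMES})

    def to_json(self) -> str:
        return json.dumps(self.as_dict())

    @classmethod
    def from_json(cls, s: str) -> "ModelParameters":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class InitialConditions:
    """Seeds of the recursion.

    A0 : baseline average drinks/day before the diary period (>= 0)
    A1 : drinks on the first diary day (>= 0)
    D1 : desire composite on the first diary day (0-12 scale)
    """

    A0: float
    A1: float
    D1: float

    def __post_init__(self) -> None:
        for name in ("A0", "A1", "D1"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"initial condition {name} must be finite")
        if self.A0 < 0 or self.A1 < 0:
            raise ValueError("A0 and A1 must be nonnegative")
        if not (0.0 <= self.D1 <= 12.0):
            raise ValueError("D1 must lie in the desire composite range [0, 12]")


@dataclass
class Trajectory:
    """A simulated path: A[k], D[k] hold the day-(k+1) values."""

    A: np.ndarray
    D: np.ndarray
    params: ModelParameters
    ics: InitialConditions
    clipped: bool

    @property
    def horizon(self) -> int:
        return len(self.A)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"day": np.arange(1, self.horizon + 1), "A": self.A, "D": self.D}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EquilibriumReport:
    """Steady-state structure of the recursion at a parameter point.

    kind is one of ``E0`` (only the abstinence state (0,0) exists),
    ``E1-line`` (d2 = 1: abstinence with any constant desire level), or
    ``E2-line`` (a2 = 1, d2 != 1: a line of moderated-drinking states with
    D* = d1*A*/(1-d2) for any sustained level A*).
    """

    kind: str
    Astar: float | None
    Dstar: float | None
    note: str

    def dstar_for(self, Astar: float) -> float:
        """Constant desire level paired with a sustained drinking level A*."""
        if self.kind != "E2-line":
            raise ValueError("D* = d1*A*/(1-d2) applies only on the E2 line")
        return self._d1 * Astar / (1.0 - self._d2)  # type: ignore[attr-defined]


def step(
    params: ModelParameters, A_prev: float, A_prev2: float, D_prev: float
) -> tuple[float, float]:
    """One evening update; desire is computed first, then alcohol.

    Returns ``(A_n, D_n)``.
    """
    for v in (A_prev, A_prev2, D_prev):
        if not math.isfinite(v):
            raise ValueError("step requires finite state inputs")
    trend = A_prev - A_prev2
    D_n = params.d1 * A_prev + params.d2 * D_prev + params.d3 * trend
    A_n = params.a1 * (D_n - D_prev) + params.a2 * A_prev + params.a3 * trend
    return A_n, D_n


def simulate(
    params: ModelParameters,
    ics: InitialConditions,
    horizon: int,
    clip_nonneg: bool = False,
) -> Trajectory:
    """Iterate the recursion for ``horizon`` days (day 1 = first diary day).

    With ``clip_nonneg`` each new A and D is floored at zero *before* being
    used in subsequent updates, which keeps long sweeps over wide parameter
    ranges biologically interpretable; calibration uses the raw linear map.
    """
    if horizon < 2:
        raise ValueError(f"horizon must be >= 2, got {horizon}")
    a1, a2, a3, d1, d2, d3 = params.as_tuple()
    A = np.empty(horizon)
    D = np.empty(horizon)
    A[0], D[0] = ics.A1, ics.D1
    a_prev, a_prev2, d_prev = float(ics.A1), float(ics.A0), float(ics.D1)
    for n in range(1, horizon):
        trend = a_prev - a_prev2
        d_n = d1 * a_prev + d2 * d_prev + d3 * trend
        a_n = a1 * (d_n - d_prev) + a2 * a_prev + a3 * trend
        if clip_nonneg:
            if a_n < 0.0:
                a_n = 0.0
            if d_n < 0.0:
                d_n = 0.0
        A[n], D[n] = a_n, d_n
        a_prev2, a_prev, d_prev = a_prev, a_n, d_n
    return Trajectory(A=A, D=D, params=params, ics=ics, clipped=clip_nonneg)


def companion_matrix(params: ModelParameters) -> np.ndarray:
    """Linear map of the stacked state ``(A_n, A_{n-1}, D_n)``.

    Substituting the desire update into the alcohol equation removes the
    same-day coupling, leaving an explicit 3x3 recursion whose spectrum
    governs long-run behavior (all solutions decay to the abstinence state
    iff the spectral radius is below one).
    """
    a1, a2, a3, d1, d2, d3 = params.as_tuple()
    return np.array(
        [
            [a1 * (d1 + d3) + a2 + a3, -(a1 * d3 + a3), a1 * (d2 - 1.0)],
            [1.0, 0.0, 0.0],
            [d1 + d3, -d3, d2],
        ]
    )


def dominant_eigenvalue_modulus(params: ModelParameters) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(params)))))


def classify_equilibrium(
    params: ModelParameters, tol: float = 1e-9
) -> EquilibriumReport:
    """Identify which steady-state family the parameter point admits.

    The abstinence state E0 = (0, 0) always exists.  When d2 = 1 a whole
    line E1 = (0, D*) of abstinent states with constant positive desire
    appears; when a2 = 1 and d2 != 1 a line E2 = (A*, d1*A*/(1-d2)) of
    sustained moderated-drinking states appears, the achieved A* depending
    on initial conditions.
    """
    d2_is_one = abs(params.d2 - 1.0) < tol
    a2_is_one = abs(params.a2 - 1.0) < tol
    if d2_is_one:
        report = EquilibriumReport(
            kind="E1-line",
            Astar=0.0,
            Dstar=None,
            note="d2 = 1: abstinence with any constant desire level D*",
        )
    elif a2_is_one:
        report = EquilibriumReport(
            kind="E2-line",
            Astar=None,
            Dstar=None,
            note=(
                "a2 = 1, d2 != 1: sustained drinking at any level A* with "
                "constant desire D* = d1*A*/(1-d2)"
            ),
        )
    else:
        report = EquilibriumReport(
            kind="none-of-special-cases",
            Astar=0.0,
            Dstar=0.0,
            note="only the abstinence state E0 = (0, 0)",
        )
    # stash coefficients so dstar_for can evaluate the E2 constraint
    object.__setattr__(report, "_d1", params.d1)
    object.__setattr__(report, "_d2", params.d2)
    return report


def classify_behavior(
    params: ModelParameters,
    ics: InitialConditions,
    horizon: int = 84,
    atol: float = 1e-9,
) -> dict:
    """Label the qualitative shape of the simulated alcohol path.

    Returns a dict with ``label`` in {monotone-increasing, monotone-decreasing,
    damped-oscillatory, growing, constant} plus the dominant eigenvalue
    modulus of the companion matrix as an independent linear-theory check.
    Thresholds: oscillation requires >= 2 sign changes in the successive
    differences of A; "growing" means the late-trajectory amplitude exceeds
    the early one (or the path diverges monotonically upward without
    settling).
    """
    if horizon < 10:
        raise ValueError("behavior classification needs horizon >= 10")
    traj = simulate(params, ics, horizon)
    # day 1 is a data-seeded initial condition, not dynamics: classify from day 2
    A = traj.A[1:]
    rho = dominant_eigenvalue_modulus(params)
    diffs = np.diff(A)
    scale = max(np.max(np.abs(A)), 1.0)
    active = diffs[np.abs(diffs) > atol * scale]
    if active.size == 0:
        return {"label": "constant", "dominant_eigenvalue_modulus": rho}
    signs = np.sign(active)
    n_sign_changes = int(np.sum(signs[1:] != signs[:-1]))
    # envelope trend: compare mean absolute deviation from the final value
    # over the first vs last third of the path
    third = max(horizon // 3, 2)
    ref = A[-1]
    early = float(np.mean(np.abs(A[:third] - ref)))
    late = float(np.mean(np.abs(A[-third:] - ref)))
    if n_sign_changes >= 2:
        label = "damped-oscillatory" if (late <= early or rho < 1.0) else "growing"
    else:
        if rho > 1.0 and np.abs(A[-1]) > np.abs(A[0]) + atol * scale:
            label = "growing"
        elif signs[0] > 0:
            label = "monotone-increasing"
        else:
            label = "monotone-decreasing"
    return {"label": label, "dominant_eigenvalue_modulus": rho}
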