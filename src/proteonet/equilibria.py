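"""Closed-form stationary states and stability of the homogeneous system.

The spatially homogeneous limit of the coupled two-protein heterodimer
model is the four-dimensional dynamical system

    du/dt  = a0 - a1*u - a2*u*ut
    dut/dt = -a1t*ut + a2*u*ut
    dv/dt  = b0 - b1*v - b2*v*vt - b3*ut*v*vt
    dvt/dt = -b1t*vt + b2*v*vt + b3*ut*v*vt

with up to four stationary states: the healthy state, a toxic-amyloid
state, a toxic-tau state, and the fully toxic state.  Which of these are
admissible (all components real and nonnegative) is decided by the balance
of clearance inequalities a1t/a2 vs a0/a1 and b1t/b2 vs b0/b1, and — for
the fully toxic state — by the amyloid-tau coupling b3.  This module
evaluates the states in closed form, classifies the regime, and provides
the Jacobian with both closed-form and numerically computed eigenvalues.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

from .params import KineticParams, validate

__all__ = [
    "EquilibriumSet",
    "StabilityReport",
    "RegimeLabel",
    "homogeneous_rhs",
    "stationary_states",
    "classify_regime",
    "jacobian",
    "eigenvalues",
    "tau_gap",
]

#: Relative tolerance at which a clearance inequality counts as an equality
#: (a transcritical boundary — the moment of susceptibility).
BOUNDARY_RTOL = 1e-12


def homogeneous_rhs(p: KineticParams, state) -> np.ndarray:
    """Right-hand side of the homogeneous (well-mixed) system at ``state``."""
    u, ut, v, vt = state
    return np.array(
        [
            p.a0 - p.a1 * u - p.a2 * u * ut,
            -p.a1t * ut + p.a2 * u * ut,
            p.b0 - p.b1 * v - p.b2 * v * vt - p.b3 * ut * v * vt,
            -p.b1t * vt + p.b2 * v * vt + p.b3 * ut * v * vt,
        ]
    )


@dataclass(frozen=True)
class EquilibriumSet:
    """The up-to-four stationary 4-tuples with admissibility flags.

    Attributes
    ----------
    states : tuple of four 4-tuples
        (u_i, ut_i, v_i, vt_i) for i = 1..4 — healthy, toxic-amyloid,
        toxic-tau, fully toxic.  All four are always evaluated; the
        ``admissible`` flags say which are physical.
    admissible : tuple of four bools
        True iff every component of the state is real and >= 0.
    mu : float
        The derived coupling scale mu = a0*b3/b2.
    degenerate : bool
        True when u1 == u2 (the fully toxic state coincides with the limit
        value obtained by l'Hopital's rule, equal to the toxic-tau state).
    """

    states: tuple
    admissible: tuple
    mu: float
    degenerate: bool = False

    def __getitem__(self, index: int):
        """1-based state access: ``eq[1]`` is the healthy state."""
        return self.states[index - 1]


def stationary_states(p: KineticParams) -> EquilibriumSet:
    """Evaluate the four stationary states of the homogeneous system.

    The fully toxic state is computed through the equivalent stable forms
    ``v4 = b1t/(b2 + b3*ut2)`` and ``vt4 = b1*(v1 - v4)/b1t`` (obtained by
    eliminating vt from the tau fixed-point equations), which remain finite
    at the degenerate point u1 == u2 and reduce there to the analytic
    limit vt4 -> b1*(v1 - v3)/b1t.
    """
    bad = validate(p)
    if bad:
        raise ValueError(f"invalid kinetic parameters: {bad}")

    u1 = p.a0 / p.a1
    v1 = p.b0 / p.b1
    u2 = p.a1t / p.a2
    ut2 = p.a1 * (u1 - u2) / p.a1t
    v3 = p.b1t / p.b2
    vt3 = p.b1 * (v1 - v3) / p.b1t
    v4 = p.b1t / (p.b2 + p.b3 * ut2)
    vt4 = p.b1 * (v1 - v4) / p.b1t

    states = (
        (u1, 0.0, v1, 0.0),
        (u2, ut2, v1, 0.0),
        (u1, 0.0, v3, vt3),
        (u2, ut2, v4, vt4),
    )
    admissible = tuple(all(c >= 0 for c in s) for s in states)
    degenerate = abs(u1 - u2) <= BOUNDARY_RTOL * max(abs(u1), abs(u2))
    return EquilibriumSet(
        states=states,
        admissible=admissible,
        mu=p.a0 * p.b3 / p.b2,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class RegimeLabel:
    """Disease-regime classification from the balance-of-clearance ratios.

    ``label`` is one of ``healthy_stable``, ``primary_tauopathy``,
    ``secondary_tauopathy``, ``amyloid_only``, ``tau_only_inadmissible_4``.
    ``amyloid_ratio`` is a1t/a2 (compared against u1 = a0/a1) and
    ``tau_ratio`` is b1t/b2 (against v1 = b0/b1).  ``boundary`` flags mark
    each comparison that is an equality to within relative 1e-12 — the
    transcritical bifurcation point at which the corresponding toxic state
    coincides with the healthy state.
    """

    label: str
    amyloid_ratio: float
    tau_ratio: float
    amyloid_threshold: float
    tau_threshold: float
    boundary: tuple


def classify_regime(p: KineticParams) -> RegimeLabel:
    """Classify the kinetic regime from the clearance inequalities."""
    bad = validate(p)
    if bad:
        raise ValueError(f"invalid kinetic parameters: {bad}")
    u1 = p.a0 / p.a1
    v1 = p.b0 / p.b1
    ra = p.a1t / p.a2
    rb = p.b1t / p.b2
    on_a = abs(ra - u1) <= BOUNDARY_RTOL * max(abs(ra), abs(u1))
    on_b = abs(rb - v1) <= BOUNDARY_RTOL * max(abs(rb), abs(v1))
    a_holds = ra > u1 or on_a  # amyloid clearance inequality holds
    b_holds = rb > v1 or on_b

    if a_holds and b_holds:
        label = "healthy_stable"
    elif not a_holds and not b_holds:
        label = "primary_tauopathy"
    elif not a_holds and b_holds:
        eq = stationary_states(p)
        label = "secondary_tauopathy" if eq.admissible[3] else "amyloid_only"
    else:
        label = "tau_only_inadmissible_4"
    return RegimeLabel(
        label=label,
        amyloid_ratio=ra,
        tau_ratio=rb,
        amyloid_threshold=u1,
        tau_threshold=v1,
        boundary=(on_a, on_b),
    )


def jacobian(p: KineticParams, state) -> np.ndarray:
    """4x4 Jacobian of the homogeneous right-hand side at ``state``."""
    u, ut, v, vt = state
    return np.array(
        [
            [-(p.a2 * ut + p.a1), -p.a2 * u, 0.0, 0.0],
            [p.a2 * ut, p.a2 * u - p.a1t, 0.0, 0.0],
            [
                0.0,
                -p.b3 * v * vt,
                -(p.b2 * vt + p.b1 + p.b3 * ut * vt),
                -p.b2 * v - p.b3 * ut * v,
            ],
            [
                0.0,
                p.b3 * v * vt,
                p.b2 * vt + p.b3 * ut * vt,
                p.b2 * v - p.b1t + p.b3 * ut * v,
            ],
        ]
    )


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalue analysis of one stationary state.

    ``eigen_closed`` holds the closed-form eigenvalue quadruple
    (lambda_amyloid_1, lambda_amyloid_2, lambda_tau_1, lambda_tau_2);
    ``eigen_numeric`` the numerically computed spectrum of the Jacobian.
    ``B``/``C`` and ``Bhat``/``Chat`` are the quadratic helpers of the
    amyloid and tau characteristic polynomials (lambda^2 + B*lambda + C).
    """

    state_index: int
    state: tuple
    jacobian: np.ndarray
    eigen_closed: tuple
    eigen_numeric: tuple
    B: float
    C: float
    Bhat: float
    Chat: float

    @property
    def stable(self) -> bool:
        return all(lam.real < 0 for lam in self.eigen_closed)


def _quadratic_pair(B: float, C: float) -> tuple[complex, complex]:
    disc = cmath.sqrt(B * B - 4.0 * C)
    return (-0.5 * (B + disc), -0.5 * (B - disc))


def eigenvalues(p: KineticParams, state, state_index: int = 0) -> StabilityReport:
    """Closed-form and numeric eigenvalues of the Jacobian at ``state``.

    The one-way amyloid-to-tau coupling makes the Jacobian block
    triangular, so the spectrum splits into an amyloid pair (roots of
    lambda^2 + B*lambda + C) and a tau pair (roots of
    lambda^2 + Bhat*lambda + Chat), where

        B = a1 + a1t + a2*(ut - u)
        C = a2*(a1t*ut - a1*u) + a1t*a1

    and Bhat/Chat are the tau analogues augmented by the coupling terms
    b3*ut*(vt - v) and b3*ut*(b1t*vt - b1*v).  Complex pairs are returned
    as complex numbers; stability is judged on real parts.
    """
    u, ut, v, vt = state
    B = p.a1 + p.a1t + p.a2 * (ut - u)
    C = p.a2 * (p.a1t * ut - p.a1 * u) + p.a1t * p.a1
    Bhat = p.b1 + p.b1t + p.b2 * (vt - v) + p.b3 * ut * (vt - v)
    Chat = p.b2 * (p.b1t * vt - p.b1 * v) + p.b1t * p.b1 + p.b3 * ut * (
        p.b1t * vt - p.b1 * v
    )
    closed = _quadratic_pair(B, C) + _quadratic_pair(Bhat, Chat)
    numeric = tuple(np.linalg.eigvals(jacobian(p, state)))
    return StabilityReport(
        state_index=state_index,
        state=tuple(state),
        jacobian=jacobian(p, state),
        eigen_closed=closed,
        eigen_numeric=numeric,
        B=B,
        C=C,
        Bhat=Bhat,
        Chat=Chat,
    )


def tau_gap(p: KineticParams) -> float:
    """Excess toxic tau sustained by toxic amyloid: vt4 - vt3.

    Only defined in the primary regime, where both the toxic-tau and the
    fully toxic state are admissible.  Evaluated from the closed form

        vt4 - vt3 = a1*b3*b1*(u1 - u2) / (b2*(a1*b3*(u1 - u2) + b2*a1t))

    which is strictly positive whenever u1 > u2 and b3 > 0: the presence
    of toxic amyloid always raises the asymptotic toxic tau level.
    """
    regime = classify_regime(p)
    if regime.label != "primary_tauopathy":
        raise ValueError(
            "tau_gap requires the primary tauopathy regime "
            f"(vt3 is inadmissible in regime {regime.label!r})"
        )
    u1 = p.a0 / p.a1
    u2 = p.a1t / p.a2
    num = p.a1 * p.b3 * p.b1 * (u1 - u2)
    den = p.b2 * (p.a1 * p.b3 * (u1 - u2) + p.b2 * p.a1t)
    return num / den
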