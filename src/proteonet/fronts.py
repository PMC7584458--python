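"""1D traveling-front simulation and the linearized front-speed catalogue.

The continuum model in one dimension supports pulled fronts connecting the
stationary states: the asymptotic speed of each front is the minimum speed
of the linearization about the invaded (unstable) state.  Writing d~1 and
d~2 for the toxic amyloid and toxic tau diffusivities, the closed forms are

    c_beta(1->2) = 2*sqrt(d~1*(a2*a0/a1 - a1t))        (amyloid invasion)
    c_tau(1->3)  = 2*sqrt(d~2*(b2*b0/b1 - b1t))        (tau invasion)
    c_beta(1->4) = c_beta(1->2),  c_tau(1->4) = c_tau(1->3)
    c_tau(2->4)  = 2*sqrt(d~2/(a2*b1*a1t) *
                   [a1t*(a2*(b0*b2 - b1*b1t) - a1*b0*b3) + a0*a2*b0*b3])
    c_beta(3->4) = c_tau(3->4) = c_beta(1->2)          (slaved to amyloid)

A speed is reported only when its radicand is nonnegative — a front between
two states can only develop when both states exist.

The 1D solver is the unit-width special case of the network integrator: a
path lattice with spacing dx has graph-Laplacian weights 1/dx**2, which is
exactly the second-order central-difference stencil with zero-flux
(Neumann) boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import netsim
from .graphs import cubic_lattice
from .params import DamageParams, KineticParams, validate

__all__ = [
    "FrontSpeedTable",
    "Field1D",
    "linear_front_speeds",
    "simulate_1d",
    "measure_front_speed",
]


@dataclass(frozen=True)
class FrontSpeedTable:
    """Closed-form linearized speeds c^(ij) per protein family.

    ``None`` marks a nonexistent front (negative radicand: the target
    state does not exist for these parameters).
    """

    c_beta_12: float | None
    c_tau_12: float
    c_beta_13: float
    c_tau_13: float | None
    c_beta_14: float | None
    c_tau_14: float | None
    c_beta_24: float
    c_tau_24: float | None
    c_beta_34: float | None
    c_tau_34: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _speed(radicand: float) -> float | None:
    """2*sqrt(radicand), or None when the front does not exist."""
    return 2.0 * math.sqrt(radicand) if radicand >= 0 else None


def linear_front_speeds(p: KineticParams) -> FrontSpeedTable:
    """Evaluate the linearized front-speed catalogue for one parameter set."""
    bad = validate(p)
    if bad:
        raise ValueError(f"invalid kinetic parameters: {bad}")
    d1t, d2t = p.rho_ut, p.rho_vt
    c12 = _speed(d1t * (p.a2 * p.a0 / p.a1 - p.a1t))
    c13 = _speed(d2t * (p.b2 * p.b0 / p.b1 - p.b1t))
    bracket = (
        p.a1t * (p.a2 * (p.b0 * p.b2 - p.b1 * p.b1t) - p.a1 * p.b0 * p.b3)
        + p.a0 * p.a2 * p.b0 * p.b3
    )
    c24 = _speed(d2t * bracket / (p.a2 * p.b1 * p.a1t))
    return FrontSpeedTable(
        c_beta_12=c12,
        c_tau_12=0.0,
        c_beta_13=0.0,
        c_tau_13=c13,
        c_beta_14=c12,
        c_tau_14=c13,
        c_beta_24=0.0,
        c_tau_24=c24,
        c_beta_34=c12,
        c_tau_34=c12,
    )


@dataclass
class Field1D:
    """Space-time fields of a 1D simulation on a uniform Neumann grid."""

    x: np.ndarray
    times: np.ndarray
    u: np.ndarray   # each shape (n_times, n_x)
    ut: np.ndarray
    v: np.ndarray
    vt: np.ndarray
    boundary: str = "neumann"
    metadata: dict = field(default_factory=dict)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    def field(self, species: str) -> np.ndarray:
        return getattr(self, species)


def simulate_1d(
    p: KineticParams,
    length: float = 100.0,
    dx: float = 0.1,
    ic=None,
    t_end: float = 100.0,
    t_eval: np.ndarray | None = None,
    damage: DamageParams | None = None,
    **solver_kwargs,
) -> Field1D:
    """Method-of-lines 1D solve with zero-flux (Neumann) boundaries.

    ``ic`` maps the grid ``x`` to initial arrays — either a callable
    ``ic(x) -> dict`` with keys among u/ut/v/vt (missing species start at
    the healthy state) or a dict of arrays/constants.  Defaults to the
    uniform healthy state.  Damage in 1D is supported only with k4 = 0:
    the nonlocal neighbor term has no continuum counterpart.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if damage is not None and damage.k4 != 0:
        raise ValueError("1D damage requires k4 = 0 (nonlocal term is graph-only)")
    n_x = int(round(length / dx)) + 1
    graph = cubic_lattice(n_x, 1, 1, spacing=dx)
    x = np.arange(n_x) * dx

    init = netsim.initial_condition(graph, p)
    given = ic(x) if callable(ic) else (ic or {})
    for species, values in given.items():
        arr = np.broadcast_to(np.asarray(values, dtype=float), (n_x,)).copy()
        if arr.min() < 0:
            raise ValueError(f"initial {species} must be nonnegative")
        setattr(init, species, arr)

    traj = netsim.simulate(
        graph, p, damage, init, t_end, t_eval=t_eval, **solver_kwargs
    )
    return Field1D(
        x=x,
        times=traj.times,
        u=traj.series("u"),
        ut=traj.series("ut"),
        v=traj.series("v"),
        vt=traj.series("vt"),
        metadata={**traj.metadata, "dx": dx, "length": length},
    )


def _crossings(profile: np.ndarray, x: np.ndarray, level: float,
               direction: str) -> float | None:
    """Outermost linearly interpolated crossing of ``level`` along ``x``."""
    above = profile >= level
    idx = np.nonzero(above[:-1] != above[1:])[0]
    if idx.size == 0:
        return None
    i = idx[-1] if direction == "right" else idx[0]
    f = (level - profile[i]) / (profile[i + 1] - profile[i])
    return float(x[i] + f * (x[i + 1] - x[i]))


def measure_front_speed(
    f: Field1D,
    species: str = "ut",
    level: float = 0.5,
    plateau: float | None = None,
    fit_window: tuple[float, float] = (0.2, 0.9),
    direction: str = "right",
) -> tuple[float, float, float]:
    """Empirical front speed from level-crossing positions.

    The front position at each time is the outermost (in the propagation
    ``direction``) linearly interpolated location where the field crosses
    ``level`` times the plateau value (plateau defaults to the overall
    field maximum).  The speed is the least-squares slope of position vs
    time over the central ``fit_window`` fraction of the traversal
    (transients and boundary effects excluded).  Returns
    ``(speed, stderr, r_squared)``.
    """
    prof = f.field(species)
    if plateau is None:
        plateau = float(prof.max())
    threshold = level * plateau
    pos = np.array([
        np.nan if (c := _crossings(prof[k], f.x, threshold, direction)) is None else c
        for k in range(len(f.times))
    ])
    ok = ~np.isnan(pos)
    if ok.sum() < 3:
        raise ValueError("no crossing: the tracked level never crosses the domain")
    t, pos = f.times[ok], pos[ok]
    # restrict to the central portion of the traversal
    span = pos.max() - pos.min()
    if span == 0:
        raise ValueError("no crossing: front position is stationary")
    lo = pos.min() + fit_window[0] * span
    hi = pos.min() + fit_window[1] * span
    sel = (pos >= lo) & (pos <= hi)
    if sel.sum() < 3:
        sel = np.ones_like(pos, dtype=bool)
    t, pos = t[sel], pos[sel]
    (slope, intercept), cov = np.polyfit(t, pos, 1, cov=True)
    fitted = slope * t + intercept
    ss_res = float(np.sum((pos - fitted) ** 2))
    ss_tot = float(np.sum((pos - pos.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(np.sqrt(cov[0, 0])), r2
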