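"""Disease-progression summaries over network trajectories.

Observables reduce a per-node trajectory to brain-wide series and scalar
progression markers: the node-averaged toxic load, the onset time (first
1% global toxic-tau concentration), the saturation time (first approach to
the analytic asymptotic toxic-tau level), and the invasion window — the
interval between the two.  Exponential least-squares fits quantify how the
window shrinks as the amyloid-tau coupling b3 grows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .equilibria import stationary_states
from .netsim import Trajectory
from .params import KineticParams

logger = logging.getLogger(__name__)

__all__ = [
    "LoadSeries",
    "InvasionWindow",
    "toxic_load",
    "asymptotic_vt",
    "invasion_window",
    "saturation_curve",
    "fit_exponential",
]


@dataclass(frozen=True)
class LoadSeries:
    """Node-averaged concentration (and damage) series."""

    times: np.ndarray
    mean_u: np.ndarray
    mean_ut: np.ndarray
    mean_v: np.ndarray
    mean_vt: np.ndarray
    mean_q: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "mean_u": self.mean_u, "mean_ut": self.mean_ut,
            "mean_v": self.mean_v, "mean_vt": self.mean_vt,
            "mean_q": self.mean_q,
        })


def toxic_load(traj: Trajectory) -> LoadSeries:
    """Arithmetic node means of every state variable per output time."""
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    means = traj.data.mean(axis=2)
    return LoadSeries(
        times=traj.times,
        mean_u=means[:, 0], mean_ut=means[:, 1],
        mean_v=means[:, 2], mean_vt=means[:, 3], mean_q=means[:, 4],
    )


def asymptotic_vt(p: KineticParams) -> float:
    """Analytic asymptotic toxic-tau level: the largest admissible vt.

    The fully toxic state dominates whenever admissible (the presence of
    toxic amyloid always raises the tau plateau); otherwise the toxic-tau
    state; zero in the stable-healthy regime.
    """
    eq = stationary_states(p)
    candidates = [eq.states[i][3] for i in (3, 2) if eq.admissible[i]]
    return max(candidates) if candidates else 0.0


def _first_crossing(times: np.ndarray, ys: np.ndarray, level: float) -> float | None:
    """First linearly interpolated time at which ys reaches level."""
    if ys[0] >= level:
        return float(times[0])
    idx = np.nonzero(ys >= level)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    f = (level - ys[i - 1]) / (ys[i] - ys[i - 1])
    return float(times[i - 1] + f * (times[i] - times[i - 1]))


@dataclass(frozen=True)
class InvasionWindow:
    """Onset-to-saturation window of the toxic-tau invasion.

    ``t_onset`` is the first time the mean toxic-tau concentration reaches
    the onset threshold (default 1%, absolute 0.01); ``t_saturation`` the
    first time it reaches ``saturation_fraction`` of the analytic
    asymptote ``vinf``.  ``censored`` marks runs that never saturate
    (``reached_fraction`` reports how far they got).
    """

    t_onset: float | None
    t_saturation: float | None
    vinf: float
    onset_threshold: float
    saturation_fraction: float
    censored: bool = False
    reached_fraction: float = 0.0

    @property
    def duration(self) -> float | None:
        if self.t_onset is None or self.t_saturation is None:
            return None
        return self.t_saturation - self.t_onset


def invasion_window(
    traj: Trajectory,
    p: KineticParams,
    onset: float = 0.01,
    saturation_fraction: float = 0.99,
) -> InvasionWindow:
    """Locate the toxic-tau invasion window of a trajectory.

    Threshold crossings are linearly interpolated on the output grid; the
    asymptote is the analytic stationary value for the active regime, not
    the trajectory maximum.
    """
    load = toxic_load(traj)
    vinf = asymptotic_vt(p)
    if vinf <= 0:
        raise ValueError("no toxic-tau asymptote in this regime (vinf = 0)")
    t_on = _first_crossing(load.times, load.mean_vt, onset)
    t_sat = _first_crossing(load.times, load.mean_vt, saturation_fraction * vinf)
    reached = float(load.mean_vt.max() / vinf)
    if t_sat is None:
        logger.info("saturation not reached (%.1f%% of vinf attained)", 100 * reached)
    return InvasionWindow(
        t_onset=t_on,
        t_saturation=t_sat,
        vinf=vinf,
        onset_threshold=onset,
        saturation_fraction=saturation_fraction,
        censored=t_sat is None,
        reached_fraction=reached,
    )


def saturation_curve(
    traj: Trajectory,
    p: KineticParams,
    normalize: str = "analytic",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean toxic-tau level as a fraction of its plateau.

    ``normalize="analytic"`` divides by the stationary asymptote vinf;
    ``normalize="max"`` divides by the trajectory's own maximum (the
    per-run normalization used when comparing different couplings).
    Values above 1 are reported as computed, with a warning.
    """
    load = toxic_load(traj)
    if normalize == "analytic":
        denom = asymptotic_vt(p)
        if denom <= 0:
            raise ValueError("no toxic-tau asymptote in this regime (vinf = 0)")
    elif normalize == "max":
        denom = float(load.mean_vt.max())
        if denom <= 0:
            raise ValueError("trajectory has no toxic tau")
    else:
        raise ValueError("normalize must be 'analytic' or 'max'")
    frac = load.mean_vt / denom
    if frac.max() > 1 + 1e-6:
        warnings.warn(
            f"saturation fraction exceeds 1 (max {frac.max():.6f})", stacklevel=2
        )
    return load.times, frac


def fit_exponential(
    xs,
    ys,
    offset: bool = True,
) -> tuple[float, float, float, float]:
    """Least-squares fit of y = A*exp(-k*x) + c with k > 0 constrained.

    Returns ``(amplitude, rate, offset, residual_norm)``.  With
    ``offset=False`` the two-parameter form is fitted and c is 0.  Raises
    on fewer than 4 points, on degenerate (constant) data, or on
    non-convergence.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 4:
        raise ValueError("need at least 4 points for an exponential fit")
    if np.ptp(ys) == 0:
        raise ValueError("constant data: decay rate is indeterminate")

    c0 = ys.min() * 0.9 if offset else 0.0
    # log-linear initial guess on the offset-corrected values
    pos = ys - c0 > 0
    if pos.sum() >= 2:
        k0 = max(1e-6, -np.polyfit(xs[pos], np.log(ys[pos] - c0), 1)[0])
    else:
        k0 = 1.0
    A0 = max(ys[0] - c0, 1e-12)

    try:
        if offset:
            def model(x, A, k, c):
                return A * np.exp(-k * x) + c
            popt, _ = curve_fit(
                model, xs, ys, p0=[A0, k0, c0],
                bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            A, k, c = popt
        else:
            def model(x, A, k):
                return A * np.exp(-k * x)
            popt, _ = curve_fit(
                model, xs, ys, p0=[A0, k0],
                bounds=([-np.inf, 1e-12], [np.inf, np.inf]), maxfev=20000,
            )
            (A, k), c = popt, 0.0
    except RuntimeError as err:
        raise RuntimeError(f"exponential fit did not converge: {err}") from err
    residual = float(np.linalg.norm(model(xs, *popt) - ys))
    return float(A), float(k), float(c), residual
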