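"""Three-state hepatocyte model of liver volume recovery after resection.

After a 70% partial hepatectomy (PHx) the remnant liver regrows toward the
pre-surgery liver-to-body-mass set point.  The model tracks the fractions of
hepatocytes that are quiescent (Q), primed (P) and replicating (R), all
expressed relative to the pre-surgery hepatocyte count, so the pre-PHx rest
state is (Q, P, R) = (1, 0, 0) and the immediate post-resection state is
(1 - resection_fraction, 0, 0).

The whole-body demand for liver function is a constant metabolic load ``M``.
With ``N = Q + P + R`` the load carried per remaining cell is ``M / N``; the
excess over baseline, ``S = max(0, M * (1/N - 1))``, is the stimulus that
drives priming and replication through a saturating (Hill) response, and at
high levels also drives cell death, scaled by the death rate constant
``Kcd``.  Relative liver volume is ``(Q + G*(P + R) + epsilon) / (1 +
epsilon)`` where ``G > 1`` accounts for the larger size of primed and
replicating hepatocytes and ``epsilon`` for non-hepatocyte volume.

State equations (rates per hour)::

    sigma = S^h_s / (theta_s^h_s + S^h_s)      # proliferative stimulus
    delta = S^h_d / (theta_d^h_d + S^h_d)      # death drive
    dQ/dt = -k_prime*sigma*Q + k_req*(1-sigma)*P + 2*k_div*R
            - Kcd*alpha_q*delta*Q
    dP/dt =  k_prime*sigma*Q - k_rep*sigma*P - k_req*(1-sigma)*P
            - Kcd*delta*P
    dR/dt =  k_rep*sigma*P - k_div*R - Kcd*delta*R

Division returns two quiescent daughters per replicating cell, so net growth
is ``k_div*R`` and the only loss pathway is the ``Kcd``-scaled death term.
The nuisance constants shipped as defaults were calibrated once (seeded
coarse search, see docs/methods.md) so that the (M, Kcd) landscape shows the
three regeneration modes — healthy (>85% volume at 1 week), suppressed
(40-85%) and failure (<40%) — in the observed arrangement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "CellState",
    "Trajectory",
    "ParameterError",
    "SimulationError",
    "initial_state",
    "derivatives",
    "simulate",
    "rel_volume_of",
    "T_WEEK",
    "T_MAX",
]

logger = logging.getLogger(__name__)

#: evaluation time for the one-week endpoint used throughout (hours)
T_WEEK = 168.0
#: end of the two-week study window (hours)
T_MAX = 336.0
#: total-cell floor below which a trajectory is declared collapsed
COLLAPSE_FLOOR = 1e-6
#: default solver tolerances (adaptive, stiff-capable)
RTOL = 1e-6
ATOL = 1e-9


class ParameterError(ValueError):
    """Raised for invalid model parameters."""


class SimulationError(RuntimeError):
    """Raised when the integrator fails to converge."""


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the regeneration model.

    ``M`` and ``Kcd`` are the two parameters scanned when fitting data; the
    remaining constants are nuisance parameters fixed by calibration.  Rates
    are per hour; ``theta_s``/``theta_d`` are on the scale of the stimulus
    ``S`` and therefore dimensionless.
    """

    M: float = 20.0
    Kcd: float = 0.01
    G: float = 1.295
    epsilon: float = 0.005
    k_prime: float = 0.0856
    k_rep: float = 0.0857
    k_div: float = 0.0193
    k_req: float = 0.934
    theta_s: float = 9.89
    h_s: int = 6
    theta_d: float = 45.0
    h_d: int = 8
    alpha_q: float = 1.0
    resection_fraction: float = 0.70

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "G", "epsilon", "k_prime", "k_rep", "k_div", "k_req",
            "theta_s", "theta_d",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive, "
                                     f"got {getattr(self, name)!r}")
        if self.M < 0:
            raise ParameterError(f"M must be non-negative, got {self.M!r}")
        if self.Kcd < 0:
            raise ParameterError(f"Kcd must be non-negative, got {self.Kcd!r}")
        for name in ("h_s", "h_d"):
            h = getattr(self, name)
            if int(h) != h or h < 1:
                raise ParameterError(f"{name} must be an integer >= 1, got {h!r}")
        if self.alpha_q < 0:
            raise ParameterError(f"alpha_q must be >= 0, got {self.alpha_q!r}")
        if not 0.0 < self.resection_fraction < 1.0:
            raise ParameterError(
                f"resection_fraction must lie in (0, 1), "
                f"got {self.resection_fraction!r}")

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ParameterError(f"parameter file {path} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter keys in {path}: {sorted(unknown)}")
        return cls(**raw)


def default_parameters_path() -> Path:
    """Path of the shipped calibrated parameter file."""
    from importlib import resources

    return Path(str(resources.files("regenfit") / "data"
                    / "default_params.yaml"))


@dataclass(frozen=True)
class CellState:
    """Hepatocyte state fractions at one time point (hours post-PHx)."""

    Q: float
    P: float
    R: float
    t: float

    @property
    def total(self) -> float:
        return self.Q + self.P + self.R


@dataclass(frozen=True)
class Trajectory:
    """Simulated cell-state fractions and relative liver volume over time."""

    times: np.ndarray
    Q: np.ndarray
    P: np.ndarray
    R: np.ndarray
    rel_volume: np.ndarray
    collapsed: bool
    params: ModelParameters

    def states(self) -> list[CellState]:
        return [CellState(q, p, r, t) for q, p, r, t in
                zip(self.Q, self.P, self.R, self.times)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_hours": self.times,
            "Q": self.Q,
            "P": self.P,
            "R": self.R,
            "rel_volume": self.rel_volume,
            "collapsed": np.repeat(self.collapsed, len(self.times)),
        })

    def at(self, t: float) -> float:
        """Relative volume at a reported time (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.times, t, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"time {t} h not among reported times")
        return float(self.rel_volume[idx[0]])


def rel_volume_of(Q, P, R, params: ModelParameters):
    """Relative liver volume (Q + G*(P+R) + epsilon) / (1 + epsilon).

    Normalised so that the intact pre-PHx liver (Q=1, P=R=0) has volume 1.
    """
    return (Q + params.G * (P + R) + params.epsilon) / (1.0 + params.epsilon)


def initial_state(params: ModelParameters) -> CellState:
    """Post-resection state: the remnant fraction, fully quiescent, at t=0."""
    params.validate()
    return CellState(Q=1.0 - params.resection_fraction, P=0.0, R=0.0, t=0.0)


def _hill(S: float, theta: float, h: int) -> float:
    # written as 1/(1 + (theta/S)^h) so large S cannot overflow
    if S <= 0.0:
        return 0.0
    return 1.0 / (1.0 + (theta / S) ** h)


def _rhs(t: float, y, p: ModelParameters):
    Q, P, R = y
    N = Q + P + R
    if N < 1e-12:
        N = 1e-12
    S = p.M * (1.0 / N - 1.0)
    if S < 0.0:
        S = 0.0
    sigma = _hill(S, p.theta_s, p.h_s)
    delta = _hill(S, p.theta_d, p.h_d)
    death = p.Kcd * delta
    dQ = (-p.k_prime * sigma * Q + p.k_req * (1.0 - sigma) * P
          + 2.0 * p.k_div * R - death * p.alpha_q * Q)
    dP = (p.k_prime * sigma * Q - p.k_rep * sigma * P
          - p.k_req * (1.0 - sigma) * P - death * P)
    dR = p.k_rep * sigma * P - p.k_div * R - death * R
    return (dQ, dP, dR)


def derivatives(state: CellState, params: ModelParameters):
    """Instantaneous rates (dQ/dt, dP/dt, dR/dt) at a given state.

    Exposed separately so the reduced system can be inspected or swapped for
    a richer equation set with the same state structure.
    """
    if min(state.Q, state.P, state.R) < 0:
        raise ParameterError("cell-state fractions must be non-negative")
    return _rhs(state.t, (state.Q, state.P, state.R), params)


def _collapse_event(t, y, p):
    return y[0] + y[1] + y[2] - COLLAPSE_FLOOR


_collapse_event.terminal = True
_collapse_event.direction = -1


def simulate(
    params: ModelParameters,
    t_eval: Sequence[float],
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the model from the post-resection state.

    ``t_eval`` must be non-empty, increasing and within [0, 336] hours.  A
    trajectory whose total cell fraction falls below ``COLLAPSE_FLOOR`` is
    declared collapsed; reported values from that point on are held at the
    organ-free floor ``epsilon / (1 + epsilon)`` so downstream likelihoods
    stay finite.
    """
    t = np.asarray(t_eval, dtype=float)
    if t.size == 0:
        raise ValueError("t_eval must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    if t[0] < 0.0 or t[-1] > T_MAX:
        raise ValueError(f"t_eval must lie within [0, {T_MAX}] hours")
    params.validate()

    y0 = (1.0 - params.resection_fraction, 0.0, 0.0)
    t_end = float(t[-1]) if t[-1] > 0 else 1.0
    sol = solve_ivp(
        _rhs, (0.0, t_end), y0, t_eval=t[t <= t_end], method="LSODA",
        rtol=rtol, atol=atol, args=(params,), events=_collapse_event,
    )
    if sol.status == -1:
        raise SimulationError(
            f"integration failed at M={params.M}, Kcd={params.Kcd}: "
            f"{sol.message}")

    n = t.size
    Q = np.zeros(n)
    P = np.zeros(n)
    R = np.zeros(n)
    k = sol.y.shape[1]
    Q[:k], P[:k], R[:k] = sol.y
    # clip solver-scale negatives to zero at report time
    np.clip(Q, 0.0, None, out=Q)
    np.clip(P, 0.0, None, out=P)
    np.clip(R, 0.0, None, out=R)
    collapsed = sol.status == 1 or bool((Q + P + R).min() < COLLAPSE_FLOOR)
    rel = rel_volume_of(Q, P, R, params)
    if k < n:  # collapsed before the end: hold at the organ-free floor
        floor = params.epsilon / (1.0 + params.epsilon)
        rel[k:] = floor
        Q[k:] = P[k:] = R[k:] = 0.0
    if collapsed:
        logger.debug("trajectory collapsed at M=%g, Kcd=%g",
                     params.M, params.Kcd)
    return Trajectory(times=t, Q=Q, P=P, R=R, rel_volume=rel,
                      collapsed=collapsed, params=params)
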