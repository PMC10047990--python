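"""Entropy, KL divergence, and their exact rates along the replicator flow.

Substituting the replicator equation into the chain rule gives closed-form
rates for the two information observables:

    S(p)   = -sum_i p_i ln p_i
    dS/dt  = -sum_i (f_i - <f>) p_i ln p_i

    I(q,p) = sum_i q_i ln(q_i / p_i)          (target q fixed)
    dI/dt  = -sum_i (f_i - <f>) q_i = sum_i f_i (p_i - q_i)

``I(q, p(t))`` acts as a Lyapunov function of the flow: toward a dominant
target it decreases monotonically, and for zero-sum games around an interior
equilibrium it is conserved.  :func:`lyapunov_analysis` measures both
behaviors on a computed trajectory.

All logarithms are natural (units: nats); probabilities below ``prob_floor``
are floored inside logs and the limit ``0 ln 0 = 0`` is applied in entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FitnessModel, SolverSettings, StateDistribution, Trajectory
from .errors import DimensionMismatch, SupportMismatch

__all__ = [
    "shannon_entropy",
    "entropy_rate",
    "kl_divergence",
    "kl_rate",
    "lyapunov_analysis",
    "LyapunovReport",
    "DEFAULT_PROB_FLOOR",
]

DEFAULT_PROB_FLOOR = SolverSettings().prob_floor


def _as_probs(p: StateDistribution | np.ndarray) -> np.ndarray:
    return p.probs if isinstance(p, StateDistribution) else np.asarray(p, float)


def _floored_log(x: np.ndarray, floor: float) -> np.ndarray:
    return np.log(np.maximum(x, floor))


def shannon_entropy(p: StateDistribution | np.ndarray) -> float:
    """Shannon entropy ``-sum p_i ln p_i`` in nats; ``0 ln 0 = 0``."""
    x = _as_probs(p)
    mask = x > 0.0
    return float(-np.sum(x[mask] * np.log(x[mask])))


def entropy_rate(
    p: StateDistribution,
    fitness: FitnessModel,
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> float:
    """Exact entropy rate ``-sum (f_i - <f>) p_i ln p_i`` along the flow."""
    x = _as_probs(p)
    f = fitness.evaluate(x)
    return float(-np.sum((f - x @ f) * x * _floored_log(x, prob_floor)))


def kl_divergence(
    q: StateDistribution,
    p: StateDistribution,
    prob_floor: float = DEFAULT_PROB_FLOOR,
    strict_support: bool = False,
) -> float:
    """Relative information ``I(q,p) = sum_i q_i ln(q_i / p_i)`` in nats.

    Non-negative; zero iff ``q == p``.  Where ``q_i > 0`` but ``p_i`` has
    fallen below ``prob_floor`` the divergence is effectively infinite; with
    ``strict_support=True`` this raises
    :class:`~biocontinuum.errors.SupportMismatch`, otherwise ``inf`` is
    returned.
    """
    qx, px = _as_probs(q), _as_probs(p)
    if qx.size != px.size:
        raise DimensionMismatch(f"q has {qx.size} entries, p has {px.size}")
    support = qx > 0.0
    if np.any(support & (px < prob_floor)):
        if strict_support:
            raise SupportMismatch(
                "q has mass where p vanishes; I(q,p) is infinite"
            )
        return float("inf")
    qs, ps = qx[support], px[support]
    return max(float(np.sum(qs * (np.log(qs) - np.log(ps)))), 0.0)


def kl_rate(
    q: StateDistribution, p: StateDistribution, fitness: FitnessModel
) -> float:
    """Exact rate ``dI(q, p(t))/dt = sum_i f_i(p) (p_i - q_i)`` (nats/time)."""
    qx, px = _as_probs(q), _as_probs(p)
    if qx.size != px.size:
        raise DimensionMismatch(f"q has {qx.size} entries, p has {px.size}")
    f = fitness.evaluate(px)
    return float(f @ (px - qx))


@dataclass(frozen=True)
class LyapunovReport:
    """Monotonicity/conservation diagnosis of ``I(q, p(t))`` on a grid.

    ``monotone_nonincreasing`` holds when no step increases I by more than
    the step tolerance; ``conserved`` when I never strays from its initial
    value by more than the conservation tolerance.
    """

    monotone_nonincreasing: bool
    max_positive_increment: float
    conserved: bool
    final_I: float
    initial_I: float
    max_drift: float


def lyapunov_analysis(
    traj: Trajectory,
    q: StateDistribution,
    step_tolerance: float = 1e-7,
    conservation_tolerance: float = 1e-6,
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> LyapunovReport:
    """Evaluate ``I(q, p(t))`` along a trajectory and classify its behavior."""
    if traj.n_times < 2:
        raise ValueError("need at least 2 trajectory points")
    I = np.array([kl_divergence(q, s, prob_floor=prob_floor) for s in traj.states])
    increments = np.diff(I)
    max_pos = max(float(increments.max(initial=0.0)), 0.0)
    drift = float(np.max(np.abs(I - I[0])))
    return LyapunovReport(
        monotone_nonincreasing=bool(max_pos <= step_tolerance),
        max_positive_increment=max_pos,
        conserved=bool(drift <= conservation_tolerance),
        final_I=float(I[-1]),
        initial_I=float(I[0]),
        max_drift=drift,
    )
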