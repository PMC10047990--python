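"""Information geometry of the biocontinuum.

Two statistical manifolds are equipped with their Fisher information metrics:

* the categorical simplex, with the Shahshahani metric ``g_ij = delta_ij / p_i``
  acting on tangent vectors that sum to zero;
* the 2-d Gaussian family in ``(mu, sigma)`` coordinates, with
  ``g = diag(1/sigma^2, 2/sigma^2)`` — the hyperbolic half-plane up to a
  factor, which yields the closed-form Fisher-Rao geodesic distance

      d = sqrt(2) * arccosh(1 + ((mu_a-mu_b)^2/2 + (sigma_a-sigma_b)^2)
                                 / (2 sigma_a sigma_b)).

Both metrics are the second-order expansion of the KL divergence,
``KL(x || x + delta) ~= 1/2 delta^T g(x) delta``, which the test suite checks
numerically.  Natural-gradient descent ``x <- x - step * g(x)^{-1} grad V(x)``
realizes the landscape flow picture: objectives built from KL divergences are
descended along the geometry the divergence itself induces.  For symmetric
payoff matrices the replicator flow is itself a Shahshahani natural-gradient
ascent of the potential ``1/2 p^T A p``, checked by
:func:`replicator_is_natural_gradient_check`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .core import FitnessModel, Scenario, StateDistribution
from .errors import (
    AsymmetricPayoff,
    BoundaryPoint,
    NonPositiveSigma,
    StalledFlow,
)
from .infodynamics import DEFAULT_PROB_FLOOR

__all__ = [
    "ManifoldPoint",
    "MetricTensor",
    "FlowPath",
    "gaussian_fisher_metric",
    "simplex_fisher_metric",
    "gaussian_geodesic_distance",
    "gaussian_kl",
    "natural_gradient_flow",
    "replicator_is_natural_gradient_check",
    "PotentialAscentReport",
]


@dataclass(frozen=True)
class ManifoldPoint:
    """A point (mu, sigma) on the Gaussian statistical manifold; sigma > 0.

    ``sigma`` is the standard deviation, in the same (arbitrary) units as the
    location ``mu``.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0.0:
            raise NonPositiveSigma(f"sigma must be positive, got {self.sigma!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.sigma], dtype=float)


@dataclass(frozen=True)
class MetricTensor:
    """A symmetric positive-definite metric on the relevant tangent space."""

    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError(f"metric must be square, got shape {g.shape}")
        if not np.allclose(g, g.T, rtol=0, atol=1e-12):
            raise ValueError("metric must be symmetric")
        g = g.copy()
        g.setflags(write=False)
        object.__setattr__(self, "g", g)

    def quadratic_form(self, v: Sequence[float]) -> float:
        v = np.asarray(v, dtype=float)
        return float(v @ self.g @ v)


def gaussian_fisher_metric(x: ManifoldPoint) -> MetricTensor:
    """Fisher metric ``diag(1/sigma^2, 2/sigma^2)`` in (mu, sigma) coordinates."""
    s2 = x.sigma * x.sigma
    return MetricTensor(np.diag([1.0 / s2, 2.0 / s2]))


def simplex_fisher_metric(
    p: StateDistribution, prob_floor: float = DEFAULT_PROB_FLOOR
) -> MetricTensor:
    """Shahshahani metric ``diag(1/p_i)`` for interior simplex points.

    Valid on tangent vectors summing to zero; boundary points (any coordinate
    below ``prob_floor``) are rejected.
    """
    if np.any(p.probs < prob_floor):
        raise BoundaryPoint(
            "simplex Fisher metric is undefined at the boundary; "
            f"min p_i = {p.probs.min():g}"
        )
    return MetricTensor(np.diag(1.0 / p.probs))


def gaussian_kl(a: ManifoldPoint, b: ManifoldPoint) -> float:
    """KL divergence KL(N(mu_a, sigma_a^2) || N(mu_b, sigma_b^2)) in nats."""
    r = a.sigma / b.sigma
    return float(
        np.log(b.sigma / a.sigma)
        + 0.5 * (r * r + ((a.mu - b.mu) / b.sigma) ** 2 - 1.0)
    )


def gaussian_geodesic_distance(a: ManifoldPoint, b: ManifoldPoint) -> float:
    """Fisher-Rao geodesic distance between two univariate Gaussians.

    Uses the Poincare half-plane closed form (the manifold is the half-plane
    with curvature -1/2 after rescaling mu by sqrt(2)).
    """
    num = 0.5 * (a.mu - b.mu) ** 2 + (a.sigma - b.sigma) ** 2
    arg = 1.0 + num / (2.0 * a.sigma * b.sigma)
    return float(np.sqrt(2.0) * np.arccosh(max(arg, 1.0)))


@dataclass(frozen=True)
class FlowPath:
    """Iterates of a natural-gradient flow with their objective values."""

    points: tuple
    objective_values: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.points) - 1

    def final(self):
        return self.points[-1]


def _numerical_gradient(
    objective: Callable[[np.ndarray], float], x: np.ndarray, rel_h: float = 1e-6
) -> np.ndarray:
    """Central-difference gradient with relative step ``h = rel_h * max(1,|x|)``."""
    grad = np.empty_like(x)
    for i in range(x.size):
        h = rel_h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        grad[i] = (objective(xp) - objective(xm)) / (2.0 * h)
    return grad


_MAX_HALVINGS = 30
_GRAD_FLAT_TOL = 1e-9  # gradient norms below this count as a stationary point
_STALL_GRAD_TOL = 1e-6  # stalls with gradients below this count as converged


def _simplex_retract(p: np.ndarray, floor: float) -> np.ndarray:
    p = np.clip(p, floor, None)
    return p / p.sum()


def natural_gradient_flow(
    objective: Callable[[np.ndarray], float],
    start: Union[ManifoldPoint, StateDistribution],
    step: float,
    n_steps: int,
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> FlowPath:
    """Descend ``objective`` by the Fisher natural gradient from ``start``.

    The update is ``x <- x - step * g(x)^{-1} grad objective(x)`` with the
    metric of the manifold ``start`` lives on; gradients are central
    differences of the user objective (called with a coordinate array:
    ``[mu, sigma]`` or the probability vector).  Simplex iterates are
    retracted onto the interior simplex each step.  A step that fails to
    decrease the objective is halved (backtracking, at most 30 halvings);
    when even the minimum step cannot decrease a non-flat objective,
    :class:`~biocontinuum.errors.StalledFlow` is raised.  At a stationary
    point (vanishing gradient) the flow simply stops early.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step!r}")
    on_simplex = isinstance(start, StateDistribution)
    x = start.probs.copy() if on_simplex else start.as_array()

    def pack(arr: np.ndarray):
        return StateDistribution(arr) if on_simplex else ManifoldPoint(*arr)

    points = [pack(x)]
    values = [float(objective(x))]
    for _ in range(n_steps):
        grad = _numerical_gradient(objective, x)
        if on_simplex:
            # Shahshahani natural gradient projected onto the tangent space:
            # (g^{-1} grad)_i = p_i grad_i, minus the component off the simplex.
            direction = x * (grad - x @ grad)
        else:
            s2 = x[1] * x[1]
            direction = np.array([s2 * grad[0], 0.5 * s2 * grad[1]])
        if np.linalg.norm(grad) < _GRAD_FLAT_TOL:
            break  # stationary point: flat objective or converged
        trial_step = step
        for _halving in range(_MAX_HALVINGS + 1):
            cand = x - trial_step * direction
            if on_simplex:
                cand = _simplex_retract(cand, prob_floor)
            elif cand[1] <= 0.0:
                trial_step *= 0.5
                continue
            cand_val = float(objective(cand))
            if cand_val <= values[-1]:
                break
            trial_step *= 0.5
        else:
            # Round-off dominates near a minimum: a tiny residual gradient
            # with no decreasing step means the flow has converged to working
            # precision.  A sizable gradient with no decrease is a real stall.
            if np.linalg.norm(grad) < _STALL_GRAD_TOL:
                break
            raise StalledFlow(
                f"no decreasing step found after {_MAX_HALVINGS} halvings "
                f"(objective {values[-1]:g}, |grad| {np.linalg.norm(grad):g})"
            )
        if np.array_equal(cand, x):
            break  # retraction pinned the iterate; no further progress
        x = cand
        points.append(pack(x))
        values.append(cand_val)
    return FlowPath(points=tuple(points), objective_values=np.array(values))


@dataclass(frozen=True)
class PotentialAscentReport:
    """Monotonicity of the potential ``1/2 p^T A p`` along a replicator run."""

    monotone_nondecreasing: bool
    min_increment: float
    potential_series: np.ndarray
    times: np.ndarray


def replicator_is_natural_gradient_check(
    payoff: np.ndarray,
    p0: StateDistribution,
    t_span: tuple[float, float],
    n_points: int = 201,
    per_step_tolerance: float = 1e-9,
) -> PotentialAscentReport:
    """Verify the gradient-flow character of the replicator dynamics.

    For a symmetric payoff ``A`` the replicator equation is the natural
    gradient ascent of ``V(p) = 1/2 p^T A p`` in the Shahshahani metric, so
    ``V`` must be non-decreasing along any simulated trajectory.
    """
    A = np.asarray(payoff, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise AsymmetricPayoff(f"payoff must be square, got shape {A.shape}")
    if not np.allclose(A, A.T, rtol=0.0, atol=1e-12):
        raise AsymmetricPayoff("payoff matrix is not symmetric")
    from .replicator import simulate

    scen = Scenario(
        fitness=FitnessModel.linear(A), p0=p0, t_span=t_span, n_points=n_points
    )
    traj = simulate(scen)
    X = traj.state_matrix()
    V = 0.5 * np.einsum("ti,ij,tj->t", X, A, X)
    increments = np.diff(V)
    min_inc = float(increments.min(initial=0.0))
    return PotentialAscentReport(
        monotone_nondecreasing=bool(min_inc >= -per_step_tolerance),
        min_increment=min_inc,
        potential_series=V,
        times=traj.times.copy(),
    )
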