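"""Replicator and Lotka-Volterra dynamics on the biocontinuum simplex.

The population share ``p_i`` of each type grows at its fitness excess over the
population mean:

    dp_i/dt = (f_i(p) - <f(p)>) p_i,     <f(p)> = sum_j p_j f_j(p).

Equivalently, unnormalized abundances follow the Lotka-Volterra form
``dP_i/dt = f_i P_i``; dividing by the total recovers the replicator flow
(quotient rule), which :func:`simulate_lv_normalized` verifies numerically.

For a constant fitness vector the flow has the exact solution

    p_i(t) = p_i(0) e^{f_i t} / sum_j p_j(0) e^{f_j t},

exposed as :func:`constant_fitness_closed_form` and used as the oracle for the
numerical integrator.  Fisher's fundamental theorem — the rate of increase of
mean fitness equals the fitness variance — holds along these trajectories for
constant fitness and is checked in the test suite by finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import logsumexp

from .core import (
    FitnessModel,
    PopulationState,
    Scenario,
    StateDistribution,
    Trajectory,
    normalize_population,
)
from .errors import DimensionMismatch, IntegrationFailure, SingularSystem

__all__ = [
    "mean_fitness",
    "fitness_variance",
    "replicator_rhs",
    "lotka_volterra_rhs",
    "simulate",
    "simulate_lv_normalized",
    "constant_fitness_closed_form",
    "find_equilibria",
    "EquilibriumReport",
]


def _as_probs(p: StateDistribution | np.ndarray) -> np.ndarray:
    return p.probs if isinstance(p, StateDistribution) else np.asarray(p, float)


def mean_fitness(p: StateDistribution, fitness: FitnessModel) -> float:
    """Mean population fitness ``<f(p)> = sum_i p_i f_i(p)`` (1/time)."""
    x = _as_probs(p)
    return float(x @ fitness.evaluate(x))


def fitness_variance(p: StateDistribution, fitness: FitnessModel) -> float:
    """Population variance of fitness ``sum p_i f_i^2 - (sum p_i f_i)^2``."""
    x = _as_probs(p)
    f = fitness.evaluate(x)
    m = x @ f
    # guard round-off below zero for (near-)constant landscapes
    return max(float(x @ (f * f) - m * m), 0.0)


def replicator_rhs(p: StateDistribution | np.ndarray, fitness: FitnessModel) -> np.ndarray:
    """Right-hand side ``(f_i(p) - <f(p)>) p_i`` of the replicator equation."""
    x = _as_probs(p)
    f = fitness.evaluate(x)
    return (f - x @ f) * x


def lotka_volterra_rhs(
    P: PopulationState | np.ndarray, fitness: FitnessModel
) -> np.ndarray:
    """Right-hand side ``f_i(p) P_i`` of the Lotka-Volterra growth equation.

    Frequency-dependent fitness is evaluated at the normalized state
    ``p = P / sum(P)``.
    """
    counts = P.counts if isinstance(P, PopulationState) else np.asarray(P, float)
    x = counts / counts.sum()
    return fitness.evaluate(x) * counts


def _project_simplex(y: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and renormalize: repair round-off drift off the simplex."""
    y = np.clip(y, 0.0, 1.0)
    return y / y.sum()


def _integrate(
    rhs, y0: np.ndarray, scenario: Scenario
) -> tuple[np.ndarray, np.ndarray]:
    s = scenario.solver
    sol = solve_ivp(
        rhs,
        scenario.t_span,
        y0,
        method="DOP853",
        t_eval=scenario.times,
        rtol=s.rtol,
        atol=s.atol,
        max_step=s.max_step,
    )
    if not sol.success:
        raise IntegrationFailure(
            f"solver failed over t_span={scenario.t_span}: {sol.message}"
        )
    return sol.t, sol.y.T


def simulate(scenario: Scenario) -> Trajectory:
    """Integrate the replicator flow and record its information observables.

    Returns a :class:`~biocontinuum.core.Trajectory` sampled on the scenario's
    uniform time grid; every reported state is projected back onto the simplex.
    The observable table carries ``S``, ``S_dot``, ``mean_fitness`` and
    ``fitness_variance`` always, plus ``I_qp``, ``I_dot`` and ``lagrangian``
    when the scenario defines a target ``q``.
    """

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        x = _project_simplex(y)
        f = scenario.fitness.evaluate(x)
        return (f - x @ f) * x

    times, raw = _integrate(rhs, scenario.p0.probs, scenario)
    states = tuple(StateDistribution(_project_simplex(y)) for y in raw)
    from .observables import observable_table  # deferred: avoids import cycle

    table = observable_table(states, scenario.fitness, scenario.q, scenario.solver)
    return Trajectory(times=times, states=states, observables=table)


def simulate_lv_normalized(scenario: Scenario, P0: PopulationState) -> Trajectory:
    """Integrate the Lotka-Volterra abundances and normalize each state.

    ``normalize(P0)`` must equal the scenario's ``p0``.  To keep abundances in
    floating range over long horizons the integration works with ``log P_i``
    (shifted each step so the largest is 0), which leaves the normalized state
    unchanged — the same overflow guard as rescaling counts by their sum.
    """
    if not normalize_population(P0).isclose(scenario.p0, atol=1e-9):
        raise ValueError("normalize_population(P0) must equal scenario.p0")

    # d(log P_i)/dt = f_i(p); p depends only on log-differences, so working in
    # log space is exact and immune to overflow.
    def rhs(_t: float, logP: np.ndarray) -> np.ndarray:
        z = logP - logsumexp(logP)
        x = _project_simplex(np.exp(z))
        return scenario.fitness.evaluate(x)

    times, raw = _integrate(rhs, np.log(P0.counts), scenario)
    states = tuple(
        StateDistribution(_project_simplex(np.exp(row - logsumexp(row))))
        for row in raw
    )
    from .observables import observable_table

    table = observable_table(states, scenario.fitness, scenario.q, scenario.solver)
    return Trajectory(times=times, states=states, observables=table)


def constant_fitness_closed_form(
    p0: StateDistribution, f: np.ndarray, t: float
) -> StateDistribution:
    """Exact replicator solution for constant fitness (exponential weighting).

    ``p_i(t) = p_i(0) e^{f_i t} / sum_j p_j(0) e^{f_j t}``, computed in log
    space for stability at large ``t``.
    """
    f = np.asarray(f, dtype=float)
    if f.size != p0.n:
        raise DimensionMismatch(f"fitness has {f.size} entries, p0 has {p0.n}")
    with np.errstate(divide="ignore"):
        logw = np.log(p0.probs)  # -inf on zero entries is intended
    logw = logw + f * t
    w = np.exp(logw - logsumexp(logw[np.isfinite(logw)]))
    return StateDistribution(w / w.sum())


@dataclass(frozen=True)
class EquilibriumReport:
    """Fixed points of the replicator flow ``p_i (f_i - <f>) = 0``.

    ``kinds`` classifies each point as a simplex ``vertex``, an ``interior``
    point (full support) or a ``face`` point.  ``neutral`` flags a landscape
    on which every state is fixed; ``singular`` flags a linear system with no
    unique interior solution.
    """

    points: tuple[StateDistribution, ...]
    kinds: tuple[str, ...]
    residuals: tuple[float, ...]
    neutral: bool = False
    singular: bool = False


def _residual(p: StateDistribution, fitness: FitnessModel) -> float:
    return float(np.max(np.abs(replicator_rhs(p, fitness))))


def find_equilibria(fitness: FitnessModel, n: int) -> EquilibriumReport:
    """Vertices plus, for linear fitness, the interior equalized-fitness point.

    Every vertex is a fixed point.  For a payoff matrix ``A`` an interior
    equilibrium solves ``(A p)_i = phi`` for all ``i`` with ``sum p_i = 1``;
    the linear solve either yields a unique candidate (kept when strictly
    inside the simplex) or the system is singular and flagged.  Constant
    fitness admits no interior equilibrium unless all entries tie, in which
    case the whole simplex is fixed and the report is flagged neutral.
    """
    if fitness.kind not in ("constant", "linear"):
        raise ValueError("equilibrium finding supports constant or linear fitness")
    if fitness.n is not None and fitness.n != n:
        raise DimensionMismatch(f"fitness is for {fitness.n} types, asked for {n}")

    points: list[StateDistribution] = []
    kinds: list[str] = []
    for i in range(n):
        v = np.zeros(n)
        v[i] = 1.0
        points.append(StateDistribution(v))
        kinds.append("vertex")

    neutral = False
    singular = False
    if fitness.kind == "constant":
        neutral = bool(np.ptp(fitness.f_const) < 1e-12)
    else:
        A = fitness.payoff
        # Unknowns (p_1..p_n, phi): A p - phi 1 = 0, 1^T p = 1.
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = A
        M[:n, n] = -1.0
        M[n, :n] = 1.0
        b = np.zeros(n + 1)
        b[n] = 1.0
        try:
            if np.linalg.matrix_rank(M) < n + 1:
                raise SingularSystem("no unique interior equilibrium")
            sol = np.linalg.solve(M, b)
            p_int = sol[:n]
            if np.all(p_int > 1e-10):
                points.append(StateDistribution(p_int / p_int.sum()))
                kinds.append("interior")
        except SingularSystem:
            singular = True

    residuals = tuple(_residual(p, fitness) for p in points)
    return EquilibriumReport(
        points=tuple(points),
        kinds=tuple(kinds),
        residuals=residuals,
        neutral=neutral,
        singular=singular,
    )
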