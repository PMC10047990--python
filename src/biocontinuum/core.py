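"""Domain types shared by every module: simplex states, fitness landscapes,
scenarios and trajectories.

The central object is a probability distribution ``p`` over the ``n`` discrete
state types of the biocontinuum — a point on the (n-1)-simplex.  A
:class:`FitnessModel` assigns each type a growth rate ``f_i(p)`` (possibly
frequency dependent), and a :class:`Scenario` bundles everything needed to
integrate the replicator flow and evaluate its information observables.

Conventions adopted throughout the package:

* probabilities exactly 0 are legal states, but every logarithm evaluates
  ``max(p_i, prob_floor)`` and entropy sums apply the limit ``0 ln 0 = 0``;
* after each solver output the state is clipped to ``[0, 1]`` and renormalized,
  since adaptive steppers drift off the simplex at round-off level;
* the number of types ``n >= 2`` is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DimensionMismatch,
    NegativeProbability,
    NonPositiveCount,
    NotNormalized,
)

__all__ = [
    "StateDistribution",
    "PopulationState",
    "FitnessModel",
    "SolverSettings",
    "Scenario",
    "Trajectory",
    "validate_distribution",
    "normalize_population",
    "register_fitness_function",
    "get_fitness_function",
    "OBSERVABLE_COLUMNS",
]

#: Columns of the per-time observable table attached to a Trajectory.
OBSERVABLE_COLUMNS = (
    "S",
    "S_dot",
    "I_qp",
    "I_dot",
    "lagrangian",
    "mean_fitness",
    "fitness_variance",
)

_NEG_TOL = 1e-12  # entries below -1e-12 are rejected as negative
_SUM_TOL = 1e-6  # |sum - 1| beyond this is rejected as unnormalized


@dataclass(frozen=True)
class StateDistribution:
    """A point on the probability simplex: fractions of each biocontinuum type.

    Parameters
    ----------
    probs
        Length-``n`` vector of non-negative reals summing to 1 (``n >= 2``).
    labels
        Optional names for the state types.
    """

    probs: np.ndarray
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size < 2:
            raise DimensionMismatch(
                f"a state distribution needs a 1-d vector of length >= 2, "
                f"got shape {probs.shape}"
            )
        if np.any(probs < -_NEG_TOL):
            raise NegativeProbability(
                f"negative probability entries: {probs[probs < -_NEG_TOL]}"
            )
        total = probs.sum()
        if abs(total - 1.0) > _SUM_TOL:
            raise NotNormalized(f"probabilities sum to {total!r}, expected 1")
        # Forgive round-off: clip tiny negatives and renormalize — but only
        # when actually off, so validation is exactly idempotent.
        if np.any(probs < 0.0):
            probs = np.clip(probs, 0.0, None)
            total = probs.sum()
        if abs(total - 1.0) > 1e-14:
            probs = probs / total
        else:
            probs = probs.copy()
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != probs.size:
                raise DimensionMismatch(
                    f"{len(labels)} labels for {probs.size} types"
                )
            object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.probs.size

    def __len__(self) -> int:
        return self.probs.size

    def isclose(self, other: "StateDistribution", atol: float = 1e-12) -> bool:
        return self.n == other.n and bool(
            np.allclose(self.probs, other.probs, rtol=0.0, atol=atol)
        )


@dataclass(frozen=True)
class PopulationState:
    """Unnormalized abundances ``P_i > 0`` of each type (Lotka-Volterra state)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 2:
            raise DimensionMismatch(
                f"a population state needs a 1-d vector of length >= 2, "
                f"got shape {counts.shape}"
            )
        if np.any(counts <= 0.0) or not np.all(np.isfinite(counts)):
            raise NonPositiveCount(f"all counts must be positive finite, got {counts}")
        counts = counts.copy()
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return self.counts.size


def validate_distribution(
    v: Sequence[float] | np.ndarray, labels: Optional[Sequence[str]] = None
) -> StateDistribution:
    """Validate a raw vector as a point on the simplex.

    Accepts round-off deviations (entries down to ``-1e-12``, sums within
    ``1e-6`` of one) and renormalizes them away; anything worse raises
    :class:`~biocontinuum.errors.NegativeProbability` or
    :class:`~biocontinuum.errors.NotNormalized`.
    """
    return StateDistribution(np.asarray(v, dtype=float), labels=tuple(labels) if labels else None)


def normalize_population(P: PopulationState | Sequence[float]) -> StateDistribution:
    """Map abundances to probability fractions ``p_i = P_i / sum_j P_j``."""
    if not isinstance(P, PopulationState):
        P = PopulationState(np.asarray(P, dtype=float))
    return StateDistribution(P.counts / P.counts.sum())


# --- fitness models ---------------------------------------------------------

_CUSTOM_FITNESS_REGISTRY: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_fitness_function(
    name: str, fn: Callable[[np.ndarray], np.ndarray]
) -> None:
    """Register a named frequency-dependent fitness map ``p -> f(p)``.

    Registered names are referable from scenario JSON (``kind: custom``).
    """
    _CUSTOM_FITNESS_REGISTRY[name] = fn


def get_fitness_function(name: str) -> Callable[[np.ndarray], np.ndarray]:
    try:
        return _CUSTOM_FITNESS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no fitness function registered under {name!r}; "
            f"known: {sorted(_CUSTOM_FITNESS_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class FitnessModel:
    """The fitness landscape ``f_i(p)`` over the biocontinuum types.

    Three kinds are supported:

    ``constant``
        ``f_i(p) = c_i`` independent of the state (vector ``f_const``).
    ``linear``
        ``f_i(p) = (A p)_i`` for an ``n x n`` payoff matrix ``A``.
    ``custom``
        a registered function name mapping the state vector to fitnesses.

    Units of fitness are 1/time.
    """

    kind: str
    f_const: Optional[np.ndarray] = None
    payoff: Optional[np.ndarray] = None
    custom_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.f_const is None:
                raise ValueError("kind='constant' requires f_const")
            f = np.asarray(self.f_const, dtype=float)
            if f.ndim != 1:
                raise DimensionMismatch("f_const must be a vector")
            f = f.copy()
            f.setflags(write=False)
            object.__setattr__(self, "f_const", f)
        elif self.kind == "linear":
            if self.payoff is None:
                raise ValueError("kind='linear' requires a payoff matrix")
            A = np.asarray(self.payoff, dtype=float)
            if A.ndim != 2 or A.shape[0] != A.shape[1]:
                raise DimensionMismatch(
                    f"payoff must be square, got shape {A.shape}"
                )
            A = A.copy()
            A.setflags(write=False)
            object.__setattr__(self, "payoff", A)
        elif self.kind == "custom":
            if self.custom_name is None:
                raise ValueError("kind='custom' requires custom_name")
        else:
            raise ValueError(f"unknown fitness kind {self.kind!r}")

    @classmethod
    def constant(cls, f: Sequence[float]) -> "FitnessModel":
        return cls(kind="constant", f_const=np.asarray(f, dtype=float))

    @classmethod
    def linear(cls, payoff: Sequence[Sequence[float]]) -> "FitnessModel":
        return cls(kind="linear", payoff=np.asarray(payoff, dtype=float))

    @classmethod
    def custom(cls, name: str) -> "FitnessModel":
        get_fitness_function(name)  # fail fast on unknown names
        return cls(kind="custom", custom_name=name)

    @property
    def n(self) -> Optional[int]:
        """Number of types the model is pinned to, or None for custom maps."""
        if self.kind == "constant":
            return self.f_const.size
        if self.kind == "linear":
            return self.payoff.shape[0]
        return None

    def evaluate(self, p: StateDistribution | np.ndarray) -> np.ndarray:
        """Per-type fitness vector at the (normalized) state ``p``."""
        x = p.probs if isinstance(p, StateDistribution) else np.asarray(p, float)
        if self.kind == "constant":
            if self.f_const.size != x.size:
                raise DimensionMismatch(
                    f"fitness has {self.f_const.size} entries, state has {x.size}"
                )
            return self.f_const.copy()
        if self.kind == "linear":
            if self.payoff.shape[0] != x.size:
                raise DimensionMismatch(
                    f"payoff is {self.payoff.shape}, state has {x.size} entries"
                )
            return self.payoff @ x
        f = np.asarray(get_fitness_function(self.custom_name)(x), dtype=float)
        if f.shape != x.shape:
            raise DimensionMismatch(
                f"custom fitness returned shape {f.shape} for state of "
                f"shape {x.shape}"
            )
        return f


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs for the integrator and for log evaluation.

    ``prob_floor`` is the smallest probability substituted inside logarithms,
    keeping entropy and KL observables finite near the simplex boundary.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    prob_floor: float = 1e-12
    max_step: float = np.inf

    def __post_init__(self) -> None:
        for name in ("rtol", "atol", "prob_floor"):
            val = getattr(self, name)
            if not (0.0 < val < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {val!r}")
        if self.max_step <= 0:
            raise ValueError(f"max_step must be positive, got {self.max_step!r}")


@dataclass(frozen=True)
class Scenario:
    """A complete simulation setup.

    Parameters
    ----------
    fitness
        The fitness landscape.
    p0
        Initial state on the simplex.
    q
        Optional fixed target distribution; when present, the KL observables
        ``I(q, p(t))``, ``dI/dt`` and the Lagrangian are recorded.
    t_span
        Integration window ``(t0, t1)`` with ``t1 > t0``.
    n_points
        Size of the uniform output grid (``>= 2``).
    """

    fitness: FitnessModel
    p0: StateDistribution
    t_span: tuple[float, float]
    n_points: int = 201
    q: Optional[StateDistribution] = None
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        t0, t1 = self.t_span
        if not t1 > t0:
            raise ValueError(f"t_span must satisfy t1 > t0, got {self.t_span}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.fitness.n is not None and self.fitness.n != self.p0.n:
            raise DimensionMismatch(
                f"fitness is for {self.fitness.n} types, p0 has {self.p0.n}"
            )
        if self.q is not None and self.q.n != self.p0.n:
            raise DimensionMismatch(
                f"target q has {self.q.n} types, p0 has {self.p0.n}"
            )
        object.__setattr__(self, "t_span", (float(t0), float(t1)))

    @property
    def n(self) -> int:
        return self.p0.n

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t_span[0], self.t_span[1], self.n_points)


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed states plus their information observables.

    ``observables`` is a DataFrame with one row per output time and the
    columns in :data:`OBSERVABLE_COLUMNS` — Shannon entropy ``S`` (nats), its
    rate ``S_dot`` (nats/time), the KL divergence ``I_qp`` from the target and
    its rate ``I_dot`` (NaN when no target was given), the Lagrangian
    integrand, the mean fitness ``<f>`` and the fitness variance.
    """

    times: np.ndarray
    states: tuple[StateDistribution, ...]
    observables: pd.DataFrame

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size != len(self.states):
            raise DimensionMismatch(
                f"{times.size} times for {len(self.states)} states"
            )
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.observables) != times.size:
            raise DimensionMismatch(
                f"observable table has {len(self.observables)} rows "
                f"for {times.size} times"
            )
        missing = [c for c in OBSERVABLE_COLUMNS if c not in self.observables]
        if missing:
            raise ValueError(f"observable table lacks columns {missing}")
        times = times.copy()
        times.setflags(write=False)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def n(self) -> int:
        return self.states[0].n

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def has_target(self) -> bool:
        return bool(np.isfinite(self.observables["I_qp"]).any())

    def state_matrix(self) -> np.ndarray:
        """All states stacked as an ``(n_times, n)`` array."""
        return np.vstack([s.probs for s in self.states])

    def final_state(self) -> StateDistribution:
        return self.states[-1]
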