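"""Scenario JSON and trajectory CSV serialization, random fixtures, library.

Scenario documents are JSON objects::

    {"n": 2,
     "fitness": {"kind": "constant", "f_const": [1.0, 0.0]},
     "p0": [0.5, 0.5],
     "q": [1.0, 0.0],            # optional / null
     "t_span": [0.0, 10.0],
     "n_points": 201,
     "solver": {"rtol": 1e-8, "atol": 1e-10,
                "prob_floor": 1e-12, "max_step": null}}

Trajectories are CSV files with header ``t,p_1..p_n,S,S_dot,I_qp,I_dot,
lagrangian,mean_fitness,fitness_variance``; KL columns are empty when the
scenario had no target.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    OBSERVABLE_COLUMNS,
    FitnessModel,
    Scenario,
    SolverSettings,
    StateDistribution,
    Trajectory,
    validate_distribution,
)
from .errors import FormatError, SchemaError

__all__ = [
    "read_scenario",
    "write_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "write_trajectory",
    "read_trajectory",
    "generate_random_scenario",
    "scenario_library",
    "ScenarioLibraryEntry",
]

PathLike = Union[str, Path]


def _require(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise SchemaError(f"scenario field {field!r}: {msg}")


def scenario_from_dict(doc: dict) -> Scenario:
    """Build a Scenario from a parsed JSON document, with field-level errors."""
    _require(isinstance(doc, dict), "<root>", "must be a JSON object")
    _require("n" in doc, "n", "missing")
    n = doc["n"]
    _require(isinstance(n, int) and n >= 2, "n", f"must be an integer >= 2, got {n!r}")

    fit_doc = doc.get("fitness")
    _require(isinstance(fit_doc, dict), "fitness", "must be an object")
    kind = fit_doc.get("kind")
    _require(
        kind in ("constant", "linear", "custom"),
        "fitness.kind",
        f"must be constant|linear|custom, got {kind!r}",
    )
    try:
        if kind == "constant":
            f = fit_doc.get("f_const")
            _require(
                isinstance(f, list) and len(f) == n,
                "fitness.f_const",
                f"must be a list of {n} numbers",
            )
            fitness = FitnessModel.constant(f)
        elif kind == "linear":
            A = fit_doc.get("payoff")
            _require(
                isinstance(A, list)
                and len(A) == n
                and all(isinstance(r, list) and len(r) == n for r in A),
                "fitness.payoff",
                f"must be an {n}x{n} matrix",
            )
            fitness = FitnessModel.linear(A)
        else:
            name = fit_doc.get("name")
            _require(isinstance(name, str), "fitness.name", "must be a string")
            fitness = FitnessModel.custom(name)
    except KeyError as exc:
        raise SchemaError(f"scenario field 'fitness.name': {exc}") from exc

    _require("p0" in doc, "p0", "missing")
    _require(
        isinstance(doc["p0"], list) and len(doc["p0"]) == n,
        "p0",
        f"must be a list of {n} probabilities",
    )
    try:
        p0 = validate_distribution(doc["p0"])
    except ValueError as exc:
        raise SchemaError(f"scenario field 'p0': {exc}") from exc

    q: Optional[StateDistribution] = None
    if doc.get("q") is not None:
        _require(
            isinstance(doc["q"], list) and len(doc["q"]) == n,
            "q",
            f"must be a list of {n} probabilities or null",
        )
        try:
            q = validate_distribution(doc["q"])
        except ValueError as exc:
            raise SchemaError(f"scenario field 'q': {exc}") from exc

    t_span = doc.get("t_span")
    _require(
        isinstance(t_span, list) and len(t_span) == 2,
        "t_span",
        "must be a [t0, t1] pair",
    )
    t0, t1 = float(t_span[0]), float(t_span[1])
    _require(t1 > t0, "t_span", f"needs t1 > t0, got {t_span}")

    n_points = doc.get("n_points", 201)
    _require(
        isinstance(n_points, int) and n_points >= 2,
        "n_points",
        f"must be an integer >= 2, got {n_points!r}",
    )

    solver_doc = doc.get("solver") or {}
    _require(isinstance(solver_doc, dict), "solver", "must be an object")
    kwargs = {}
    for key in ("rtol", "atol", "prob_floor", "max_step"):
        if solver_doc.get(key) is not None:
            kwargs[key] = float(solver_doc[key])
    try:
        solver = SolverSettings(**kwargs)
    except ValueError as exc:
        raise SchemaError(f"scenario field 'solver': {exc}") from exc

    return Scenario(
        fitness=fitness, p0=p0, q=q, t_span=(t0, t1), n_points=n_points, solver=solver
    )


def scenario_to_dict(scenario: Scenario) -> dict:
    """Canonical JSON-ready dict (stable key order, plain lists)."""
    fit = scenario.fitness
    if fit.kind == "constant":
        fitness_doc = {"kind": "constant", "f_const": fit.f_const.tolist()}
    elif fit.kind == "linear":
        fitness_doc = {"kind": "linear", "payoff": fit.payoff.tolist()}
    else:
        fitness_doc = {"kind": "custom", "name": fit.custom_name}
    s = scenario.solver
    return {
        "n": scenario.n,
        "fitness": fitness_doc,
        "p0": scenario.p0.probs.tolist(),
        "q": scenario.q.probs.tolist() if scenario.q is not None else None,
        "t_span": [scenario.t_span[0], scenario.t_span[1]],
        "n_points": scenario.n_points,
        "solver": {
            "rtol": s.rtol,
            "atol": s.atol,
            "prob_floor": s.prob_floor,
            "max_step": None if math.isinf(s.max_step) else s.max_step,
        },
    }


def read_scenario(path: PathLike) -> Scenario:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return scenario_from_dict(doc)


def write_scenario(scenario: Scenario, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(scenario_to_dict(scenario), fh, indent=2)
        fh.write("\n")


# --- trajectory CSV ---------------------------------------------------------


def _trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    n = traj.n
    df = pd.DataFrame({"t": traj.times})
    X = traj.state_matrix()
    for i in range(n):
        df[f"p_{i + 1}"] = X[:, i]
    for col in OBSERVABLE_COLUMNS:
        df[col] = traj.observables[col].to_numpy()
    return df


def write_trajectory(traj: Trajectory, path: PathLike) -> None:
    """Write the trajectory CSV; absent KL observables become empty fields."""
    df = _trajectory_frame(traj)
    df.to_csv(path, index=False, float_format="%.15g", na_rep="")


def read_trajectory(path: PathLike) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: malformed trajectory CSV ({exc})") from exc
    cols = list(df.columns)
    p_cols = [c for c in cols if c.startswith("p_")]
    expected = ["t"] + p_cols + list(OBSERVABLE_COLUMNS)
    if cols != expected or not p_cols:
        raise FormatError(
            f"{path}: header mismatch; expected t,p_1..p_n,"
            f"{','.join(OBSERVABLE_COLUMNS)}, got {','.join(cols)}"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: empty trajectory")
    states = tuple(
        StateDistribution(row) for row in df[p_cols].to_numpy(dtype=float)
    )
    obs = df[list(OBSERVABLE_COLUMNS)].astype(float).reset_index(drop=True)
    return Trajectory(
        times=df["t"].to_numpy(dtype=float), states=states, observables=obs
    )


# --- random fixtures --------------------------------------------------------

RANDOM_KINDS = ("constant", "linear-symmetric", "linear-zero-sum")


def generate_random_scenario(
    n: int,
    kind: str,
    seed: int,
    t_span: tuple[float, float] = (0.0, 5.0),
    n_points: int = 201,
    with_target: bool = False,
) -> Scenario:
    """Seeded random scenario for fixtures: same seed, same scenario.

    ``p0`` (and the optional target ``q``) are flat-Dirichlet draws; constant
    fitness has standard-normal entries; payoff matrices are symmetrized
    ``(A + A^T)/2`` or antisymmetrized ``(A - A^T)/2`` standard-normal draws.
    """
    if kind not in RANDOM_KINDS:
        raise ValueError(f"kind must be one of {RANDOM_KINDS}, got {kind!r}")
    rng = np.random.default_rng(seed)
    p0 = StateDistribution(rng.dirichlet(np.ones(n)))
    if kind == "constant":
        fitness = FitnessModel.constant(rng.standard_normal(n))
    else:
        A = rng.standard_normal((n, n))
        A = (A + A.T) / 2.0 if kind == "linear-symmetric" else (A - A.T) / 2.0
        fitness = FitnessModel.linear(A)
    q = StateDistribution(rng.dirichlet(np.ones(n))) if with_target else None
    return Scenario(fitness=fitness, p0=p0, q=q, t_span=t_span, n_points=n_points)


# --- shipped scenario library ----------------------------------------------


@dataclass(frozen=True)
class ScenarioLibraryEntry:
    name: str
    scenario: Scenario
    description: str


def scenario_library() -> dict[str, ScenarioLibraryEntry]:
    """Small named library of canonical study scenarios."""
    entries = [
        ScenarioLibraryEntry(
            name="two_type_selection",
            scenario=Scenario(
                fitness=FitnessModel.constant([1.0, 0.0]),
                p0=validate_distribution([0.5, 0.5]),
                q=validate_distribution([1.0, 0.0]),
                t_span=(0.0, 10.0),
                n_points=501,
            ),
            description=(
                "Two types under constant selection (fitness gap 1/time); "
                "the fitter type fixates and I(q, p) decays to zero."
            ),
        ),
        ScenarioLibraryEntry(
            name="neutral",
            scenario=Scenario(
                fitness=FitnessModel.constant([1.0, 1.0, 1.0]),
                p0=validate_distribution([0.2, 0.3, 0.5]),
                t_span=(0.0, 10.0),
                n_points=101,
            ),
            description="Equal fitness: every state is stationary.",
        ),
        ScenarioLibraryEntry(
            name="rock_paper_scissors",
            scenario=Scenario(
                fitness=FitnessModel.linear(
                    [[0.0, -1.0, 1.0], [1.0, 0.0, -1.0], [-1.0, 1.0, 0.0]]
                ),
                p0=validate_distribution([0.5, 0.3, 0.2]),
                q=validate_distribution([1 / 3, 1 / 3, 1 / 3]),
                t_span=(0.0, 50.0),
                n_points=2001,
            ),
            description=(
                "Zero-sum rock-paper-scissors; orbits circle the interior "
                "equilibrium and I(q, p) is a conserved quantity."
            ),
        ),
        ScenarioLibraryEntry(
            name="potential_game",
            scenario=Scenario(
                fitness=FitnessModel.linear(
                    [[1.0, 0.2, 0.0], [0.2, 2.0, 0.1], [0.0, 0.1, 0.5]]
                ),
                p0=validate_distribution([0.4, 0.2, 0.4]),
                t_span=(0.0, 20.0),
                n_points=401,
            ),
            description=(
                "Symmetric payoff (partnership game): the flow is a "
                "Shahshahani natural-gradient ascent of 1/2 p^T A p."
            ),
        ),
    ]
    return {e.name: e for e in entries}
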