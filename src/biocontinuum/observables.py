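"""Assemble the per-time observable table attached to trajectories."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import OBSERVABLE_COLUMNS, FitnessModel, SolverSettings, StateDistribution
from .infodynamics import entropy_rate, kl_divergence, kl_rate, shannon_entropy
from .replicator import fitness_variance, mean_fitness

__all__ = ["observable_table"]


def observable_table(
    states: Sequence[StateDistribution],
    fitness: FitnessModel,
    q: Optional[StateDistribution],
    solver: Optional[SolverSettings] = None,
) -> pd.DataFrame:
    """Evaluate S, S_dot, I_qp, I_dot, lagrangian, <f> and Var(f) per state.

    The KL-based columns are NaN when no target ``q`` is given.
    """
    floor = (solver or SolverSettings()).prob_floor
    rows = np.empty((len(states), len(OBSERVABLE_COLUMNS)))
    for k, s in enumerate(states):
        S = shannon_entropy(s)
        S_dot = entropy_rate(s, fitness, prob_floor=floor)
        mf = mean_fitness(s, fitness)
        var = fitness_variance(s, fitness)
        if q is not None:
            I = kl_divergence(q, s, prob_floor=floor)
            I_dot = kl_rate(q, s, fitness)
            lag = I_dot - I
        else:
            I = I_dot = lag = np.nan
        rows[k] = (S, S_dot, I, I_dot, lag, mf, var)
    return pd.DataFrame(rows, columns=list(OBSERVABLE_COLUMNS))
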