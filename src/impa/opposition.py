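"""Opposition-based learning (OBL).

The opposite of a point y in the box [lb, ub] is the mirror image
lb + ub - y.  Evaluating each candidate's opposite and keeping the
fitter of the pair probes the search region symmetric to the current
population and speeds convergence when the initial population landed
far from the optimum.  Opposition is applied in the same coordinate
system the optimizer moves in, so log-scaled dimensions are reflected
on the exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OppositionContext", "opposite", "opposite_population", "greedy_merge"]

_TOL = 1e-9


@dataclass(frozen=True)
class OppositionContext:
    """Static reflection bounds (the search-space box, not the population's extent)."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if lb.shape != ub.shape:
            raise ValueError("lb and ub must have the same shape")
        if not np.all(lb < ub):
            raise ValueError("lb must be elementwise < ub")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def m(self) -> int:
        """Dimensionality of the reflected space."""
        return self.lb.size


def opposite(position: np.ndarray, ctx: OppositionContext) -> np.ndarray:
    """Elementwise mirror image lb + ub - position."""
    position = np.asarray(position, dtype=float)
    tol = _TOL * np.maximum(1.0, np.abs(ctx.ub - ctx.lb))
    if np.any(position < ctx.lb - tol) or np.any(position > ctx.ub + tol):
        raise ValueError("position lies outside the opposition bounds")
    return ctx.lb + ctx.ub - position


def opposite_population(prey: np.ndarray, ctx: OppositionContext) -> np.ndarray:
    """Rowwise opposite of a population matrix; shape preserved."""
    prey = np.asarray(prey, dtype=float)
    return np.vstack([opposite(row, ctx) for row in prey]) if prey.ndim == 2 else opposite(prey, ctx)


def greedy_merge(
    prey: np.ndarray,
    fitness: np.ndarray,
    opp: np.ndarray,
    opp_fitness: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per row keep the lower-fitness of (original, opposite); ties keep the original."""
    prey = np.asarray(prey, dtype=float)
    opp = np.asarray(opp, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    opp_fitness = np.asarray(opp_fitness, dtype=float)
    if prey.shape != opp.shape or fitness.shape != opp_fitness.shape:
        raise ValueError("population and opposite arrays must be aligned by row")
    if fitness.shape[0] != prey.shape[0]:
        raise ValueError("fitness length must match the number of rows")
    take_opp = opp_fitness < fitness
    merged = np.where(take_opp[:, None], opp, prey)
    merged_fit = np.where(take_opp, opp_fitness, fitness)
    return merged, merged_fit
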