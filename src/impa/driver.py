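"""Optimization drivers: IMPA, plain MPA, random search, and a comparison harness.

IMPA = the marine predators loop seeded and refined with opposition-based
learning.  One run executes:

1. uniform initialization and evaluation (N evaluations);
2. opposite population, evaluation, greedy merge (N evaluations);
3. for each iteration: velocity-phase update by iteration third,
   evaluation, memory save, Elite update; FADs perturbation, evaluation,
   memory save, Elite update; per-iteration OBL (opposite population,
   evaluation, greedy merge), Elite update.

The per-iteration budget is therefore 3N and the total N(3 it_max + 2);
plain MPA skips both OBL applications for N(2 it_max + 1).  Evaluation
accounting is asserted at the end of every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from impa.mpa_core import (
    OptimizerConfig,
    PopulationState,
    compute_cf,
    fads_perturbation,
    memory_save,
    phase1_update,
    phase2_update,
    phase3_update,
    phase_of_iteration,
    update_elite,
)
from impa.opposition import OppositionContext, greedy_merge, opposite_population
from impa.search_space import SearchSpace, clamp, sample_uniform

__all__ = [
    "ObjectiveAdapter",
    "OptResult",
    "run_impa",
    "run_mpa",
    "run_random_search",
    "compare_optimizers",
    "OPTIMIZERS",
]


class ObjectiveAdapter:
    """Wraps a position -> fitness callable with direction and eval accounting.

    The optimizer minimizes internally; ``direction="maximize"``
    objectives are negated at this boundary.
    """

    def __init__(self, fn: Callable[[np.ndarray], float], direction: str = "minimize"):
        if direction not in ("minimize", "maximize"):
            raise ValueError(f"direction must be minimize or maximize, got {direction!r}")
        self._fn = fn
        self.direction = direction
        self.eval_count = 0

    def evaluate(self, position: np.ndarray) -> float:
        self.eval_count += 1
        val = float(self._fn(np.asarray(position, dtype=float)))
        return -val if self.direction == "maximize" else val

    def evaluate_matrix(self, positions: np.ndarray, context: str = "") -> np.ndarray:
        out = np.empty(positions.shape[0])
        for i, row in enumerate(positions):
            try:
                out[i] = self.evaluate(row)
            except Exception as exc:  # re-raise with run context
                raise RuntimeError(
                    f"objective evaluation failed at {context or 'unknown step'}, row {i}"
                ) from exc
        return out


@dataclass
class OptResult:
    """Outcome of one optimizer run."""

    best_position: np.ndarray
    best_fitness: float
    convergence: list[float]
    total_evaluations: int
    seed: int
    config: OptimizerConfig | None = None
    optimizer: str = ""

    def convergence_frame(self) -> pd.DataFrame:
        """Per-iteration best-so-far trace as (iteration, best_fitness, evaluations)."""
        n = self.config.n_agents if self.config is not None else 0
        per_iter = 3 * n if self.optimizer == "impa" else 2 * n
        init = 2 * n if self.optimizer == "impa" else n
        evals = [init + per_iter * (i + 1) for i in range(len(self.convergence))]
        if self.optimizer == "random":
            evals = list(range(1, len(self.convergence) + 1))
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.convergence) + 1),
                "best_fitness": self.convergence,
                "evaluations": evals,
            }
        )


def _init_state(
    objective: ObjectiveAdapter,
    space: SearchSpace,
    config: OptimizerConfig,
    rng: np.random.Generator,
    use_obl: bool,
) -> PopulationState:
    ctx = OppositionContext(*space.bounds())
    prey = sample_uniform(space, config.n_agents, rng)
    fitness = objective.evaluate_matrix(prey, "initialization")
    if use_obl:
        opp = opposite_population(prey, ctx)
        opp_fit = objective.evaluate_matrix(opp, "opposition init")
        prey, fitness = greedy_merge(prey, fitness, opp, opp_fit)
    i = int(np.argmin(fitness))
    return PopulationState(
        prey=prey.copy(),
        fitness=fitness.copy(),
        best_position=prey[i].copy(),
        best_fitness=float(fitness[i]),
        prev_prey=prey.copy(),
        prev_fitness=fitness.copy(),
    )


def _run_mpa_loop(
    objective: ObjectiveAdapter,
    space: SearchSpace,
    config: OptimizerConfig,
    use_obl: bool,
) -> OptResult:
    rng = np.random.default_rng(config.seed)
    lb, ub = space.bounds()
    ctx = OppositionContext(lb, ub)
    state = _init_state(objective, space, config, rng, use_obl)
    start_evals = objective.eval_count
    expected_init = config.n_agents * (2 if use_obl else 1)
    convergence: list[float] = []

    for it in range(1, config.it_max + 1):
        phase = phase_of_iteration(it, config.it_max)
        if phase == 1:
            new_prey = phase1_update(state, config.p, rng)
        elif phase == 2:
            new_prey = phase2_update(
                state, it, config.it_max, config.p, rng, config.levy_exponent
            )
        else:
            new_prey = phase3_update(
                state, it, config.it_max, config.p, rng, config.levy_exponent
            )
        state.prey = clamp(new_prey, space)
        state.fitness = objective.evaluate_matrix(state.prey, f"iteration {it} phase {phase}")
        memory_save(state)
        update_elite(state)

        cf = compute_cf(it, config.it_max)
        state.prey = clamp(
            fads_perturbation(state.prey, cf, config.fads, lb, ub, rng), space
        )
        state.fitness = objective.evaluate_matrix(state.prey, f"iteration {it} FADs")
        memory_save(state)
        update_elite(state)

        if use_obl:
            opp = opposite_population(state.prey, ctx)
            opp_fit = objective.evaluate_matrix(opp, f"iteration {it} opposition")
            state.prey, state.fitness = greedy_merge(
                state.prey, state.fitness, opp, opp_fit
            )
            state.prev_prey = state.prey.copy()
            state.prev_fitness = state.fitness.copy()
            update_elite(state)

        convergence.append(state.best_fitness)

    per_iter = config.n_agents * (3 if use_obl else 2)
    total = objective.eval_count
    expected = start_evals + per_iter * config.it_max
    assert total == expected, f"evaluation accounting mismatch: {total} != {expected}"
    assert start_evals == expected_init

    return OptResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        convergence=convergence,
        total_evaluations=total,
        seed=config.seed,
        config=config,
        optimizer="impa" if use_obl else "mpa",
    )


def run_impa(
    objective: ObjectiveAdapter, space: SearchSpace, config: OptimizerConfig
) -> OptResult:
    """Run the opposition-enhanced marine predators algorithm."""
    return _run_mpa_loop(objective, space, config, use_obl=True)


def run_mpa(
    objective: ObjectiveAdapter, space: SearchSpace, config: OptimizerConfig
) -> OptResult:
    """Run the original marine predators algorithm (no opposition steps)."""
    return _run_mpa_loop(objective, space, config, use_obl=False)


def run_random_search(
    objective: ObjectiveAdapter, space: SearchSpace, budget: int, seed: int
) -> OptResult:
    """Best of ``budget`` uniform samples; the no-structure baseline."""
    if budget < 1:
        raise ValueError(f"budget must be >= 1, got {budget}")
    rng = np.random.default_rng(seed)
    samples = sample_uniform(space, budget, rng)
    fitness = objective.evaluate_matrix(samples, "random search")
    best_so_far = np.minimum.accumulate(fitness)
    i = int(np.argmin(fitness))
    return OptResult(
        best_position=samples[i].copy(),
        best_fitness=float(fitness[i]),
        convergence=best_so_far.tolist(),
        total_evaluations=budget,
        seed=seed,
        config=None,
        optimizer="random",
    )


def _impa_runner(factory, space, config: OptimizerConfig, seed: int) -> OptResult:
    cfg = OptimizerConfig(
        config.n_agents, config.it_max, config.p, config.fads, config.levy_exponent, seed
    )
    return run_impa(factory(), space, cfg)


def _mpa_runner(factory, space, config: OptimizerConfig, seed: int) -> OptResult:
    cfg = OptimizerConfig(
        config.n_agents, config.it_max, config.p, config.fads, config.levy_exponent, seed
    )
    return run_mpa(factory(), space, cfg)


def _random_runner(factory, space, config: OptimizerConfig, seed: int) -> OptResult:
    # matched evaluation budget against IMPA's schedule
    budget = config.n_agents * (3 * config.it_max + 2)
    return run_random_search(factory(), space, budget, seed)


#: Plug-in registry; external algorithms register a callable with the same
#: signature (objective_factory, space, config, seed) -> OptResult.
OPTIMIZERS: dict[str, Callable] = {
    "impa": _impa_runner,
    "mpa": _mpa_runner,
    "random": _random_runner,
}


def compare_optimizers(
    objective_factory: Callable[[], ObjectiveAdapter],
    space: SearchSpace,
    configs: Mapping[str, OptimizerConfig],
    n_seeds: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run each registered optimizer across seeds and tabulate best fitness.

    ``objective_factory`` builds a fresh adapter per run so evaluation
    counters do not leak between runs.  Returns one row per optimizer
    with median/mean/std of best fitness and the mean evaluation count.
    """
    if not configs:
        raise ValueError("at least one optimizer must be registered for comparison")
    rows = []
    for name, config in configs.items():
        if name not in OPTIMIZERS:
            raise KeyError(f"unknown optimizer {name!r}; registered: {sorted(OPTIMIZERS)}")
        bests, evals = [], []
        for s in range(n_seeds):
            res = OPTIMIZERS[name](objective_factory, space, config, base_seed + s)
            bests.append(res.best_fitness)
            evals.append(res.total_evaluations)
        rows.append(
            {
                "optimizer": name,
                "median_best": float(np.median(bests)),
                "mean_best": float(np.mean(bests)),
                "std_best": float(np.std(bests)),
                "mean_evaluations": float(np.mean(evals)),
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(rows).set_index("optimizer")
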