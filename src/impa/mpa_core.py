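"""Core machinery of the Marine Predators Algorithm.

The population (prey) and the replicated-best (Elite) matrices, the
Brownian and Lévy step samplers, the three velocity phases that the
iteration budget is split into, the iteration-dependent step damping
factor CF, the FADs (fish-aggregating-devices) long-jump perturbation,
and the memory-saving / Elite-update bookkeeping.

Phase regimes over iterations 1..it_max:

* phase 1 (prey faster than predator, pure exploration): Brownian steps
  relative to the prey's own position;
* phase 2 (equal speed): first half of the population takes Lévy steps,
  second half Brownian steps anchored at the Elite and damped by CF;
* phase 3 (predator faster, exploitation): Lévy steps anchored at the
  Elite, damped by CF.

All public update functions accept an optional pre-drawn step bundle so
that unit tests can pin the random factors and compare against
hand-evaluated closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "OptimizerConfig",
    "PopulationState",
    "StepSample",
    "brownian_matrix",
    "levy_matrix",
    "compute_cf",
    "phase_of_iteration",
    "phase1_update",
    "phase2_update",
    "phase3_update",
    "fads_perturbation",
    "memory_save",
    "update_elite",
]


@dataclass
class OptimizerConfig:
    """Run parameters of the (I)MPA.

    Defaults follow the published parameter settings: population size
    30, 50 iterations, step-scale constant P = 0.5, FADs probability
    0.2, Lévy tail index 1.5.
    """

    n_agents: int = 30
    it_max: int = 50
    p: float = 0.5
    fads: float = 0.2
    levy_exponent: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2 or self.n_agents % 2 != 0:
            raise ValueError(
                f"population size must be an even integer >= 2 (phase 2 splits halves), "
                f"got {self.n_agents}"
            )
        if self.it_max < 3:
            raise ValueError(f"it_max must be >= 3 (three phase regimes), got {self.it_max}")
        if not 1.0 < self.levy_exponent <= 2.0:
            raise ValueError(f"levy_exponent must lie in (1, 2], got {self.levy_exponent}")
        if not 0.0 <= self.fads <= 1.0:
            raise ValueError(f"FADs probability must lie in [0, 1], got {self.fads}")


@dataclass
class PopulationState:
    """Prey/Elite matrices plus fitness memory.

    ``elite`` is the best-so-far position replicated across all rows;
    ``prev_prey``/``prev_fitness`` hold the previous accepted iteration
    for the memory-saving step.
    """

    prey: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    prev_prey: Optional[np.ndarray] = None
    prev_fitness: Optional[np.ndarray] = None

    @property
    def n_agents(self) -> int:
        return self.prey.shape[0]

    @property
    def dim(self) -> int:
        return self.prey.shape[1]

    @property
    def elite(self) -> np.ndarray:
        return np.tile(self.best_position, (self.n_agents, 1))


@dataclass(frozen=True)
class StepSample:
    """Pre-drawn random multipliers for one phase update.

    ``outer`` and ``inner`` are the two step-sample factors appearing in
    a phase equation (drawn independently); ``uniform`` is the U[0,1]
    multiplier matrix R.
    """

    outer: np.ndarray
    inner: np.ndarray
    uniform: np.ndarray


def brownian_matrix(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. standard-normal step multipliers (Brownian motion)."""
    if rows < 1 or cols < 1:
        raise ValueError("matrix dimensions must be >= 1")
    return rng.standard_normal((rows, cols))


def levy_matrix(
    rows: int, cols: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed Lévy step multipliers via Mantegna's construction.

    step = u / |v|^(1/alpha) with u ~ N(0, sigma_u^2), v ~ N(0, 1) and

        sigma_u = [ Gamma(1+a) sin(pi a / 2)
                    / (Gamma((1+a)/2) * a * 2^((a-1)/2)) ]^(1/a).

    The resulting distribution has tail index ``exponent``; occasional
    very long jumps are the point.
    """
    if rows < 1 or cols < 1:
        raise ValueError("matrix dimensions must be >= 1")
    if not 1.0 < exponent <= 2.0:
        raise ValueError(f"Lévy exponent must lie in (1, 2], got {exponent}")
    a = exponent
    sigma_u = (
        math.gamma(1 + a)
        * math.sin(math.pi * a / 2)
        / (math.gamma((1 + a) / 2) * a * 2 ** ((a - 1) / 2))
    ) ** (1 / a)
    u = rng.standard_normal((rows, cols)) * sigma_u
    v = rng.standard_normal((rows, cols))
    return u / np.abs(v) ** (1 / a)


def compute_cf(it: int | float, it_max: int) -> float:
    """Step-damping factor (1 - it/it_max)^(2 it/it_max), from 1 to 0."""
    if not 0 <= it <= it_max:
        raise ValueError(f"iteration {it} outside [0, {it_max}]")
    x = it / it_max
    if x == 1.0:
        return 0.0
    return (1.0 - x) ** (2.0 * x)


def phase_of_iteration(it: int, it_max: int) -> int:
    """Which velocity regime iteration ``it`` (1-based) belongs to."""
    if it < math.ceil(it_max / 3):
        return 1
    if it < math.ceil(2 * it_max / 3):
        return 2
    return 3


# ---------------------------------------------------------------------------
# Phase update rules.  Each has a pure kernel taking explicit random factors,
# and a public wrapper that draws them from the rng.
# ---------------------------------------------------------------------------


def phase1_kernel(
    prey: np.ndarray, elite: np.ndarray, steps: StepSample, p: float
) -> np.ndarray:
    """High-velocity rule: prey_j += P * R * [RB (Elite_j - RB prey_j)]."""
    stepsize = steps.outer * (elite - steps.inner * prey)
    return prey + p * steps.uniform * stepsize


def phase2_levy_kernel(
    prey: np.ndarray, elite: np.ndarray, steps: StepSample, p: float
) -> np.ndarray:
    """Unit-velocity rule, exploring half: Lévy steps around the prey."""
    stepsize = steps.outer * (elite - steps.inner * prey)
    return prey + p * steps.uniform * stepsize


def phase2_brownian_kernel(
    prey: np.ndarray, elite: np.ndarray, steps: StepSample, p: float, cf: float
) -> np.ndarray:
    """Unit-velocity rule, exploiting half: prey = Elite + P*CF*[RB (RB Elite - prey)]."""
    stepsize = steps.outer * (steps.inner * elite - prey)
    return elite + p * cf * stepsize


def phase3_kernel(
    prey: np.ndarray, elite: np.ndarray, steps: StepSample, p: float, cf: float
) -> np.ndarray:
    """Low-velocity rule: prey = Elite + P*CF*[RL (RL Elite - prey)]."""
    stepsize = steps.outer * (steps.inner * elite - prey)
    return elite + p * cf * stepsize


def _draw(
    sampler, rows: int, cols: int, rng: np.random.Generator, **kw
) -> StepSample:
    return StepSample(
        outer=sampler(rows, cols, rng=rng, **kw),
        inner=sampler(rows, cols, rng=rng, **kw),
        uniform=rng.uniform(size=(rows, cols)),
    )


def phase1_update(
    state: PopulationState,
    p: float,
    rng: np.random.Generator,
    steps: Optional[StepSample] = None,
) -> np.ndarray:
    """Apply the high-velocity (exploration) rule to every row."""
    n, d = state.prey.shape
    if steps is None:
        steps = _draw(brownian_matrix, n, d, rng)
    return phase1_kernel(state.prey, state.elite, steps, p)


def phase2_update(
    state: PopulationState,
    it: int,
    it_max: int,
    p: float,
    rng: np.random.Generator,
    levy_exponent: float = 1.5,
    steps_levy: Optional[StepSample] = None,
    steps_brownian: Optional[StepSample] = None,
) -> np.ndarray:
    """Apply the split unit-velocity rule (first half Lévy, second half Brownian)."""
    n, d = state.prey.shape
    if n % 2 != 0:
        raise ValueError("phase 2 requires an even population size")
    half = n // 2
    cf = compute_cf(it, it_max)
    elite = state.elite
    if steps_levy is None:
        steps_levy = _draw(levy_matrix, half, d, rng, exponent=levy_exponent)
    if steps_brownian is None:
        steps_brownian = _draw(brownian_matrix, half, d, rng)
    new = np.empty_like(state.prey)
    new[:half] = phase2_levy_kernel(state.prey[:half], elite[:half], steps_levy, p)
    new[half:] = phase2_brownian_kernel(
        state.prey[half:], elite[half:], steps_brownian, p, cf
    )
    return new


def phase3_update(
    state: PopulationState,
    it: int,
    it_max: int,
    p: float,
    rng: np.random.Generator,
    levy_exponent: float = 1.5,
    steps: Optional[StepSample] = None,
) -> np.ndarray:
    """Apply the low-velocity (exploitation) Lévy rule to every row."""
    n, d = state.prey.shape
    cf = compute_cf(it, it_max)
    if steps is None:
        steps = _draw(levy_matrix, n, d, rng, exponent=levy_exponent)
    return phase3_kernel(state.prey, state.elite, steps, p, cf)


def fads_perturbation(
    prey: np.ndarray,
    cf: float,
    fads: float,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fish-aggregating-devices long jump.

    Per row, with one uniform scalar r: if r <= FADs the row takes a
    CF-scaled jump towards a random box point, masked per dimension by
    a Bernoulli(FADs) indicator; otherwise it moves along the
    difference of two distinct random rows scaled by FADs(1-r)+r.
    """
    n, d = prey.shape
    new = prey.copy()
    for j in range(n):
        r = rng.uniform()
        if r <= fads:
            mask = (rng.uniform(size=d) < fads).astype(float)
            new[j] += cf * (lb + r * (ub - lb)) * mask
        else:
            if n >= 2:
                r1, r2 = rng.choice(n, size=2, replace=False)
                new[j] += (fads * (1.0 - r) + r) * (prey[r1] - prey[r2])
    return new


def memory_save(state: PopulationState) -> PopulationState:
    """Rowwise greedy memory: keep the better of current and previous rows.

    After selection the previous-iteration copies are refreshed, so the
    per-row fitness trajectory is non-increasing.
    """
    if state.prev_prey is None or state.prev_fitness is None:
        raise ValueError("memory_save requires populated prev_prey / prev_fitness")
    worse = state.fitness > state.prev_fitness
    state.prey[worse] = state.prev_prey[worse]
    state.fitness[worse] = state.prev_fitness[worse]
    state.prev_prey = state.prey.copy()
    state.prev_fitness = state.fitness.copy()
    return state


def update_elite(state: PopulationState) -> PopulationState:
    """Refresh the replicated-best Elite if a strictly better row appeared.

    Ties keep the incumbent best.
    """
    i = int(np.argmin(state.fitness))
    if state.fitness[i] < state.best_fitness:
        state.best_fitness = float(state.fitness[i])
        state.best_position = state.prey[i].copy()
    return state
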