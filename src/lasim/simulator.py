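"""Stochastic forward simulation of score trajectories.

Individuals are drawn from the hierarchical population distributions
(variant 1: no offset; variant 2: a shared per-individual offset ``d``),
scores are binomial draws along a regular stimulation grid, and durations
are derived with the triple-6 stopping rule (right-censored at the end of
the grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lasim.model_core import (
    N_DRUGS,
    N_STIM,
    Arm,
    DrugCurveParams,
    PopulationParams,
    reaction_probability,
)

__all__ = [
    "IndividualParams",
    "ScoreTable",
    "DurationRecord",
    "default_grid",
    "draw_individual",
    "simulate_scores",
    "simulate_cohort",
    "duration_from_scores",
    "durations_from_cohort",
]

#: Consecutive full scores required to declare the effect subsided.
STOP_RUN: int = 3

#: Default stimulation grids (minutes): raw-data emulation stops at 100,
#: simulation at 120.
T_MAX_RAW: int = 100
T_MAX_SIM: int = 120
GRID_STEP: int = 5


def default_grid(t_max: int = T_MAX_SIM, step: int = GRID_STEP, t_start: int | None = None) -> np.ndarray:
    """Regular stimulation grid ``t_start, t_start+step, ..., t_max``."""
    if t_start is None:
        t_start = step
    if step <= 0 or t_max < t_start:
        raise ValueError(f"invalid grid: start={t_start}, step={step}, t_max={t_max}")
    return np.arange(t_start, t_max + 1, step, dtype=float)


@dataclass(frozen=True)
class IndividualParams:
    """One individual's parameters: offset ``d`` and per-drug (mu, sigma)."""

    d: float
    mu: np.ndarray  # shape (4,), per drug
    sigma: np.ndarray  # shape (4,), per drug, > 0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != (N_DRUGS,) or sigma.shape != (N_DRUGS,):
            raise ValueError(f"mu and sigma must have shape ({N_DRUGS},)")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be > 0 for every drug")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class ScoreTable:
    """One animal-arm trajectory: integer scores on a regular time grid."""

    animal_id: str
    arm: Arm
    times: np.ndarray
    scores: np.ndarray
    n_stim: int = N_STIM

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        scores = np.asarray(self.scores, dtype=int)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if scores.shape != times.shape:
            raise ValueError("scores and times must have the same length")
        steps = np.diff(times)
        if times.size > 1 and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("times must be strictly increasing with a constant step")
        if np.any(scores < 0) or np.any(scores > self.n_stim):
            raise ValueError(f"scores must be integers in 0..{self.n_stim}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "scores", scores)

    @property
    def t_max(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class DurationRecord:
    """Duration of effect for one animal-arm; ``event=False`` means censored."""

    animal_id: str
    arm: Arm
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be > 0, got {self.time}")


def draw_individual(
    pop: PopulationParams,
    model_variant: int,
    rng: np.random.Generator,
) -> IndividualParams:
    """Draw one individual's (d, mu, sigma) from the population distributions.

    Variant 2 draws ``d ~ Normal(0, sd_d)`` and centers each drug's mu at
    ``mu0 + d``; variant 1 fixes ``d = 0``.  In both variants
    ``sigma ~ LogNormal(log_sigma0, log_s_sigma0)``.
    """
    if model_variant not in (1, 2):
        raise ValueError(f"model_variant must be 1 or 2, got {model_variant}")
    d = float(rng.normal(0.0, pop.sd_d)) if model_variant == 2 else 0.0
    mu = rng.normal(pop.mu0 + d, pop.s_mu0)
    sigma = np.exp(rng.normal(pop.log_sigma0, pop.log_s_sigma0))
    return IndividualParams(d=d, mu=mu, sigma=sigma)


def simulate_scores(
    ind: IndividualParams,
    arm: Arm,
    pop_adr: float,
    grid: np.ndarray,
    rng: np.random.Generator,
    animal_id: str = "sim",
    n_stim: int = N_STIM,
) -> ScoreTable:
    """Simulate one score trajectory.

    Scores at different times are independent binomial draws (no serial
    dependence) with success probability from the individual's curve for
    this arm's drug, with the adrenaline slope modifier applied when
    ``arm.v_adr`` is set.
    """
    i = arm.drug_index - 1
    params = DrugCurveParams(
        mu=float(ind.mu[i]),
        sigma=float(ind.sigma[i]),
        adr_effect=pop_adr * arm.v_adr,
    )
    p = reaction_probability(np.asarray(grid, dtype=float), params)
    scores = rng.binomial(n_stim, p)
    return ScoreTable(animal_id=animal_id, arm=arm, times=grid, scores=scores, n_stim=n_stim)


def simulate_cohort(
    pop: PopulationParams,
    n_individuals: int,
    arms: list[Arm],
    grid: np.ndarray,
    model_variant: int = 2,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    n_stim: int = N_STIM,
    id_prefix: str = "animal",
) -> list[ScoreTable]:
    """Simulate ``n_individuals`` animals, each with one trajectory per arm.

    Each individual's offset and per-drug (mu, sigma) are drawn once and
    shared across its arms; in particular a Lid and a Lid+Adr trajectory of
    the same animal use identical (mu, sigma) and differ only through the
    adrenaline slope modifier.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    if not arms:
        raise ValueError("arms must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    width = len(str(n_individuals))
    tables: list[ScoreTable] = []
    for k in range(n_individuals):
        ind = draw_individual(pop, model_variant, rng)
        animal_id = f"{id_prefix}{k + 1:0{width}d}"
        for arm in arms:
            tables.append(
                simulate_scores(ind, arm, pop.adr, grid, rng, animal_id=animal_id, n_stim=n_stim)
            )
    return tables


def duration_from_scores(table: ScoreTable, stop_run: int = STOP_RUN) -> DurationRecord:
    """Derive the duration record via the triple-6 stopping rule.

    Scans for the first run of ``stop_run`` consecutive full scores
    (``n_stim``); the duration is the time of the LAST score in that run
    (the moment stimulation stops).  Without such a run the record is
    censored at the end of the grid.
    """
    full = table.scores == table.n_stim
    run = 0
    for k, hit in enumerate(full):
        run = run + 1 if hit else 0
        if run >= stop_run:
            return DurationRecord(
                animal_id=table.animal_id, arm=table.arm, time=float(table.times[k]), event=True
            )
    return DurationRecord(
        animal_id=table.animal_id, arm=table.arm, time=table.t_max, event=False
    )


def durations_from_cohort(tables: list[ScoreTable], stop_run: int = STOP_RUN) -> list[DurationRecord]:
    return [duration_from_scores(t, stop_run=stop_run) for t in tables]
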