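"""Stochastic multi-objective evolutionary optimizer (optBioCAD).

The algorithm evolves a population of real-valued decision vectors, each
carrying self-adaptive Gaussian step sizes and an age.  Every generation the
population is copied ``dup`` times, the copies undergo a *local search*
(self-adaptive Gaussian mutation of one randomly chosen variable, fired with
probability ``exp(-rho * F)``) and a *global search* (convex-combination
perturbation toward another member's value, fired with probability
``exp(-F) / beta``), where ``F`` in [0, 1] is the fitness: the mean of the
objective values normalized by the best values observed over all
generations.  Candidates older than ``tau_B + 1`` are moved into a
fixed-capacity archive; selection is a feasibility-first pairwise
tournament, refilled from the archive when too few candidates survive.

The optimizer is generic over an *evaluator*: any callable mapping a
decision vector to ``(objective vector, constraint value)``.  Objectives are
reported raw; senses are declared through an :class:`~biocad.pareto.ObjectiveSpec`.
A constraint value of ``None`` or an evaluator returning ``None`` objectives
marks the candidate infeasible with maximal violation (e.g. an infeasible
FBA problem).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pareto import ObjectiveSpec, ParetoFront, pareto_front

__all__ = [
    "Candidate",
    "OptConfig",
    "Archive",
    "RunResult",
    "initialize_population",
    "fitness",
    "copying",
    "local_search",
    "global_search",
    "evaluate_constraints",
    "diversity_enforcing",
    "selection",
    "run_optbiocad",
]


@dataclass
class Candidate:
    """One member of the population."""

    x: np.ndarray
    sigma: np.ndarray
    age: int = 0
    objectives: np.ndarray | None = None  # raw objective values, or None
    violation: float = 0.0
    feasible: bool = True

    def copy(self) -> "Candidate":
        return Candidate(
            self.x.copy(),
            self.sigma.copy(),
            self.age,
            None if self.objectives is None else self.objectives.copy(),
            self.violation,
            self.feasible,
        )


@dataclass(frozen=True)
class OptConfig:
    """Algorithm parameters (defaults follow the published setting)."""

    d: int = 20  # population size
    dup: int = 2  # copies per member
    tau_B: int = 50  # age limit
    rho: float = 1.0  # local-search rate parameter
    beta: float = 7.0  # global-search rate parameter
    s_a: int = 160  # archive capacity
    t_final: int = 100  # generation budget
    theta: float = 0.0  # feasibility threshold
    seed: int = 0
    stagnation: int | None = None  # stop after this many non-improving generations
    classical_es_rates: bool = False  # use 1/sqrt(2n), 1/sqrt(2 sqrt(n)) learning rates

    def __post_init__(self):
        if min(self.d, self.dup, self.s_a, self.t_final) < 1:
            raise ValueError("d, dup, s_a and t_final must all be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


class Archive:
    """Fixed-capacity candidate store with first-free-slot insertion."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("archive capacity must be >= 1")
        self.slots: list = [None] * capacity

    @property
    def capacity(self) -> int:
        return len(self.slots)

    @property
    def occupancy(self) -> int:
        return sum(s is not None for s in self.slots)

    def members(self) -> list:
        return [s for s in self.slots if s is not None]

    def insert(self, candidate: Candidate, rng: np.random.Generator):
        """Insert into the first free slot, else overwrite a random slot."""
        for i, s in enumerate(self.slots):
            if s is None:
                self.slots[i] = candidate
                return
        self.slots[int(rng.integers(self.capacity))] = candidate


# ---------------------------------------------------------------------------
# Operators


def initialize_population(bounds, config: OptConfig, rng: np.random.Generator) -> list:
    """Uniform random population with step sizes ``0.4 (hi - lo) / n``."""
    lo, hi = _split_bounds(bounds)
    n = lo.size
    pop = []
    for _ in range(config.d):
        x = rng.uniform(lo, hi)
        sigma = 0.4 * (hi - lo) / n
        pop.append(Candidate(x=x, sigma=sigma, age=0))
    return pop


def _split_bounds(bounds):
    arr = np.asarray(bounds, dtype=float)
    lo, hi = arr[:, 0], arr[:, 1]
    if np.any(lo > hi):
        raise ValueError("decision bounds have lb > ub")
    if not np.all(np.isfinite(arr)):
        raise ValueError("decision bounds must be finite")
    return lo, hi


def fitness(objectives, f_max, spec: ObjectiveSpec) -> float:
    """Normalized fitness ``F = (sum_i f_i / f_max_i) / r`` clamped to [0, 1].

    Objectives and the running best vector ``f_max`` are first oriented so
    that every objective is maximized.  Non-positive ``f_max`` coordinates
    use a denominator of 1 so that F stays defined at startup.
    """
    if objectives is None:
        return 0.0
    f = np.asarray(objectives, dtype=float)
    fm = np.asarray(f_max, dtype=float)
    if f.shape != (spec.r,) or fm.shape != (spec.r,):
        raise ValueError("objective / f_max length mismatch")
    f = f * spec.sign_vector()
    denom = np.where(fm > 0, fm, 1.0)
    return float(np.clip(np.sum(f / denom) / spec.r, 0.0, 1.0))


def copying(population: list, dup: int) -> list:
    """Copy each member *dup* times; copies inherit the parent's age, after
    which the parent's own age increments by one."""
    copies = []
    for parent in population:
        for _ in range(dup):
            copies.append(parent.copy())
        parent.age += 1
    return copies


def _learning_rates(n: int, classical: bool):
    if classical:
        return 1.0 / math.sqrt(2.0 * n), 1.0 / math.sqrt(2.0 * math.sqrt(n))
    return 1.0 / (2.0 * n), 1.0 / (2.0 * n)


def local_search(
    c: Candidate,
    F: float,
    rho: float,
    bounds,
    rng: np.random.Generator,
    classical_es_rates: bool = False,
) -> Candidate:
    """Self-adaptive Gaussian mutation of one randomly chosen variable.

    Fires with probability ``alpha = exp(-rho * F)``; otherwise the candidate
    is returned unchanged.  When it fires, ``sigma_i`` is log-normally
    perturbed with learning rates ``gamma = gamma' = 1 / (2n)`` and the
    variable moves by ``sigma_i * N(0, 1)``, clipped to its box.
    """
    alpha = math.exp(-rho * F)
    if rng.random() >= alpha:
        return c
    lo, hi = _split_bounds(bounds)
    n = c.x.size
    g, gp = _learning_rates(n, classical_es_rates)
    out = c.copy()
    i = int(rng.integers(n))
    out.sigma[i] *= math.exp(g * rng.standard_normal() + gp * rng.standard_normal())
    out.x[i] = np.clip(out.x[i] + out.sigma[i] * rng.standard_normal(), lo[i], hi[i])
    out.objectives = None  # stale, needs re-evaluation
    return out


def global_search(
    c: Candidate,
    pool: list,
    F: float,
    beta: float,
    bounds,
    rng: np.random.Generator,
) -> Candidate:
    """Convex-combination perturbation toward another member's value.

    Fires with probability ``alpha = exp(-F) / beta``.  The donor value is
    taken at a uniformly random other index of a uniformly random other pool
    member (resampled once if it equals the current value); the perturbation
    ``x_i <- (1 - gamma) x_i + gamma x_k`` uses ``gamma ~ N(0, 1)``, so it is
    occasionally extrapolating, and is clipped to the variable's box.
    """
    if not pool:
        raise ValueError("global search needs a non-empty pool")
    alpha = math.exp(-F) / beta
    if rng.random() >= alpha:
        return c
    lo, hi = _split_bounds(bounds)
    n = c.x.size
    out = c.copy()
    i = int(rng.integers(n))
    xk = _draw_donor(c, pool, i, rng)
    gamma = rng.standard_normal()
    out.x[i] = np.clip((1.0 - gamma) * out.x[i] + gamma * xk, lo[i], hi[i])
    out.objectives = None
    return out


def _draw_donor(c: Candidate, pool: list, i: int, rng: np.random.Generator) -> float:
    n = c.x.size
    for _ in range(2):  # resample once if the donor equals the current value
        donor = pool[int(rng.integers(len(pool)))]
        if n > 1:
            k = int(rng.integers(n - 1))
            if k >= i:
                k += 1
        else:
            k = 0
        xk = float(donor.x[k])
        if xk != c.x[i]:
            return xk
    return xk


def evaluate_constraints(g_value, theta: float):
    """Map a raw constraint value to ``(feasible, violation)``.

    ``None`` (non-evaluable, e.g. infeasible FBA) yields an infeasible
    candidate with infinite violation.
    """
    if g_value is None or not np.isfinite(g_value):
        return False, float("inf")
    return g_value <= theta, max(0.0, float(g_value) - theta)


def diversity_enforcing(
    population: list, mutants: list, tau_B: int, archive: Archive, rng: np.random.Generator
):
    """Move candidates older than ``tau_B + 1`` into the archive.

    A candidate aged exactly ``tau_B + 1`` survives.  Returns the filtered
    ``(population, mutants)`` lists.
    """

    def sweep(group):
        kept = []
        for c in group:
            if c.age > tau_B + 1:
                archive.insert(c, rng)
            else:
                kept.append(c)
        return kept

    return sweep(population), sweep(mutants)


def _score(c: Candidate, f_max, spec: ObjectiveSpec):
    """Feasible-candidate quality: fitness first, oriented objective mean as
    tie-break (the clamped F is flat when every objective is non-positive)."""
    if c.objectives is None:
        return (0.0, -np.inf)
    mean_oriented = float(np.mean(c.objectives * spec.sign_vector()))
    return (fitness(c.objectives, f_max, spec), mean_oriented)


def _rank_key(c: Candidate, f_max, spec: ObjectiveSpec):
    # feasibility first, then fitness (descending), then violation (ascending)
    if c.feasible:
        F, tie = _score(c, f_max, spec)
        return (0, -F, -tie)
    return (1, c.violation, 0.0)


def _tournament_winner(p1: Candidate, p2: Candidate, f_max, spec: ObjectiveSpec) -> Candidate:
    if p1.feasible != p2.feasible:
        return p1 if p1.feasible else p2
    if p1.feasible:
        return p1 if _score(p1, f_max, spec) >= _score(p2, f_max, spec) else p2
    return p1 if p1.violation <= p2.violation else p2


def selection(
    population: list,
    mutants: list,
    archive: Archive,
    d: int,
    f_max,
    spec: ObjectiveSpec,
    rng: np.random.Generator,
    bounds=None,
    config: OptConfig | None = None,
) -> list:
    """Pairwise tournament over parents and mutants.

    A feasible candidate beats an infeasible one; between feasibles the
    better fitness wins; between infeasibles the lower violation wins.  If
    fewer than *d* candidates survive, the deficit is filled with uniformly
    random archive members, then with fresh random candidates.
    """
    winners = list(population) + list(mutants)
    # elimination rounds of randomly paired tournaments until the pool fits;
    # each round knocks out exactly one member per pair played
    while len(winners) > d:
        excess = len(winners) - d
        n_pairs = min(excess, len(winners) // 2)
        order = rng.permutation(len(winners))
        nxt = [
            _tournament_winner(winners[order[2 * i]], winners[order[2 * i + 1]], f_max, spec)
            for i in range(n_pairs)
        ]
        nxt.extend(winners[i] for i in order[2 * n_pairs :])
        winners = nxt
    while len(winners) < d:
        members = archive.members()
        if members:
            winners.append(members[int(rng.integers(len(members)))].copy())
        elif bounds is not None:
            cfg = config or OptConfig(d=1)
            winners.extend(initialize_population(bounds, OptConfig(d=d - len(winners), seed=cfg.seed), rng))
        else:
            break
    return winners


# ---------------------------------------------------------------------------
# Main loop


@dataclass
class RunResult:
    """Everything a run produces."""

    population: list
    archive: Archive
    fronts: list  # per-generation ParetoFront
    cumulative_front: ParetoFront
    f_max: np.ndarray
    n_evaluations: int
    generations_run: int
    spec: ObjectiveSpec = None
    log: list = field(default_factory=list)


def _evaluate(c: Candidate, evaluator, theta: float):
    obj, g = evaluator(c.x)
    c.objectives = None if obj is None else np.asarray(obj, dtype=float)
    c.feasible, c.violation = evaluate_constraints(g, theta)
    if c.objectives is not None and not np.all(np.isfinite(c.objectives)):
        c.objectives = None
        c.feasible, c.violation = False, float("inf")
    return c.objectives is not None or not c.feasible


def run_optbiocad(
    evaluator,
    bounds,
    spec: ObjectiveSpec,
    config: OptConfig,
) -> RunResult:
    """Run the full evolutionary loop.

    Per generation: copy -> local search -> global search -> evaluate ->
    age update -> diversity enforcing -> archive union -> selection.  Ages
    reset to 0 on objective improvement (judged against the candidate's
    pre-mutation fitness) and increment otherwise.  ``f_max`` tracks the
    best oriented objective values over all generations and normalizes the
    fitness.  Raises ``RuntimeError`` when the evaluator fails on more than
    half of a generation.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = _split_bounds(bounds)
    sg = spec.sign_vector()
    archive = Archive(config.s_a)
    f_max = np.full(spec.r, -np.inf)

    evaluated_obj: list = []  # feasible evaluated points, raw objectives
    evaluated_dec: list = []
    n_evaluations = 0

    def eval_group(group):
        nonlocal n_evaluations, f_max
        failures = 0
        for c in group:
            if c.objectives is not None:
                continue  # unchanged since last evaluation
            try:
                _evaluate(c, evaluator, config.theta)
                n_evaluations += 1
            except Exception:
                c.objectives = None
                c.feasible, c.violation = False, float("inf")
                failures += 1
            if c.objectives is not None:
                f_max = np.maximum(f_max, c.objectives * sg)
                if c.feasible:
                    evaluated_obj.append(c.objectives.copy())
                    evaluated_dec.append(c.x.copy())
        if group and failures > 0.5 * len(group):
            raise RuntimeError(
                f"evaluator failed on {failures}/{len(group)} candidates in one generation"
            )

    population = initialize_population(bounds, config, rng)
    eval_group(population)

    fronts: list = []
    log: list = []
    best_F = -1.0
    stagnant = 0
    t = 0
    while t < config.t_final:
        copies = copying(population, config.dup)
        pre_F = [fitness(c.objectives, f_max, spec) for c in copies]
        p_ls = [
            local_search(c, F, config.rho, bounds, rng, config.classical_es_rates)
            for c, F in zip(copies, pre_F)
        ]
        p_gs = [
            global_search(c, p_ls, F, config.beta, bounds, rng)
            for c, F in zip(p_ls, pre_F)
        ]
        eval_group(p_gs)
        for c, (copy_pre, F_old) in zip(p_gs, zip(copies, pre_F)):
            if c.objectives is not None and _score(c, f_max, spec) > _score(
                copy_pre, f_max, spec
            ):
                c.age = 0
            else:
                c.age += 1
        population, p_gs = diversity_enforcing(population, p_gs, config.tau_B, archive, rng)
        for c in population + p_gs:
            archive.insert(c.copy(), rng)
        population = selection(
            population, p_gs, archive, config.d, f_max, spec, rng, bounds, config
        )
        eval_group(population)  # archive/fresh refills may be stale

        gen_pool_obj = [c.objectives for c in population + p_gs if c.objectives is not None and c.feasible]
        gen_pool_dec = [c.x for c in population + p_gs if c.objectives is not None and c.feasible]
        if gen_pool_obj:
            fronts.append(
                ParetoFront.from_points(gen_pool_obj, gen_pool_dec, spec, generation=t)
            )
        gen_best = max(
            (fitness(c.objectives, f_max, spec) for c in population if c.objectives is not None),
            default=0.0,
        )
        log.append(
            {
                "generation": t,
                "front_size": len(fronts[-1]) if fronts else 0,
                "best_F": gen_best,
                "archive_occupancy": archive.occupancy,
            }
        )
        if gen_best > best_F + 1e-12:
            best_F = gen_best
            stagnant = 0
        else:
            stagnant += 1
        t += 1
        if config.stagnation is not None and stagnant >= config.stagnation:
            break

    if not evaluated_obj:
        raise RuntimeError("no feasible candidate was ever evaluated")
    cumulative = ParetoFront.from_points(evaluated_obj, evaluated_dec, spec, generation=t)
    return RunResult(
        population=population,
        archive=archive,
        fronts=fronts,
        cumulative_front=cumulative,
        f_max=f_max,
        n_evaluations=n_evaluations,
        generations_run=t,
        spec=spec,
        log=log,
    )
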