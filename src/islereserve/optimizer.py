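"""Spatially explicit genetic-algorithm reserve selection.

Optimizes a binary protection raster directly (every operator acts on the
raster, not on a permutation or site list) under two classic formulations:

* **minimum set** — reach every species' representation target with the
  fewest protected cells; solutions missing any target are infeasible and
  carry a null (sentinel) fitness;
* **maximum coverage** — maximize target attainment subject to a protected-
  cell budget; solutions over budget are infeasible.

Fitness is a weighted combination of representation, cost and connectivity,
where connectivity is the number of rook-adjacent protected pairs divided by
2k for k protected cells (an upper bound on the pair count, so the score
lies in [0, 1] and compact blocks score high). Crossover swaps a random
rectangular window between parents; mutation perturbs one cell, adopting the
majority class of its rook neighbours with a configurable bias so patch
edges grow or contract preferentially. Selection is tournament (size 2) with
elitism, so the best-so-far fitness is non-decreasing across generations.

Exhaustive subset enumeration (small instances) and a greedy heuristic are
provided as independent yardsticks for the GA.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .raster import BinaryGrid, StudyArea, require_aligned

__all__ = [
    "ProblemSpec",
    "GAConfig",
    "FitnessWeights",
    "FitnessBreakdown",
    "Solution",
    "InfeasibleProblemError",
    "representation",
    "connectivity_score",
    "evaluate_fitness",
    "spatial_crossover",
    "spatial_mutation",
    "ga_optimize",
    "exhaustive_minimum_set",
    "exhaustive_maximum_coverage",
    "greedy_baseline",
]

#: Fitness assigned to infeasible solutions: strictly below any feasible fitness.
NULL_FITNESS = -np.inf

_EPS = 1e-9


class InfeasibleProblemError(RuntimeError):
    """No solution can satisfy the problem's targets/budget."""


@dataclasses.dataclass
class FitnessWeights:
    """Relative weights of the three fitness components.

    ``w_conn`` is kept small by default so that a one-cell cost difference
    always dominates a connectivity difference on desk-scale islands.
    """

    w_repr: float = 1.0
    w_cost: float = 1.0
    w_conn: float = 0.05


@dataclasses.dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Rates are expressed out of 100. The full-scale defaults are a population
    of 1000 evolved for 100000 generations with crossover 90.0/100 and
    mutation 50.0/100 (per offspring); :meth:`test_scale` returns a reduced
    configuration (population 40, 2000 generations) for desk-scale runs.
    """

    population_size: int = 1000
    generations: int = 100000
    crossover_rate: float = 90.0
    mutation_rate: float = 50.0
    tournament_size: int = 2
    elite: int = 1
    neighborhood_bias: float = 0.8
    #: random immigrants injected per generation to keep the population from
    #: collapsing onto a local optimum (cost-reducing two-swaps need mixing)
    immigrants: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 100 and 0 <= self.mutation_rate <= 100):
            raise ValueError("rates must lie in [0, 100]")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.elite >= self.population_size:
            raise ValueError("elite must be smaller than the population")

    @classmethod
    def test_scale(cls, seed: int = 0, generations: int = 2000, **kw) -> "GAConfig":
        return cls(population_size=40, generations=generations, seed=seed, **kw)


@dataclasses.dataclass
class ProblemSpec:
    """A reserve-selection problem instance.

    species_layers: species_id -> aligned BinaryGrid presence maps.
    weights: species_id -> weight (default 1; single-island endemics may get
    more). target is the base proportion of each species' range to protect;
    per-species targets are scaled as min(1, target * w_s / mean(w)).
    budget (maximum protected cells) applies to maximum_coverage only.
    """

    species_layers: dict
    study_area: StudyArea
    formulation: str = "minimum_set"
    target: float = 0.5
    budget: int | None = None
    weights: dict | None = None
    fitness_weights: FitnessWeights = dataclasses.field(default_factory=FitnessWeights)
    lock_in: BinaryGrid | None = None
    #: optional per-species base targets (species_id -> proportion in [0, 1]);
    #: overrides the scalar ``target``. A zero target leaves that species
    #: unconstrained. Weight scaling applies on top either way.
    per_species_targets: dict | None = None

    def __post_init__(self) -> None:
        if self.formulation not in ("minimum_set", "maximum_coverage"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if not (0.0 < self.target <= 1.0):
            raise ValueError("target must lie in (0, 1]")
        if self.formulation == "maximum_coverage":
            if self.budget is None:
                raise ValueError("maximum_coverage requires a budget")
            if self.budget > self.study_area.n_cells:
                raise ValueError("budget exceeds the study-area cell count")
        layers = list(self.species_layers.values())
        require_aligned(self.study_area.mask, *layers)

    @property
    def species_ids(self) -> list:
        return list(self.species_layers)

    def species_weights(self) -> np.ndarray:
        w = self.weights or {}
        arr = np.array([float(w.get(s, 1.0)) for s in self.species_ids])
        if np.any(arr < 0):
            raise ValueError("species weights must be non-negative")
        return arr

    def species_targets(self) -> np.ndarray:
        """Per-species targets after weight scaling, clamped at 1."""
        w = self.species_weights()
        if self.per_species_targets is not None:
            base = np.array([float(self.per_species_targets[s]) for s in self.species_ids])
            if np.any((base < 0) | (base > 1)):
                raise ValueError("per-species targets must lie in [0, 1]")
        else:
            base = np.full(len(w), self.target)
        return np.minimum(1.0, base * w / w.mean())


@dataclasses.dataclass
class FitnessBreakdown:
    representation: dict      # species_id -> protected proportion of range
    cost: int
    connectivity: float
    feasible: bool
    fitness: float


@dataclasses.dataclass
class Solution:
    protection: BinaryGrid
    fitness: FitnessBreakdown | None = None

    @property
    def cost(self) -> int:
        return self.protection.n_ones


# ---------------------------------------------------------------------------
# Compiled problem: flat-array view shared by GA, oracles and greedy
# ---------------------------------------------------------------------------

class _Compiled:
    """Island-cell flattening of a ProblemSpec for vectorized evaluation."""

    def __init__(self, spec: ProblemSpec):
        self.spec = spec
        area = spec.study_area
        self.shape = area.mask.values.shape
        island = area.cells
        self.island_flat = np.flatnonzero(island.ravel())  # grid order = lexicographic
        self.n = self.island_flat.size
        self.rows, self.cols = np.unravel_index(self.island_flat, self.shape)
        # species membership matrix over island cells
        mats = []
        for sid in spec.species_ids:
            layer = spec.species_layers[sid]
            pres = layer.presence.ravel()[self.island_flat]
            if not pres.any():
                raise ValueError(
                    f"species {sid!r} has no cells in the study area; "
                    "apply the extinct-species filter before optimizing"
                )
            mats.append(pres)
        self.S = np.asarray(mats)                       # (n_species, n_island)
        self.range_sizes = self.S.sum(axis=1)
        self.targets = spec.species_targets()
        self.weights = spec.species_weights()
        # rook-adjacent island-cell pairs (each unordered pair once)
        pos = -np.ones(self.shape, dtype=int)
        pos[self.rows, self.cols] = np.arange(self.n)
        pairs_i, pairs_j = [], []
        for dr, dc in ((0, 1), (1, 0)):
            r2, c2 = self.rows + dr, self.cols + dc
            ok = (r2 < self.shape[0]) & (c2 < self.shape[1])
            nb = pos[r2[ok], c2[ok]]
            src = np.arange(self.n)[ok]
            inside = nb >= 0
            pairs_i.append(src[inside])
            pairs_j.append(nb[inside])
        self.adj_i = np.concatenate(pairs_i)
        self.adj_j = np.concatenate(pairs_j)
        self.lock = (
            spec.lock_in.presence.ravel()[self.island_flat]
            if spec.lock_in is not None
            else None
        )
        # per-cell rook-neighbour lookup (padded with -1)
        nbrs = [[] for _ in range(self.n)]
        for i, j in zip(self.adj_i, self.adj_j):
            nbrs[i].append(j)
            nbrs[j].append(i)
        self.nbr_count = np.array([len(x) for x in nbrs])
        self.nbr_idx = np.full((self.n, 4), -1, dtype=int)
        for c, x in enumerate(nbrs):
            self.nbr_idx[c, : len(x)] = x

    # -- evaluation over a (pop, n) boolean matrix --------------------------
    def connectivity(self, pop: np.ndarray) -> np.ndarray:
        k = pop.sum(axis=1)
        pairs = (pop[:, self.adj_i] & pop[:, self.adj_j]).sum(axis=1)
        out = np.zeros(pop.shape[0])
        nz = k > 0
        out[nz] = pairs[nz] / (2.0 * k[nz])
        return out

    def representation(self, pop: np.ndarray) -> np.ndarray:
        counts = pop.astype(float) @ self.S.T.astype(float)
        return counts / self.range_sizes

    def evaluate(self, pop: np.ndarray):
        """Fitness, feasibility, cost, representation for a population matrix."""
        spec, fw = self.spec, self.spec.fitness_weights
        cost = pop.sum(axis=1)
        conn = self.connectivity(pop)
        rep = self.representation(pop)
        if spec.formulation == "minimum_set":
            feasible = np.all(rep >= self.targets[None, :] - _EPS, axis=1)
            fitness = -fw.w_cost * cost / self.n + fw.w_conn * conn
            fitness = np.where(feasible, fitness, NULL_FITNESS)
        else:
            feasible = cost <= spec.budget
            attain = np.minimum(rep / self.targets[None, :], 1.0)
            score = (attain * self.weights[None, :]).sum(axis=1) / self.weights.sum()
            fitness = fw.w_repr * score + fw.w_conn * conn
            fitness = np.where(feasible, fitness, NULL_FITNESS)
        return fitness, feasible, cost, rep

    # -- conversions --------------------------------------------------------
    def to_grid(self, flat: np.ndarray) -> BinaryGrid:
        vals = np.zeros(self.shape)
        vals.ravel()[self.island_flat[flat]] = 1.0
        ref = self.spec.study_area.mask
        return BinaryGrid(
            values=vals,
            nodata_mask=ref.nodata_mask.copy(),
            cellsize=ref.cellsize,
            origin=ref.origin,
            nodata_value=ref.nodata_value,
        )

    def from_grid(self, grid: BinaryGrid) -> np.ndarray:
        return grid.presence.ravel()[self.island_flat]

    def solution(self, flat: np.ndarray) -> Solution:
        fitness, feasible, cost, rep = self.evaluate(flat[None, :])
        breakdown = FitnessBreakdown(
            representation=dict(zip(self.spec.species_ids, rep[0])),
            cost=int(cost[0]),
            connectivity=float(self.connectivity(flat[None, :])[0]),
            feasible=bool(feasible[0]),
            fitness=float(fitness[0]),
        )
        return Solution(protection=self.to_grid(flat), fitness=breakdown)


# ---------------------------------------------------------------------------
# Public single-solution operations
# ---------------------------------------------------------------------------

def representation(solution: Solution, spec: ProblemSpec) -> dict:
    """Per-species protected proportion of range under ``solution``."""
    comp = _Compiled(spec)
    rep = comp.representation(comp.from_grid(solution.protection)[None, :])[0]
    return dict(zip(spec.species_ids, rep))


def connectivity_score(solution: Solution) -> float:
    """Rook-adjacent protected pairs over 2k protected cells, in [0, 1]."""
    prot = solution.protection.presence
    k = int(prot.sum())
    if k == 0:
        return 0.0
    pairs = int((prot[:, :-1] & prot[:, 1:]).sum() + (prot[:-1, :] & prot[1:, :]).sum())
    return pairs / (2.0 * k)


def evaluate_fitness(
    solution: Solution, spec: ProblemSpec, weights: FitnessWeights | None = None
) -> FitnessBreakdown:
    if weights is not None:
        spec = dataclasses.replace(spec, fitness_weights=weights)
    comp = _Compiled(spec)
    return comp.solution(comp.from_grid(solution.protection)).fitness


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _window_swap(a: np.ndarray, b: np.ndarray, rows, cols, shape, rng):
    """Swap a random inclusive rectangular window between flat island vectors."""
    r0, r1 = np.sort(rng.integers(0, shape[0], size=2))
    c0, c1 = np.sort(rng.integers(0, shape[1], size=2))
    inwin = (rows >= r0) & (rows <= r1) & (cols >= c0) & (cols <= c1)
    a2, b2 = a.copy(), b.copy()
    a2[inwin], b2[inwin] = b[inwin], a[inwin]
    return a2, b2


def spatial_crossover(a: Solution, b: Solution, spec: ProblemSpec, rng) -> tuple:
    """Exchange a random rectangular raster window between two parents."""
    require_aligned(a.protection, b.protection)
    comp = _Compiled(spec)
    fa, fb = comp.from_grid(a.protection), comp.from_grid(b.protection)
    oa, ob = _window_swap(fa, fb, comp.rows, comp.cols, comp.shape, rng)
    return comp.solution(oa), comp.solution(ob)


def _mutate_flat(flat: np.ndarray, comp: _Compiled, config: GAConfig, rng) -> np.ndarray:
    if rng.random() * 100.0 >= config.mutation_rate:
        return flat
    out = flat.copy()
    i = int(rng.integers(comp.n))
    if rng.random() < config.neighborhood_bias:
        r, c = comp.rows[i], comp.cols[i]
        nb = (np.abs(comp.rows - r) + np.abs(comp.cols - c)) == 1
        n_nb = int(nb.sum())
        if n_nb:
            n_prot = int(out[nb].sum())
            if 2 * n_prot > n_nb:
                out[i] = True
            elif 2 * n_prot < n_nb:
                out[i] = False
            else:
                out[i] = ~out[i]
        else:
            out[i] = ~out[i]
    else:
        out[i] = ~out[i]
    if comp.lock is not None:
        out |= comp.lock
    return out


def spatial_mutation(s: Solution, spec: ProblemSpec, config: GAConfig, rng) -> Solution:
    """With probability mutation_rate/100, reassign one random island cell:
    with probability ``neighborhood_bias`` it adopts the majority class of
    its rook neighbours (so patch edges grow or shrink), otherwise it flips.
    """
    comp = _Compiled(spec)
    return comp.solution(_mutate_flat(comp.from_grid(s.protection), comp, config, rng))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _init_population(comp: _Compiled, config: GAConfig, rng) -> np.ndarray:
    """Random-density individuals plus two deterministic seeds: the trivial
    feasible point (everything / nothing protected) and the greedy solution,
    a standard memetic starting point the GA then refines."""
    n, m = config.population_size, comp.n
    density = rng.random((n, 1))
    pop = rng.random((n, m)) < density
    if comp.spec.formulation == "minimum_set":
        pop[0, :] = True  # protecting everything is the guaranteed feasible point
    else:
        pop[0, :] = False
        over = pop.sum(axis=1) > comp.spec.budget
        for i in np.flatnonzero(over):
            keep = rng.choice(np.flatnonzero(pop[i]), size=comp.spec.budget, replace=False)
            pop[i] = False
            pop[i, keep] = True
    if n > 1:
        try:
            pop[1] = comp.from_grid(greedy_baseline(comp.spec).protection)
        except InfeasibleProblemError:  # pragma: no cover - caught earlier
            pass
    if comp.lock is not None:
        pop |= comp.lock[None, :]
    return pop


def _check_feasible_region(comp: _Compiled) -> None:
    """The all-protected raster must meet every target (minimum_set)."""
    full = np.ones((1, comp.n), dtype=bool)
    _, feasible, _, rep = comp.evaluate(full)
    if comp.spec.formulation == "minimum_set" and not feasible[0]:
        bad = [
            f"{sid} (reach {rep[0][i]:.3f} < target {comp.targets[i]:.3f})"
            for i, sid in enumerate(comp.spec.species_ids)
            if rep[0][i] < comp.targets[i] - _EPS
        ]
        raise InfeasibleProblemError(
            "no feasible solution: even full protection misses " + "; ".join(bad)
        )


def _prune_incumbent(flat: np.ndarray, comp: _Compiled, rng) -> np.ndarray:
    """Fitness-improving local search for minimum set: drop protected cells
    (random order, repeated passes) while the solution stays feasible and
    its fitness rises. Turns any feasible solution into a 1-minimal one."""
    current = flat.copy()
    fit = comp.evaluate(current[None, :])[0][0]
    improved = True
    while improved:
        improved = False
        cells = np.flatnonzero(current)
        if comp.lock is not None:
            cells = cells[~comp.lock[cells]]
        for c in rng.permutation(cells):
            trial = current.copy()
            trial[c] = False
            tfit, tfeas, _, _ = comp.evaluate(trial[None, :])
            if tfeas[0] and tfit[0] > fit:
                current, fit = trial, float(tfit[0])
                improved = True
    return current


def _swap_improve(flat: np.ndarray, comp: _Compiled, rng, top: int = 12) -> np.ndarray:
    """One-for-one swap neighbourhood for minimum set: replace a protected
    cell with an unprotected one, re-prune, and accept on strict fitness
    improvement. Escapes the remove-two-add-one traps single-cell mutation
    cannot cross."""
    current = flat.copy()
    fit = comp.evaluate(current[None, :])[0][0]
    best, best_fit = current.copy(), fit
    sideways = 0
    max_sideways = 40  # bounded plateau walk across cost-equal solutions
    moved = True
    while moved:
        moved = False
        prot = np.flatnonzero(current)
        if comp.lock is not None:
            prot = prot[~comp.lock[prot]]
        unprot = np.flatnonzero(~current)
        if unprot.size == 0:
            break
        for c in rng.permutation(prot):
            trials = np.repeat(current[None, :], unprot.size, axis=0)
            trials[:, c] = False
            trials[np.arange(unprot.size), unprot] = True
            tfit, tfeas, _, _ = comp.evaluate(trials)
            order = np.argsort(tfit)[::-1][:top]
            for j in order:
                if not tfeas[j]:
                    continue
                pruned = _prune_incumbent(trials[j], comp, rng)
                pfit = float(comp.evaluate(pruned[None, :])[0][0])
                if pfit > fit + _EPS:
                    current, fit = pruned, pfit
                    sideways = 0
                    moved = True
                elif pfit > fit - _EPS and sideways < max_sideways:
                    current, fit = pruned, pfit
                    sideways += 1
                    moved = True
                if moved:
                    if fit > best_fit + _EPS:
                        best, best_fit = current.copy(), fit
                    break
            if moved:
                break
    return best


def ga_optimize(spec: ProblemSpec, config: GAConfig, seed_solutions=None) -> Solution:
    """Run the genetic algorithm and return the best feasible solution found.

    Deterministic for a fixed (spec, config): a single seeded generator
    drives initialization, selection and variation. Elitism re-injects the
    incumbent each generation, so the best fitness never decreases.
    ``seed_solutions`` (BinaryGrids, e.g. the current reserve network) are
    injected into the initial population as known candidates.
    """
    comp = _Compiled(spec)
    _check_feasible_region(comp)
    rng = np.random.default_rng(config.seed)
    pop = _init_population(comp, config, rng)
    for i, grid in enumerate(seed_solutions or []):
        slot = min(2 + i, config.population_size - 1)
        pop[slot] = comp.from_grid(grid)
    n_pop = config.population_size

    best_flat: np.ndarray | None = None
    best_fitness = NULL_FITNESS
    for _gen in range(config.generations + 1):
        fitness, feasible, _, _ = comp.evaluate(pop)
        gen_best = int(np.argmax(fitness))
        if feasible[gen_best] and fitness[gen_best] > best_fitness:
            cand = pop[gen_best].copy()
            if spec.formulation == "minimum_set":
                cand = _prune_incumbent(cand, comp, rng)
                if comp.n <= 100:  # affordable only on small instances
                    cand = _swap_improve(cand, comp, rng)
            best_fitness = float(comp.evaluate(cand[None, :])[0][0])
            best_flat = cand
        if _gen == config.generations:
            break
        # tournament selection (size 2, vectorized)
        cand = rng.integers(n_pop, size=(config.tournament_size, n_pop))
        winners = cand[0]
        for t in range(1, config.tournament_size):
            better = fitness[cand[t]] > fitness[winners]
            winners = np.where(better, cand[t], winners)
        offspring = pop[winners].copy()
        # pairwise rectangular-window crossover (batched draws)
        npairs = n_pop // 2
        do_cx = rng.random(npairs) * 100.0 < config.crossover_rate
        rwin = np.sort(rng.integers(0, comp.shape[0], size=(npairs, 2)), axis=1)
        cwin = np.sort(rng.integers(0, comp.shape[1], size=(npairs, 2)), axis=1)
        for p in np.flatnonzero(do_cx):
            i = 2 * p
            inwin = (
                (comp.rows >= rwin[p, 0]) & (comp.rows <= rwin[p, 1])
                & (comp.cols >= cwin[p, 0]) & (comp.cols <= cwin[p, 1])
            )
            tmp = offspring[i, inwin].copy()
            offspring[i, inwin] = offspring[i + 1, inwin]
            offspring[i + 1, inwin] = tmp
        # per-offspring single-cell mutation (batched draws)
        do_mut = rng.random(n_pop) * 100.0 < config.mutation_rate
        cells = rng.integers(comp.n, size=n_pop)
        majority = rng.random(n_pop) < config.neighborhood_bias
        for i in np.flatnonzero(do_mut):
            ci = cells[i]
            n_nb = comp.nbr_count[ci]
            if majority[i] and n_nb:
                nb = comp.nbr_idx[ci, :n_nb]
                n_prot = int(offspring[i, nb].sum())
                if 2 * n_prot > n_nb:
                    offspring[i, ci] = True
                elif 2 * n_prot < n_nb:
                    offspring[i, ci] = False
                else:
                    offspring[i, ci] = ~offspring[i, ci]
            else:
                offspring[i, ci] = ~offspring[i, ci]
        if comp.lock is not None:
            offspring |= comp.lock[None, :]
        # random immigrants keep exploring after the population converges
        n_imm = min(config.immigrants, n_pop - 1 - min(config.elite, 1))
        if n_imm > 0:
            dens = rng.random((n_imm, 1))
            imm = rng.random((n_imm, comp.n)) < dens
            if comp.lock is not None:
                imm |= comp.lock[None, :]
            offspring[-n_imm:] = imm
        # elitism: re-inject the incumbent(s)
        if best_flat is not None:
            for e in range(min(config.elite, 1)):
                offspring[e] = best_flat
        elif config.elite:
            offspring[0] = pop[gen_best]
        pop = offspring

    if best_flat is None:
        raise InfeasibleProblemError(
            "genetic algorithm found no feasible solution "
            f"({spec.formulation}, {config.generations} generations)"
        )
    return comp.solution(best_flat)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

_EXHAUSTIVE_GUARD = 25


def _enumerate_feasible(comp: _Compiled, candidates: np.ndarray, k: int, batch=200_000):
    """Yield (combo_matrix, feasible_mask) for all size-k subsets of candidates."""
    m = candidates.size
    combos = itertools.combinations(range(m), k)
    while True:
        chunk = np.array(list(itertools.islice(combos, batch)), dtype=int)
        if chunk.size == 0:
            return
        onehot = np.zeros((chunk.shape[0], comp.n), dtype=bool)
        rows = np.repeat(np.arange(chunk.shape[0]), k)
        onehot[rows, candidates[chunk.ravel()]] = True
        yield chunk, onehot


def exhaustive_minimum_set(spec: ProblemSpec) -> Solution:
    """Brute-force minimum set: smallest feasible subset, ties broken by
    higher connectivity then lexicographic cell order. Guarded to study
    areas of at most 25 cells.
    """
    comp = _Compiled(spec)
    if comp.n > _EXHAUSTIVE_GUARD:
        raise ValueError(f"exhaustive search limited to {_EXHAUSTIVE_GUARD} cells")
    _check_feasible_region(comp)
    # a minimum-cardinality feasible set never contains a cell outside every range
    candidates = np.flatnonzero(comp.S.any(axis=0))
    for k in range(1, candidates.size + 1):
        best = None
        for chunk, onehot in _enumerate_feasible(comp, candidates, k):
            rep = comp.representation(onehot)
            feas = np.all(rep >= comp.targets[None, :] - _EPS, axis=1)
            if not feas.any():
                continue
            conn = comp.connectivity(onehot[feas])
            idx = np.flatnonzero(feas)
            # combos stream in lexicographic order: first max-connectivity wins
            j = idx[int(np.argmax(conn))]
            if best is None or comp.connectivity(onehot[[j]])[0] > best[0]:
                best = (float(comp.connectivity(onehot[[j]])[0]), onehot[j])
        if best is not None:
            return comp.solution(best[1])
    raise InfeasibleProblemError("no feasible subset exists")  # pragma: no cover


def exhaustive_maximum_coverage(spec: ProblemSpec) -> Solution:
    """Brute-force maximum coverage: the subset within budget maximizing the
    same scalar fitness the GA uses. Guarded to 25 cells."""
    comp = _Compiled(spec)
    if comp.n > _EXHAUSTIVE_GUARD:
        raise ValueError(f"exhaustive search limited to {_EXHAUSTIVE_GUARD} cells")
    candidates = np.arange(comp.n)
    best_fit, best_flat = NULL_FITNESS, np.zeros(comp.n, dtype=bool)
    empty_fit, _, _, _ = comp.evaluate(best_flat[None, :])
    best_fit = float(empty_fit[0])
    for k in range(1, int(spec.budget) + 1):
        for _chunk, onehot in _enumerate_feasible(comp, candidates, k):
            fitness, _, _, _ = comp.evaluate(onehot)
            j = int(np.argmax(fitness))
            if fitness[j] > best_fit + _EPS:
                best_fit, best_flat = float(fitness[j]), onehot[j].copy()
    return comp.solution(best_flat)


def greedy_baseline(spec: ProblemSpec) -> Solution:
    """Greedy heuristic: repeatedly add the cell with the largest marginal
    weighted-target gain until feasible (minimum set) or the budget is
    exhausted (maximum coverage)."""
    comp = _Compiled(spec)
    if spec.formulation == "minimum_set":
        _check_feasible_region(comp)
    needed = np.ceil(comp.targets * comp.range_sizes - _EPS).astype(int)
    counts = np.zeros(len(needed), dtype=int)
    chosen = np.zeros(comp.n, dtype=bool)
    limit = comp.n if spec.formulation == "minimum_set" else int(spec.budget)
    w = comp.weights
    while chosen.sum() < limit:
        deficit = counts < needed
        if not deficit.any():
            break
        # marginal gain: weighted count of still-deficient species covered
        gains = (comp.S[deficit].astype(float) * w[deficit, None]).sum(axis=0)
        gains[chosen] = -1.0
        best = int(np.argmax(gains))  # ties: lexicographic (argmax takes first)
        if gains[best] <= 0:
            break
        chosen[best] = True
        counts += comp.S[:, best]
    return comp.solution(chosen)
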