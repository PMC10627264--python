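"""Mating-design optimization: candidate filtering, integer linear
programming for linear criteria, greedy allocation for unconstrained
designs, and a genetic algorithm with sharing for allocation-dependent
criteria (EMBV, UC3).

A design is an integer allocation vector D over candidate crosses. The
linear criteria (PM, UC1, UC2, OHV, and PROBA through log(1 - q)
coefficients) give objectives sum(c_ij * D_ij) optimized exactly by MILP;
EMBV and UC3 change value with the allocation itself and are optimized by
the GA, seeded with linear-programming solutions of a related criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .data_model import ConstraintSet, MatingDesign, canonical_pair

__all__ = [
    "OptimizationProblem",
    "GaConfig",
    "preselect_by_pm",
    "filter_related_pairs",
    "milp_optimize",
    "greedy_allocate",
    "ga_optimize",
    "validate_design",
    "relaxed_constraints",
]


# ---------------------------------------------------------------------------
# candidate filtering


def preselect_by_pm(cross_table: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Keep the top ceil(fraction * n) crosses by PM.

    Ties are broken by descending sigma, then by pair id, so the subset is
    deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if len(cross_table) == 0:
        raise ValueError("empty cross table")
    k = math.ceil(fraction * len(cross_table))
    ranked = cross_table.sort_values(
        by=["pm", "sigma", "parent_i", "parent_j"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return ranked.head(k).reset_index(drop=True)


def filter_related_pairs(
    cross_table: pd.DataFrame,
    G2: np.ndarray,
    parent_ids: list[str],
    quantile: float = 0.99,
) -> pd.DataFrame:
    """Drop crosses whose parents' G(2) covariance exceeds the empirical
    ``quantile`` of candidate-pair covariances (constraint C6).

    With quantile = 0.99 about 1% of candidate crosses are removed.
    """
    index = {p: k for k, p in enumerate(parent_ids)}
    missing = [p for p in set(cross_table["parent_i"]) | set(cross_table["parent_j"])
               if p not in index]
    if missing:
        raise KeyError(f"parents missing from G2: {missing[:5]}")
    ii = cross_table["parent_i"].map(index).to_numpy()
    jj = cross_table["parent_j"].map(index).to_numpy()
    cov = np.asarray(G2)[ii, jj]
    if quantile >= 1.0:
        return cross_table.reset_index(drop=True)
    thr = np.quantile(cov, quantile)
    return cross_table.loc[cov <= thr].reset_index(drop=True)


# ---------------------------------------------------------------------------
# problems and validation


@dataclass
class OptimizationProblem:
    """Linear allocation problem over candidate crosses."""

    pairs: list[tuple[str, str]]
    coefficients: np.ndarray
    constraints: ConstraintSet
    sense: str = "maximize"

    def __post_init__(self) -> None:
        self.pairs = [canonical_pair(a, b) for a, b in self.pairs]
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.size != len(self.pairs):
            raise ValueError("one coefficient per candidate cross required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite objective coefficients")
        if self.sense not in ("maximize", "minimize"):
            raise ValueError("sense must be maximize or minimize")

    def parents(self) -> list[str]:
        seen: dict = {}
        for a, b in self.pairs:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        return sorted(seen)


def _parent_incidence(pairs, parents) -> sparse.csr_matrix:
    pidx = {p: k for k, p in enumerate(parents)}
    rows, cols = [], []
    for j, (a, b) in enumerate(pairs):
        rows.extend((pidx[a], pidx[b]))
        cols.extend((j, j))
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(parents), len(pairs)))


def validate_design(
    design: MatingDesign,
    constraints: ConstraintSet,
    allowed_pairs: list[tuple[str, str]] | None = None,
) -> list[str]:
    """Independent constraint checker; returns a list of violations."""
    cons = constraints
    problems = []
    if design.total_progeny != cons.D_total:
        problems.append(f"C1: total progeny {design.total_progeny} != {cons.D_total}")
    for a, b, d in design.crosses:
        if not (cons.D_min <= d <= cons.D_max):
            problems.append(f"C2: cross {a}x{b} has {d} progeny outside "
                            f"[{cons.D_min}, {cons.D_max}]")
    if not (cons.K_min <= design.n_crosses <= cons.K_max):
        problems.append(f"C3: {design.n_crosses} crosses outside "
                        f"[{cons.K_min}, {cons.K_max}]")
    loads: dict[str, int] = {}
    for a, b, d in design.crosses:
        loads[a] = loads.get(a, 0) + d
        loads[b] = loads.get(b, 0) + d
    for p, load in loads.items():
        if load > cons.C_max:
            problems.append(f"C4: parent {p} receives {load} > {cons.C_max} progeny")
    if not (cons.P_min <= len(loads) <= cons.P_max):
        problems.append(f"C5: {len(loads)} parents outside "
                        f"[{cons.P_min}, {cons.P_max}]")
    if allowed_pairs is not None:
        allowed = {canonical_pair(a, b) for a, b in allowed_pairs}
        for a, b, _ in design.crosses:
            if (a, b) not in allowed:
                problems.append(f"C6: cross {a}x{b} not among candidate crosses")
    return problems


def relaxed_constraints(
    D_total: int, D_min: int, D_max: int, n_candidates: int, n_parents: int
) -> ConstraintSet:
    """C1 + C2 only: cross-count, parent-count and per-parent caps vacuous."""
    return ConstraintSet(
        D_total=D_total,
        D_min=D_min,
        D_max=D_max,
        K_min=math.ceil(D_total / D_max),
        K_max=n_candidates,
        C_max=D_total,
        P_min=2,
        P_max=n_parents,
        similarity_quantile=1.0,
    )


# ---------------------------------------------------------------------------
# MILP


def milp_optimize(
    problem: OptimizationProblem,
    mip_rel_gap: float = 1e-4,
    time_limit: float | None = None,
) -> MatingDesign:
    """Exact allocation for linear criteria by mixed-integer programming.

    Variables: D_ij (integer progeny counts), y_ij (cross used) and z_i
    (parent recruited). Encodes C1-C5 exactly; C6 is a pre-filter on the
    candidate list. Solved with the HiGHS branch-and-bound backend to a
    relative gap of ``mip_rel_gap``.
    """
    cons = problem.constraints
    pairs = problem.pairs
    n = len(pairs)
    parents = problem.parents()
    p = len(parents)
    M = _parent_incidence(pairs, parents)

    # variable layout: [D (n), y (n), z (p)]
    nv = 2 * n + p
    c = np.zeros(nv)
    c[:n] = problem.coefficients if problem.sense == "minimize" else -problem.coefficients

    A_rows = []
    lbs, ubs = [], []

    def add(A, lo, hi):
        A_rows.append(A)
        lbs.append(lo)
        ubs.append(hi)

    I_n = sparse.identity(n, format="csr")
    Z_np = sparse.csr_matrix((n, p))
    # C1: sum D = D_total
    add(sparse.hstack([sparse.csr_matrix(np.ones((1, n))),
                       sparse.csr_matrix((1, n + p))]),
        np.array([cons.D_total]), np.array([cons.D_total]))
    # C2: D_min*y <= D <= D_max*y
    add(sparse.hstack([I_n, -cons.D_max * I_n, Z_np]),
        np.full(n, -np.inf), np.zeros(n))
    add(sparse.hstack([I_n, -cons.D_min * I_n, Z_np]),
        np.zeros(n), np.full(n, np.inf))
    # C3: K_min <= sum y <= K_max
    add(sparse.hstack([sparse.csr_matrix((1, n)),
                       sparse.csr_matrix(np.ones((1, n))),
                       sparse.csr_matrix((1, p))]),
        np.array([cons.K_min]), np.array([cons.K_max]))
    # C4: per-parent progeny load <= C_max
    add(sparse.hstack([M, sparse.csr_matrix((p, n + p))]),
        np.zeros(p), np.full(p, cons.C_max))
    # C5 link: y_ij <= z_i for both parents of each pair
    pidx = {q: k for k, q in enumerate(parents)}
    rows, cols, data = [], [], []
    rr = 0
    for j, (a, b) in enumerate(pairs):
        for q in (a, b):
            rows.extend((rr, rr))
            cols.extend((n + j, 2 * n + pidx[q]))
            data.extend((1.0, -1.0))
            rr += 1
    add(sparse.csr_matrix((data, (rows, cols)), shape=(rr, nv)),
        np.full(rr, -np.inf), np.zeros(rr))
    # C5 link: z_i <= sum of y over pairs containing i
    add(sparse.hstack([sparse.csr_matrix((p, n)), -M, sparse.identity(p, format="csr")]),
        np.full(p, -np.inf), np.zeros(p))
    # C5: P_min <= sum z <= P_max
    add(sparse.hstack([sparse.csr_matrix((1, 2 * n)),
                       sparse.csr_matrix(np.ones((1, p)))]),
        np.array([cons.P_min]), np.array([cons.P_max]))

    A = sparse.vstack(A_rows, format="csc")
    constraint = LinearConstraint(A, np.concatenate([np.atleast_1d(l) for l in lbs]),
                                  np.concatenate([np.atleast_1d(u) for u in ubs]))
    bounds = Bounds(
        lb=np.zeros(nv),
        ub=np.concatenate([np.full(n, cons.D_max), np.ones(n + p)]),
    )
    options = {"mip_rel_gap": mip_rel_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(c, constraints=constraint, bounds=bounds,
               integrality=np.ones(nv), options=options)
    if res.status == 2 or res.x is None:
        raise RuntimeError(
            "infeasible mating-design problem under constraints "
            f"D_total={cons.D_total}, D=[{cons.D_min},{cons.D_max}], "
            f"K=[{cons.K_min},{cons.K_max}], C_max={cons.C_max}, "
            f"P=[{cons.P_min},{cons.P_max}]"
        )
    if res.status != 0:
        import warnings

        warnings.warn(f"MILP stopped early (status {res.status}); "
                      "returning best incumbent", stacklevel=2)
    D = np.rint(res.x[:n]).astype(int)
    crosses = [(a, b, int(d)) for (a, b), d in zip(pairs, D) if d > 0]
    return MatingDesign(crosses)


# ---------------------------------------------------------------------------
# greedy (NO CONSTRAINT rule)


def greedy_allocate(
    pairs: list[tuple[str, str]],
    coefficients: np.ndarray,
    D_total: int,
    D_max: int,
    sense: str = "maximize",
) -> MatingDesign:
    """Rank crosses by criterion value and fill the best with D_max progeny
    each; any remainder goes to the next cross."""
    coefficients = np.asarray(coefficients, float)
    k_full, rem = divmod(D_total, D_max)
    need = k_full + (1 if rem else 0)
    if need > len(pairs):
        raise ValueError(f"need {need} candidate crosses, only {len(pairs)} available")
    keys = -coefficients if sense == "maximize" else coefficients
    order = np.lexsort(
        (np.array([b for _, b in pairs]), np.array([a for a, _ in pairs]), keys)
    )
    crosses = [(pairs[k][0], pairs[k][1], D_max) for k in order[:k_full]]
    if rem:
        a, b = pairs[order[k_full]]
        crosses.append((a, b, rem))
    return MatingDesign(crosses)


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass
class GaConfig:
    """Tuning parameters for the allocation GA."""

    population_size: int = 100
    max_generations: int = 150
    stagnation_patience: int = 25
    mutation_rate: float = 0.4
    crossover_rate: float = 0.9
    sharing_radius: int = 0
    tournament_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.mutation_rate, self.crossover_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")


class _Repairer:
    """Feasibility repair: shift progeny from violating to slack crosses,
    dropping the lowest-coefficient crosses when counts must shrink."""

    def __init__(self, pairs, constraints: ConstraintSet, coeffs: np.ndarray):
        self.pairs = pairs
        self.cons = constraints
        self.coeffs = np.asarray(coeffs, float)
        self.parents = sorted({p for pr in pairs for p in pr})
        self.pidx = {p: k for k, p in enumerate(self.parents)}
        self.M = _parent_incidence(pairs, self.parents).toarray().astype(bool)
        # candidate order from worst to best coefficient, stable
        self.order_bad = np.lexsort(
            (np.arange(len(pairs)), self.coeffs)
        )
        self.order_good = self.order_bad[::-1]

    def loads(self, D: np.ndarray) -> np.ndarray:
        return self.M @ D

    def repair(self, D: np.ndarray, max_iter: int = 30) -> np.ndarray | None:
        cons = self.cons
        D = np.clip(np.rint(np.asarray(D, float)), 0, cons.D_max).astype(int)
        D[(D > 0) & (D < cons.D_min)] = cons.D_min
        for _ in range(max_iter):
            changed = False
            active = D > 0
            # C3 upper: drop worst active crosses
            if active.sum() > cons.K_max:
                for k in self.order_bad:
                    if active.sum() <= cons.K_max:
                        break
                    if D[k] > 0:
                        D[k] = 0
                        active[k] = False
                        changed = True
            # C5 upper: remove the least-loaded parents entirely
            while len(self._used_parents(D)) > cons.P_max:
                loads = self.loads(D)
                used = loads > 0
                worst = np.flatnonzero(used)[np.argmin(loads[used])]
                D[self.M[worst]] = 0
                changed = True
            # C4: reduce overloaded parents, worst coefficient first
            loads = self.loads(D)
            for pk in np.flatnonzero(loads > cons.C_max):
                excess = loads[pk] - cons.C_max
                for k in self.order_bad:
                    if excess <= 0:
                        break
                    if self.M[pk, k] and D[k] > 0:
                        cut = min(excess, D[k] - cons.D_min)
                        if cut < excess and D[k] > 0:
                            # dropping the cross entirely frees more
                            drop = D[k]
                            D[k] = 0
                            excess -= drop
                        else:
                            D[k] -= cut
                            excess -= cut
                        changed = True
                loads = self.loads(D)
            # C3 lower / C5 lower: activate best inactive crosses
            need_parents = cons.P_min - len(self._used_parents(D))
            need_crosses = cons.K_min - int((D > 0).sum())
            if need_parents > 0 or need_crosses > 0:
                used = set(self._used_parents(D))
                for k in self.order_good:
                    if D[k] > 0:
                        continue
                    a, b = self.pairs[k]
                    new_parents = {a, b} - used
                    if need_parents > 0 and not new_parents:
                        continue
                    if len(used | {a, b}) > cons.P_max:
                        continue
                    loads = self.loads(D)
                    if (loads[self.pidx[a]] + cons.D_min > cons.C_max
                            or loads[self.pidx[b]] + cons.D_min > cons.C_max):
                        continue
                    D[k] = cons.D_min
                    used |= {a, b}
                    need_parents = cons.P_min - len(used)
                    need_crosses -= 1
                    changed = True
                    if need_parents <= 0 and need_crosses <= 0:
                        break
            # C1: adjust the total
            diff = cons.D_total - int(D.sum())
            if diff > 0:
                loads = self.loads(D)
                for k in self.order_good:
                    if diff <= 0:
                        break
                    if D[k] == 0:
                        continue
                    a, b = self.pairs[k]
                    slack = min(
                        cons.D_max - D[k],
                        cons.C_max - loads[self.pidx[a]],
                        cons.C_max - loads[self.pidx[b]],
                    )
                    add = min(diff, max(slack, 0))
                    if add > 0:
                        D[k] += add
                        loads[self.pidx[a]] += add
                        loads[self.pidx[b]] += add
                        diff -= add
                        changed = True
                if diff > 0:
                    # open additional crosses if allowed
                    used = set(self._used_parents(D))
                    for k in self.order_good:
                        if diff <= 0 or (D > 0).sum() >= cons.K_max:
                            break
                        if D[k] > 0:
                            continue
                        a, b = self.pairs[k]
                        if len(used | {a, b}) > cons.P_max:
                            continue
                        loads = self.loads(D)
                        slack = min(
                            cons.D_max,
                            cons.C_max - loads[self.pidx[a]],
                            cons.C_max - loads[self.pidx[b]],
                        )
                        add = min(diff, slack)
                        if add >= cons.D_min:
                            D[k] = add
                            used |= {a, b}
                            diff -= add
                            changed = True
            elif diff < 0:
                for k in self.order_bad:
                    if diff >= 0:
                        break
                    if D[k] == 0:
                        continue
                    cut = min(-diff, D[k] - cons.D_min)
                    if cut > 0:
                        D[k] -= cut
                        diff += cut
                        changed = True
                if diff < 0:
                    for k in self.order_bad:
                        if diff >= 0 or (D > 0).sum() <= cons.K_min:
                            break
                        if D[k] > 0 and D[k] <= -diff:
                            diff += D[k]
                            D[k] = 0
                            changed = True
            if not changed and self._feasible(D):
                return D
            if self._feasible(D):
                return D
        return D if self._feasible(D) else None

    def _used_parents(self, D: np.ndarray) -> list[str]:
        loads = self.loads(D)
        return [self.parents[k] for k in np.flatnonzero(loads > 0)]

    def _feasible(self, D: np.ndarray) -> bool:
        design = _vector_to_design(D, self.pairs)
        if design is None:
            return False
        return not validate_design(design, self.cons)


def _vector_to_design(D: np.ndarray, pairs) -> MatingDesign | None:
    crosses = [(a, b, int(d)) for (a, b), d in zip(pairs, D) if d > 0]
    if not crosses:
        return None
    try:
        return MatingDesign(crosses)
    except ValueError:
        return None


def _design_to_vector(design: MatingDesign, pairs) -> np.ndarray:
    alloc = design.allocation()
    return np.array([alloc.get(pr, 0) for pr in pairs], dtype=int)


def ga_optimize(
    objective,
    pairs: list[tuple[str, str]],
    constraints: ConstraintSet,
    seed_designs: list[MatingDesign],
    config: GaConfig | None = None,
    repair_coeffs: np.ndarray | None = None,
) -> MatingDesign:
    """Genetic algorithm over allocation vectors (maximization).

    ``objective`` maps an (m, n_candidates) allocation array to m values.
    Half the initial population comes from the seed designs (typically
    linear-programming solutions of a related criterion), half from
    repaired random allocations. Selection is by tournament on
    sharing-adjusted fitness (fitness divided by the count of population
    members within Hamming distance ``sharing_radius``; the default radius
    0 counts exact duplicates). Crossover exchanges per-cross allocations
    uniformly; mutation moves progeny between crosses; every offspring is
    repaired to feasibility. Elitism guarantees the result is at least as
    good as the best seed. Deterministic given ``config.seed``.
    """
    config = config or GaConfig()
    rng = np.random.default_rng(config.seed)
    pairs = [canonical_pair(a, b) for a, b in pairs]
    n = len(pairs)
    if repair_coeffs is None:
        repair_coeffs = np.zeros(n)
    rep = _Repairer(pairs, constraints, repair_coeffs)

    seeds = []
    for dsn in seed_designs:
        vec = _design_to_vector(dsn, pairs)
        if vec.sum() != dsn.total_progeny:
            raise ValueError("seed design contains crosses outside the candidate set")
        if not rep._feasible(vec):
            raise ValueError("seed design violates the constraint set")
        seeds.append(vec)
    if not seeds:
        base = rep.repair(np.zeros(n, dtype=int))
        if base is None:
            raise RuntimeError("no feasible design constructible by repair")
        seeds = [base]

    pop = []
    half = config.population_size // 2
    while len(pop) < min(half, len(seeds) * 8):
        base = seeds[len(pop) % len(seeds)]
        if len(pop) < len(seeds):
            pop.append(base.copy())
        else:
            pop.append(_mutate(base, rep, rng))
    while len(pop) < config.population_size:
        rand = np.zeros(n, dtype=int)
        k = rng.integers(constraints.K_min, constraints.K_max + 1)
        picks = rng.choice(n, size=min(k, n), replace=False)
        rand[picks] = rng.integers(constraints.D_min, constraints.D_max + 1,
                                   size=len(picks))
        fixed = rep.repair(rand)
        pop.append(fixed if fixed is not None else seeds[0].copy())
    pop = np.array(pop)

    best_vec = None
    best_val = -np.inf
    stagnant = 0
    for _gen in range(config.max_generations):
        fitness = np.asarray(objective(pop), float)
        # sharing: penalize duplicated allocation vectors
        if config.sharing_radius == 0:
            _, inverse, counts = np.unique(
                pop, axis=0, return_inverse=True, return_counts=True
            )
            niche = counts[inverse]
        else:
            ham = (pop[:, None, :] != pop[None, :, :]).sum(axis=2)
            niche = (ham <= config.sharing_radius).sum(axis=1)
        shifted = fitness - fitness.min() + 1e-9
        shared = shifted / niche

        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_val + 1e-12:
            best_val = float(fitness[gen_best])
            best_vec = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= config.stagnation_patience:
            break

        children = [best_vec.copy()]  # elitism
        while len(children) < config.population_size:
            a = _tournament(shared, config.tournament_size, rng)
            b = _tournament(shared, config.tournament_size, rng)
            if rng.random() < config.crossover_rate:
                mask = rng.random(n) < 0.5
                child = np.where(mask, pop[a], pop[b])
            else:
                child = pop[a].copy()
            if rng.random() < config.mutation_rate:
                child = _mutate(child, rep, rng, repair=False)
            fixed = rep.repair(child)
            children.append(fixed if fixed is not None else
                            seeds[int(rng.integers(len(seeds)))].copy())
        pop = np.array(children)

    final_fit = np.asarray(objective(pop), float)
    gen_best = int(np.argmax(final_fit))
    if final_fit[gen_best] > best_val:
        best_val = float(final_fit[gen_best])
        best_vec = pop[gen_best].copy()
    design = _vector_to_design(best_vec, pairs)
    assert design is not None
    return design


def _tournament(shared: np.ndarray, size: int, rng: np.random.Generator) -> int:
    picks = rng.integers(0, len(shared), size=size)
    return int(picks[np.argmax(shared[picks])])


def _mutate(vec: np.ndarray, rep: _Repairer, rng: np.random.Generator,
            repair: bool = True) -> np.ndarray:
    """Move progeny between crosses; occasionally open or close a cross."""
    child = vec.copy()
    n = len(child)
    move = int(rng.integers(1, 6))
    active = np.flatnonzero(child > 0)
    if len(active) == 0:
        return child
    src = int(rng.choice(active))
    dst = int(rng.integers(0, n))
    child[src] = max(child[src] - move, 0)
    child[dst] += move
    if rng.random() < 0.2:  # open a random new cross
        k = int(rng.integers(0, n))
        if child[k] == 0:
            child[k] = rep.cons.D_min
    if repair:
        fixed = rep.repair(child)
        return fixed if fixed is not None else vec.copy()
    return child
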