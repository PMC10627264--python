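"""Mating-design optimization: preselection, relatedness filtering, MILP
against brute force, greedy allocation, GA behaviour, validation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from crossplan.data_model import ConstraintSet, MatingDesign
from crossplan.gblup import grm_ld_weighted
from crossplan.optimize import (
    GaConfig,
    OptimizationProblem,
    filter_related_pairs,
    ga_optimize,
    greedy_allocate,
    milp_optimize,
    preselect_by_pm,
    relaxed_constraints,
    validate_design,
)
from crossplan.progeny_variance import all_pairs
from crossplan.simulate import SimulationConfig, generate_founders


TOY_PAIRS = [("P0", "P1"), ("P0", "P2"), ("P1", "P2"), ("P2", "P3"),
             ("P3", "P4"), ("P4", "P5"), ("P1", "P4"), ("P0", "P5")]
TOY_CONS = ConstraintSet(D_total=20, D_min=2, D_max=10, K_min=2, K_max=4,
                         C_max=12, P_min=3, P_max=6)


def _enumerate_best(pairs, cons, value):
    """Exhaustive search over feasible designs; value(vec) -> float."""
    best, best_vec = -np.inf, None
    for k in range(cons.K_min, cons.K_max + 1):
        for subset in itertools.combinations(range(len(pairs)), k):
            for alloc in itertools.product(
                range(cons.D_min, cons.D_max + 1), repeat=k
            ):
                if sum(alloc) != cons.D_total:
                    continue
                design = MatingDesign(
                    [(pairs[i][0], pairs[i][1], a) for i, a in zip(subset, alloc)]
                )
                if validate_design(design, cons):
                    continue
                vec = np.zeros(len(pairs), dtype=int)
                vec[list(subset)] = alloc
                v = value(vec)
                if v > best:
                    best, best_vec = v, vec
    return best, best_vec


class TestPreselect:
    def _table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "parent_i": [f"a{k}" for k in range(n)],
            "parent_j": [f"b{k}" for k in range(n)],
            "pm": rng.normal(size=n),
            "sigma": rng.uniform(0.5, 2.0, n),
        })

    def test_full_fraction_is_identity(self):
        t = self._table()
        out = preselect_by_pm(t, 1.0)
        assert set(map(tuple, out[["parent_i", "parent_j"]].values)) == set(
            map(tuple, t[["parent_i", "parent_j"]].values)
        )

    def test_ceiling_count(self):
        t = self._table(n=35)
        assert len(preselect_by_pm(t, 0.10)) == math.ceil(3.5)

    def test_ten_percent_of_full_diallel(self):
        assert math.ceil(0.10 * 348_195) == 34_820

    def test_tie_break_deterministic(self):
        t = self._table()
        t["pm"] = 1.0
        out1 = preselect_by_pm(t, 0.2)
        out2 = preselect_by_pm(t.sample(frac=1.0, random_state=3), 0.2)
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            preselect_by_pm(self._table(0), 0.1)


class TestRelatednessFilter:
    def test_quantile_one_removes_nothing(self, small_panel):
        f = small_panel["founders"]
        pairs = all_pairs(f.ids)
        table = pd.DataFrame(pairs, columns=["parent_i", "parent_j"])
        G2 = grm_ld_weighted(f)
        out = filter_related_pairs(table, G2, f.ids, 1.0)
        assert len(out) == len(table)

    def test_removes_about_one_percent(self):
        cfg = SimulationConfig(n_founders=200, n_loci=150, n_chromosomes=3,
                               seed=4)
        f, _ = generate_founders(cfg)
        pairs = all_pairs(f.ids)
        table = pd.DataFrame(pairs, columns=["parent_i", "parent_j"])
        G2 = grm_ld_weighted(f)
        out = filter_related_pairs(table, G2, f.ids, 0.99)
        removed = 1.0 - len(out) / len(table)
        assert removed == pytest.approx(0.01, abs=0.002)

    def test_matches_brute_force_on_toy(self):
        cfg = SimulationConfig(n_founders=20, n_loci=60, n_chromosomes=2, seed=5)
        f, _ = generate_founders(cfg)
        pairs = all_pairs(f.ids)
        table = pd.DataFrame(pairs, columns=["parent_i", "parent_j"])
        G2 = grm_ld_weighted(f)
        out = filter_related_pairs(table, G2, f.ids, 0.95)
        idx = {p: k for k, p in enumerate(f.ids)}
        covs = np.array([G2[idx[a], idx[b]] for a, b in pairs])
        thr = np.quantile(covs, 0.95)
        expected = {(a, b) for (a, b), c in zip(pairs, covs) if c <= thr}
        assert set(map(tuple, out[["parent_i", "parent_j"]].values)) == expected

    def test_missing_parent_rejected(self, small_panel):
        f = small_panel["founders"]
        table = pd.DataFrame([("ghost", f.ids[0])],
                             columns=["parent_i", "parent_j"])
        with pytest.raises(KeyError, match="ghost"):
            filter_related_pairs(table, grm_ld_weighted(f), f.ids, 0.99)


class TestMilp:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        coeffs = rng.normal(10, 2, len(TOY_PAIRS))
        design = milp_optimize(OptimizationProblem(TOY_PAIRS, coeffs, TOY_CONS))
        assert not validate_design(design, TOY_CONS, TOY_PAIRS)
        obj = sum(coeffs[TOY_PAIRS.index((a, b))] * d for a, b, d in design.crosses)
        best, _ = _enumerate_best(TOY_PAIRS, TOY_CONS, lambda v: float(v @ coeffs))
        assert obj == pytest.approx(best, rel=1e-6)

    def test_minimize_sense_matches_enumeration(self):
        rng = np.random.default_rng(1)
        coeffs = -rng.uniform(0.1, 1.0, len(TOY_PAIRS))  # PROBA-like log(1-q)
        design = milp_optimize(
            OptimizationProblem(TOY_PAIRS, coeffs, TOY_CONS, sense="minimize")
        )
        obj = sum(coeffs[TOY_PAIRS.index((a, b))] * d for a, b, d in design.crosses)
        best, _ = _enumerate_best(TOY_PAIRS, TOY_CONS, lambda v: -float(v @ coeffs))
        assert obj == pytest.approx(-best, rel=1e-6)

    def test_relaxed_constraints_reduce_to_greedy(self):
        rng = np.random.default_rng(2)
        coeffs = rng.uniform(5, 15, len(TOY_PAIRS))
        cons = relaxed_constraints(20, 2, 10, len(TOY_PAIRS), 6)
        design = milp_optimize(OptimizationProblem(TOY_PAIRS, coeffs, cons))
        greedy = greedy_allocate(TOY_PAIRS, coeffs, 20, 10)
        obj = sum(coeffs[TOY_PAIRS.index((a, b))] * d for a, b, d in design.crosses)
        gobj = sum(coeffs[TOY_PAIRS.index((a, b))] * d for a, b, d in greedy.crosses)
        assert obj == pytest.approx(gobj, rel=1e-9)

    def test_beats_any_hand_design(self):
        rng = np.random.default_rng(3)
        coeffs = rng.normal(10, 3, len(TOY_PAIRS))
        design = milp_optimize(OptimizationProblem(TOY_PAIRS, coeffs, TOY_CONS))
        obj = sum(coeffs[TOY_PAIRS.index((a, b))] * d for a, b, d in design.crosses)
        hand = MatingDesign([("P0", "P1", 8), ("P2", "P3", 6), ("P4", "P5", 6)])
        assert not validate_design(hand, TOY_CONS)
        hobj = sum(coeffs[TOY_PAIRS.index(tuple(sorted((a, b))))] * d
                   for a, b, d in hand.crosses)
        assert obj >= hobj - 1e-9

    def test_infeasible_constraint_set_guarded(self):
        with pytest.raises(ValueError, match="infeasible"):
            ConstraintSet(D_total=10, D_min=6, D_max=10, K_min=2, K_max=3,
                          P_min=2, P_max=6)


class TestGreedy:
    def test_paper_scale_allocation(self):
        pairs = [(f"x{k}", f"y{k}") for k in range(100)]
        coeffs = np.arange(100, dtype=float)
        design = greedy_allocate(pairs, coeffs, 3300, 60)
        assert design.n_crosses == 55
        assert all(d == 60 for _, _, d in design.crosses)

    def test_remainder_allocation(self):
        pairs = [(f"x{k}", f"y{k}") for k in range(5)]
        design = greedy_allocate(pairs, np.array([5.0, 4, 3, 2, 1]), 130, 60)
        assert sorted((d for _, _, d in design.crosses), reverse=True) == [60, 60, 10]

    def test_single_candidate_takes_all(self):
        design = greedy_allocate([("a", "b")], np.array([1.0]), 40, 60)
        assert design.crosses == [("a", "b", 40)]

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidate"):
            greedy_allocate([("a", "b")], np.array([1.0]), 200, 60)


class TestGa:
    def _objective(self):
        rng = np.random.default_rng(42)
        pm_v = rng.normal(10, 2, len(TOY_PAIRS))
        sig = np.abs(rng.normal(2, 0.5, len(TOY_PAIRS)))

        from crossplan import criteria as csc

        def objective(pop):
            pop = np.atleast_2d(pop)
            ints = csc.embv_int(np.maximum(pop, 1))
            return (pop * (pm_v + ints * sig)).sum(axis=1)

        return objective, pm_v, sig

    def test_finds_enumeration_optimum_in_most_seeds(self):
        objective, pm_v, sig = self._objective()
        best, _ = _enumerate_best(TOY_PAIRS, TOY_CONS,
                                  lambda v: float(objective(v)[0]))
        seed_design = milp_optimize(
            OptimizationProblem(TOY_PAIRS, pm_v + 1.2 * sig, TOY_CONS)
        )
        hits = 0
        for s in range(10):
            d = ga_optimize(
                objective, TOY_PAIRS, TOY_CONS, [seed_design],
                GaConfig(population_size=40, max_generations=80,
                         stagnation_patience=30, seed=s),
                repair_coeffs=pm_v,
            )
            vec = np.zeros(len(TOY_PAIRS), dtype=int)
            for a, b, dd in d.crosses:
                vec[TOY_PAIRS.index((a, b))] = dd
            assert not validate_design(d, TOY_CONS, TOY_PAIRS)
            hits += abs(objective(vec)[0] - best) < 1e-9
        assert hits >= 9

    def test_never_below_seed_objective(self):
        objective, pm_v, sig = self._objective()
        seed_design = milp_optimize(
            OptimizationProblem(TOY_PAIRS, pm_v, TOY_CONS)
        )
        seed_vec = np.zeros(len(TOY_PAIRS), dtype=int)
        for a, b, dd in seed_design.crosses:
            seed_vec[TOY_PAIRS.index((a, b))] = dd
        seed_obj = objective(seed_vec)[0]
        for s in range(5):
            d = ga_optimize(
                objective, TOY_PAIRS, TOY_CONS, [seed_design],
                GaConfig(population_size=30, max_generations=20,
                         stagnation_patience=10, seed=s),
                repair_coeffs=pm_v,
            )
            vec = np.zeros(len(TOY_PAIRS), dtype=int)
            for a, b, dd in d.crosses:
                vec[TOY_PAIRS.index((a, b))] = dd
            assert objective(vec)[0] >= seed_obj - 1e-9

    def test_deterministic_given_seed(self):
        objective, pm_v, sig = self._objective()
        seed_design = milp_optimize(
            OptimizationProblem(TOY_PAIRS, pm_v, TOY_CONS)
        )
        d1 = ga_optimize(objective, TOY_PAIRS, TOY_CONS, [seed_design],
                         GaConfig(population_size=30, max_generations=25,
                                  stagnation_patience=10, seed=7),
                         repair_coeffs=pm_v)
        d2 = ga_optimize(objective, TOY_PAIRS, TOY_CONS, [seed_design],
                         GaConfig(population_size=30, max_generations=25,
                                  stagnation_patience=10, seed=7),
                         repair_coeffs=pm_v)
        assert d1.allocation() == d2.allocation()


class TestValidator:
    def test_detects_each_violation(self):
        cons = TOY_CONS
        # wrong total
        v = validate_design(MatingDesign([("P0", "P1", 10), ("P2", "P3", 9)]), cons)
        assert any(x.startswith("C1") for x in v)
        # progeny bounds
        v = validate_design(
            MatingDesign([("P0", "P1", 1), ("P2", "P3", 10), ("P1", "P4", 9)]),
            cons,
        )
        assert any(x.startswith("C2") for x in v)
        # unknown pair
        v = validate_design(
            MatingDesign([("P0", "P3", 10), ("P1", "P2", 10)]), cons, TOY_PAIRS
        )
        assert any(x.startswith("C6") for x in v)

    def test_proba_design_beats_pm_on_no_success_probability(self):
        """Minimizing sum D*log(1-q) yields a design whose probability of
        producing no progeny over the threshold is at most that of the
        PM-optimal design."""
        rng = np.random.default_rng(11)
        pm_v = rng.normal(10, 2, len(TOY_PAIRS))
        q = np.clip(rng.uniform(0.001, 0.2, len(TOY_PAIRS)), 1e-9, 1)
        log_coeff = np.log1p(-q)
        d_proba = milp_optimize(
            OptimizationProblem(TOY_PAIRS, log_coeff, TOY_CONS, sense="minimize")
        )
        d_pm = milp_optimize(OptimizationProblem(TOY_PAIRS, pm_v, TOY_CONS))

        def logp_no_success(design):
            return sum(log_coeff[TOY_PAIRS.index((a, b))] * d
                       for a, b, d in design.crosses)

        assert logp_no_success(d_proba) <= logp_no_success(d_pm) + 1e-9
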