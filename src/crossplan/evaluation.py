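"""Scoring mating designs by simulated progeny: realized genetic gain,
genic variance, estimation diagnostics, parental-contribution profiles,
Pareto fronts, and the scenario runner combining them.

The central consistency property of the package is checked here: family
means of simulated F5 progeny match the parental mean, and family variances
match the analytic progeny variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import criteria as csc
from .data_model import (
    ConstraintSet,
    EffectVector,
    GeneticMap,
    GenotypeMatrix,
    MatingDesign,
    TraitArchitecture,
    compute_breeding_values,
)
from .gblup import backsolve_effects, grm_ld_weighted, grm_vanraden, reml_fit
from .optimize import (
    GaConfig,
    OptimizationProblem,
    filter_related_pairs,
    ga_optimize,
    greedy_allocate,
    milp_optimize,
    preselect_by_pm,
    relaxed_constraints,
)
from .progeny_variance import all_pairs, batch_cross_variances, build_kernel
from .simulate import (
    SimulationConfig,
    build_selected_population,
    generate_founders,
    ril_f5_batch,
    sample_architecture,
    simulate_phenotypes,
    _interval_recomb,
)

__all__ = [
    "ScenarioSpec",
    "simulate_design_progeny",
    "relative_gain",
    "genic_variance",
    "relative_genic_change",
    "diagnostics",
    "contribution_profile",
    "pareto_front",
    "run_scenario",
    "CRITERIA",
]

CRITERIA = ("pm", "uc1", "uc2", "uc3", "proba", "embv", "ohv")


@dataclass
class ScenarioSpec:
    """One cell of the scenario grid plus its simulation effort."""

    population: str = "unselected"  # {unselected, selected}
    effects: str = "true"  # {true, estimated}
    constraint_modes: tuple = ("constraint", "no_constraint")
    n_architectures: int = 30
    n_progeny_reps: int = 20
    selection_rates: tuple = (0.0003, 0.01, 0.07)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population not in ("unselected", "selected"):
            raise ValueError("population must be unselected or selected")
        if self.effects not in ("true", "estimated"):
            raise ValueError("effects must be true or estimated")
        if self.n_progeny_reps < 1:
            raise ValueError("n_progeny_reps must be >= 1")
        for r in self.selection_rates:
            if not (0.0 < r <= 1.0):
                raise ValueError("selection rates must be in (0, 1]")


# ---------------------------------------------------------------------------
# progeny simulation and summaries


def simulate_design_progeny(
    design: MatingDesign,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    architecture: TraitArchitecture,
    n_reps: int,
    seed: int,
) -> list[dict]:
    """Simulate the F5 RIL progeny of a mating design.

    Returns one dict per replicate with keys ``tbv`` (progeny TBV),
    ``doses_qtl`` (progeny QTL doses) and ``family`` (cross index per
    progeny). Each replicate regenerates every progeny by meiosis, so
    family summaries can be compared to the analytic predictions.
    """
    effects = architecture.effects()
    qtl_cols = [genotypes.locus_ids.index(l) for l in effects.locus_ids]
    flip_cache = _interval_recomb(gmap)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    out = []
    for _rep in range(n_reps):
        tbv_parts, dose_parts, fam_parts = [], [], []
        for k, (a, b, d) in enumerate(design.crosses):
            prog = ril_f5_batch(
                genotypes.row(a), genotypes.row(b), d, gmap, rng,
                flip_cache=flip_cache,
            )
            dq = prog[:, qtl_cols]
            tbv_parts.append(dq @ effects.values)
            dose_parts.append(dq)
            fam_parts.append(np.full(d, k))
        out.append(
            {
                "tbv": np.concatenate(tbv_parts),
                "doses_qtl": np.vstack(dose_parts),
                "family": np.concatenate(fam_parts),
            }
        )
    return out


def _top_fraction(values: np.ndarray, rate: float) -> np.ndarray:
    k = max(1, int(round(rate * len(values))))
    idx = np.argsort(values)[::-1][:k]
    return idx


def relative_gain(
    progeny_tbv_csc: list[np.ndarray],
    progeny_tbv_pm: list[np.ndarray],
    parent_tbv_mean: float,
    rate: float,
) -> float:
    """Additional gain of a criterion over PM, averaged over replicates:
    mean over reps of (TBV_csc - TBV_pm) / (TBV_pm - TBV_parents), with
    TBV_* the mean of the top ``rate`` fraction of progeny.
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError("rate must be in (0, 1]")
    vals = []
    for t_c, t_p in zip(progeny_tbv_csc, progeny_tbv_pm):
        top_c = t_c[_top_fraction(t_c, rate)].mean()
        top_p = t_p[_top_fraction(t_p, rate)].mean()
        denom = top_p - parent_tbv_mean
        if denom == 0:
            return float("nan")
        vals.append((top_c - top_p) / denom)
    return float(np.mean(vals))


def genic_variance(doses_qtl: np.ndarray, beta: np.ndarray) -> float:
    """Linkage-equilibrium genetic variance sum_l 4 beta_l^2 p_l (1 - p_l)
    at the QTL allele frequencies of the given progeny set."""
    if doses_qtl.shape[0] == 0:
        raise ValueError("empty progeny selection")
    p = doses_qtl.mean(axis=0) / 2.0
    return float(np.sum(4.0 * beta**2 * p * (1.0 - p)))


def relative_genic_change(
    genic_csc: list[float], genic_pm: list[float], genic_parents: float
) -> float:
    """Relative change in genic variance of a criterion vs PM, scaled by the
    PM-to-parents contrast, averaged over replicates."""
    vals = []
    for g_c, g_p in zip(genic_csc, genic_pm):
        denom = g_p - genic_parents
        if denom == 0:
            return float("nan")
        vals.append((g_c - g_p) / denom)
    return float(np.mean(vals))


def diagnostics(
    table_true: pd.DataFrame,
    table_est: pd.DataFrame | None = None,
    top_pm_fraction: float = 0.10,
) -> dict:
    """t-ratio and accuracy correlations over the top-PM candidate crosses.

    t = var(sigma) / var(PM) on the ``top_pm_fraction`` highest-PM crosses
    of the *true* table; with an estimated table aligned on the same pairs,
    Pearson correlations cor(PM_hat, PM) and cor(sigma_hat, sigma) are
    computed on the subset ranked by estimated PM.
    """
    ranked = table_true.sort_values("pm", ascending=False, kind="mergesort")
    k = max(3, math.ceil(top_pm_fraction * len(ranked)))
    if len(ranked) < 3:
        raise ValueError("need at least 3 crosses")
    sub = ranked.head(k)
    out = {
        "t_ratio": float(np.var(sub["sigma"], ddof=1) / np.var(sub["pm"], ddof=1)),
    }
    if table_est is not None:
        key = ["parent_i", "parent_j"]
        merged = table_est.sort_values("pm", ascending=False, kind="mergesort").head(
            max(3, math.ceil(top_pm_fraction * len(table_est)))
        ).merge(table_true, on=key, suffixes=("_est", "_true"))
        out["cor_pm"] = float(np.corrcoef(merged["pm_est"], merged["pm_true"])[0, 1])
        out["cor_sigma"] = float(
            np.corrcoef(merged["sigma_est"], merged["sigma_true"])[0, 1]
        )
        out["t_ratio_est"] = float(
            np.var(merged["sigma_est"], ddof=1) / np.var(merged["pm_est"], ddof=1)
        )
        # unconditioned accuracies over every candidate cross: free of the
        # range restriction that top-PM conditioning induces on small panels
        full = table_est.merge(table_true, on=key, suffixes=("_est", "_true"))
        out["cor_pm_all"] = float(
            np.corrcoef(full["pm_est"], full["pm_true"])[0, 1]
        )
        out["cor_sigma_all"] = float(
            np.corrcoef(full["sigma_est"], full["sigma_true"])[0, 1]
        )
    return out


def contribution_profile(design: MatingDesign) -> pd.DataFrame:
    """Per-parent progeny counts and shares (each progeny counts once for
    each of its two parents, consistent with the per-parent cap)."""
    loads: dict[str, int] = {}
    for a, b, d in design.crosses:
        loads[a] = loads.get(a, 0) + d
        loads[b] = loads.get(b, 0) + d
    total = design.total_progeny
    df = pd.DataFrame(
        {"parent": list(loads), "n_progeny": list(loads.values())}
    ).sort_values("n_progeny", ascending=False, kind="mergesort")
    df["share"] = df["n_progeny"] / (2.0 * total)
    return df.reset_index(drop=True)


def pareto_front(points: dict[str, tuple[float, float]]) -> list[str]:
    """Non-dominated subset under (>=, >=) dominance of (gain, diversity)."""
    names = list(points)
    front = []
    for a in names:
        ga, da = points[a]
        dominated = any(
            (points[b][0] >= ga and points[b][1] >= da)
            and (points[b][0] > ga or points[b][1] > da)
            for b in names
            if b != a
        )
        if not dominated:
            front.append(a)
    return front


# ---------------------------------------------------------------------------
# scenario runner


def _optimize_for_criterion(
    crit: str,
    table: pd.DataFrame,
    constraints: ConstraintSet,
    mode: str,
    seed: int,
    ga_config: GaConfig | None = None,
    lp_cache: dict | None = None,
) -> MatingDesign:
    pairs = list(zip(table["parent_i"], table["parent_j"]))
    sig = table["sigma"].to_numpy(float)
    pm_v = table["pm"].to_numpy(float)
    lp_cache = lp_cache if lp_cache is not None else {}

    def linear(crit_name):
        if crit_name == "proba":
            return csc.proba_objective_coeff(table["proba"].to_numpy()), "minimize"
        return table[crit_name].to_numpy(float), "maximize"

    if mode == "no_constraint":
        cons = relaxed_constraints(
            constraints.D_total, constraints.D_min, constraints.D_max,
            len(pairs), len(set(table["parent_i"]) | set(table["parent_j"])),
        )
    else:
        cons = constraints

    if crit in ("pm", "uc1", "uc2", "ohv", "proba"):
        coeffs, sense = linear(crit)
        if mode == "no_constraint":
            return greedy_allocate(pairs, coeffs, cons.D_total, cons.D_max, sense)
        key = (crit, mode)
        if key not in lp_cache:
            lp_cache[key] = milp_optimize(
                OptimizationProblem(pairs, coeffs, cons, sense)
            )
        return lp_cache[key]

    # allocation-dependent criteria
    ga_config = ga_config or GaConfig()
    ga_config = GaConfig(
        population_size=ga_config.population_size,
        max_generations=ga_config.max_generations,
        stagnation_patience=ga_config.stagnation_patience,
        mutation_rate=ga_config.mutation_rate,
        crossover_rate=ga_config.crossover_rate,
        sharing_radius=ga_config.sharing_radius,
        tournament_size=ga_config.tournament_size,
        seed=seed,
    )
    if crit == "embv":
        def objective(pop):
            pop = np.atleast_2d(pop)
            ints = csc.embv_int(np.maximum(pop, 1))
            vals = pop * (pm_v + ints * sig)
            return vals.sum(axis=1)

        seed_crit = "uc1"
    elif crit == "uc3":
        q = 0.07

        def objective(pop):
            pop = np.atleast_2d(pop)
            return np.array(
                [csc.uc3_objective(row, pm_v, sig, q) for row in pop]
            )

        seed_crit = "proba"
    else:
        raise ValueError(f"unknown criterion {crit!r}")

    coeffs, sense = linear(seed_crit)
    if mode == "no_constraint":
        seed_design = greedy_allocate(pairs, coeffs, cons.D_total, cons.D_max, sense)
    else:
        key = (seed_crit, mode)
        if key not in lp_cache:
            lp_cache[key] = milp_optimize(
                OptimizationProblem(pairs, coeffs, cons, sense)
            )
        seed_design = lp_cache[key]
    # repair decisions rank crosses by the seed criterion's coefficients
    repair_coeffs = coeffs if sense == "maximize" else -coeffs
    return ga_optimize(objective, pairs, cons, [seed_design], ga_config,
                       repair_coeffs=repair_coeffs)


def _scored_tables(
    parents: GenotypeMatrix,
    gmap: GeneticMap,
    architecture: TraitArchitecture,
    spec: ScenarioSpec,
    sim: SimulationConfig,
    arch_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """True-effects cross table, and estimated-effects table when the spec
    asks for ESTIMATED scenarios (GBLUP fitted once and reused)."""
    true_eff = architecture.effects()
    tbv = compute_breeding_values(parents, true_eff)
    pairs = all_pairs(parents.ids)

    kernel_true = build_kernel(true_eff, gmap)
    table_true = batch_cross_variances(parents, kernel_true, pairs)
    alpha_true = dict(zip(parents.ids, tbv))
    table_true = csc.score_table(
        table_true, alpha_true, genotypes=parents, effects=true_eff, gmap=gmap
    )

    info = {"tbv": tbv, "parent_mean_tbv": float(tbv.mean())}
    if spec.effects == "true":
        return table_true, None, info

    y = simulate_phenotypes(tbv, sim.noise_variance, arch_seed + 13)
    qtl_set = set(true_eff.locus_ids)
    G, Z, p, marker_ids = grm_vanraden(parents, exclude=qtl_set)
    fit = reml_fit(y, G)
    beta_hat = backsolve_effects(fit, Z, p, marker_ids, G=G)
    gebv = fit.u_hat
    kernel_est = build_kernel(beta_hat, gmap)
    table_est = batch_cross_variances(parents, kernel_est, pairs)
    alpha_est = dict(zip(parents.ids, gebv))
    table_est = csc.score_table(
        table_est, alpha_est, genotypes=parents, effects=beta_hat, gmap=gmap
    )
    info["h2_hat"] = fit.h2_hat
    info["gebv"] = gebv
    return table_true, table_est, info


def run_scenario(
    spec: ScenarioSpec,
    sim: SimulationConfig,
    constraints: ConstraintSet,
    ga_config: GaConfig | None = None,
    preselect_fraction: float = 0.10,
) -> dict:
    """Run one scenario cell end to end.

    Per architecture: build the parental population, score all candidate
    crosses with every criterion (fitting GBLUP once for ESTIMATED
    scenarios and reusing it across constraint modes), optimize a design
    per criterion and mode, simulate progeny replicates, and aggregate
    gains, genic variance, diagnostics and contributions. Returns a dict of
    tidy DataFrames: gains, genic, diagnostics, contributions.
    """
    gains_rows, genic_rows, diag_rows, contrib_rows = [], [], [], []
    for a in range(spec.n_architectures):
        arch_seed = spec.seed * 10007 + a
        sim_a = SimulationConfig(**{**sim.__dict__, "seed": arch_seed})
        founders, gmap = generate_founders(sim_a)
        architecture, _ = sample_architecture(
            founders, gmap, sim_a.n_qtl, sim_a.target_tbv_variance, arch_seed + 1
        )
        if spec.population == "selected":
            parents = build_selected_population(founders, gmap, architecture, sim_a)
        else:
            parents = founders

        table_true, table_est, info = _scored_tables(
            parents, gmap, architecture, spec, sim_a, arch_seed
        )
        working = table_est if spec.effects == "estimated" else table_true

        diag = diagnostics(table_true, table_est)
        diag_rows.append({"architecture": a, **diag,
                          **({"h2_hat": info["h2_hat"]} if "h2_hat" in info else {})})

        cand = preselect_by_pm(working, preselect_fraction)
        cand_constraint = cand
        if "constraint" in spec.constraint_modes:
            G2 = grm_ld_weighted(parents)
            pid = {p: k for k, p in enumerate(parents.ids)}
            cand_constraint = filter_related_pairs(
                cand, G2, parents.ids, constraints.similarity_quantile
            )

        true_eff = architecture.effects()
        qtl_cols = [parents.locus_ids.index(l) for l in true_eff.locus_ids]
        genic_parents = genic_variance(parents.doses[:, qtl_cols], true_eff.values)

        sims: dict = {}
        for mode in spec.constraint_modes:
            tab = cand_constraint if mode == "constraint" else cand
            lp_cache: dict = {}
            for crit in CRITERIA:
                design = _optimize_for_criterion(
                    crit, tab, constraints, mode, arch_seed + 7,
                    ga_config, lp_cache,
                )
                reps = simulate_design_progeny(
                    design, parents, gmap, architecture,
                    spec.n_progeny_reps, arch_seed + 1000 + CRITERIA.index(crit),
                )
                sims[(mode, crit)] = (design, reps)
                prof = contribution_profile(design)
                contrib_rows.append(
                    {
                        "architecture": a,
                        "mode": mode,
                        "criterion": crit,
                        "n_crosses": design.n_crosses,
                        "n_parents": len(design.parents()),
                        "best_parent_share": float(prof["share"].iloc[0]),
                        "top20_share": float(prof["share"].head(20).sum()),
                    }
                )

        for mode in spec.constraint_modes:
            _, reps_pm = sims[(mode, "pm")]
            tbv_pm = [r["tbv"] for r in reps_pm]
            genic_pm = [
                genic_variance(r["doses_qtl"][_top_fraction(r["tbv"], 0.07)],
                               true_eff.values)
                for r in reps_pm
            ]
            for crit in CRITERIA:
                _, reps = sims[(mode, crit)]
                tbv_c = [r["tbv"] for r in reps]
                for rate in spec.selection_rates:
                    gains_rows.append(
                        {
                            "architecture": a,
                            "mode": mode,
                            "criterion": crit,
                            "rate": rate,
                            "relative_gain": relative_gain(
                                tbv_c, tbv_pm, info["parent_mean_tbv"], rate
                            ),
                        }
                    )
                genic_c = [
                    genic_variance(r["doses_qtl"][_top_fraction(r["tbv"], 0.07)],
                                   true_eff.values)
                    for r in reps
                ]
                genic_rows.append(
                    {
                        "architecture": a,
                        "mode": mode,
                        "criterion": crit,
                        "genic_variance": float(np.mean(genic_c)),
                        "genic_parents": genic_parents,
                        "relative_genic_change": relative_genic_change(
                            genic_c, genic_pm, genic_parents
                        ),
                    }
                )

    return {
        "gains": pd.DataFrame(gains_rows),
        "genic": pd.DataFrame(genic_rows),
        "diagnostics": pd.DataFrame(diag_rows),
        "contributions": pd.DataFrame(contrib_rows),
    }
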