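"""Synthetic breeding material: founder panels, trait architectures,
phenotypes, meiosis and F5 recombinant inbred lines, and populations that
have undergone truncation selection (Bulmer-affected material).

The founder generator emulates an elite inbred panel: fully homozygous
lines, minor allele frequency above a floor, and linkage disequilibrium
that decays with genetic map distance. LD is produced by a distance-indexed
Markov copy process along each chromosome rather than a coalescent
simulation: moving left to right, each haplotype either copies its allele
state from the previous locus or refreshes from the locus allele frequency,
with refresh probability 1 - exp(-ld_decay_rate * d) for inter-locus
distance d (morgans). Only the MAF floor and decaying LD matter downstream.

Meiosis follows the Haldane model: crossovers form a Poisson process of
rate 1 per morgan with no interference, so the recombination fraction at
distance d is r = (1 - exp(-2d)) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    EffectVector,
    GeneticMap,
    GenotypeMatrix,
    TraitArchitecture,
    compute_breeding_values,
)

__all__ = [
    "SimulationConfig",
    "generate_founders",
    "sample_architecture",
    "simulate_phenotypes",
    "simulate_gamete",
    "gametes_batch",
    "make_ril_f5",
    "ril_f5_batch",
    "build_selected_population",
]


@dataclass
class SimulationConfig:
    """Study conditions for synthetic material.

    Defaults are the full-scale conditions: 835 founder lines genotyped at
    ~16k SNPs (MAF > 0.10) on 21 wheat chromosomes, 300 QTLs with N(0,1)
    effects rescaled to a TBV variance of 14 (quintal/ha)^2, phenotype noise
    variance 21 (quintal/ha)^2 so that h2 = 14/(14+21) = 0.4, and selection
    cycles of 300 crosses x 11 F5 RILs with (1, 1, 3) progeny kept per cross
    over 3 cycles (900 lines, 835 sampled). All counts are configurable so
    the same pipeline runs at desk scale.
    """

    n_founders: int = 835
    n_loci: int = 16429
    n_chromosomes: int = 21
    chrom_length_morgans: float = 1.5
    maf_min: float = 0.10
    ld_decay_rate: float = 8.0
    n_qtl: int = 300
    target_tbv_variance: float = 14.0
    noise_variance: float = 21.0
    seed: int = 0
    # selected-population pipeline counts
    n_cycles: int = 3
    crosses_per_cycle: int = 300
    progeny_per_cross: int = 11
    keep_per_cross: tuple = (1, 1, 3)
    top_parents: int = 300
    sample_n: int = 835

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.target_tbv_variance <= 0:
            raise ValueError("target_tbv_variance must be positive")
        for name in ("n_founders", "n_loci", "n_chromosomes", "n_qtl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.keep_per_cross) != self.n_cycles:
            raise ValueError("keep_per_cross must list one count per cycle")


def _random_map(config: SimulationConfig, rng: np.random.Generator) -> GeneticMap:
    per = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per[: config.n_loci % config.n_chromosomes] += 1
    rows = []
    k = 0
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.uniform(0.0, config.chrom_length_morgans, per[c]))
        for p in pos:
            rows.append((f"chr{c + 1}", f"m{k:05d}", float(p)))
            k += 1
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "locus_id", "pos_morgans"]))


def generate_founders(
    config: SimulationConfig, max_attempts: int = 200
) -> tuple[GenotypeMatrix, GeneticMap]:
    """Generate a fully inbred founder panel with MAF >= maf_min and LD
    decaying with map distance. Deterministic given ``config.seed``.

    Columns are drawn chromosome by chromosome, left to right; a column
    whose realized MAF falls below the floor is redrawn (conditional on the
    previous accepted column, preserving local LD) up to ``max_attempts``
    times before an error is raised.
    """
    rng = np.random.default_rng(config.seed)
    gmap = _random_map(config, rng)
    n = config.n_founders
    # target frequencies kept away from the floor so acceptance is quick
    lo = min(0.5, config.maf_min + 0.10)
    freqs = rng.uniform(lo, 1.0 - lo, config.n_loci)
    hap = np.empty((n, config.n_loci), dtype=np.int8)
    col = 0
    for chrom, idx in gmap.chrom_slices().items():
        pos = gmap.table.loc[idx, "pos_morgans"].to_numpy(float)
        prev = None
        for j, locus in enumerate(idx):
            d = pos[j] - pos[j - 1] if j > 0 else np.inf
            rho = 1.0 - np.exp(-config.ld_decay_rate * d) if np.isfinite(d) else 1.0
            for attempt in range(max_attempts):
                fresh = (rng.random(n) < freqs[locus]).astype(np.int8)
                if prev is None or rho >= 1.0:
                    cand = fresh
                else:
                    refresh = rng.random(n) < rho
                    cand = np.where(refresh, fresh, prev)
                maf = min(cand.mean(), 1.0 - cand.mean())
                if maf >= config.maf_min:
                    break
            else:
                raise RuntimeError(
                    f"could not reach MAF >= {config.maf_min} at locus "
                    f"{gmap.locus_ids[locus]} after {max_attempts} attempts"
                )
            hap[:, locus] = cand
            prev = cand
            col += 1
    genotypes = GenotypeMatrix(
        [f"L{i:04d}" for i in range(n)], (2 * hap).astype(np.int8), gmap.locus_ids
    )
    return genotypes, gmap


def sample_architecture(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    n_qtl: int,
    target_var: float,
    seed: int,
) -> tuple[TraitArchitecture, EffectVector]:
    """Draw a random trait architecture and rescale effects to the target
    TBV variance over the given panel.

    QTLs are picked uniformly without replacement; raw effects are i.i.d.
    N(0,1); the favorable allele is randomized by an independent sign flip;
    the whole effect vector is then multiplied by the single scalar making
    var(TBV) over ``genotypes`` equal ``target_var`` exactly.
    """
    if target_var <= 0:
        raise ValueError("target_var must be positive")
    if n_qtl > genotypes.n_loci:
        raise ValueError("more QTLs requested than loci available")
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(genotypes.n_loci, size=n_qtl, replace=False))
    qtl_ids = [genotypes.locus_ids[i] for i in pick]
    beta = rng.standard_normal(n_qtl)
    sign = np.where(rng.random(n_qtl) < 0.5, 1.0, -1.0)
    beta *= sign
    arch = TraitArchitecture(qtl_ids, beta)
    tbv = compute_breeding_values(genotypes, arch.effects())
    raw_var = tbv.var(ddof=1)
    if raw_var <= 0:
        raise ValueError("degenerate architecture: zero TBV variance before scaling")
    arch = TraitArchitecture(qtl_ids, beta * np.sqrt(target_var / raw_var))
    return arch, arch.effects()


def simulate_phenotypes(
    tbv: np.ndarray, noise_variance: float, seed: int
) -> np.ndarray:
    """Phenotypes y = TBV + e with e ~ N(0, noise_variance)."""
    if noise_variance < 0:
        raise ValueError("noise_variance must be >= 0")
    rng = np.random.default_rng(seed)
    return np.asarray(tbv, float) + rng.normal(0.0, np.sqrt(noise_variance), len(tbv))


# ---------------------------------------------------------------------------
# meiosis


def simulate_gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    gmap: GeneticMap,
    seed: int | np.random.Generator,
    return_crossovers: bool = False,
):
    """Simulate one gamete from a diplotype under the Haldane model.

    Crossover counts per chromosome are Poisson(chromosome map length in
    morgans); crossover positions are uniform; the starting haplotype is a
    fair coin per chromosome. Reference implementation with explicit
    crossover placement; :func:`gametes_batch` is the vectorized equivalent.
    """
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    if hap_a.shape != hap_b.shape or hap_a.size != len(gmap.table):
        raise ValueError("haplotype length does not match the map")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty_like(hap_a)
    n_xo = 0
    for chrom, idx in gmap.chrom_slices().items():
        pos = gmap.table.loc[idx, "pos_morgans"].to_numpy(float)
        length = pos.max() - pos.min() if len(pos) > 1 else 0.0
        k = rng.poisson(length)
        n_xo += k
        cuts = np.sort(rng.uniform(pos.min(), pos.max(), k)) if k else np.empty(0)
        start = int(rng.random() < 0.5)
        # active strand at each locus = start parity XOR #crossovers before it
        strand = (start + np.searchsorted(cuts, pos, side="left")) % 2
        out[idx] = np.where(strand == 0, hap_a[idx], hap_b[idx])
    if return_crossovers:
        return out, n_xo
    return out


def _interval_recomb(gmap: GeneticMap) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus 'flip' probabilities for vectorized meiosis.

    Under a Poisson crossover process the parities of crossover counts in
    disjoint intervals are independent, so at the typed loci a gamete is
    exactly reproduced by: fair-coin start per chromosome, then an
    independent strand switch with probability r(d) per inter-locus
    interval. Returns (p_flip, is_chrom_start) aligned to locus order.
    """
    L = len(gmap.table)
    p = np.empty(L)
    start = np.zeros(L, dtype=bool)
    for chrom, idx in gmap.chrom_slices().items():
        pos = gmap.table.loc[idx, "pos_morgans"].to_numpy(float)
        p[idx[0]] = 0.5
        start[idx[0]] = True
        if len(idx) > 1:
            d = np.diff(pos)
            p[idx[1:]] = 0.5 * (1.0 - np.exp(-2.0 * d))
    return p, start


def gametes_batch(
    hap1: np.ndarray,
    hap2: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
    flip_cache: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Simulate one gamete per row of (n, L) parental haplotype pairs."""
    p_flip, is_start = flip_cache if flip_cache is not None else _interval_recomb(gmap)
    n, L = hap1.shape
    flips = rng.random((n, L)) < p_flip
    # cumulative XOR within chromosome: reset the running parity at starts
    strand = np.zeros((n, L), dtype=np.int8)
    seg = np.cumsum(is_start) - 1  # chromosome index per locus
    cum = np.cumsum(flips, axis=1)
    # subtract the cumulative count at each chromosome start to reset parity
    starts = np.flatnonzero(is_start)
    base = np.zeros((n, L), dtype=cum.dtype)
    for s in starts:
        if s > 0:
            base[:, s:] = cum[:, s - 1 : s]
    strand = ((cum - base) % 2).astype(np.int8)
    return np.where(strand == 0, hap1, hap2)


def _self_generation(
    H1: np.ndarray, H2: np.ndarray, gmap: GeneticMap,
    rng: np.random.Generator, flip_cache,
) -> tuple[np.ndarray, np.ndarray]:
    """One round of single-seed-descent selfing: two gametes per individual."""
    g1 = gametes_batch(H1, H2, gmap, rng, flip_cache)
    g2 = gametes_batch(H1, H2, gmap, rng, flip_cache)
    return g1, g2


def make_ril_f5(
    parent_i: np.ndarray,
    parent_j: np.ndarray,
    gmap: GeneticMap,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One F5 RIL (dose row) from two fully inbred parents.

    F1 takes one haplotype from each parent; four rounds of single-seed
    descent selfing follow. Residual heterozygosity at a locus where the
    parents differ has expectation (1/2)^4.
    """
    return ril_f5_batch(parent_i, parent_j, 1, gmap, seed)[0]


def ril_f5_batch(
    parent_i: np.ndarray,
    parent_j: np.ndarray,
    n: int,
    gmap: GeneticMap,
    seed: int | np.random.Generator,
    n_selfings: int = 4,
    flip_cache=None,
) -> np.ndarray:
    """Simulate ``n`` F5 RILs from one cross; returns (n, L) dose matrix."""
    parent_i = np.asarray(parent_i)
    parent_j = np.asarray(parent_j)
    if np.any(parent_i == 1) or np.any(parent_j == 1):
        raise ValueError("parents must be fully inbred (no dose 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if flip_cache is None:
        flip_cache = _interval_recomb(gmap)
    h_i = (parent_i // 2).astype(np.int8)
    h_j = (parent_j // 2).astype(np.int8)
    H1, H2 = _ril_f5_haplotypes(
        (h_i, h_i), (h_j, h_j), n, gmap, rng, n_selfings, flip_cache
    )
    return (H1 + H2).astype(np.int8)


def _ril_f5_haplotypes(
    diplo_i: tuple[np.ndarray, np.ndarray],
    diplo_j: tuple[np.ndarray, np.ndarray],
    n: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    n_selfings: int = 4,
    flip_cache=None,
) -> tuple[np.ndarray, np.ndarray]:
    """F5 RIL haplotype pairs from two (possibly heterozygous) parents.

    The F1 of each progeny takes one gamete from each parent's diplotype;
    ``n_selfings`` rounds of single-seed descent follow. Used by the
    selection-cycle simulator, where parents are residually heterozygous
    F5 RILs themselves.
    """
    if flip_cache is None:
        flip_cache = _interval_recomb(gmap)
    L = diplo_i[0].size
    Ai = np.broadcast_to(diplo_i[0], (n, L)).copy()
    Bi = np.broadcast_to(diplo_i[1], (n, L)).copy()
    Aj = np.broadcast_to(diplo_j[0], (n, L)).copy()
    Bj = np.broadcast_to(diplo_j[1], (n, L)).copy()
    H1 = gametes_batch(Ai, Bi, gmap, rng, flip_cache)
    H2 = gametes_batch(Aj, Bj, gmap, rng, flip_cache)
    for _ in range(n_selfings):
        H1, H2 = _self_generation(H1, H2, gmap, rng, flip_cache)
    return H1, H2


# ---------------------------------------------------------------------------
# selected populations (Bulmer effect)


def build_selected_population(
    founders: GenotypeMatrix,
    gmap: GeneticMap,
    architecture: TraitArchitecture,
    config: SimulationConfig,
    return_presample: bool = False,
):
    """Derive a 'Selected' parental population by truncation-selection cycles.

    Each cycle pairs the ``top_parents`` highest-TBV lines at random into
    ``crosses_per_cycle`` crosses (uniform pairs with replacement across
    crosses, no self-crosses), produces ``progeny_per_cross`` F5 RILs per
    cross, and keeps the ``keep_per_cross[cycle]`` best progenies per cross
    by TBV. With default counts the final population has 900 lines, from
    which ``sample_n`` (835) are drawn at random.

    Returns the sampled population; with ``return_presample=True`` also the
    full pre-sampling population and the per-cycle mean-TBV trajectory.
    """
    if founders.n_individuals < config.top_parents:
        raise ValueError(
            f"need at least {config.top_parents} founders, got {founders.n_individuals}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 915]))
    effects = architecture.effects()
    eff_idx = [founders.locus_ids.index(l) for l in effects.locus_ids]
    beta = effects.values
    flip_cache = _interval_recomb(gmap)

    # track haplotype pairs: cycle parents are residually heterozygous RILs
    H1 = (founders.doses // 2).astype(np.int8)
    H2 = H1.copy()
    history = []
    for cycle in range(config.n_cycles):
        doses = H1 + H2
        tbv = doses[:, eff_idx] @ beta
        history.append(tbv.mean())
        top = np.argsort(tbv)[::-1][: config.top_parents]
        keep = config.keep_per_cross[cycle]
        next1, next2 = [], []
        for _ in range(config.crosses_per_cycle):
            a, b = rng.choice(top, size=2, replace=False)
            p1, p2 = _ril_f5_haplotypes(
                (H1[a], H2[a]), (H1[b], H2[b]), config.progeny_per_cross,
                gmap, rng, flip_cache=flip_cache,
            )
            ptbv = (p1 + p2)[:, eff_idx] @ beta
            best = np.argsort(ptbv)[::-1][:keep]
            next1.append(p1[best])
            next2.append(p2[best])
        H1 = np.vstack(next1)
        H2 = np.vstack(next2)
    doses = (H1 + H2).astype(np.int8)
    final_tbv = doses[:, eff_idx] @ beta
    history.append(final_tbv.mean())
    ids = [f"S{i:04d}" for i in range(doses.shape[0])]
    pre = GenotypeMatrix(ids, doses, list(founders.locus_ids), allow_het=True)
    take = rng.choice(doses.shape[0], size=min(config.sample_n, doses.shape[0]),
                      replace=False)
    take.sort()
    sampled = GenotypeMatrix(
        [ids[i] for i in take], doses[take], list(founders.locus_ids), allow_het=True
    )
    if return_presample:
        return sampled, pre, history
    return sampled
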