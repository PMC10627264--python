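"""Analytic progeny variance of biparental F5-RIL families.

For a cross between two inbred parents, segregation at the loci where they
differ makes progeny breeding values a quadratic form in the effect vector:

    sigma2_ij = d' K d,    d_l = (x_l^i - x_l^j) / 2 in {-1, 0, +1},

where ``d`` encodes which loci segregate and in which phase, and the kernel
K_kl = beta_k * beta_l * C(r_kl) carries the dose (co)variance C(r) between
two segregating loci in the final selfing generation. C(r) is computed by
an exact two-locus Markov-chain recursion over selfing generations starting
from the F1 double heterozygote; it is validated against Monte-Carlo
meiosis rather than against any closed-form rendering.

Key values (4 selfings, i.e. F5): C(0) = 15/16 (residual heterozygosity),
C(0.5) = 0 (unlinked loci factorize under selfing). In the infinite-selfing
limit C(r) -> (1 - 2r) / (1 + 2r), the Haldane-Waddington result, with
C(0) = 1. The ``f_inf`` mode uses that limit (the classical full-inbreeding
formula 4*sum(beta^2 p(1-p)) on the diagonal); the default ``f5`` mode uses
the finite-selfing recursion throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .data_model import EffectVector, GeneticMap, GenotypeMatrix, canonical_pair

__all__ = [
    "haldane_r",
    "ril_cov_factor",
    "RecombinationModel",
    "VarianceKernel",
    "build_kernel",
    "cross_variance",
    "batch_cross_variances",
    "all_pairs",
]


def haldane_r(d):
    """Recombination fraction r = (1 - exp(-2d)) / 2 for map distance d (M)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# exact two-locus selfing recursion
#
# State space: ordered diplotypes (h1, h2), each haplotype one of
# {00, 01, 10, 11} coding (allele at locus k, allele at locus l).
# A gamete picks its source strand at locus k by a fair coin and keeps the
# same strand at locus l with probability 1 - r. Selfing draws two
# independent gametes from the same individual.

_HAPS = [(0, 0), (0, 1), (1, 0), (1, 1)]


def _gamete_dist(state: tuple[int, int], r: float) -> np.ndarray:
    h1, h2 = _HAPS[state[0]], _HAPS[state[1]]
    q = np.zeros(4)
    for s in (0, 1):  # source at locus k
        for t in (0, 1):  # source at locus l
            p = (1.0 - r) / 2.0 if s == t else r / 2.0
            a = (h1, h2)[s][0]
            b = (h1, h2)[t][1]
            q[a * 2 + b] += p
    return q


def _ril_cov_exact(r: float, n_selfings: int) -> float:
    """Dose covariance between two coupling-phase segregating loci after
    ``n_selfings`` rounds of selfing from the F1 (AB/ab)."""
    # distribution over ordered diplotypes (16 states)
    P = np.zeros((4, 4))
    P[3, 0] = 1.0  # F1: AB / ab
    gam = np.array([_gamete_dist((i, j), r) for i in range(4) for j in range(4)])
    gam = gam.reshape(4, 4, 4)
    for _ in range(n_selfings):
        # two independent gametes from the SAME individual (selfing)
        P = np.einsum("ij,ijg,ijh->gh", P, gam, gam)
    # doses
    dose_k = np.array([h[0] for h in _HAPS])
    dose_l = np.array([h[1] for h in _HAPS])
    dk = dose_k[:, None] + dose_k[None, :]
    dl = dose_l[:, None] + dose_l[None, :]
    e_kl = float(np.sum(P * dk * dl))
    e_k = float(np.sum(P * dk))
    e_l = float(np.sum(P * dl))
    return e_kl - e_k * e_l


def ril_cov_factor(r, n_selfings: int | None = 4):
    """Dose (co)variance factor C(r) between segregating coupling-phase loci
    in RIL progeny after ``n_selfings`` selfing generations.

    ``n_selfings=None`` gives the infinite-selfing (complete inbreeding)
    limit C(r) = (1 - 2r) / (1 + 2r). Accepts scalars or arrays; array
    evaluation goes through the exact polynomial representation of the
    recursion (C is a polynomial in r of degree <= 2 * n_selfings).
    """
    scalar = np.isscalar(r)
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any((r_arr < 0) | (r_arr > 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    if n_selfings is None:
        out = (1.0 - 2.0 * r_arr) / (1.0 + 2.0 * r_arr)
    else:
        if n_selfings < 1:
            raise ValueError("n_selfings must be >= 1")
        if scalar:
            return _ril_cov_exact(float(r_arr[0]), int(n_selfings))
        if n_selfings <= 10:
            out = _cov_polynomial(int(n_selfings))(r_arr)
        else:  # high selfing counts: exact recursion per unique value
            uniq, inv = np.unique(r_arr, return_inverse=True)
            vals = np.array([_ril_cov_exact(float(x), int(n_selfings))
                             for x in uniq])
            out = vals[inv].reshape(r_arr.shape)
    return float(out[0]) if scalar else out


@lru_cache(maxsize=8)
def _cov_polynomial(n_selfings: int):
    """Exact polynomial representation of C(r) for a selfing count.

    Each selfing round composes a map quadratic in r with the previous
    distribution, so C has degree <= 2*n_selfings; fitting at more nodes
    than the degree recovers it exactly (residuals at machine precision).
    """
    deg = 2 * n_selfings
    nodes = np.linspace(0.0, 0.5, 2 * deg + 3)
    vals = np.array([_ril_cov_exact(float(x), n_selfings) for x in nodes])
    poly = np.polynomial.Polynomial.fit(nodes, vals, deg)
    assert np.max(np.abs(poly(nodes) - vals)) < 1e-10
    return poly


# ---------------------------------------------------------------------------
# kernels and cross variances


@dataclass
class RecombinationModel:
    """Pairwise recombination fractions per chromosome plus selfing count."""

    gmap: GeneticMap
    n_selfings: int | None = 4

    def recomb_matrix(self, chrom) -> np.ndarray:
        pos = self.gmap.positions(chrom)
        return haldane_r(np.abs(pos[:, None] - pos[None, :]))


@dataclass
class VarianceKernel:
    """Per-chromosome kernels K_kl = beta_k beta_l C(r_kl) over effect loci.

    ``blocks`` maps chromosome -> (locus index array into the effect-locus
    order, kernel matrix). ``cross_chrom_factor`` is C(0.5) for the given
    selfing count (exactly 0 under selfing from an F1)."""

    locus_ids: list[str]
    blocks: dict
    cross_chrom_factor: float
    beta: np.ndarray


def build_kernel(
    effects: EffectVector,
    gmap: GeneticMap,
    model: RecombinationModel | None = None,
    mode: str = "f5",
) -> VarianceKernel:
    """Build the block-diagonal variance kernel for an effect vector.

    ``mode='f5'`` uses the finite-selfing recursion (4 selfings);
    ``mode='f_inf'`` the complete-inbreeding limit.
    """
    if model is None:
        model = RecombinationModel(gmap)
    n_selfings = None if mode == "f_inf" else model.n_selfings
    order = {l: i for i, l in enumerate(gmap.locus_ids)}
    missing = [l for l in effects.locus_ids if l not in order]
    if missing:
        raise KeyError(f"effect loci absent from map: {missing[:5]}")
    eff_index = {l: i for i, l in enumerate(effects.locus_ids)}
    beta = effects.values
    blocks = {}
    for chrom, idx in gmap.chrom_slices().items():
        ids_here = [gmap.locus_ids[i] for i in idx if gmap.locus_ids[i] in eff_index]
        if not ids_here:
            continue
        e_idx = np.array([eff_index[l] for l in ids_here])
        pos = gmap.table.set_index("locus_id").loc[ids_here, "pos_morgans"].to_numpy(float)
        r = haldane_r(np.abs(pos[:, None] - pos[None, :]))
        C = ril_cov_factor(r, n_selfings)
        b = beta[e_idx]
        blocks[chrom] = (e_idx, (b[:, None] * b[None, :]) * C)
    ccf = ril_cov_factor(0.5, n_selfings)
    return VarianceKernel(list(effects.locus_ids), blocks, float(ccf), beta.copy())


def _segregation_vector(
    parent_i: np.ndarray, parent_j: np.ndarray, n_loci: int
) -> np.ndarray:
    if np.any(parent_i == 1) or np.any(parent_j == 1):
        raise ValueError("cross variance requires fully inbred parents")
    return (np.asarray(parent_i, float) - np.asarray(parent_j, float)) / 2.0


def cross_variance(
    parent_i: np.ndarray,
    parent_j: np.ndarray,
    kernel: VarianceKernel,
    ignore_transchrom: bool = False,
) -> tuple[float, float]:
    """Analytic progeny variance (and SD) for one cross.

    ``parent_i``/``parent_j`` are dose rows aligned to ``kernel.locus_ids``.
    Returns (sigma2, sigma). Zero when the parents are genotype-identical
    over the effect scope.
    """
    d = _segregation_vector(parent_i, parent_j, len(kernel.locus_ids))
    sigma2 = 0.0
    s_chrom = []
    for chrom, (idx, K) in kernel.blocks.items():
        dc = d[idx]
        sigma2 += float(dc @ K @ dc)
        s_chrom.append(float(np.sum(kernel.beta[idx] * dc)))
    if not ignore_transchrom and kernel.cross_chrom_factor != 0.0:
        s = np.array(s_chrom)
        total = s.sum()
        sigma2 += kernel.cross_chrom_factor * float(total * total - np.sum(s * s))
    sigma2 = max(sigma2, 0.0)
    return sigma2, float(np.sqrt(sigma2))


def all_pairs(ids: list[str]) -> list[tuple[str, str]]:
    """All unordered parent pairs in canonical order."""
    out = []
    ids_sorted = sorted(ids)
    for i in range(len(ids_sorted)):
        for j in range(i + 1, len(ids_sorted)):
            out.append((ids_sorted[i], ids_sorted[j]))
    return out


def batch_cross_variances(
    genotypes: GenotypeMatrix,
    kernel: VarianceKernel,
    pairs: list[tuple[str, str]],
    ignore_transchrom: bool = False,
) -> pd.DataFrame:
    """Progeny variance for many candidate crosses at once.

    Uses the identity sigma2_ij = (A_ii + A_jj - 2 A_ij) / 4 with
    A = X K X' accumulated per chromosome block, so the cost is one
    matrix product per chromosome rather than one per pair. Returns a
    CrossTable skeleton (parent_i, parent_j, sigma2, sigma).
    """
    sub = genotypes.subset_loci(kernel.locus_ids)
    index = {p: k for k, p in enumerate(sub.ids)}
    for a, b in pairs:
        if a not in index or b not in index:
            raise KeyError(f"unknown individual in pair ({a}, {b})")
    X = sub.doses.astype(float)
    if np.any(X == 1):
        raise ValueError("cross variance requires fully inbred parents")
    n = X.shape[0]
    A = np.zeros((n, n))
    S_chrom = []  # per-chromosome effect sums, for the trans-chromosome term
    for chrom, (idx, K) in kernel.blocks.items():
        Xc = X[:, idx]
        A += Xc @ K @ Xc.T
        S_chrom.append(Xc @ kernel.beta[idx])
    ii = np.array([index[a] for a, _ in pairs])
    jj = np.array([index[b] for _, b in pairs])
    sigma2 = (A[ii, ii] + A[jj, jj] - 2.0 * A[ii, jj]) / 4.0
    if not ignore_transchrom and kernel.cross_chrom_factor != 0.0:
        S = np.column_stack(S_chrom)  # (n, n_chrom) per-parent block sums
        D = (S[ii] - S[jj]) / 2.0
        tot = D.sum(axis=1)
        sigma2 += kernel.cross_chrom_factor * (tot * tot - np.sum(D * D, axis=1))
    sigma2 = np.maximum(sigma2, 0.0)
    return pd.DataFrame(
        {
            "parent_i": [a for a, _ in pairs],
            "parent_j": [b for _, b in pairs],
            "sigma2": sigma2,
            "sigma": np.sqrt(sigma2),
        }
    )
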