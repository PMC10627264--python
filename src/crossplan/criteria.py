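"""Cross-selection criteria (CSC) and their objective-function coefficients.

All criteria treat the progeny breeding-value distribution of a cross as
N(PM, sigma^2), with PM the parental mean and sigma the analytic progeny
SD. The heritability factor in the usefulness criterion UC = PM + i_q*h*sigma
is 1 by default (genomic values are used directly); it is exposed as the
``h`` argument for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import GenotypeMatrix, EffectVector, GeneticMap, MatingDesign

__all__ = [
    "selection_intensity",
    "pm",
    "uc",
    "embv_int",
    "embv",
    "proba_exceed",
    "proba_objective_coeff",
    "default_threshold",
    "uc3_threshold",
    "uc3_objective",
    "ohv",
    "ohv_table",
    "score_table",
]

_EPS = 1e-12  # tail clamp keeping log(1 - q) finite


def selection_intensity(q):
    """Selection intensity i_q = phi(z_q)/q (inverse Mills ratio), the mean
    of a standard normal conditional on exceeding its upper-q quantile."""
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q_arr <= 0.0) | (q_arr >= 1.0)):
        raise ValueError("selection rate q must lie in (0, 1)")
    z = norm.isf(q_arr)
    out = norm.pdf(z) / q_arr
    return float(out[0]) if np.isscalar(q) else out


def pm(alpha_i, alpha_j):
    """Parental mean (expected progeny mean): (alpha_i + alpha_j) / 2."""
    return (np.asarray(alpha_i, float) + np.asarray(alpha_j, float)) / 2.0


def uc(pm_value, sigma, q: float, h: float = 1.0):
    """Usefulness criterion: expected mean of the top fraction q of progeny,
    PM + i_q * h * sigma."""
    sigma = np.asarray(sigma, float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    return np.asarray(pm_value, float) + selection_intensity(q) * h * sigma


def embv_int(D):
    """Burrows approximation of E[max of D standard normal draws]:
    INT_{1/D} = i_{1/D} - (D - 1) / (2 (D + 1) i_{1/D}); INT(1) = 0."""
    D_arr = np.atleast_1d(np.asarray(D))
    if np.any(D_arr < 1) or not np.all(D_arr == np.floor(D_arr)):
        raise ValueError("progeny count D must be a positive integer")
    D_f = D_arr.astype(float)
    out = np.zeros_like(D_f)
    big = D_arr > 1
    if np.any(big):
        i_q = selection_intensity(1.0 / D_f[big])
        out[big] = i_q - (D_f[big] - 1.0) / (2.0 * (D_f[big] + 1.0) * i_q)
    return float(out[0]) if np.isscalar(D) else out


def embv(pm_value, sigma, D):
    """Expected maximum breeding value among D progeny:
    PM + INT_{1/D} * sigma."""
    sigma = np.asarray(sigma, float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    return np.asarray(pm_value, float) + embv_int(D) * sigma


def proba_exceed(pm_value, sigma, lam: float):
    """Probability q that one progeny of the cross exceeds the threshold
    ``lam`` under N(PM, sigma^2); degenerate sigma = 0 gives the indicator
    of PM > lam. Clamped to [eps, 1 - eps]."""
    pm_arr = np.atleast_1d(np.asarray(pm_value, float))
    sig = np.atleast_1d(np.asarray(sigma, float))
    if np.any(sig < 0):
        raise ValueError("sigma must be >= 0")
    q = np.empty_like(pm_arr)
    zero = sig == 0
    q[zero] = (pm_arr[zero] > lam).astype(float)
    nz = ~zero
    q[nz] = norm.sf(lam, loc=pm_arr[nz], scale=sig[nz])
    q = np.clip(q, _EPS, 1.0 - _EPS)
    return float(q[0]) if np.isscalar(pm_value) else q


def proba_objective_coeff(q):
    """PROBA allocation coefficient log(1 - q); the design objective
    sum(D_ij * log(1 - q_ij)) is *minimized* (log-probability that no
    progeny exceeds the threshold)."""
    q = np.clip(np.asarray(q, float), _EPS, 1.0 - _EPS)
    return np.log1p(-q)


def default_threshold(parent_values) -> float:
    """PROBA threshold: genetic value of the best candidate parent."""
    vals = np.asarray(parent_values, float)
    if vals.size == 0:
        raise ValueError("no parental values supplied")
    return float(vals.max())


# ---------------------------------------------------------------------------
# UC3: design-level usefulness under a common threshold


def uc3_threshold(
    design_alloc: np.ndarray,
    pm_values: np.ndarray,
    sigmas: np.ndarray,
    q: float,
    tol_factor: float = 1e-6,
) -> float:
    """Solve for the common threshold s_q with sum(D_ij q_ij(s)) = q * D.

    The left side is continuous and strictly decreasing in s wherever some
    sigma > 0; bisection to |sum - qD| <= tol_factor * D. With all sigmas
    zero the equation is a step function; the nearest achievable threshold
    is returned with a warning.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    D = np.asarray(design_alloc, float)
    pm_v = np.asarray(pm_values, float)
    sg = np.asarray(sigmas, float)
    total = D.sum()
    if total <= 0:
        raise ValueError("design has no progeny")
    target = q * total

    def expected_above(s: float) -> float:
        above = np.where(sg > 0, norm.sf(s, loc=pm_v, scale=np.where(sg > 0, sg, 1.0)),
                         (pm_v > s).astype(float))
        return float(np.sum(D * above))

    lo = float(np.min(pm_v - 10.0 * np.maximum(sg, 1e-6)))
    hi = float(np.max(pm_v + 10.0 * np.maximum(sg, 1e-6)))
    if np.all(sg == 0):
        import warnings

        warnings.warn("all progeny SDs are zero; UC3 threshold set at the "
                      "nearest achievable step", stacklevel=2)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = expected_above(mid)
        if abs(val - target) <= tol_factor * total:
            return mid
        if val > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def uc3_objective(
    design_alloc: np.ndarray,
    pm_values: np.ndarray,
    sigmas: np.ndarray,
    q: float,
    s_q: float | None = None,
) -> float:
    """Expected mean of the top q fraction of the whole design's progeny.

    Per family the mean above s_q is the truncated-normal mean
    UC3_ij = PM + sigma * phi(z_ij)/q_ij with z_ij = (s_q - PM)/sigma; the
    objective is the q*D-progeny weighted mean sum(D q UC3) / (q D_total).
    """
    D = np.asarray(design_alloc, float)
    pm_v = np.asarray(pm_values, float)
    sg = np.asarray(sigmas, float)
    if np.all(sg == 0):
        import warnings

        warnings.warn("all progeny SDs are zero; UC3 objective computed by "
                      "direct enumeration of family means", stacklevel=2)
        # every progeny equals its family PM: enumerate the top q*D directly
        order = np.argsort(pm_v)[::-1]
        k = q * D.sum()
        taken, acc = 0.0, 0.0
        for i in order:
            take = min(D[i], k - taken)
            if take <= 0:
                break
            acc += take * pm_v[i]
            taken += take
        return float(acc / taken)
    if s_q is None:
        s_q = uc3_threshold(D, pm_v, sg, q)
    q_ij = np.where(
        sg > 0,
        norm.sf(s_q, loc=pm_v, scale=np.where(sg > 0, sg, 1.0)),
        (pm_v > s_q).astype(float),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sg > 0, (s_q - pm_v) / np.where(sg > 0, sg, 1.0), 0.0)
        mean_above = np.where(
            sg > 0, pm_v + sg * norm.pdf(z) / np.maximum(q_ij, _EPS), pm_v
        )
    contrib = np.where(q_ij < _EPS, 0.0, D * q_ij * mean_above)
    denom = q * D.sum()
    return float(contrib.sum() / denom)


# ---------------------------------------------------------------------------
# OHV


def _block_labels(gmap: GeneticMap, locus_ids: list[str]) -> np.ndarray:
    arms = gmap.arms()
    table = gmap.table.assign(arm=arms.values).set_index("locus_id")
    missing = [l for l in locus_ids if l not in table.index]
    if missing:
        raise KeyError(f"loci missing block assignment: {missing[:5]}")
    sel = table.loc[locus_ids]
    return (sel["chrom"].astype(str) + ":" + sel["arm"].astype(str)).to_numpy()


def ohv_table(
    genotypes: GenotypeMatrix,
    effects: EffectVector,
    gmap: GeneticMap,
    pairs: list[tuple[str, str]],
) -> np.ndarray:
    """Optimal haploid value 2 * sum_b max(beta_b^i, beta_b^j) for each
    pair, with 3 blocks per chromosome (two arms plus centromere)."""
    sub = genotypes.subset_loci(effects.locus_ids)
    hap_eff = (sub.doses / 2.0) * effects.values  # per-haplotype allele effects
    labels = _block_labels(gmap, effects.locus_ids)
    blocks = pd.unique(labels)
    scores = np.column_stack(
        [hap_eff[:, labels == b].sum(axis=1) for b in blocks]
    )  # (n_parents, n_blocks)
    index = {p: k for k, p in enumerate(sub.ids)}
    ii = np.array([index[a] for a, _ in pairs])
    jj = np.array([index[b] for _, b in pairs])
    return 2.0 * np.maximum(scores[ii], scores[jj]).sum(axis=1)


def ohv(parent_i, parent_j, effects: EffectVector, block_labels: np.ndarray) -> float:
    """OHV for one cross given explicit per-locus block labels."""
    parent_i = np.asarray(parent_i)
    parent_j = np.asarray(parent_j)
    if np.any(parent_i == 1) or np.any(parent_j == 1):
        raise ValueError("OHV requires inbred parents")
    if len(block_labels) != len(effects.locus_ids):
        raise ValueError("block labels must cover every effect locus")
    hi = (parent_i / 2.0) * effects.values
    hj = (parent_j / 2.0) * effects.values
    total = 0.0
    for b in pd.unique(np.asarray(block_labels)):
        mask = np.asarray(block_labels) == b
        total += max(hi[mask].sum(), hj[mask].sum())
    return 2.0 * total


# ---------------------------------------------------------------------------
# assembling a scored cross table


def score_table(
    cross_table: pd.DataFrame,
    alpha: dict[str, float],
    q1: float = 0.07,
    q2: float = 0.0001,
    lam: float | None = None,
    genotypes: GenotypeMatrix | None = None,
    effects: EffectVector | None = None,
    gmap: GeneticMap | None = None,
    h: float = 1.0,
) -> pd.DataFrame:
    """Add PM, UC1, UC2, PROBA (and optionally OHV) columns to a cross
    table carrying parent_i, parent_j, sigma2, sigma.

    EMBV and UC3 depend on the allocation and are computed at optimization
    time; EMBV at a reference allocation D_max can be added separately.
    """
    out = cross_table.copy()
    a_i = out["parent_i"].map(alpha).to_numpy(float)
    a_j = out["parent_j"].map(alpha).to_numpy(float)
    if np.any(np.isnan(a_i)) or np.any(np.isnan(a_j)):
        raise KeyError("genetic value missing for some parents")
    out["pm"] = pm(a_i, a_j)
    sig = out["sigma"].to_numpy(float)
    out["uc1"] = uc(out["pm"], sig, q1, h)
    out["uc2"] = uc(out["pm"], sig, q2, h)
    if lam is None:
        lam = default_threshold(list(alpha.values()))
    out["proba"] = proba_exceed(out["pm"].to_numpy(), sig, lam)
    out.attrs["lambda"] = lam
    if genotypes is not None and effects is not None and gmap is not None:
        pairs = list(zip(out["parent_i"], out["parent_j"]))
        out["ohv"] = ohv_table(genotypes, effects, gmap, pairs)
    return out
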