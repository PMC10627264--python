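"""GBLUP: genomic relationship matrices, single-component REML, and
marker-effect backsolving.

Model: y_i = mu + a_i + e_i with a ~ N(0, G sigma2_a), e ~ N(0, I sigma2_e),
G the VanRaden-style relationship built from centered doses. Variance
components are estimated by restricted maximum likelihood via the spectral
decomposition of G and a one-dimensional search over the variance ratio
(deterministic, no iterative AI updates). Marker effects are recovered by
backsolving beta_hat = Z' G^-1 u_hat / (2 sum p(1-p)), so that the GEBV of
any genotype is the cross product of its doses with beta_hat.

With doses coded 0/2 on inbred lines the diagonal of G is close to 2, so
the heritability estimate reported is h2_hat = 2 sigma2_a / var(y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .data_model import EffectVector, GenotypeMatrix

__all__ = [
    "grm_vanraden",
    "grm_ld_weighted",
    "centered_genotypes",
    "GblupFit",
    "reml_fit",
    "backsolve_effects",
]


def centered_genotypes(
    genotypes: GenotypeMatrix, exclude: set[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Centered dose matrix Z = X - 2p over polymorphic loci.

    Returns (Z, p, locus_ids) with monomorphic and excluded loci dropped.
    """
    exclude = exclude or set()
    keep = [k for k, l in enumerate(genotypes.locus_ids) if l not in exclude]
    X = genotypes.doses[:, keep].astype(float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    X = X[:, poly]
    p = p[poly]
    ids = [genotypes.locus_ids[keep[k]] for k in np.flatnonzero(poly)]
    return X - 2.0 * p, p, ids


def grm_vanraden(
    genotypes: GenotypeMatrix, exclude: set[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """G = Z Z' / (2 sum_l p_l (1 - p_l)) with Z centered at 2p_l.

    Returns (G, Z, p, locus_ids); the extra pieces feed the backsolve.
    """
    Z, p, ids = centered_genotypes(genotypes, exclude)
    if Z.shape[1] < 2:
        raise ValueError("need at least 2 polymorphic loci to build a GRM")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    return G, Z, p, ids


def grm_ld_weighted(
    genotypes: GenotypeMatrix, weights: np.ndarray | None = None
) -> np.ndarray:
    """LD-weighted covariance matrix G(2) = W W' with columns
    W_l = w_l (Z_l - 2 p_l) / sqrt(p_l (1 - p_l)).

    With unit weights this is proportional to a standardized-genotype GRM.
    Weights quantify local LD (as produced by per-SNP weighting software)
    and are accepted as input, not estimated here.
    """
    Z, p, _ = centered_genotypes(genotypes)
    if weights is None:
        weights = np.ones(Z.shape[1])
    weights = np.asarray(weights, float)
    if weights.size != Z.shape[1]:
        raise ValueError("weights length must match the polymorphic locus count")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    W = weights * Z / np.sqrt(p * (1.0 - p))
    return W @ W.T


@dataclass
class GblupFit:
    mu: float
    u_hat: np.ndarray
    sigma2_a: float
    sigma2_e: float
    h2_hat: float
    log_reml: float
    beta_hat: EffectVector | None = None


def reml_fit(phenotypes: np.ndarray, G: np.ndarray) -> GblupFit:
    """REML estimates of (sigma2_a, sigma2_e) and BLUP genetic values.

    Profiles mu and sigma2_e out of the restricted likelihood and optimizes
    it over log(lambda), lambda = sigma2_a / sigma2_e, by bounded scalar
    search on the eigenbasis of G.
    """
    y = np.asarray(phenotypes, float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 phenotyped individuals")
    if np.var(y) == 0:
        raise ValueError("constant phenotype")
    G = np.asarray(G, float)
    if G.shape != (n, n) or not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G must be a symmetric n x n matrix")
    w, U = np.linalg.eigh(G)
    if w.min() < -1e-6 * max(w.max(), 1.0):
        raise ValueError("G is not positive semi-definite")
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = lam * w + 1.0
        Wd = 1.0 / d
        xwx = float(np.sum(xt * xt * Wd))
        mu = float(np.sum(xt * yt * Wd)) / xwx
        resid = yt - xt * mu
        rss = float(np.sum(resid * resid * Wd))
        sigma2_e = rss / (n - 1)
        ll = -0.5 * (
            (n - 1) * (np.log(2.0 * np.pi * sigma2_e) + 1.0)
            + float(np.sum(np.log(d)))
            + np.log(xwx)
        )
        return -ll

    res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    d = lam * w + 1.0
    Wd = 1.0 / d
    xwx = float(np.sum(xt * xt * Wd))
    mu = float(np.sum(xt * yt * Wd)) / xwx
    resid = yt - xt * mu
    sigma2_e = float(np.sum(resid * resid * Wd)) / (n - 1)
    sigma2_a = lam * sigma2_e
    # BLUP: u = lam * G (lam G + I)^-1 (y - mu)
    u_hat = U @ (lam * w * Wd * resid)
    h2_hat = 2.0 * sigma2_a / float(np.var(y, ddof=1))
    return GblupFit(
        mu=mu,
        u_hat=u_hat,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        h2_hat=h2_hat,
        log_reml=-res.fun,
    )


def backsolve_effects(
    fit: GblupFit,
    Z: np.ndarray,
    p: np.ndarray,
    locus_ids: list[str],
    G: np.ndarray | None = None,
    scope: str = "markers_excluding_qtl",
) -> EffectVector:
    """Backsolve marker effects: beta_hat = Z' G^-1 u_hat / (2 sum p(1-p)).

    G defaults to Z Z' / (2 sum p(1-p)); a ridge jitter of 1e-8 * mean(diag)
    stabilizes the inverse. In the full-rank case Z beta_hat reproduces
    u_hat exactly.
    """
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if G is None:
        G = (Z @ Z.T) / denom
    G = G + np.eye(G.shape[0]) * (1e-8 * float(np.mean(np.diag(G))))
    try:
        alpha = np.linalg.solve(G, fit.u_hat)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("G singular even after jitter") from exc
    beta = Z.T @ alpha / denom
    return EffectVector(list(locus_ids), beta, scope=scope)
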