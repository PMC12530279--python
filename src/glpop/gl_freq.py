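"""Genotype likelihoods, EM allele frequencies, SNP calling, site filters.

This is the workhorse for ~1x data: genotypes are never called.  Each
individual contributes a likelihood triple L(g) for g = 0,1,2 copies of the
minor allele, computed from its major/minor read counts under a symmetric
base-error model (a read from one allele is misread as a specific other base
with probability eps/3).  Population allele frequencies are maximum-
likelihood estimates under a Hardy-Weinberg prior, obtained by EM over the
likelihood triples; a site is declared a SNP by a chi-square(1) likelihood-
ratio test of f = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from glpop.containers import GenotypeLikelihoodMatrix, ReadCountMatrix

__all__ = [
    "genotype_likelihoods", "em_allele_frequency", "snp_test",
    "site_filters", "SiteFilterConfig", "FilterReport",
    "posterior_dosage", "loglik_at",
]

EM_F0 = 0.1
EM_TOL = 1e-8
EM_MAX_ITER = 200
_GCOMB = np.array([1.0, 2.0, 1.0])  # C(2, g)


def genotype_likelihoods(counts: ReadCountMatrix, eps: float) -> GenotypeLikelihoodMatrix:
    """Likelihood triples from major/minor read counts.

    P(minor read | g) = (g/2)(1-eps) + (1-g/2)(eps/3); the major-read
    probability is the mirror image.  The product over reads is taken in log
    space and rescaled so each triple has maximum exactly 1; individuals with
    no reads get (1,1,1).
    """
    if not 0 < eps < 0.75:
        raise ValueError("error rate must lie in (0, 0.75)")
    g = np.array([0.0, 1.0, 2.0])
    p_minor = (g / 2.0) * (1.0 - eps) + (1.0 - g / 2.0) * (eps / 3.0)
    p_major = (1.0 - g / 2.0) * (1.0 - eps) + (g / 2.0) * (eps / 3.0)
    nmaj = counts.n_major[..., None]
    nmin = counts.n_minor[..., None]
    loggl = nmin * np.log(p_minor) + nmaj * np.log(p_major)
    loggl -= loggl.max(axis=2, keepdims=True)
    gl = np.exp(loggl)
    return GenotypeLikelihoodMatrix(
        counts.chrom, counts.pos, counts.major, counts.minor,
        gl, eps, list(counts.samples),
    )


def _hwe_prior(f: np.ndarray) -> np.ndarray:
    """P(g | f) for g = 0,1,2 under Hardy-Weinberg; f may be (S,)."""
    f = np.asarray(f, dtype=np.float64)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def loglik_at(gl: np.ndarray, f) -> np.ndarray:
    """Marginal log-likelihood sum_i log sum_g L_i(g) P(g|f), per site.

    ``gl`` has shape (S, N, 3); ``f`` is scalar or (S,).
    """
    prior = _hwe_prior(np.broadcast_to(np.asarray(f, dtype=np.float64), gl.shape[:1]))
    per_ind = np.einsum("sng,sg->sn", gl, prior)
    with np.errstate(divide="ignore"):
        return np.log(per_ind).sum(axis=1)


@dataclass
class SiteFrequencyResult:
    """EM output per site (arrays over sites)."""

    fhat: np.ndarray
    maf: np.ndarray
    n_used: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    noninformative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fhat": self.fhat, "maf": self.maf, "n_used": self.n_used,
            "iterations": self.iterations, "converged": self.converged,
            "noninformative": self.noninformative,
        })


def em_allele_frequency(
    gl: np.ndarray, f0: float = EM_F0, tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> SiteFrequencyResult:
    """EM estimate of the minor-allele frequency at each site.

    ``gl`` has shape (S, N, 3), individuals with no data carrying flat
    triples.  Posterior weights w_i(g) propto L_i(g) P(g|f); the update is
    f <- sum_i E[g_i]/(2N).  The marginal log-likelihood never decreases
    across iterations.  Sites where every individual is flat stay at the
    fixed point of the starting value and are flagged non-informative.
    """
    gl = np.atleast_3d(np.asarray(gl, dtype=np.float64))
    S, N, _ = gl.shape
    if N < 1:
        raise ValueError("need at least one individual")
    flat = np.isclose(gl, gl[..., :1]).all(axis=2)  # (S, N): no information
    n_used = (~flat).sum(axis=1)
    noninformative = n_used == 0
    f = np.full(S, float(f0))
    iterations = np.zeros(S, dtype=np.int64)
    converged = np.zeros(S, dtype=bool)
    active = ~noninformative
    for it in range(1, max_iter + 1):
        if not active.any():
            break
        prior = _hwe_prior(f[active])                      # (A, 3)
        w = gl[active] * prior[:, None, :]                 # (A, N, 3)
        denom = w.sum(axis=2, keepdims=True)
        denom = np.where(denom == 0, 1.0, denom)
        eg = (w * np.array([0.0, 1.0, 2.0])).sum(axis=2) / denom[..., 0]
        f_new = eg.sum(axis=1) / (2.0 * N)
        moved = np.abs(f_new - f[active]) >= tol
        iterations[active] = it
        f[active] = f_new
        idx = np.flatnonzero(active)
        converged[idx[~moved]] = True
        still = idx[moved]
        active = np.zeros(S, dtype=bool)
        active[still] = True
    # non-informative sites: EM fixed point is f0 itself
    converged[noninformative] = True
    f[noninformative] = f0
    maf = np.minimum(f, 1.0 - f)
    return SiteFrequencyResult(f, maf, n_used, iterations, converged, noninformative)


def posterior_dosage(gl: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Posterior expected minor-allele dosage E[g | data, f], shape (S, N)."""
    gl = np.atleast_3d(np.asarray(gl, dtype=np.float64))
    prior = _hwe_prior(np.broadcast_to(np.asarray(f, dtype=np.float64), gl.shape[:1]))
    w = gl * prior[:, None, :]
    denom = w.sum(axis=2)
    denom = np.where(denom == 0, 1.0, denom)
    return (w * np.array([0.0, 1.0, 2.0])).sum(axis=2) / denom


def snp_test(gl: np.ndarray, fhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test of f = 0 versus f = fhat, per site.

    Lambda = 2[l(fhat) - l(0)] clamped at 0; the p-value is the upper tail of
    chi-square with 1 df.  The boundary mixture correction is deliberately
    not applied (conservative).
    """
    gl = np.atleast_3d(np.asarray(gl, dtype=np.float64))
    lam = 2.0 * (loglik_at(gl, fhat) - loglik_at(gl, 0.0))
    lam = np.clip(lam, 0.0, None)
    lam = np.where(np.isnan(lam), np.inf, lam)  # l(0) = -inf at informative sites
    p = stats.chi2.sf(lam, df=1)
    return lam, p


@dataclass
class SiteFilterConfig:
    """Thresholds for the post-estimation site filters.

    Depth bounds are multipliers of the mean total (pooled) site depth;
    the MAF threshold is strict (> min_maf), matching the usual minor-allele
    cutoff semantics; min_ind_depth is carried as metadata for upstream
    per-individual depth masking and is not applied here.
    """

    depth_mult_low: float = 0.5
    depth_mult_high: float = 1.5
    min_maf: float = 0.05
    snp_pval: float = 1e-6
    min_individuals: int = 10
    min_ind_depth: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.depth_mult_low < self.depth_mult_high:
            raise ValueError("require 0 < low depth multiplier < high multiplier")
        if not 0 < self.snp_pval <= 1:
            raise ValueError("snp_pval must lie in (0, 1]")
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must lie in [0, 0.5)")


@dataclass
class FilterReport:
    mask: np.ndarray
    fail_depth: int
    fail_maf: int
    fail_snp: int
    fail_ind: int


def site_filters(
    counts: ReadCountMatrix, freqs: SiteFrequencyResult,
    snp_p: np.ndarray, config: SiteFilterConfig | None = None,
) -> FilterReport:
    """Combined site mask: depth window, MAF, SNP p-value, individuals with data.

    A site passes iff its total depth lies within [low, high] x mean total
    depth, MAF > min_maf (strict), the SNP test p-value is below the cutoff,
    and at least ``min_individuals`` individuals have reads.
    """
    cfg = config or SiteFilterConfig()
    if counts.n_sites == 0:
        return FilterReport(np.zeros(0, dtype=bool), 0, 0, 0, 0)
    total = counts.depth.sum(axis=1).astype(np.float64)
    mean_depth = total.mean()
    ok_depth = (total >= cfg.depth_mult_low * mean_depth) & \
               (total <= cfg.depth_mult_high * mean_depth)
    ok_maf = freqs.maf > cfg.min_maf
    ok_snp = np.asarray(snp_p) < cfg.snp_pval
    ok_ind = (counts.depth > 0).sum(axis=1) >= cfg.min_individuals
    mask = ok_depth & ok_maf & ok_snp & ok_ind
    return FilterReport(
        mask,
        int((~ok_depth).sum()), int((~ok_maf).sum()),
        int((~ok_snp).sum()), int((~ok_ind).sum()),
    )


def frequency_table(glm: GenotypeLikelihoodMatrix,
                    freqs: SiteFrequencyResult,
                    snp_p: np.ndarray) -> pd.DataFrame:
    """Per-site frequency report (chrom, pos, major, minor, fhat, maf, n_used, snp_p)."""
    return pd.DataFrame({
        "chrom": glm.chrom, "pos": glm.pos,
        "major": glm.major, "minor": glm.minor,
        "fhat": freqs.fhat, "maf": freqs.maf,
        "n_used": freqs.n_used, "snp_p": np.asarray(snp_p),
    })
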