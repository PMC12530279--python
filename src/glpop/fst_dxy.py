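"""2D-SFS estimation and SFS-prior FST and dxy.

The joint spectrum gamma(j,k) over allele-count classes of two populations
is estimated by EM on the outer-product likelihood SAF1_s(j) SAF2_s(k).
Per-site FST numerator/denominator components (Hudson/Bhatia by default,
a Reynolds-style variance-components alternative) and dxy are posterior
expectations under that prior; window and global FST are ratios of sums,
which keeps the estimator well-behaved when per-site denominators are tiny.
Negative per-site numerators are retained so window sums stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "estimate_sfs2d", "posterior2d_expectation", "fst_components",
    "window_fst", "global_fst", "dxy", "FstComponents",
]

SFS2D_TOL = 1e-8
SFS2D_MAX_ITER = 500


def estimate_sfs2d(
    saf1: np.ndarray, saf2: np.ndarray,
    tol: float = SFS2D_TOL, max_iter: int = SFS2D_MAX_ITER,
    return_loglik: bool = False,
):
    """EM estimate of the joint SFS gamma(j,k) from paired SAF matrices.

    Same convergence contract as the 1-D EM: uniform start, stop on
    max |Delta gamma| < tol, likelihood non-decreasing.
    """
    A = np.asarray(saf1, dtype=np.float64)
    B = np.asarray(saf2, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError("SAF matrices must be 2-D with equal site counts")
    S, J = A.shape
    K = B.shape[1]
    gamma = np.full((J, K), 1.0 / (J * K))
    logliks = []
    for _ in range(max_iter):
        z = ((A @ gamma) * B).sum(axis=1)
        logliks.append(float(np.log(z).sum()))
        # sum_s q_s(j,k) = gamma * (A/z)^T B
        acc = (A / z[:, None]).T @ B
        gamma_new = gamma * acc / S
        gamma_new /= gamma_new.sum()
        if np.abs(gamma_new - gamma).max() < tol:
            gamma = gamma_new
            break
        gamma = gamma_new
    if return_loglik:
        return gamma, np.array(logliks)
    return gamma


def posterior2d_expectation(
    saf1: np.ndarray, saf2: np.ndarray, gamma: np.ndarray, grid: np.ndarray,
) -> np.ndarray:
    """Per-site posterior expectation of a (J,K) grid function under the
    2D-SFS prior: E_s[grid] with q_s(j,k) propto gamma(j,k) a_s(j) b_s(k)."""
    A = np.asarray(saf1, dtype=np.float64)
    B = np.asarray(saf2, dtype=np.float64)
    z = ((A @ gamma) * B).sum(axis=1)
    num = ((A @ (gamma * grid)) * B).sum(axis=1)
    return num / z


@dataclass
class FstComponents:
    """Per-site FST estimator components alpha (numerator) and beta
    (denominator) plus coordinates and the estimator label."""

    chrom: np.ndarray
    pos: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    estimator: str


def _hudson_grids(n1: int, n2: int):
    """Hudson/Bhatia per-(j,k) numerator and denominator grids."""
    m1, m2 = 2 * n1, 2 * n2
    p1 = (np.arange(m1 + 1) / m1)[:, None]
    p2 = (np.arange(m2 + 1) / m2)[None, :]
    num = (p1 - p2) ** 2 \
        - p1 * (1 - p1) / (m1 - 1) \
        - p2 * (1 - p2) / (m2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _reynolds_grids(n1: int, n2: int):
    """Reynolds/Weir-Cockerham variance components on allele-count classes.

    Method-of-moments a (between) and b (within) for two samples of m1, m2
    chromosomes; theta = a/(a+b).  Equals the Reynolds (1983) two-population
    estimator at equal sample sizes.
    """
    m1, m2 = 2 * n1, 2 * n2
    p1 = (np.arange(m1 + 1) / m1)[:, None]
    p2 = (np.arange(m2 + 1) / m2)[None, :]
    mbar = (m1 + m2) / 2.0
    mc = (m1 + m2 - (m1**2 + m2**2) / (m1 + m2))  # r-1 = 1
    pbar = (m1 * p1 + m2 * p2) / (m1 + m2)
    s2 = (m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2) / mbar
    b = (mbar / (mbar - 1.0)) * (pbar * (1 - pbar) - s2 / 2.0)
    a = (mbar / mc) * (s2 - b / (mbar))
    return a, a + b


def fst_components(
    saf1: np.ndarray, saf2: np.ndarray, gamma: np.ndarray,
    n1: int, n2: int, chrom: np.ndarray, pos: np.ndarray,
    estimator: str = "hudson",
) -> FstComponents:
    """Posterior-expected per-site FST components under the 2D-SFS prior."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs at least 2 diploids")
    if estimator == "hudson":
        gnum, gden = _hudson_grids(n1, n2)
    elif estimator == "reynolds":
        gnum, gden = _reynolds_grids(n1, n2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    alpha = posterior2d_expectation(saf1, saf2, gamma, gnum)
    beta = posterior2d_expectation(saf1, saf2, gamma, gden)
    return FstComponents(np.asarray(chrom, dtype=object),
                         np.asarray(pos, dtype=np.int64),
                         alpha, beta, estimator)


def global_fst(comp: FstComponents, chroms=None) -> float:
    """Genome-wide ratio-of-sums FST, optionally restricted to a chromosome
    subset (the first-few-chromosomes shortcut used for whole-genome
    averages)."""
    sel = np.ones(len(comp.alpha), dtype=bool)
    if chroms is not None:
        sel = np.isin(comp.chrom.astype(str), list(chroms))
    b = comp.beta[sel].sum()
    if b <= 0:
        raise ValueError("no usable sites (denominator sum is zero)")
    return float(comp.alpha[sel].sum() / b)


def window_fst(comp: FstComponents, window: int = 10_000) -> pd.DataFrame:
    """Per-window ratio-of-sums FST; empty windows are omitted."""
    widx = (comp.pos - 1) // window
    rows = []
    for c in pd.unique(comp.chrom):
        m = comp.chrom == c
        for w in np.unique(widx[m]):
            sel = m & (widx == w)
            bsum = comp.beta[sel].sum()
            if bsum <= 0:
                continue
            rows.append((c, int(w) * window, (int(w) + 1) * window,
                         int(sel.sum()), float(comp.alpha[sel].sum() / bsum)))
    df = pd.DataFrame(rows, columns=["chrom", "start0", "end", "n_sites", "fst"])
    df["estimator"] = comp.estimator
    return df


def dxy(
    saf1: np.ndarray, saf2: np.ndarray, gamma: np.ndarray,
    n1: int, n2: int, chrom=None, pos=None, window: int | None = None,
):
    """Absolute divergence per site, and per-window means when requested.

    d_xy(site) = E[p1(1-p2) + p2(1-p1)] under the joint posterior; the
    window value is the mean over covered sites (variant and invariant).
    """
    m1, m2 = 2 * n1, 2 * n2
    p1 = (np.arange(m1 + 1) / m1)[:, None]
    p2 = (np.arange(m2 + 1) / m2)[None, :]
    grid = p1 * (1 - p2) + p2 * (1 - p1)
    per_site = posterior2d_expectation(saf1, saf2, gamma, grid)
    if window is None:
        return per_site
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    widx = (pos - 1) // window
    rows = []
    for c in pd.unique(chrom):
        m = chrom == c
        for w in np.unique(widx[m]):
            sel = m & (widx == w)
            rows.append((c, int(w) * window, (int(w) + 1) * window,
                         int(sel.sum()), float(per_site[sel].mean())))
    return per_site, pd.DataFrame(
        rows, columns=["chrom", "start0", "end", "n_sites", "dxy"])
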