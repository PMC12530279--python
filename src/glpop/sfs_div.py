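"""Sample-allele-frequency likelihoods, SFS estimation, windowed diversity.

The SAF vector at a site holds P(read data | j minor alleles among the 2N
sampled chromosomes), obtained by a dynamic program that convolves the
individuals' genotype-likelihood triples weighted by C(2,g).  An EM over
sites estimates the site-frequency spectrum gamma(j); per-site posteriors
q(j) under that empirical-Bayes prior feed the windowed estimators of
pairwise nucleotide diversity pi, Watterson's theta and Tajima's D (the
latter evaluated on expected segregating-site counts, hence approximate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

__all__ = [
    "saf", "fold_saf", "estimate_sfs", "site_posteriors",
    "per_site_pi", "window_diversity",
]

SFS_TOL = 1e-8
SFS_MAX_ITER = 500
_GCOMB = np.array([1.0, 2.0, 1.0])


def saf(gl: np.ndarray, fold: bool = False) -> np.ndarray:
    """Sample-allele-frequency likelihoods, shape (S, 2N+1) (or (S, N+1) folded).

    Dynamic program: h starts at [1]; each individual extends it by
    h(j) <- sum_g h_prev(j-g) L_i(g) C(2,g); finally SAF(j) = h(j)/C(2N,j).
    Rows are rescaled to maximum 1 (only relative values matter downstream).
    """
    gl = np.atleast_3d(np.asarray(gl, dtype=np.float64))
    S, N, _ = gl.shape
    if N < 1:
        raise ValueError("need at least one individual")
    h = np.ones((S, 1))
    for i in range(N):
        w = gl[:, i, :] * _GCOMB                       # (S, 3)
        new = np.zeros((S, h.shape[1] + 2))
        for g in range(3):
            new[:, g:g + h.shape[1]] += h * w[:, g:g + 1]
        mx = new.max(axis=1, keepdims=True)
        mx = np.where(mx == 0, 1.0, mx)
        h = new / mx                                    # guard against underflow
    out = h / comb(2 * N, np.arange(2 * N + 1))
    mx = out.max(axis=1, keepdims=True)
    mx = np.where(mx == 0, 1.0, mx)
    out = out / mx
    return fold_saf(out) if fold else out


def fold_saf(saf_unfolded: np.ndarray) -> np.ndarray:
    """Fold a SAF vector: class j merges with 2N-j; length becomes N+1."""
    m = saf_unfolded.shape[1] - 1          # = 2N
    if m % 2 != 0:
        raise ValueError("unfolded SAF length must be odd (2N+1)")
    n = m // 2
    folded = saf_unfolded[:, : n + 1].copy()
    folded[:, :n] += saf_unfolded[:, : n - 1 - m: -1]
    return folded


def estimate_sfs(
    saf_mat: np.ndarray, tol: float = SFS_TOL, max_iter: int = SFS_MAX_ITER,
    return_loglik: bool = False,
):
    """EM estimate of the SFS from per-site SAF likelihoods.

    E-step: w_s(j) propto gamma(j) SAF_s(j).  M-step: gamma(j) = mean over
    sites of w_s(j).  Starts uniform; stops on max |Delta gamma| < tol.  The
    mixture log-likelihood is non-decreasing; optionally returned per
    iteration for auditing.
    """
    A = np.asarray(saf_mat, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError("SAF matrix must be 2-D (sites x classes)")
    if (A < 0).any() or (A.max(axis=1) <= 0).any():
        raise ValueError("each SAF row needs at least one positive entry")
    S, J = A.shape
    gamma = np.full(J, 1.0 / J)
    logliks = []
    for _ in range(max_iter):
        mix = A @ gamma                       # (S,)
        logliks.append(float(np.log(mix).sum()))
        w = A * gamma                         # (S, J)
        w /= mix[:, None]
        gamma_new = w.mean(axis=0)
        if np.abs(gamma_new - gamma).max() < tol:
            gamma = gamma_new
            break
        gamma = gamma_new
    gamma = gamma / gamma.sum()
    if return_loglik:
        return gamma, np.array(logliks)
    return gamma


def site_posteriors(saf_mat: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Posterior q_s(j) propto gamma(j) SAF_s(j), each row summing to 1."""
    A = np.asarray(saf_mat, dtype=np.float64)
    if A.shape[1] != len(gamma):
        raise ValueError("SAF and SFS dimensions differ")
    q = A * np.asarray(gamma)
    z = q.sum(axis=1, keepdims=True)
    z = np.where(z == 0, 1.0, z)
    return q / z


def per_site_pi(post: np.ndarray, n_diploids: int, folded: bool = False) -> np.ndarray:
    """Expected heterozygosity per site: sum_j q(j) 2j(2N-j)/(2N(2N-1)).

    The weight j(2N-j) is symmetric under j <-> 2N-j, so folded posteriors
    give identical pi.
    """
    m = 2 * n_diploids
    j = np.arange(post.shape[1])
    w = 2.0 * j * (m - j) / (m * (m - 1.0))
    return post @ w


def _p_segregating(post: np.ndarray, n_diploids: int, folded: bool) -> np.ndarray:
    m = 2 * n_diploids
    j = np.arange(post.shape[1])
    if folded:
        seg = (j > 0)                      # folded top class j = N is variable
    else:
        seg = (j > 0) & (j < m)
    return post[:, seg].sum(axis=1)


def _tajima_constants(n: int) -> tuple[float, float, float, float]:
    """a1, a2, e1, e2 for sample size n chromosomes (Tajima 1989)."""
    k = np.arange(1, n)
    a1 = float((1.0 / k).sum())
    a2 = float((1.0 / k**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, e1, e2


@dataclass
class WindowScheme:
    """Non-overlapping windows of ``size`` bp aligned to multiples from position 1."""

    size: int = 10_000

    def index(self, pos: np.ndarray) -> np.ndarray:
        return (np.asarray(pos) - 1) // self.size


def window_diversity(
    post: np.ndarray, chrom: np.ndarray, pos: np.ndarray, n_diploids: int,
    window: int = 10_000, folded: bool = False,
) -> pd.DataFrame:
    """Windowed pi, Watterson's theta and Tajima's D for one population.

    Window pi is the per-site expected heterozygosity summed over covered
    sites and divided by the number of covered sites (not the window
    length); theta_W uses expected segregating-site counts over a_{2N-1};
    Tajima's D plugs the expected counts into the classical variance formula
    with n = 2N and is therefore approximate.  Windows with no covered sites
    are emitted with n_sites = 0 and missing statistics; D is flagged
    missing when the expected number of segregating sites is below 3.
    """
    if window <= 0:
        raise ValueError("window length must be positive")
    post = np.asarray(post, dtype=np.float64)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    pis = per_site_pi(post, n_diploids, folded)
    pseg = _p_segregating(post, n_diploids, folded)
    n_chr = 2 * n_diploids
    a1, _, e1, e2 = _tajima_constants(n_chr)
    scheme = WindowScheme(window)
    widx = scheme.index(pos)
    rows = []
    for c in pd.unique(chrom):
        m = chrom == c
        for w in np.unique(widx[m]):
            sel = m & (widx == w)
            n_sites = int(sel.sum())
            pi_sum = float(pis[sel].sum())
            s_exp = float(pseg[sel].sum())
            theta_w = s_exp / a1
            if s_exp >= 3:
                var = e1 * s_exp + e2 * s_exp * (s_exp - 1.0)
                taj_d = (pi_sum - theta_w) / np.sqrt(var) if var > 0 else np.nan
            else:
                taj_d = np.nan
            rows.append((c, int(w) * window, (int(w) + 1) * window, n_sites,
                         pi_sum / n_sites if n_sites else np.nan,
                         theta_w / n_sites if n_sites else np.nan,
                         taj_d))
    return pd.DataFrame(
        rows, columns=["chrom", "start0", "end", "n_sites", "pi", "thetaW", "tajD"])
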