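"""Binary group-contrast differentiation screen on genotype likelihoods.

For each SNP two super-pools A and B are compared.  The primary statistic
is a two-population frequency likelihood-ratio test: maximise the marginal
likelihood separately per group and pooled (each by the allele-frequency
EM) and refer Lambda = 2[l_A + l_B - l_pooled] to chi-square(1).  A score
test on posterior expected dosages — the statistic of association screens
on genotype likelihoods — is provided as a variant and agrees with the LRT
asymptotically at high depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from glpop.containers import GenotypeLikelihoodMatrix
from glpop.gl_freq import em_allele_frequency, loglik_at, posterior_dosage

__all__ = [
    "ContrastDesign", "contrast_lrt", "score_test", "thresholds",
    "ThresholdSet", "run_contrast",
]

P_FLOOR = 1e-320


@dataclass
class ContrastDesign:
    """Binary super-pool labels aligned 1:1 with GL columns."""

    labels: np.ndarray
    name: str = "contrast"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        vals = set(np.unique(self.labels).tolist())
        if not vals <= {0, 1} or len(vals) != 2:
            raise ValueError("labels must contain both 0 and 1 and nothing else")


def _group_loglik_and_freq(gl: np.ndarray):
    res = em_allele_frequency(gl)
    return loglik_at(gl, res.fhat), res


def contrast_lrt(gl: np.ndarray, design: ContrastDesign):
    """Frequency-difference LRT per site.

    Returns (lambda, p, f_A, f_B, informative) arrays; sites where either
    group has no informative individual are masked out (informative=False)
    rather than reported.
    """
    gl = np.atleast_3d(np.asarray(gl, dtype=np.float64))
    ga = gl[:, design.labels == 0, :]
    gb = gl[:, design.labels == 1, :]
    la, ra = _group_loglik_and_freq(ga)
    lb, rb = _group_loglik_and_freq(gb)
    lp, _ = _group_loglik_and_freq(gl)
    lam = np.clip(2.0 * (la + lb - lp), 0.0, None)
    p = stats.chi2.sf(lam, df=1)
    informative = ~(ra.noninformative | rb.noninformative)
    return lam, p, ra.fhat, rb.fhat, informative


def score_test(gl: np.ndarray, design: ContrastDesign):
    """Score test on posterior expected dosages under the pooled frequency.

    U = sum_i (y_i - ybar) E_i, V = ybar(1-ybar) sum_i (E_i - Ebar)^2,
    T = U^2/V referred to chi-square(1).  Degenerate sites (V = 0) get
    T = 0, p = 1.
    """
    gl = np.atleast_3d(np.asarray(gl, dtype=np.float64))
    y = design.labels.astype(np.float64)
    pooled = em_allele_frequency(gl)
    E = posterior_dosage(gl, pooled.fhat)          # (S, N)
    ybar = y.mean()
    U = ((y - ybar) * E).sum(axis=1)
    V = ybar * (1 - ybar) * ((E - E.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    # guard against float dust from identical dosages, not just exact zeros
    ok = V > 1e-12 * E.shape[1]
    T = np.where(ok, U**2 / np.where(ok, V, 1.0), 0.0)
    p = np.where(ok, stats.chi2.sf(T, df=1), 1.0)
    return T, p


@dataclass
class ThresholdSet:
    """Multiple-testing cutoffs for one contrast."""

    bonferroni_p: float
    empirical_cutoff: float        # -log10(p) at the top-q rank
    q: float
    alpha: float
    m: int


def thresholds(pvals: np.ndarray, q: float = 1e-4, alpha: float = 0.05) -> ThresholdSet:
    """Bonferroni cutoff alpha/m and the empirical top-quantile cutoff.

    The empirical cutoff is -log10 of the p-value at ascending rank
    K = max(1, floor(q*m)); outliers are SNPs with -log10(p) at or above it.
    """
    p = np.sort(np.asarray(pvals, dtype=np.float64))
    m = p.size
    if m < 1:
        raise ValueError("need at least one p-value")
    K = max(1, int(np.floor(q * m)))
    cutoff = -np.log10(max(p[K - 1], P_FLOOR))
    return ThresholdSet(alpha / m, float(cutoff), q, alpha, m)


def run_contrast(
    glm: GenotypeLikelihoodMatrix, design: ContrastDesign,
    q: float = 1e-4, alpha: float = 0.05, statistic: str = "lrt",
) -> tuple[pd.DataFrame, ThresholdSet]:
    """Full per-SNP screen: statistic, p, -log10(p), outlier flag.

    p-values are floored at 1e-320 before taking -log10 so plots stay
    finite; the empirical threshold is computed on the tested SNP set only.
    """
    if statistic == "lrt":
        lam, p, fa, fb, informative = contrast_lrt(glm.gl, design)
    elif statistic == "score":
        lam, p = score_test(glm.gl, design)
        res = em_allele_frequency(glm.gl)
        fa = fb = res.fhat
        informative = ~res.noninformative
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    df = pd.DataFrame({
        "chrom": glm.chrom, "pos": glm.pos,
        "major": glm.major, "minor": glm.minor,
        "fA": fa, "fB": fb, "lrt": lam, "p": p,
    })
    df = df[informative].reset_index(drop=True)
    df["log10p"] = -np.log10(np.maximum(df["p"].to_numpy(), P_FLOOR))
    ts = thresholds(df["p"].to_numpy(), q=q, alpha=alpha)
    df["outlier"] = df["log10p"] >= ts.empirical_cutoff
    return df, ts
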