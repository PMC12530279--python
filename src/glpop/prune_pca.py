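"""VIF-based LD pruning and standardized-dosage PCA.

Pruning mirrors PLINK's ``--indep``: in 100-SNP windows shifted by 5 SNPs,
each SNP's variance inflation factor VIF = 1/(1-R^2) is computed from the
window correlation matrix (R^2 is the coefficient of determination of that
SNP's dosage regressed on the others); while the maximum VIF exceeds the
threshold the offending SNP is removed, ties resolved by dropping the
lower-MAF SNP.  PCA runs on posterior expected dosages standardized by the
estimated allele frequency, X = (E - 2f)/sqrt(2f(1-f)) — a plain dosage PCA
rather than an iterated individual-allele-frequency model, adequate for the
cohort sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PruneConfig", "vif_prune", "compute_vif", "vif_audit",
           "PcaResult", "dosage_pca"]

RIDGE = 1e-8


@dataclass
class PruneConfig:
    window: int = 100
    step: int = 5
    vif_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not self.window > self.step > 0:
            raise ValueError("require window > step > 0")
        if self.vif_threshold <= 1:
            raise ValueError("VIF threshold must exceed 1")


def compute_vif(dosage: np.ndarray) -> np.ndarray:
    """VIF of each column of a dosage block via the inverse correlation
    matrix (diagonal entries), with a small ridge for singular blocks."""
    X = np.asarray(dosage, dtype=np.float64)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = X / sd
    R = (Z.T @ Z) / len(Z)        # correlation matrix (unit diagonal)
    R[np.diag_indices_from(R)] += RIDGE
    return np.diag(np.linalg.inv(R)).copy()


def vif_prune(dosage: np.ndarray, config: PruneConfig | None = None,
              maf: np.ndarray | None = None) -> np.ndarray:
    """Indices of SNPs kept after windowed VIF pruning.

    ``dosage`` is (individuals, SNPs) with SNPs in position order.
    Monomorphic SNPs are removed up front; a SNP removed in any window
    stays removed.  Deterministic given input order.
    """
    cfg = config or PruneConfig()
    X = np.asarray(dosage, dtype=np.float64)
    n_ind, n_snp = X.shape
    keep = np.ones(n_snp, dtype=bool)
    keep &= X.std(axis=0) > 0
    if maf is None:
        f = X.mean(axis=0) / 2.0
        maf = np.minimum(f, 1 - f)
    starts = range(0, max(n_snp - cfg.step, 0) + 1, cfg.step) if n_snp else []
    for w0 in starts:
        idx = np.flatnonzero(keep[w0:w0 + cfg.window]) + w0
        while len(idx) >= 2:
            vifs = compute_vif(X[:, idx])
            vmax = vifs.max()
            if vmax <= cfg.vif_threshold:
                break
            worst = np.flatnonzero(np.isclose(vifs, vmax))
            # tie-break: drop the lower-MAF SNP (keeps informative sites)
            drop = worst[np.argmin(maf[idx[worst]])]
            keep[idx[drop]] = False
            idx = np.delete(idx, drop)
        if w0 + cfg.window >= n_snp:
            break
    return np.flatnonzero(keep)


def vif_audit(dosage: np.ndarray, kept: np.ndarray,
              config: PruneConfig | None = None) -> float:
    """Maximum VIF over every original window restricted to the kept set —
    the brute-force check that pruning achieved its contract."""
    cfg = config or PruneConfig()
    kept = np.asarray(kept)
    kmask = np.zeros(dosage.shape[1], dtype=bool)
    kmask[kept] = True
    worst = 1.0
    n_snp = dosage.shape[1]
    for w0 in range(0, max(n_snp - cfg.step, 0) + 1, cfg.step):
        idx = np.flatnonzero(kmask[w0:w0 + cfg.window]) + w0
        if len(idx) >= 2:
            worst = max(worst, float(compute_vif(dosage[:, idx]).max()))
        if w0 + cfg.window >= n_snp:
            break
    return worst


@dataclass
class PcaResult:
    coords: np.ndarray        # (individuals, k)
    eigenvalues: np.ndarray   # non-increasing
    var_explained: np.ndarray


def dosage_pca(dosage: np.ndarray, freqs: np.ndarray, k: int = 2) -> PcaResult:
    """PCA of standardized expected dosages.

    ``dosage`` is (individuals, SNPs); ``freqs`` the per-SNP minor-allele
    frequency used for standardization.  Eigendecomposition of the
    individual x individual covariance; variance-explained fractions are
    eigenvalue shares of the trace.
    """
    E = np.asarray(dosage, dtype=np.float64)
    f = np.asarray(freqs, dtype=np.float64)
    n_ind, n_snp = E.shape
    if k >= n_ind:
        raise ValueError("k must be smaller than the number of individuals")
    ok = (f > 0) & (f < 1)
    E = E[:, ok]
    f = f[ok]
    X = (E - 2 * f) / np.sqrt(2 * f * (1 - f))
    X = X - X.mean(axis=0)      # centre individuals so PCs reflect structure
    C = (X @ X.T) / X.shape[1]
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    total = vals.sum()
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0, None))
    return PcaResult(coords, vals[:k], vals[:k] / total if total > 0 else vals[:k])
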