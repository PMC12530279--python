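"""Outlier aggregation: signal merging, gene assignment, overlap testing.

Outlier SNPs from a contrast are compiled into independent signals by
single-linkage clustering along each chromosome with a conservative gap
rule (a new cluster starts whenever the distance to the previous outlier
reaches the gap, 500 kb by default).  Signals and SNPs are assigned to
candidate genes when they fall within the gene body extended by a
strand-aware promoter/terminator window (5 kb upstream, 3 kb downstream of
the gene's own orientation).  Cross-contrast overlaps are tested against a
binomial null scaled by the total number of SNPs screened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from glpop.gl_freq import em_allele_frequency

__all__ = [
    "ScanConfig", "merge_signals", "assign_genes", "overlap_test",
    "OverlapResult", "frequency_matrix",
]


@dataclass
class ScanConfig:
    merge_gap: int = 500_000
    quantile: float = 1e-4
    gene_upstream: int = 5_000
    gene_downstream: int = 3_000

    def __post_init__(self) -> None:
        if self.merge_gap <= 0:
            raise ValueError("merge gap must be positive")
        if self.gene_upstream < 0 or self.gene_downstream < 0:
            raise ValueError("gene windows must be >= 0")


def merge_signals(snps: pd.DataFrame, gap: int = 500_000,
                  score_col: str = "log10p") -> pd.DataFrame:
    """Compile outlier SNPs into independent signals.

    Consecutive outliers on one chromosome closer than ``gap`` bp join one
    cluster; a distance of exactly ``gap`` (or more) starts a new cluster.
    Clusters never span chromosomes.  Returns one row per cluster with the
    member count and the peak SNP (maximum score, ties to the leftmost).
    """
    if len(snps) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps",
                                     "peak_pos", "peak_score"])
    df = snps.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    rows = []
    for c, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        score = sub[score_col].to_numpy() if score_col in sub else np.zeros(len(sub))
        breaks = np.flatnonzero(np.diff(pos) >= gap)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            seg_score = score[s:e + 1]
            peak = s + int(np.argmax(seg_score))
            rows.append((c, int(pos[s]), int(pos[e]), int(e - s + 1),
                         int(pos[peak]), float(seg_score[peak - s])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "peak_pos", "peak_score"])


def assign_genes(snps: pd.DataFrame, genes: pd.DataFrame,
                 upstream: int = 5_000, downstream: int = 3_000) -> pd.DataFrame:
    """Strand-aware SNP-to-gene assignment.

    A SNP hits a gene when its position lies within the gene body extended
    by ``upstream`` bp on the 5' side and ``downstream`` bp on the 3' side
    of the gene's strand (for a minus-strand gene the upstream extension is
    on the right).  A SNP may hit several genes; SNPs hitting none are
    labelled intergenic.  Returns one row per SNP with a sorted list of
    gene ids and the signed distance to the nearest assigned gene body
    (0 when inside).
    """
    out_genes: list[list[str]] = [[] for _ in range(len(snps))]
    out_dist: list[float] = [np.nan] * len(snps)
    snp_pos = snps["pos"].to_numpy()
    snp_chrom = snps["chrom"].to_numpy()
    for _, g in genes.iterrows():
        if g.strand == "+":
            lo, hi = g.start - upstream, g.end + downstream
        else:
            lo, hi = g.start - downstream, g.end + upstream
        hit = (snp_chrom == g.chrom) & (snp_pos >= lo) & (snp_pos <= hi)
        for i in np.flatnonzero(hit):
            out_genes[i].append(g.gene_id)
            d = 0
            if snp_pos[i] < g.start:
                d = int(snp_pos[i] - g.start)
            elif snp_pos[i] > g.end:
                d = int(snp_pos[i] - g.end)
            if np.isnan(out_dist[i]) or abs(d) < abs(out_dist[i]):
                out_dist[i] = d
    res = snps[["chrom", "pos"]].copy()
    res["genes"] = [",".join(sorted(g)) if g else "intergenic" for g in out_genes]
    res["distance"] = out_dist
    return res


def distinct_genes(assignments: pd.DataFrame) -> list[str]:
    """Distinct gene ids over an assignment table (a gene hit by SNPs in
    several clusters counts once)."""
    ids: set[str] = set()
    for cell in assignments["genes"]:
        if cell != "intergenic":
            ids.update(cell.split(","))
    return sorted(ids)


@dataclass
class OverlapResult:
    n_c: int
    n_d: int
    shared: int
    total_tests: int
    p: float
    log10_p: float
    underflow: bool    # p below double precision, reported as 0.0


def overlap_test(set_c, set_d, total_tests: int) -> OverlapResult:
    """One-sided binomial test of cross-contrast outlier overlap.

    k = |C intersect D| is referred to Binomial(n_C, n_D/M) with M the total
    number of SNPs screened; the upper tail is evaluated in log space so the
    magnitude is reported even when the p-value underflows to 0.0.
    """
    from scipy.special import logsumexp

    C, D = set(set_c), set(set_d)
    n_c, n_d = len(C), len(D)
    if total_tests < max(n_c, n_d):
        raise ValueError("total_tests must be at least the larger set size")
    k = len(C & D)
    if k > 0:
        logp = float(stats.binom.logsf(k - 1, n_c, n_d / total_tests))
        if not np.isfinite(logp):
            # logsf itself underflows for extreme tails; sum the log pmf
            x = np.arange(k, n_c + 1)
            logp = float(logsumexp(stats.binom.logpmf(x, n_c, n_d / total_tests)))
    else:
        logp = 0.0
    p = float(np.exp(logp))
    return OverlapResult(n_c, n_d, k, total_tests, p,
                         float(logp / np.log(10.0)), p == 0.0)


def frequency_matrix(
    region: tuple[str, int, int],
    pop_gls: dict[str, "np.ndarray"],
    chrom: np.ndarray, pos: np.ndarray,
) -> pd.DataFrame:
    """Per-population EM allele frequencies for SNPs in a region.

    ``pop_gls`` maps population name to its (S, N_pop, 3) GL array over the
    same site list described by ``chrom``/``pos``.  Rows are region SNPs,
    columns populations — the export behind allele-frequency heatmaps.
    """
    c, lo, hi = region
    sel = (np.asarray(chrom, dtype=object) == c) & (pos >= lo) & (pos <= hi)
    if not sel.any():
        import warnings
        warnings.warn(f"region {c}:{lo}-{hi} contains no SNPs", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "pos", *pop_gls])
    out = pd.DataFrame({"chrom": np.asarray(chrom, dtype=object)[sel],
                        "pos": np.asarray(pos)[sel]})
    for name, gl in pop_gls.items():
        out[name] = em_allele_frequency(np.asarray(gl)[sel]).fhat
    return out.reset_index(drop=True)
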