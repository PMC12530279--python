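"""Reproducibility suite: the package's headline quantities, recomputed
from scratch on synthetic cohorts at documented study conditions.

Each function simulates its own data (seeded through the stage-keyed
derivation, so results are reproducible and independent of call order),
runs the relevant pipeline stages, and returns the measured quantity with
the problem size.  Both the test suite and ``scripts/acceptance.py`` run
these; nothing here reads anything from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from glpop.containers import ReadCountMatrix
from glpop.contrast import ContrastDesign, contrast_lrt, score_test, thresholds
from glpop.fst_dxy import estimate_sfs2d, fst_components, global_fst
from glpop.gl_freq import (SiteFilterConfig, em_allele_frequency,
                           genotype_likelihoods, site_filters, snp_test)
from glpop.scan import assign_genes, distinct_genes, merge_signals
from glpop.seeds import derive_seed
from glpop.sfs_div import estimate_sfs, fold_saf, saf, site_posteriors, window_diversity
from glpop.synthdata import (OutlierSpec, PopulationModel, SimDesign,
                             draw_population_frequencies, inject_outliers,
                             simulate_read_counts)

__all__ = [
    "fst_drift_recovery", "maf_rmse_high_depth", "sfs_recovery_tv",
    "contrast_type1_rate", "outlier_power", "end_to_end_scan",
    "neutral_pi", "overlap_underflow",
]


def fst_drift_recovery(seed: int, n_sites: int = 50_000, n_per_pop: int = 25,
                       depth: float = 4.0, drift: float = 0.1) -> dict:
    """Genome-wide Hudson ratio-of-sums FST on a Balding-Nichols cohort.

    The drift parameter c is the per-population FST, so the estimator should
    recover ``drift`` up to simulation noise.
    """
    s = derive_seed(seed, "fst-recovery")
    model = PopulationModel(2, drift, n_sites,
                            chrom_lengths={"chr1": 40_000_000, "chr2": 40_000_000})
    truth = draw_population_frequencies(model, s)
    counts, _ = simulate_read_counts(truth, SimDesign(n_per_pop, depth, 0.005, s))
    glm = genotype_likelihoods(counts, 0.005)
    A = saf(glm.gl[:, :n_per_pop, :])
    B = saf(glm.gl[:, n_per_pop:, :])
    gamma = estimate_sfs2d(A, B)
    comp = fst_components(A, B, gamma, n_per_pop, n_per_pop, glm.chrom, glm.pos)
    return {"value": global_fst(comp), "n": n_sites}


def maf_rmse_high_depth(seed: int, n_sites: int = 1_000, n_ind: int = 50,
                        depth: float = 30.0) -> dict:
    """RMSE of the EM frequency against the realized sample allele frequency
    (mean genotype dosage / 2) at high depth, where the genotypes are the
    estimand's own truth."""
    s = derive_seed(seed, "maf-rmse")
    model = PopulationModel(1, 0.0, n_sites, chrom_lengths={"chr1": 10_000_000})
    truth = draw_population_frequencies(model, s)
    counts, truth = simulate_read_counts(truth, SimDesign(n_ind, depth, 0.005, s))
    glm = genotype_likelihoods(counts, 0.005)
    fhat = em_allele_frequency(glm.gl).fhat
    f_sample = truth.genotypes.mean(axis=1) / 2.0
    return {"value": float(np.sqrt(((fhat - f_sample) ** 2).mean())), "n": n_sites}


def sfs_recovery_tv(seed: int, n_sites: int = 20_000, n_ind: int = 10,
                    depth: float = 4.0) -> dict:
    """Total-variation distance between the estimated and true folded SFS.

    Sites are drawn from a Watterson-shaped spectrum (mass 1/j on variable
    classes, 60% monomorphic), chromosomes assigned exchangeably so the SAF
    model is exactly matched.  Folding follows the study's folded-spectrum
    workflow and cancels major/minor polarization confusion, the dominant
    error mode at low depth.
    """
    rng = np.random.default_rng(derive_seed(seed, "sfs-recovery"))
    m = 2 * n_ind
    gamma_star = np.r_[0.6, 0.4 / np.arange(1, m + 1) / np.log(m + 1)]
    gamma_star /= gamma_star.sum()
    j = rng.choice(m + 1, size=n_sites, p=gamma_star)
    rank = rng.random((n_sites, m)).argsort(axis=1).argsort(axis=1)
    g = (rank < j[:, None]).reshape(n_sites, n_ind, 2).sum(axis=2)
    depth_arr = rng.poisson(depth, size=(n_sites, n_ind))
    eps = 0.005
    pm = (g / 2) * (1 - eps) + (1 - g / 2) * eps / 3
    nmin = rng.binomial(depth_arr, pm)
    counts = ReadCountMatrix(
        np.array(["c"] * n_sites, dtype=object), np.arange(1, n_sites + 1),
        np.array(["A"] * n_sites, dtype=object),
        np.array(["C"] * n_sites, dtype=object), depth_arr - nmin, nmin)
    gl = genotype_likelihoods(counts, eps).gl
    gamma_hat = estimate_sfs(saf(gl), max_iter=2000)

    def fold(v):
        out = v[: n_ind + 1].copy()
        out[:n_ind] += v[: n_ind - 1 - m: -1]
        return out

    tv = 0.5 * np.abs(fold(gamma_hat) - fold(gamma_star)).sum()
    return {"value": float(tv), "n": n_sites}


def contrast_type1_rate(seed: int, n_sites: int = 20_000, n_per_group: int = 15,
                        depth: float = 1.0, f: float = 0.2) -> dict:
    """Empirical size of the group-contrast score test at alpha = 0.05 on
    null sites sharing one frequency."""
    s = derive_seed(seed, "contrast-type1")
    model = PopulationModel(2, 0.0, n_sites, chrom_lengths={"chr1": 20_000_000})
    truth = draw_population_frequencies(model, s)
    truth.freqs[:] = f
    counts, _ = simulate_read_counts(truth, SimDesign(n_per_group, depth, 0.005, s))
    gl = genotype_likelihoods(counts, 0.005).gl
    design = ContrastDesign([0] * n_per_group + [1] * n_per_group)
    _, p = score_test(gl, design)
    return {"value": float((p < 0.05).mean()), "n": n_sites}


def outlier_power(seed: int, n_null: int = 100_000, n_out: int = 200,
                  n_per_group: int = 30, depth: float = 1.0) -> dict:
    """Detection power for planted 0.5 frequency shifts at ~1x depth.

    Outlier sites carry the fixed-in-one-group pattern (0 vs 0.5) typical of
    strong local-adaptation loci; detection is at the empirical rank
    threshold matched to the planted fraction.
    """
    s = derive_seed(seed, "outlier-power")
    model = PopulationModel(2, 0.0, n_null + n_out,
                            chrom_lengths={"chr1": 200_000_000})
    truth = draw_population_frequencies(model, s)
    truth.freqs[:] = 0.25
    out_idx = np.arange(n_out) * (n_null // n_out)
    truth.freqs[out_idx, 0] = 0.0
    truth.freqs[out_idx, 1] = 0.5
    counts, _ = simulate_read_counts(truth, SimDesign(n_per_group, depth, 0.005, s))
    gl = genotype_likelihoods(counts, 0.005).gl
    design = ContrastDesign([0] * n_per_group + [1] * n_per_group)
    _, p, _, _, info = contrast_lrt(gl, design)
    ts = thresholds(p[info], q=n_out / len(p))
    called = -np.log10(np.maximum(p, 1e-320)) >= ts.empirical_cutoff
    return {"value": float(called[out_idx].mean()), "n": n_null + n_out}


def _run_scan_once(seed: int, n_background: int, n_loci: int, snps_per_locus: int,
                   n_per_pop: int, depth: float):
    """One full simulate -> GL -> filter -> contrast -> merge pass."""
    model = PopulationModel(
        2, 0.02, n_background,
        chrom_lengths={f"chr{i}": 10_000_000 for i in range(1, 5)})
    truth = draw_population_frequencies(model, seed)
    # plant fixed-difference loci as short SNP clusters, well separated:
    # locus centers at fixed fractions of each chromosome's site list
    site_order = np.lexsort((truth.pos, truth.chrom.astype(str)))
    per_chrom = {}
    for idx in site_order:
        per_chrom.setdefault(str(truth.chrom[idx]), []).append(idx)
    centers = []
    frac = np.linspace(0.1, 0.9, n_loci // 4)
    for c in sorted(per_chrom):
        sites = per_chrom[c]
        for fr in frac:
            centers.append(sites[int(fr * len(sites))])
    planted = []
    for ctr in centers:
        planted.extend(range(ctr, ctr + snps_per_locus))
    planted = np.array(sorted(planted))
    truth = inject_outliers(
        truth, OutlierSpec(planted, np.array([0, 1]),
                           target_freq=np.array([0.0, 1.0])))
    counts, truth = simulate_read_counts(
        truth, SimDesign(n_per_pop, depth, 0.005, seed))
    glm = genotype_likelihoods(counts, 0.005)
    freqs = em_allele_frequency(glm.gl)
    _, snp_p = snp_test(glm.gl, freqs.fhat)
    rep = site_filters(counts, freqs, snp_p, SiteFilterConfig())
    glm_f = glm.subset_sites(rep.mask)
    design = ContrastDesign([0] * n_per_pop + [1] * n_per_pop)
    lam, p, fa, fb, info = contrast_lrt(glm_f.gl, design)
    table = pd.DataFrame({
        "chrom": glm_f.chrom, "pos": glm_f.pos, "p": p,
        "log10p": -np.log10(np.maximum(p, 1e-320)),
    })[info].reset_index(drop=True)
    # Bonferroni threshold plus the single-SNP exclusion rule for signals
    cutoff = -np.log10(0.05 / len(table))
    outliers = table[table["log10p"] >= cutoff]
    clusters = merge_signals(outliers, gap=500_000)
    clusters = clusters[clusters["n_snps"] >= 2].reset_index(drop=True)
    return truth, planted, table, clusters


def end_to_end_scan(seed: int, n_background: int = 16_000, n_loci: int = 20,
                    snps_per_locus: int = 5, n_per_pop: int = 24,
                    depth: float = 1.08) -> dict:
    """Full synthetic selection scan with 20 planted outlier loci.

    Returns the number of independent signals (expected: exactly the number
    planted), whether every planted locus was hit, whether gene assignment
    recovered the toy gene placed over each locus peak, and whether a rerun
    under the same seed reproduced the outlier table byte-for-byte.
    """
    s = derive_seed(seed, "e2e-scan")
    truth, planted, table, clusters = _run_scan_once(
        s, n_background, n_loci, snps_per_locus, n_per_pop, depth)
    truth2, _, table2, clusters2 = _run_scan_once(
        s, n_background, n_loci, snps_per_locus, n_per_pop, depth)
    identical = table.to_csv(sep="\t", index=False) == \
        table2.to_csv(sep="\t", index=False)

    planted_keys = {(str(truth.chrom[i]), int(truth.pos[i])) for i in planted}
    hits_per_cluster = []
    for row in clusters.itertuples(index=False):
        members = {(row.chrom, int(p)) for p in
                   table.loc[(table["chrom"] == row.chrom)
                             & (table["pos"] >= row.start)
                             & (table["pos"] <= row.end), "pos"]}
        hits_per_cluster.append(len({(row.chrom, m[1]) for m in members}
                                    & planted_keys))
    every_cluster_planted = all(h > 0 for h in hits_per_cluster)

    # toy gene over every locus peak: assignment must recover it
    genes = pd.DataFrame({
        "chrom": clusters["chrom"],
        "start": np.maximum(clusters["peak_pos"] - 1_000, 1),
        "end": clusters["peak_pos"] + 1_000,
        "strand": ["+", "-"] * (len(clusters) // 2) +
                  ["+"] * (len(clusters) % 2),
        "gene_id": [f"toygene{i}" for i in range(len(clusters))],
    })
    peaks = clusters.rename(columns={"peak_pos": "pos"})[["chrom", "pos"]]
    asg = assign_genes(peaks, genes)
    genes_ok = all(f"toygene{i}" in cell.split(",")
                   for i, cell in enumerate(asg["genes"]))
    return {
        "n_signals": int(len(clusters)),
        "n_planted": n_loci,
        "every_cluster_contains_planted": bool(every_cluster_planted),
        "genes_ok": bool(genes_ok),
        "n_candidate_genes": len(distinct_genes(asg)),
        "deterministic": bool(identical),
        "n_snps_tested": int(len(table)),
    }


def neutral_pi(seed: int, n_sites: int = 20_000, n_ind: int = 15,
               depth: float = 4.0) -> dict:
    """Windowed nucleotide diversity on a neutral cohort whose realized
    heterozygosity is ~0.004 (the magnitude typical of diverse vertebrate
    populations); returns the coverage-weighted mean window pi."""
    s = derive_seed(seed, "neutral-pi")
    rng = np.random.default_rng(s)
    model = PopulationModel(1, 0.0, n_sites, chrom_lengths={"chr1": 200_000})
    truth = draw_population_frequencies(model, s)
    truth.freqs[:] = 0.0
    poly = rng.random(n_sites) < 0.02
    truth.freqs[poly, 0] = rng.uniform(0.02, 0.2, size=int(poly.sum()))
    counts, _ = simulate_read_counts(truth, SimDesign(n_ind, depth, 0.005, s))
    gl = genotype_likelihoods(counts, 0.005).gl
    A = saf(gl, fold=True)
    gamma = estimate_sfs(A)
    post = site_posteriors(A, gamma)
    df = window_diversity(post, counts.chrom, counts.pos, n_ind,
                          window=10_000, folded=True)
    pi = float((df["pi"] * df["n_sites"]).sum() / df["n_sites"].sum())
    h_true = float((2 * truth.freqs[:, 0] * (1 - truth.freqs[:, 0])).mean())
    return {"value": pi, "truth": h_true, "n": n_sites}


def overlap_underflow() -> dict:
    """Binomial overlap test at genome-screen scale: 288 SNPs shared between
    outlier sets of 1199 and 1237 among 20 million tests underflows double
    precision; the log-space magnitude is still reported."""
    from glpop.scan import overlap_test
    C = {("c", i) for i in range(1199)}
    D = {("c", i) for i in range(288)} | {("d", i) for i in range(949)}
    res = overlap_test(C, D, 20_000_000)
    return {"value": res.p, "log10_p": res.log10_p, "n": 20_000_000}
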