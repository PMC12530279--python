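# glpop

Genotype-likelihood population genomics for low-coverage whole-genome
sequencing.

When a cohort is sequenced at ~1x depth, individual genotypes cannot be
called: a heterozygote with one read is indistinguishable from a
homozygote.  The standard remedy — used across studies of wild fish, bird
and plant populations — is to keep every genotype's likelihood and do all
inference on those likelihoods directly.  `glpop` implements that pipeline
as a reusable, tested Python library with a command-line interface, aimed
at population-genomic screens of the kind run on salmonid lake/coastal
cohorts: a dozen populations of 18–30 diploids each, ~1x mean depth,
background differentiation FST ~ 0.01–0.16, and a handful of strongly
diverged loci to find.

## What it computes

For biallelic sites with per-individual major/minor read counts
(n_maj, n_min) and error rate ε, the genotype likelihood for g ∈ {0,1,2}
copies of the minor allele is

    L(g) = [ (g/2)(1−ε) + (1−g/2)·ε/3 ]^n_min · [ (1−g/2)(1−ε) + (g/2)·ε/3 ]^n_maj

On top of this one primitive the package builds:

- **Allele frequencies** — EM maximisation of Σᵢ log Σ_g Lᵢ(g) P(g|f)
  under Hardy–Weinberg P(g|f); SNP calling by a χ²₁ likelihood-ratio test
  of f = 0; depth/MAF/coverage site filters.
- **Site-frequency spectra** — per-site sample-allele-frequency (SAF)
  likelihoods P(data | j of 2N chromosomes) by dynamic programming, and a
  spectrum γ(j) by EM across sites, folded or unfolded.
- **Diversity** — windowed π = Σ_j q(j)·2j(2N−j)/(2N(2N−1)), Watterson's
  θ_W and Tajima's D from allele-count posteriors q under the estimated
  spectrum (empirical Bayes).
- **Divergence** — a joint 2D-SFS by EM over paired SAFs; per-site
  Hudson/Bhatia FST components α = (p₁−p₂)² − p₁(1−p₁)/(2N₁−1) −
  p₂(1−p₂)/(2N₂−1), β = p₁(1−p₂) + p₂(1−p₁) as posterior expectations,
  aggregated as ratio-of-sums per window and genome-wide; a Reynolds-style
  variance-components alternative; and d_xy = E[p₁(1−p₂) + p₂(1−p₁)].
- **Outlier screens** — a binary super-pool contrast per SNP: a
  two-population frequency LRT and a score test on posterior expected
  dosages; Bonferroni and empirical top-quantile thresholds; compilation
  of outlier SNPs into independent signals (≥ 500 kb apart); strand-aware
  candidate-gene assignment (5 kb upstream / 3 kb downstream); binomial
  cross-contrast overlap tests.
- **Structure** — VIF-based LD pruning (windowed, PLINK-style) and
  standardized-dosage PCA.
- **Assembly QC** — 50-kb windowed depth profiling to flag collapsed
  tetrasomic regions (doubled normalized depth).
- **Synthetic cohorts** — a Balding–Nichols generator with known truth
  (frequencies, genotypes, planted outliers) whose error model exactly
  matches the GL model, so every estimator can be validated end to end.

## Worked example

Simulate two populations (drift c = 0.08, 20 diploids each, 4x depth,
three planted outlier sites), compute likelihoods and filtered
frequencies:

```
$ glpop simulate --out sim --pops 2 --drift 0.08 --sites 2000 \
      --n-per-pop 20 --depth 4 --outliers 3 --seed 7
INFO glpop: simulated 2000 sites x 40 individuals
$ glpop gl --counts sim/counts.tsv --eps 0.005 --out gl.beagle
INFO glpop: wrote 2000 sites to gl.beagle
$ glpop maf --beagle gl.beagle --counts sim/counts.tsv --out freq.tsv
INFO glpop: filters: depth-fail 0, maf-fail 390, snp-fail 150, ind-fail 0
INFO glpop: wrote 1608 sites
$ head -3 freq.tsv
chrom   pos     major   minor   fhat    maf     n_used  snp_p
chr1    116     A       C       0.158237        0.158237        40      1.43987e-62
chr1    8509    A       C       0.920089        0.0799113       38      0
```

1608 of 2000 simulated sites pass the filters; 390 fail the MAF > 5% rule
and 150 the SNP test (the generator's Beta(0.8, 0.8) ancestral spectrum
puts substantial mass near fixation).  `fhat` is the EM minor-allele
frequency estimate; `snp_p` the χ²₁ test of monomorphism.  Downstream:

```
$ glpop theta --beagle gl.beagle --window 10000 --out theta.tsv
$ head -3 theta.tsv
chrom   start0  end     n_sites pi      thetaW  tajD
chr1    0       10000   2       0.211342        0.201899
chr1    30000   40000   1       0.00199517      0.0137627
```

Here π is per covered site (these are SNP-dense simulated panels, not
whole-genome tracks, hence the large values); `tajD` is empty where the
expected number of segregating sites is below 3.  `glpop fst`, `dxy`,
`contrast`, `scan`, `genes`, `overlap`, `prune`, `pca` and `depthqc`
complete the workflow; each writes plain TSV/BED/GFF text.

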