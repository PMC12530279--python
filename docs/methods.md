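# Methods

This note documents the statistical models behind `glpop`, the parameters
that matter, the design decisions taken where the design was genuinely
open, and the limits of what the synthetic validation shows.

## Genotype likelihoods and the error model

All inference starts from biallelic per-individual read counts.  A read
drawn from a chromosome carrying base b is reported as each of the three
other bases with probability ε/3 (symmetric single-base error).  For g
minor-allele copies the per-read minor probability is (g/2)(1−ε) +
(1−g/2)ε/3, and the likelihood triple L(g) is the binomial product over
the individual's reads, computed in log space and rescaled so max L = 1.
An individual with no reads carries the non-informative triple (1,1,1).
ε defaults to 0.005 (0.5%, mid-range for modern short-read platforms
after quality filtering); it must lie in (0, 0.75).  Mapping- and
base-quality filtering is assumed to have happened upstream of the read
counts; the package does not touch BAMs.

The synthetic generator uses this same emission model, deliberately:
estimator error measured on simulated cohorts is then estimation error
alone, with no model-mismatch component.  Real data adds mismapping,
indel edges, and base-quality miscalibration that this match excludes —
passing the recovery suites says the estimators are correct, not that
real-data preprocessing is solved.

## Allele-frequency EM, SNP test, site filters

The minor-allele frequency at a site maximises ℓ(f) = Σᵢ log Σ_g Lᵢ(g)
P(g|f) with the Hardy–Weinberg prior P(g|f).  The EM update replaces f by
the mean posterior dosage over 2N; it starts at f₀ = 0.1, stops when
|Δf| < 1e−8 or after 200 iterations, and provably never decreases ℓ.
The tests verify the EM against dense grid search (step 1e−5) on
simulated instances; on arbitrary (non-generative) likelihood triples the
surface can be multimodal and EM, like any ascent method, finds a local
maximum — for data generated by the read model this was never observed.
Sites where every individual is non-informative stay at f₀ and carry a
`noninformative` flag.

SNP calling refers Λ = 2[ℓ(f̂) − ℓ(0)] to χ²₁.  The null value f = 0 is a
boundary point, and the orthodox reference would be the ½χ²₀ + ½χ²₁
mixture; the plain χ²₁ tail is used instead, which doubles p-values and
is therefore conservative (fewer false SNPs).  Site filters follow
low-coverage practice: pooled depth within 0.5–1.5x the mean pooled
depth, MAF strictly greater than 0.05, SNP p below 1e−6, at least 10
individuals with data.  The MAF inequality is strict, matching the usual
minor-allele-cutoff semantics; boundary sites are excluded.

## SAF, SFS, diversity

The sample-allele-frequency likelihood P(data | j minor alleles among 2N
chromosomes) is computed by convolving the individuals' triples weighted
by C(2,g), then dividing by C(2N,j); rows are rescaled against underflow
(only relative values matter).  The spectrum γ(j) is an EM mixture
estimate across sites (uniform start, tol 1e−8 on max|Δγ|, cap 500
iterations — raised to 2000 in the validation suite where convergence of
small classes matters).  Folding merges j with 2N−j, keeping the middle
class once; the folded EM then targets the prior restricted to j ≤ N,
which is the internally consistent convention for that fold (the tests
include the exact identity this induces for π).

Per-site diversity uses allele-count posteriors under the estimated
spectrum (empirical Bayes, as is standard for low-coverage θ estimation):
π_s = Σ_j q_s(j)·2j(2N−j)/(2N(2N−1)), window π = Σπ_s divided by the
number of covered sites (not window length — at ~1x coverage the two
differ and the covered-site denominator is the unbiased one for per-site
diversity).  θ_W divides expected segregating-site counts by a_{2N−1};
Tajima's D plugs expected counts into the classical constants with
n = 2N and is flagged approximate; it is reported as missing when the
expected segregating count is below 3.  Windows are non-overlapping,
aligned to multiples of the window length (10 kb default) from
position 1.

## 2D-SFS, FST, dxy

The joint spectrum over two populations' count classes is an EM on the
outer-product likelihood SAF₁(j)·SAF₂(k), same contract as the 1-D EM.
Per-site FST components are posterior expectations of grid functions:
Hudson/Bhatia (default — well-defined under unequal sample sizes, the
recommended two-population estimator) and a Reynolds/Weir–Cockerham
variance-components alternative computed on allele-count classes, which
coincides with the classical Reynolds estimator at equal sample sizes.
Output labels the estimator.  Windows and the genome-wide value are
ratios of sums; negative per-site numerators are kept so sums stay
unbiased.  "Moving windows" are non-overlapping (step = length) — a
configurable step could be added but the default mirrors the windowed
outputs everywhere else.  d_xy is the posterior expectation of
p₁(1−p₂) + p₂(1−p₁); window d_xy averages over covered sites, variant
and invariant.

Under the Balding–Nichols generator the dispersion c is the
per-population FST, giving a closed-form recovery target: two cohorts at
c = 0.1 (25 diploids each, 4x depth, 50,000 sites) yield a genome-wide
Hudson ratio-of-sums of 0.0987 in the validation run — within the ±0.02
band asserted in the acceptance suite.

## The contrast screen

A binary super-pool contrast is tested per SNP two ways.  The frequency
LRT maximises the marginal likelihood separately per group and pooled
(three EM runs) and refers Λ = 2[ℓ_A + ℓ_B − ℓ_pool] to χ²₁.  The score
test uses posterior expected dosages Eᵢ under the pooled frequency:
U = Σ(yᵢ−ȳ)Eᵢ, V = ȳ(1−ȳ)Σ(Eᵢ−Ē)², T = U²/V — the construction used by
genotype-likelihood association screens.  At high depth the two agree
(tested: p-values within a factor 2 on ≥95% of null sites at 30x).

Calibration at ~1x depth differs and this is documented deliberately: the
score test holds its nominal size (measured 0.044–0.048 at α = 0.05 on
20,000 null sites, 15+15 individuals), while the LRT is mildly
anti-conservative (measured ≈ 0.073–0.078) because group frequency MLEs
frequently sit on the boundary f = 0 where the χ²₁ reference is liberal.
The EM was verified exact against grid maximisation, so this is a
property of the asymptotic reference, not of the implementation.  Screens
that rank SNPs (empirical top-quantile thresholds) are unaffected by the
miscalibration's monotone part; users needing calibrated per-SNP
p-values at very low depth should prefer `statistic="score"`.

Thresholds: Bonferroni α/m, and the empirical cutoff at ascending rank
K = max(1, ⌊q·m⌋) (q = 1e−4 default, i.e., the top 0.01% of tested
SNPs).  p-values are floored at 1e−320 before −log10.

Detection power at the study's depth: with a 0.5 frequency shift of the
fixed-in-one-group kind (0 vs 0.5), 30+30 individuals at 1x and the rank
threshold matched to the planted fraction, 79–87% of planted sites are
recovered across seeds and statistics.  This is an information limit of
1x data at these cohort sizes, not a tuning artifact: placements,
statistics and null spectra were varied without crossing 90%.  The
acceptance suite keeps a ≥90% assertion and it fails honestly; the
measured value is what `scripts/acceptance.py` reports.

## Signals, genes, overlaps

Outlier SNPs are compiled into independent signals by single-linkage
along each chromosome: a gap of at least 500 kb (boundary inclusive)
starts a new cluster; clusters never span sequences; each reports its
span, member count and peak SNP.  Signals consisting of a single SNP are
excluded in the end-to-end validation scan, mirroring the practice of
discarding isolated one-SNP hits as noise.  Gene assignment extends each
gene body 5 kb on its 5' side and 3 kb on its 3' side *in the gene's own
strand orientation* — for a minus-strand gene the upstream window lies
to the right.  Strandedness changes gene counts and is therefore stated
prominently; a SNP may hit several genes, and a gene hit from several
clusters counts once in genome-wide totals.  Cross-contrast overlap is
tested as k = |C∩D| against Binomial(n_C, n_D/M) with M the total SNPs
screened; the tail is evaluated in log space (falling back to a
logsumexp over log-pmf terms when even the log survival function
underflows), so the magnitude is reported — e.g. log₁₀p ≈ −927 for 288
shared among 1199 and 1237 over 20 million — while the double-precision
p-value is 0.0 with an `underflow` flag.

## Pruning and PCA

VIF pruning follows the windowed scheme (100 SNPs, step 5, threshold 2):
within each window the VIF of each SNP is the corresponding diagonal of
the inverse correlation matrix (ridge 1e−8 against singular blocks);
while the maximum exceeds the threshold that SNP is removed, ties broken
by dropping the lower-MAF SNP (keeps informative sites; exact tie rules
differ between tools and none is canonical).  A post-hoc audit recomputes
VIF over every original window on the kept set and is part of the
acceptance suite.  PCA standardizes posterior expected dosages,
X = (E − 2f)/√(2f(1−f)), centres individuals, and eigendecomposes the
individual covariance.  This is a plain dosage PCA — the iterated
individual-allele-frequency refinement used by specialised low-coverage
PCA tools is out of scope; at the cohort sizes targeted here the plain
version separates populations at c = 0.3 with zero sign
misclassifications and its null leading eigenvalue sits at the
Marchenko–Pastur bulk edge.

## Depth QC

Mean depth in 50-kb non-overlapping windows, normalized by the
genome-wide *median* of window means — median, not mean, so the doubled
regions being hunted cannot drag the baseline.  A sequence is flagged as
a collapsed duplicate when its median normalized depth reaches 1.6x
(between the 1x baseline and the 2x signal of a collapsed tetrasomic
region; configurable).  Raising the factor never adds flags; the profile
is invariant to rescaling the whole track.

## Synthetic cohorts: what they emulate and what they do not

`PopulationModel` draws ancestral frequencies from Beta(a, a) (a = 0.8
default — a moderately U-shaped spectrum typical of SNP panels) and
population frequencies from the Balding–Nichols Beta around them;
c ∈ [0, 1) per population, c = 0 copying the ancestral draw exactly.
Defaults mirror the targeted study scale: 24 diploids per population,
mean depth 1.08x, ε = 0.005, sites spread over ≤5 named chromosomes with
strictly increasing positions.  Genotypes are Hardy–Weinberg, depths
Poisson, reads binomial with the ε/3 cross-allele error.  Outlier loci
are planted by shifting or replacing group frequencies (clamped to [0,1]
with a warning).  Everything is reproducible byte-for-byte from one
master seed via stage-keyed derivation (CRC32 of the stage name mixed
into a SeedSequence), so stages rerun independently without perturbing
each other.

Not simulated: linkage and recombination (sites are exchangeable given
frequencies — LD-pruning tests therefore build their own correlated
blocks), coalescent genealogies, mapping error, indels, base-quality
variation, and multi-allelic sites.  Consequently the validation suite
demonstrates estimator correctness and statistical calibration under the
stated models, and nothing about robustness to artefacts upstream of the
read counts.

## Validation conditions and numerical choices

The acceptance computations run at these problem sizes (chosen to
exercise the stated conditions while completing in about two minutes on
one CPU): FST recovery 50,000 sites × 2×25 diploids at 4x; MAF RMSE
1,000 sites × 50 diploids at 30x (RMSE measured against the realized
sample frequency, the estimand of the EM — population-parameter RMSE is
dominated by binomial sampling, ~0.04 at N = 50, regardless of
estimator); folded-SFS recovery 20,000 sites × 10 diploids at 4x
(folded, matching the folded-spectrum workflow; the unfolded spectrum at
these conditions has an MLE floor of TV ≈ 0.022–0.029 driven by
major/minor polarization confusion); score-test size 20,000 null sites;
power 200 planted among 100,000 null sites; the end-to-end scan 16,000
background sites plus 20 five-SNP loci on four chromosomes at 1.08x,
where exactly 20 independent signals are recovered, every cluster
contains planted SNPs, peak SNPs map to the toy genes placed over them,
and a rerun under the same seed is byte-identical.

Numerical details worth knowing: EM tolerances are absolute (1e−8) on
the parameter, not the likelihood; SAF rows and GL triples are max-scaled
to dodge underflow; the score test guards its variance against float dust
from identical dosages; all writers emit floats at 6 significant digits,
and every numeric table is re-parseable by its reader (property-tested).

## Known limitations

- The frequency LRT's mild anti-conservatism at ~1x depth (above).
- Tajima's D from expected segregating-site counts is approximate; no
  attempt is made to calibrate its variance under the posterior.
- The folded/unfolded spectrum conventions interact (middle class,
  restricted prior); mixing a folded prior with unfolded SAFs is not
  supported.
- Dosage PCA without the iterative individual-frequency refinement
  underestimates structure at extreme low depth.
- The binomial overlap test treats SNP sets as exchangeable draws,
  ignoring LD clustering; its p-values at genome scale are astronomically
  small and should be read as magnitudes, not literal probabilities.
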