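"""Synthetic low-coverage cohorts with known truth.

The generator emulates the statistical structure of a lake/coastal salmonid
resequencing study: a handful of populations of ~18-30 diploids sequenced at
~1x mean depth, background divergence in the FST ~ 0.01-0.16 range, and a
minority of outlier loci with large between-group frequency shifts.

Population allele frequencies follow the Balding-Nichols model: given an
ancestral frequency p ~ Beta(a, a), population k draws its frequency from
Beta(p (1-c_k)/c_k, (1-p)(1-c_k)/c_k).  The dispersion parameter c_k equals
that population's FST against the ancestral pool, which gives closed-form
recovery targets for the estimators downstream.  Reads are Poisson in depth
with a symmetric 3-way base-error split (a true base misreads to each of the
three other bases with probability eps/3), exactly the emission model the
genotype-likelihood stage assumes, so estimator error can be measured free
of model mismatch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glpop.containers import ReadCountMatrix
from glpop.io_formats import write_gff3
from glpop.seeds import stage_rng

__all__ = [
    "PopulationModel", "OutlierSpec", "SimDesign", "SimTruth",
    "draw_population_frequencies", "inject_outliers", "simulate_read_counts",
    "make_toy_annotation",
]

logger = logging.getLogger(__name__)

# Study-scale defaults: ~24 diploids per population, ~1.08x mean depth,
# 0.5% per-base error, moderately U-shaped ancestral frequency spectrum.
DEFAULT_N_PER_POP = 24
DEFAULT_DEPTH = 1.08
DEFAULT_ERROR = 0.005
DEFAULT_BETA_A = 0.8


@dataclass
class PopulationModel:
    """Balding-Nichols divergence model over a small synthetic genome.

    ``drift`` holds one dispersion parameter c in [0, 1) per population
    (c = per-population FST); ``beta_a`` parameterises the symmetric
    Beta(a, a) ancestral-frequency distribution; sites are spread over at
    most a few named chromosomes with strictly increasing positions.
    """

    n_pops: int
    drift: np.ndarray
    n_sites: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000})
    beta_a: float = DEFAULT_BETA_A

    def __post_init__(self) -> None:
        self.drift = np.broadcast_to(
            np.asarray(self.drift, dtype=np.float64), (self.n_pops,)).copy()
        if ((self.drift < 0) | (self.drift >= 1)).any():
            raise ValueError("drift parameters must lie in [0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.beta_a <= 0:
            raise ValueError("beta_a must be positive")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class OutlierSpec:
    """Planted outlier loci: which sites, which populations, what shift.

    Either ``delta`` (a frequency shift in [-1, 1] added to the target
    populations' frequencies, clamped to [0, 1]) or ``target_freq`` (absolute
    per-population target frequencies, one row per site) must be given.
    """

    site_indices: np.ndarray
    target_pops: np.ndarray
    delta: float | None = None
    target_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        self.target_pops = np.asarray(self.target_pops, dtype=np.int64)
        if (self.delta is None) == (self.target_freq is None):
            raise ValueError("give exactly one of delta or target_freq")
        if self.delta is not None and not -1 <= self.delta <= 1:
            raise ValueError("delta must lie in [-1, 1]")


@dataclass
class SimDesign:
    """Sequencing design: cohort sizes, mean depth, error rate, seed."""

    n_per_pop: int = DEFAULT_N_PER_POP
    depth: float = DEFAULT_DEPTH
    error: float = DEFAULT_ERROR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("mean depth must be >= 0")
        if not 0 <= self.error < 0.75:
            raise ValueError("error rate must lie in [0, 0.75)")
        if self.n_per_pop < 1:
            raise ValueError("need at least one individual per population")


@dataclass
class SimTruth:
    """Ground truth of a simulation: frequencies, genotypes, outlier flags."""

    chrom: np.ndarray
    pos: np.ndarray
    freqs: np.ndarray                  # (sites, pops) true minor-allele freq
    outlier: np.ndarray                # (sites,) bool
    genotypes: np.ndarray | None = None  # (sites, individuals) in {0,1,2}
    pop_of_individual: np.ndarray | None = None

    def copy(self) -> "SimTruth":
        return SimTruth(
            self.chrom.copy(), self.pos.copy(), self.freqs.copy(),
            self.outlier.copy(),
            None if self.genotypes is None else self.genotypes.copy(),
            None if self.pop_of_individual is None else self.pop_of_individual.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for k in range(self.freqs.shape[1]):
            df[f"freq_pop{k}"] = self.freqs[:, k]
        df["outlier"] = self.outlier.astype(int)
        return df


def _assign_positions(model: PopulationModel, rng: np.random.Generator):
    """Spread sites over chromosomes proportionally to length, with strictly
    increasing positions within each chromosome."""
    names = list(model.chrom_lengths)
    lengths = np.array([model.chrom_lengths[n] for n in names], dtype=np.float64)
    share = lengths / lengths.sum()
    counts = np.floor(share * model.n_sites).astype(int)
    for i in range(model.n_sites - counts.sum()):
        counts[i % len(names)] += 1
    chroms, poss = [], []
    for name, length, cnt in zip(names, lengths, counts):
        if cnt == 0:
            continue
        if cnt > length:
            raise ValueError(f"cannot place {cnt} sites on {name} of length {int(length)}")
        p = np.sort(rng.choice(int(length), size=cnt, replace=False)) + 1
        chroms.extend([name] * cnt)
        poss.extend(p.tolist())
    return np.array(chroms, dtype=object), np.array(poss, dtype=np.int64)


def draw_population_frequencies(model: PopulationModel, seed: int) -> SimTruth:
    """Draw per-population minor-allele frequencies under Balding-Nichols.

    A population with c = 0 copies the ancestral draw exactly (the Beta
    degenerates to a point mass).
    """
    rng = stage_rng(seed, "frequencies")
    chrom, pos = _assign_positions(model, rng)
    p = rng.beta(model.beta_a, model.beta_a, size=model.n_sites)
    freqs = np.empty((model.n_sites, model.n_pops))
    for k, c in enumerate(model.drift):
        if c == 0.0:
            freqs[:, k] = p
        else:
            scale = (1.0 - c) / c
            a = np.clip(p * scale, 1e-12, None)
            b = np.clip((1.0 - p) * scale, 1e-12, None)
            freqs[:, k] = rng.beta(a, b)
    return SimTruth(chrom, pos, freqs, np.zeros(model.n_sites, dtype=bool))


def inject_outliers(truth: SimTruth, spec: OutlierSpec) -> SimTruth:
    """Replace or shift group frequencies at the listed sites and flag them.

    Shifted frequencies outside [0, 1] are clamped with a logged warning;
    all other sites are untouched.
    """
    n_sites, n_pops = truth.freqs.shape
    if spec.site_indices.size and (
            spec.site_indices.min() < 0 or spec.site_indices.max() >= n_sites):
        raise IndexError("outlier spec references a nonexistent site")
    if spec.target_pops.size and (
            spec.target_pops.min() < 0 or spec.target_pops.max() >= n_pops):
        raise IndexError("outlier spec references a nonexistent population")
    out = truth.copy()
    sel = np.ix_(spec.site_indices, spec.target_pops)
    if spec.delta is not None:
        shifted = out.freqs[sel] + spec.delta
    else:
        tf = np.asarray(spec.target_freq, dtype=np.float64)
        shifted = np.broadcast_to(tf, out.freqs[sel].shape).copy()
    if (shifted < 0).any() or (shifted > 1).any():
        logger.warning("outlier target frequencies outside [0,1]; clamping")
        warnings.warn("outlier target frequencies clamped to [0,1]", stacklevel=2)
        shifted = np.clip(shifted, 0.0, 1.0)
    out.freqs[sel] = shifted
    out.outlier[spec.site_indices] = True
    return out


def simulate_read_counts(
    truth: SimTruth, design: SimDesign
) -> tuple[ReadCountMatrix, SimTruth]:
    """Simulate HWE genotypes and low-coverage reads from true frequencies.

    Genotype g ~ Binomial(2, f_pop); per-individual site depth d ~
    Poisson(depth); minor-allele reads ~ Binomial(d, (g/2)(1-eps) +
    (1-g/2) eps/3); the rest are major reads.  Returns the read counts and a
    truth updated with the sampled genotypes.
    """
    rng = stage_rng(design.seed, "reads")
    n_sites, n_pops = truth.freqs.shape
    n_ind = n_pops * design.n_per_pop
    pop_of = np.repeat(np.arange(n_pops), design.n_per_pop)
    g = rng.binomial(2, truth.freqs[:, pop_of])            # (sites, inds)
    depth = rng.poisson(design.depth, size=(n_sites, n_ind))
    p_minor = (g / 2.0) * (1.0 - design.error) + (1.0 - g / 2.0) * design.error / 3.0
    n_minor = rng.binomial(depth, p_minor)
    n_major = depth - n_minor
    major = np.full(n_sites, "A", dtype=object)
    minor = np.full(n_sites, "C", dtype=object)
    samples = [f"pop{p}_ind{i}" for p in range(n_pops) for i in range(design.n_per_pop)]
    counts = ReadCountMatrix(truth.chrom, truth.pos, major, minor,
                             n_major, n_minor, samples)
    out = truth.copy()
    out.genotypes = g
    out.pop_of_individual = pop_of
    return counts, out


def make_toy_annotation(
    chrom_lengths: dict[str, int], n_genes: int, seed: int, path=None,
    gene_length: int = 2000, min_gap: int = 1000,
) -> pd.DataFrame:
    """Generate non-overlapping strand-labelled gene features as GFF3.

    Genes are spread evenly over chromosomes; raises if they cannot fit.
    Writing the same seed twice yields byte-identical files.
    """
    if any(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = stage_rng(seed, "annotation")
    names = list(chrom_lengths)
    per_chrom = np.zeros(len(names), dtype=int)
    for i in range(n_genes):
        per_chrom[i % len(names)] += 1
    rows = []
    gid = 0
    for name, cnt in zip(names, per_chrom):
        length = chrom_lengths[name]
        span = gene_length + min_gap
        if cnt * span > length:
            raise ValueError(f"{cnt} genes do not fit on {name} ({length} bp)")
        # place genes on an even grid, then jitter within the free slack
        slot = length // max(cnt, 1)
        for j in range(cnt):
            lo = j * slot + 1
            hi = (j + 1) * slot - gene_length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((name, start, start + gene_length - 1, strand, f"gene{gid}"))
            gid += 1
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    if path is not None:
        write_gff3(genes, path)
    return genes
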