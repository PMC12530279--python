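"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReadCountMatrix", "GenotypeLikelihoodMatrix"]

BASES = ("A", "C", "G", "T")
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class ReadCountMatrix:
    """Per-site, per-individual counts of major- and minor-allele reads.

    Sites are rows (chrom, 1-based pos, major base, minor base); individuals
    are columns.  The major allele is the reference base; counts are reads
    supporting each of the two alleles after upstream quality filtering.
    """

    chrom: np.ndarray
    pos: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    n_major: np.ndarray
    n_minor: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = _as_str_array(self.chrom)
        self.major = _as_str_array(self.major)
        self.minor = _as_str_array(self.minor)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.n_major = np.asarray(self.n_major, dtype=np.int64)
        self.n_minor = np.asarray(self.n_minor, dtype=np.int64)
        if self.n_major.ndim != 2 or self.n_major.shape != self.n_minor.shape:
            raise ValueError("count matrices must be 2-D and congruent")
        if (self.n_major < 0).any() or (self.n_minor < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.major == self.minor).any():
            raise ValueError("major and minor allele must differ at every site")
        if not self.samples:
            self.samples = [f"ind{i}" for i in range(self.n_major.shape[1])]
        if len(self.samples) != self.n_major.shape[1]:
            raise ValueError("sample names do not match count columns")
        # positions unique within a chromosome
        keys = {}
        for c, p in zip(self.chrom, self.pos):
            if (c, p) in keys:
                raise ValueError(f"duplicate position {c}:{p}")
            keys[(c, p)] = True

    @property
    def n_sites(self) -> int:
        return int(self.n_major.shape[0])

    @property
    def n_individuals(self) -> int:
        return int(self.n_major.shape[1])

    @property
    def depth(self) -> np.ndarray:
        """Total reads per site per individual, shape (sites, individuals)."""
        return self.n_major + self.n_minor

    def subset_sites(self, mask: np.ndarray) -> "ReadCountMatrix":
        m = np.asarray(mask)
        return ReadCountMatrix(
            self.chrom[m], self.pos[m], self.major[m], self.minor[m],
            self.n_major[m], self.n_minor[m], list(self.samples),
        )


@dataclass
class GenotypeLikelihoodMatrix:
    """Relative likelihoods of 0/1/2 minor-allele copies, per site x individual.

    ``gl`` has shape (sites, individuals, 3) and is scaled so each triple has
    maximum exactly 1; an individual with no reads at a site carries (1,1,1).
    ``eps`` records the per-base error rate used to compute the likelihoods
    (unknown when read from disk).
    """

    chrom: np.ndarray
    pos: np.ndarray
    major: np.ndarray
    minor: np.ndarray
    gl: np.ndarray
    eps: float | None = None
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = _as_str_array(self.chrom)
        self.major = _as_str_array(self.major)
        self.minor = _as_str_array(self.minor)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gl = np.asarray(self.gl, dtype=np.float64)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError("gl must have shape (sites, individuals, 3)")
        if not self.samples:
            self.samples = [f"ind{i}" for i in range(self.gl.shape[1])]

    @property
    def n_sites(self) -> int:
        return int(self.gl.shape[0])

    @property
    def n_individuals(self) -> int:
        return int(self.gl.shape[1])

    def subset_sites(self, mask: np.ndarray) -> "GenotypeLikelihoodMatrix":
        m = np.asarray(mask)
        return GenotypeLikelihoodMatrix(
            self.chrom[m], self.pos[m], self.major[m], self.minor[m],
            self.gl[m], self.eps, list(self.samples),
        )

    def subset_individuals(self, idx) -> "GenotypeLikelihoodMatrix":
        idx = np.asarray(idx)
        return GenotypeLikelihoodMatrix(
            self.chrom, self.pos, self.major, self.minor,
            self.gl[:, idx, :], self.eps,
            [self.samples[i] for i in idx],
        )
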