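"""Readers and writers for every on-disk format the pipeline touches.

Conventions: positions are 1-based inclusive everywhere internally (matching
GFF3); BED output is the single point where coordinates are converted to
0-based half-open.  All writers are deterministic (stable column order,
floats at 6 significant digits) and gzip-transparent: a path ending in
``.gz`` is compressed/decompressed on the fly.
"""

from __future__ import annotations

import gzip
import io
import os
from typing import Iterable

import numpy as np
import pandas as pd

from glpop.containers import BASES, BASE_TO_CODE, GenotypeLikelihoodMatrix, ReadCountMatrix

__all__ = [
    "read_beagle", "write_beagle", "read_counts", "write_counts",
    "read_gff3", "write_gff3", "write_bed", "write_table",
    "read_sfs", "write_sfs", "read_sfs2d", "write_sfs2d",
]

FLOAT_FMT = "%.6g"


def _open(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class FormatError(ValueError):
    """A file violated the documented on-disk format."""


# ---------------------------------------------------------------- Beagle GL

def write_beagle(glm: GenotypeLikelihoodMatrix, path) -> None:
    """Write a Beagle genotype-likelihood text file.

    Header is ``marker allele1 allele2`` then three columns per individual;
    marker is ``chrom_pos``; alleles are coded 0-3 for A,C,G,T; likelihoods
    are max-scaled; fields are tab-separated.
    """
    with _open(path, "wt") as fh:
        cols = ["marker", "allele1", "allele2"]
        for s in glm.samples:
            cols.extend([s, s, s])
        fh.write("\t".join(cols) + "\n")
        for i in range(glm.n_sites):
            row = [
                f"{glm.chrom[i]}_{glm.pos[i]}",
                str(BASE_TO_CODE[glm.major[i]]),
                str(BASE_TO_CODE[glm.minor[i]]),
            ]
            row.extend(FLOAT_FMT % v for v in glm.gl[i].ravel())
            fh.write("\t".join(row) + "\n")


def read_beagle(path) -> GenotypeLikelihoodMatrix:
    chroms, poss, majors, minors, rows = [], [], [], [], []
    seen = set()
    with _open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 6 or (len(header) - 3) % 3 != 0:
            raise FormatError(f"{path}: malformed Beagle header")
        n_ind = (len(header) - 3) // 3
        samples = header[3::3]
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + 3 * n_ind:
                raise FormatError(
                    f"{path}:{lineno}: expected {3 + 3 * n_ind} columns, got {len(fields)}"
                )
            marker = fields[0]
            if marker in seen:
                raise FormatError(f"{path}:{lineno}: duplicate marker {marker}")
            seen.add(marker)
            try:
                chrom, pos = marker.rsplit("_", 1)
                poss.append(int(pos))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad marker {marker!r}") from exc
            chroms.append(chrom)
            try:
                majors.append(BASES[int(fields[1])])
                minors.append(BASES[int(fields[2])])
                vals = np.array(fields[3:], dtype=np.float64)
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            rows.append(vals.reshape(n_ind, 3))
    gl = np.array(rows) if rows else np.zeros((0, n_ind, 3))
    glm = GenotypeLikelihoodMatrix(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(majors, dtype=object), np.array(minors, dtype=object),
        gl, None, samples,
    )
    mx = glm.gl.max(axis=2)
    if glm.n_sites and not np.allclose(mx, 1.0, atol=1e-6):
        raise FormatError(f"{path}: likelihood triples are not max-scaled")
    return glm


# ------------------------------------------------------------- read counts

def write_counts(counts: ReadCountMatrix, path) -> None:
    """Write the read-count TSV: chrom, pos, major, minor, then per
    individual a ``nMajor,nMinor`` pair."""
    with _open(path, "wt") as fh:
        fh.write("\t".join(["chrom", "pos", "major", "minor"] + list(counts.samples)) + "\n")
        for i in range(counts.n_sites):
            cells = [f"{counts.n_major[i, j]},{counts.n_minor[i, j]}"
                     for j in range(counts.n_individuals)]
            fh.write("\t".join([str(counts.chrom[i]), str(counts.pos[i]),
                                str(counts.major[i]), str(counts.minor[i])] + cells) + "\n")


def read_counts(path) -> ReadCountMatrix:
    with _open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "major", "minor"]:
            raise FormatError(f"{path}: malformed count-file header")
        samples = header[4:]
        chroms, poss, majors, minors, nmaj, nmin = [], [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4 + len(samples):
                raise FormatError(f"{path}:{lineno}: ragged row")
            chroms.append(fields[0])
            try:
                poss.append(int(fields[1]))
                pairs = [tuple(map(int, c.split(","))) for c in fields[4:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric count") from exc
            majors.append(fields[2])
            minors.append(fields[3])
            nmaj.append([p[0] for p in pairs])
            nmin.append([p[1] for p in pairs])
    n = len(samples)
    return ReadCountMatrix(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(majors, dtype=object), np.array(minors, dtype=object),
        np.array(nmaj, dtype=np.int64).reshape(-1, n),
        np.array(nmin, dtype=np.int64).reshape(-1, n),
        list(samples),
    )


# -------------------------------------------------------------------- GFF3

def read_gff3(path) -> pd.DataFrame:
    """Parse gene features from a GFF3 file.

    Returns a DataFrame (chrom, start, end, strand, gene_id) with 1-based
    inclusive coordinates, sorted by chrom then start.  Malformed lines are
    rejected with their line number.
    """
    import gffutils

    with _open(path, "rt") as fh:
        text = fh.read()
    # light pre-validation so errors carry line numbers
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
        try:
            s, e = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if s < 1 or e < s:
            raise FormatError(f"{path}:{lineno}: invalid interval [{s},{e}]")
        if fields[6] not in "+-.":
            raise FormatError(f"{path}:{lineno}: invalid strand {fields[6]!r}")
    db = gffutils.create_db(text, ":memory:", from_string=True,
                            merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append((feat.seqid, feat.start, feat.end, feat.strand, feat.id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene features (chrom, start, end, strand, gene_id) as GFF3."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write("\t".join([
                str(row.chrom), "glpop", "gene", str(int(row.start)),
                str(int(row.end)), ".", str(row.strand), ".",
                f"ID={row.gene_id}",
            ]) + "\n")


# --------------------------------------------------------------- BED / TSV

def write_bed(records: pd.DataFrame, path) -> None:
    """Write intervals as BED (0-based half-open).

    ``records`` carries 1-based inclusive (chrom, start, end) plus any extra
    columns, which are appended after the three BED fields.
    """
    with _open(path, "wt") as fh:
        extra = [c for c in records.columns if c not in ("chrom", "start", "end")]
        for row in records.itertuples(index=False):
            d = row._asdict()
            fields = [str(d["chrom"]), str(int(d["start"]) - 1), str(int(d["end"]))]
            for c in extra:
                v = d[c]
                fields.append(FLOAT_FMT % v if isinstance(v, float) else str(v))
            fh.write("\t".join(fields) + "\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV export used by every stage's report writer."""
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


# ------------------------------------------------------------------- SFS

def write_sfs(gamma: np.ndarray, path) -> None:
    """Write a 1-D SFS as a single whitespace-separated line."""
    with _open(path, "wt") as fh:
        fh.write(" ".join("%.10g" % v for v in np.asarray(gamma).ravel()) + "\n")


def read_sfs(path) -> np.ndarray:
    with _open(path, "rt") as fh:
        return np.array(fh.readline().split(), dtype=np.float64)


def write_sfs2d(gamma: np.ndarray, path) -> None:
    """Write a 2-D SFS as a (2N1+1) x (2N2+1) whitespace matrix."""
    g = np.asarray(gamma)
    with _open(path, "wt") as fh:
        for row in g:
            fh.write(" ".join("%.10g" % v for v in row) + "\n")


def read_sfs2d(path) -> np.ndarray:
    with _open(path, "rt") as fh:
        rows = [np.array(line.split(), dtype=np.float64) for line in fh if line.strip()]
    return np.vstack(rows)
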