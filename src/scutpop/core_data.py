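"""Shared domain containers and file I/O.

The whole pipeline operates on four light-weight containers:

* :class:`GenotypeTable` -- diploid microsatellite genotypes (integer repeat
  scores) with a deme label per individual.
* :class:`SequenceAlignment` -- equal-length haploid sequences (cpDNA) with a
  deme label per sequence.
* :class:`SiteTable` -- one sampling site with coordinates, altitude and
  bioclimatic variables.
* :class:`DistanceMatrix` -- labelled symmetric matrix over populations, the
  currency of the Mantel/MMRR layer.

GenePop (2- or 3-digit allele dialect), FASTA and CSV readers/writers are
provided here; everything downstream consumes the containers only.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: allele code used for a missing gene copy (GenePop "000"/"00")
MISSING = 0

BIOCLIM_VARS = ("bio2", "bio8", "bio9", "bio13", "bio18", "bio19")


class ScutpopError(Exception):
    """Base class for package errors."""


class ParseError(ScutpopError):
    pass


class ValidationError(ScutpopError):
    pass


# ---------------------------------------------------------------------------
# GenotypeTable
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Diploid genotypes: ``genotypes[i, l, :]`` are the two allele codes of
    individual ``i`` at locus ``l`` (positive integers; ``MISSING`` = 0).

    Both copies of a genotype are missing together or neither is.
    """

    individual_ids: list[str]
    demes: list[str]  # parallel to individual_ids
    loci: list[str]
    genotypes: np.ndarray  # (n_individuals, n_loci, 2) int

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if len(self.demes) != n:
            raise ValidationError("demes must be parallel to individual_ids")
        if self.genotypes.shape != (n, L, 2):
            raise ValidationError(
                f"genotypes shape {self.genotypes.shape} != {(n, L, 2)}"
            )
        if n < 1 or L < 1:
            raise ValidationError("need >=1 individual and >=1 locus")
        if (self.genotypes < 0).any():
            raise ValidationError("allele codes must be positive or MISSING (0)")
        half_missing = (self.genotypes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValidationError("half-missing genotype: both alleles or neither")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def deme_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.demes:
            seen.setdefault(d, None)
        return list(seen)

    def deme_of(self, individual_id: str) -> str:
        return self.demes[self.individual_ids.index(individual_id)]

    def individuals_in(self, deme: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.demes) == deme)

    def allele_counts(self, deme: str, locus_index: int) -> dict[int, int]:
        """Counts of non-missing gene copies for one deme at one locus."""
        idx = self.individuals_in(deme)
        copies = self.genotypes[idx, locus_index, :].ravel()
        copies = copies[copies != MISSING]
        vals, cnts = np.unique(copies, return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))

    def subset_demes(self, keep: list[str]) -> "GenotypeTable":
        mask = np.isin(self.demes, keep)
        return GenotypeTable(
            [i for i, m in zip(self.individual_ids, mask) if m],
            [d for d, m in zip(self.demes, mask) if m],
            list(self.loci),
            self.genotypes[mask],
        )


def read_genepop(path_or_buf) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit allele dialect).

    Demes are taken from POP blocks and named ``pop1``, ``pop2``, ... unless
    every individual id in a block shares a common prefix before ``_``, in
    which case that prefix is used. Missing genotypes are ``0000``/``000000``
    (or all-zero in either dialect).
    """
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty GenePop file")
    # line 0: title; then locus names until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names may be comma-separated on one line
        for name in lines[i].replace(",", "\n").splitlines():
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if not loci:
        raise ParseError("no locus names before first POP")
    ids: list[str] = []
    demes: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    block_ids: list[str] = []
    digits = None

    def flush_block():
        nonlocal block_ids
        if not block_ids:
            return
        prefixes = {b.split("_")[0] for b in block_ids}
        label = prefixes.pop() if len(prefixes) == 1 and prefixes != {""} else f"pop{pop_idx}"
        demes.extend([label] * len(block_ids))
        ids.extend(block_ids)
        block_ids = []

    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            flush_block()
            pop_idx += 1
            continue
        if pop_idx == 0:
            raise ParseError(f"line {lineno}: genotype row before first POP")
        if "," in line:
            ind_id, geno_part = line.split(",", 1)
        else:
            parts = line.split()
            ind_id, geno_part = parts[0], " ".join(parts[1:])
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"line {lineno}: {len(fields)} genotypes for {len(loci)} loci"
            )
        row = []
        for f in fields:
            if digits is None:
                if len(f) in (4, 6):
                    digits = len(f) // 2
                else:
                    raise ParseError(f"line {lineno}: bad genotype field '{f}'")
            if len(f) != 2 * digits or not f.isdigit():
                raise ParseError(f"line {lineno}: bad genotype field '{f}'")
            a, b = int(f[:digits]), int(f[digits:])
            if (a == 0) != (b == 0):
                # GenePop allows one-sided zero; normalise to fully missing
                a = b = MISSING
            row.append((a, b))
        rows.append(row)
        block_ids.append(ind_id.strip())
    flush_block()
    if not rows:
        raise ParseError("no genotype rows")
    return GenotypeTable(ids, demes, loci, np.array(rows, dtype=np.int64))


def write_genepop(gt: GenotypeTable, path_or_buf, digits: int = 3,
                  title: str = "scutpop export") -> None:
    """Write a GenotypeTable in the GenePop dialect with ``digits`` per allele."""
    if int(gt.genotypes.max(initial=0)) >= 10 ** digits:
        raise ValidationError(f"allele code too large for {digits}-digit dialect")
    out = io.StringIO()
    out.write(title + "\n")
    for loc in gt.loci:
        out.write(loc + "\n")
    demes_arr = np.asarray(gt.demes)
    for deme in gt.deme_names:
        out.write("POP\n")
        for i in np.flatnonzero(demes_arr == deme):
            genos = " ".join(
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in gt.genotypes[i]
            )
            out.write(f"{gt.individual_ids[i]}, {genos}\n")
    text = out.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# SequenceAlignment
# ---------------------------------------------------------------------------

_VALID_BASES = set("ACGT-N")


@dataclass
class SequenceAlignment:
    """Equal-length haploid sequences over {A,C,G,T,-,N} with deme labels."""

    sequence_ids: list[str]
    demes: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise ValidationError("alignment needs >=1 sequence")
        if len({len(s) for s in self.sequences}) != 1:
            raise ValidationError("sequences have unequal lengths")
        if len(self.demes) != len(self.sequence_ids) or len(self.sequences) != len(
            self.sequence_ids
        ):
            raise ValidationError("ids, demes, sequences must be parallel")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - _VALID_BASES
        if bad:
            raise ValidationError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def deme_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.demes:
            seen.setdefault(d, None)
        return list(seen)

    def subset_deme(self, deme: str) -> "SequenceAlignment":
        keep = [i for i, d in enumerate(self.demes) if d == deme]
        return SequenceAlignment(
            [self.sequence_ids[i] for i in keep],
            [self.demes[i] for i in keep],
            [self.sequences[i] for i in keep],
        )

    def matrix(self) -> np.ndarray:
        """(n, length) array of single-character strings."""
        return np.array([list(s) for s in self.sequences])


def read_fasta_alignment(path_or_buf, deme_delimiter: str = "_") -> SequenceAlignment:
    """Read an aligned FASTA; the deme is the id text before ``deme_delimiter``."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    ids, seqs = [], []
    cur: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            ids.append(line[1:].split()[0])
            cur = []
            seqs.append(cur)
        else:
            if not ids:
                raise ParseError("sequence data before first FASTA header")
            cur.append(line)
    if not ids:
        raise ParseError("no FASTA records")
    sequences = ["".join(c) for c in seqs]
    demes = [i.split(deme_delimiter)[0] for i in ids]
    return SequenceAlignment(ids, demes, sequences)


def write_fasta_alignment(aln: SequenceAlignment, path_or_buf) -> None:
    text = "".join(f">{i}\n{s}\n" for i, s in zip(aln.sequence_ids, aln.sequences))
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# SiteTable
# ---------------------------------------------------------------------------


@dataclass
class SiteTable:
    """One sampling site: coordinates, altitude and bioclim variables."""

    population: str
    latitude: float
    longitude: float
    altitude: float
    climate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-90 <= self.latitude <= 90):
            raise ValidationError(f"latitude {self.latitude} out of range")
        if not (-180 <= self.longitude <= 180):
            raise ValidationError(f"longitude {self.longitude} out of range")


_SITE_REQUIRED = ("population", "latitude", "longitude", "altitude")


def read_site_table(path_or_buf) -> list[SiteTable]:
    """Read a site/climate CSV. Required columns: population, latitude,
    longitude, altitude; any other numeric columns are kept as climate
    variables. Thousands separators in precipitation columns are accepted."""
    df = pd.read_csv(path_or_buf, thousands=",")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _SITE_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"site table missing columns: {missing}")
    if len(df["population"]) != df["population"].nunique():
        raise ValidationError("duplicate population labels in site table")
    sites = []
    climate_cols = [c for c in df.columns if c not in _SITE_REQUIRED and c != "species"]
    for _, row in df.iterrows():
        sites.append(
            SiteTable(
                population=str(row["population"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                altitude=float(row["altitude"]),
                climate={c: float(row[c]) for c in climate_cols},
            )
        )
    return sites


def write_site_table(sites: list[SiteTable], path_or_buf) -> None:
    climate_cols = list(sites[0].climate) if sites else []
    rows = [
        {
            "population": s.population,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "altitude": s.altitude,
            **{c: s.climate[c] for c in climate_cols},
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix with zero diagonal.

    Negative off-diagonal entries are rejected unless ``kind`` is
    ``"linearized"`` (Rousset-linearized F_ST matrices may carry small
    negative values inherited from negative F_ST estimates).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n},{n})")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-9:
            raise ValidationError("matrix is not symmetric (tol 1e-9)")
        self.values = (self.values + self.values.T) / 2.0
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-9:
            raise ValidationError("diagonal must be zero")
        np.fill_diagonal(self.values, 0.0)
        if self.kind != "linearized" and self.values.min(initial=0.0) < -1e-9:
            raise ValidationError("negative distances (only 'linearized' may)")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


def unfold_upper(matrix: DistanceMatrix) -> np.ndarray:
    """Row-major strict upper triangle as a vector of length n(n-1)/2.

    Ordering: (0,1), (0,2), ..., (0,n-1), (1,2), ... -- numpy's
    ``triu_indices`` order; :func:`fold_upper` is the exact inverse.
    """
    if matrix.n < 2:
        raise ValidationError("need n >= 2 to unfold")
    iu = np.triu_indices(matrix.n, k=1)
    return matrix.values[iu].copy()


def fold_upper(vec: np.ndarray, labels: list[str], kind: str = "generic") -> DistanceMatrix:
    """Inverse of :func:`unfold_upper`."""
    vec = np.asarray(vec, dtype=float)
    n = len(labels)
    if vec.shape != (n * (n - 1) // 2,):
        raise ValidationError("vector length does not match n(n-1)/2")
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = vec
    m = m + m.T
    return DistanceMatrix(list(labels), m, kind)


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i (a_0 = 0)."""
    return float(sum(1.0 / i for i in range(1, k + 1)))
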