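"""Data model and file I/O for genetic maps, genotype matrices, and phenotypes.

All downstream modules consume the three container types defined here:

* :class:`GeneticMap` — ordered markers with chromosome, genetic (cM) and
  physical (bp) coordinates.
* :class:`GenotypeMatrix` — lines × markers allele-count codes for a fully
  inbred biparental panel.  Codes are 0 (AA, first founder) or 2 (BB, second
  founder); missing cells carry the sentinel :data:`MISSING`.
* :class:`PlotPhenotypes` — plot-level trait records ``(line, replicate,
  value)`` feeding the one-way ANOVA.

On-disk formats are plain CSV/TSV: a map file has columns
``marker,chrom,cM,bp``; a genotype file has the line id in the first column
and one symbol column per marker; a phenotype file has columns
``line,replicate,value``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype code.  Distinct from the valid codes {0, 2}.
MISSING: int = -1

#: Default symbol dialect for genotype files: symbol -> code.
DEFAULT_DIALECT: dict[str, int] = {"A": 0, "B": 2, "NA": MISSING, "-": MISSING}

#: Opt-in dialect that additionally maps a heterozygote call to MISSING, for
#: panels scored before inbreeding was complete.
HET_AS_MISSING_DIALECT: dict[str, int] = {**DEFAULT_DIALECT, "H": MISSING}


class MapError(ValueError):
    """Raised for an invalid genetic map (order, duplicates, coordinates)."""


class GenotypeError(ValueError):
    """Raised for an invalid genotype matrix or genotype file."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map over one or more chromosomes.

    Markers are stored sorted by ``(chromosome, genetic_pos)``; genetic and
    physical order must agree within each chromosome.
    """

    marker_ids: np.ndarray  # dtype object/str, shape (n_markers,)
    chromosome: np.ndarray  # int, 1..n_chr
    genetic_pos: np.ndarray  # float cM, nondecreasing within chromosome
    physical_pos: np.ndarray  # int bp (1-based), nondecreasing within chromosome

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_ids", np.asarray(self.marker_ids, dtype=object))
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=np.int64))
        object.__setattr__(self, "genetic_pos", np.asarray(self.genetic_pos, dtype=float))
        object.__setattr__(self, "physical_pos", np.asarray(self.physical_pos, dtype=np.int64))
        n = len(self.marker_ids)
        if not (len(self.chromosome) == len(self.genetic_pos) == len(self.physical_pos) == n):
            raise MapError("map column lengths differ")
        if n == 0:
            raise MapError("empty map")
        if len(set(self.marker_ids)) != n:
            dup = pd.Series(self.marker_ids)[pd.Series(self.marker_ids).duplicated()].iloc[0]
            raise MapError(f"duplicate marker id: {dup!r}")
        if (self.genetic_pos < 0).any():
            row = int(np.flatnonzero(self.genetic_pos < 0)[0])
            raise MapError(f"negative cM coordinate at row {row} ({self.marker_ids[row]!r})")
        if (self.physical_pos < 1).any():
            row = int(np.flatnonzero(self.physical_pos < 1)[0])
            raise MapError(f"physical position < 1 bp at row {row} ({self.marker_ids[row]!r})")
        # canonical sort: chromosomes ascending, within-chromosome file order kept
        order = np.argsort(self.chromosome, kind="stable")
        if not np.array_equal(order, np.arange(n)):
            for name in ("marker_ids", "chromosome", "genetic_pos", "physical_pos"):
                object.__setattr__(self, name, getattr(self, name)[order])
        for chrom in np.unique(self.chromosome):
            idx = np.flatnonzero(self.chromosome == chrom)
            g = self.genetic_pos[idx]
            p = self.physical_pos[idx]
            if (np.diff(g) < 0).any():
                row = int(idx[int(np.flatnonzero(np.diff(g) < 0)[0]) + 1])
                raise MapError(
                    f"cM not nondecreasing on chromosome {chrom} at row {row} "
                    f"({self.marker_ids[row]!r})"
                )
            if (np.diff(p) < 0).any():
                row = int(idx[int(np.flatnonzero(np.diff(p) < 0)[0]) + 1])
                raise MapError(
                    f"bp order disagrees with cM order on chromosome {chrom} at row {row} "
                    f"({self.marker_ids[row]!r})"
                )

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def n_chromosomes(self) -> int:
        return len(np.unique(self.chromosome))

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_slice(self, chrom: int) -> slice:
        """Contiguous index slice of the markers on one chromosome."""
        idx = np.flatnonzero(self.chromosome == chrom)
        if idx.size == 0:
            raise MapError(f"chromosome {chrom} has no markers")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def total_length_cm(self) -> float:
        """Total map length: sum over chromosomes of (max cM − min cM)."""
        total = 0.0
        for chrom in self.chromosomes:
            g = self.genetic_pos[self.chrom_slice(chrom)]
            total += float(g[-1] - g[0])
        return total

    def index_of(self, marker_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given marker ids (errors on unknown ids)."""
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=np.intp)
        except KeyError as exc:
            raise MapError(f"unknown marker id: {exc.args[0]!r}") from None

    def subset(self, marker_ids: Sequence[str]) -> "GeneticMap":
        idx = np.sort(self.index_of(marker_ids))
        return GeneticMap(
            self.marker_ids[idx], self.chromosome[idx],
            self.genetic_pos[idx], self.physical_pos[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chrom": self.chromosome,
                "cM": self.genetic_pos,
                "bp": self.physical_pos,
            }
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Lines × markers matrix of allele-count codes {0, 2, MISSING}.

    This is the model matrix ``X`` of the ridge prediction model: element
    ``(i, j)`` is 0 or 2 according to whether line *i* is homozygous for the
    first or second founder allele at marker *j*.
    """

    line_ids: np.ndarray  # object, shape (n_lines,)
    map: GeneticMap
    codes: np.ndarray  # int8, shape (n_lines, n_markers)

    def __post_init__(self) -> None:
        object.__setattr__(self, "line_ids", np.asarray(self.line_ids, dtype=object))
        object.__setattr__(self, "codes", np.asarray(self.codes, dtype=np.int8))
        if self.codes.ndim != 2:
            raise GenotypeError("codes must be 2-D (lines × markers)")
        if self.codes.shape != (len(self.line_ids), len(self.map)):
            raise GenotypeError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.line_ids)} lines × {len(self.map)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise GenotypeError("duplicate line ids")
        bad = ~np.isin(self.codes, (0, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid code {int(self.codes[i, j])} at line {self.line_ids[i]!r}, "
                f"marker {self.map.marker_ids[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.map)

    @property
    def n_missing(self) -> int:
        return int((self.codes == MISSING).sum())

    def line_index(self, line_ids: Sequence[str]) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([lookup[l] for l in line_ids], dtype=np.intp)
        except KeyError as exc:
            raise GenotypeError(f"unknown line id: {exc.args[0]!r}") from None

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = np.sort(self.map.index_of(marker_ids))
        return GenotypeMatrix(self.line_ids, self.map.subset(self.map.marker_ids[idx]),
                              self.codes[:, idx])

    def subset_lines(self, line_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.line_index(line_ids)
        return GenotypeMatrix(self.line_ids[idx], self.map, self.codes[idx])

    def to_frame(self, dialect: Mapping[str, int] = DEFAULT_DIALECT) -> pd.DataFrame:
        inv = _invert_dialect(dialect)
        sym = np.empty(self.codes.shape, dtype=object)
        for code, symbol in inv.items():
            sym[self.codes == code] = symbol
        df = pd.DataFrame(sym, columns=list(self.map.marker_ids))
        df.insert(0, "line", self.line_ids)
        return df


@dataclass(frozen=True)
class PlotPhenotypes:
    """Plot-level phenotype records: one row per (line, replicate) plot."""

    table: pd.DataFrame  # columns: line, replicate, value

    def __post_init__(self) -> None:
        required = ["line", "replicate", "value"]
        if list(self.table.columns[:3]) != required:
            raise ValueError(f"phenotype table must have columns {required}")
        if self.table["line"].isna().any() or self.table["value"].isna().any():
            raise ValueError("phenotype table contains missing line ids or values")
        counts = self.table.groupby("line").size()
        if (counts < 1).any():  # pragma: no cover - groupby cannot yield 0
            raise ValueError("every line needs at least one plot")

    @property
    def line_ids(self) -> np.ndarray:
        return self.table["line"].unique()

    @property
    def is_balanced(self) -> bool:
        return self.table.groupby("line").size().nunique() == 1

    def n_reps(self) -> pd.Series:
        return self.table.groupby("line").size()

    def line_means(self, order: Sequence[str] | None = None) -> pd.Series:
        """Per-line phenotype means (the ``y`` of the prediction model)."""
        means = self.table.groupby("line")["value"].mean()
        if order is not None:
            means = means.reindex(list(order))
            if means.isna().any():
                missing = means.index[means.isna()][0]
                raise ValueError(f"no phenotype records for line {missing!r}")
        return means


def _invert_dialect(dialect: Mapping[str, int]) -> dict[int, str]:
    # first symbol listed for a code wins on write
    inv: dict[int, str] = {}
    for symbol, code in dialect.items():
        inv.setdefault(code, symbol)
    for code in (0, 2, MISSING):
        if code not in inv:
            raise ValueError(f"dialect lacks a symbol for code {code}")
    return inv


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype={0: str})


def read_map(path: str | Path) -> GeneticMap:
    """Read a marker map from a CSV/TSV file with columns marker,chrom,cM,bp."""
    df = _read_table(path)
    required = ["marker", "chrom", "cM", "bp"]
    if not set(required).issubset(df.columns):
        raise MapError(f"map file must have columns {required}, got {list(df.columns)}")
    return GeneticMap(
        df["marker"].astype(str).to_numpy(dtype=object),
        df["chrom"].to_numpy(),
        df["cM"].to_numpy(dtype=float),
        df["bp"].to_numpy(),
    )


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.to_frame().to_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", index=False)


def read_genotypes(
    path: str | Path,
    gmap: GeneticMap,
    dialect: Mapping[str, int] = DEFAULT_DIALECT,
) -> GenotypeMatrix:
    """Read a genotype matrix and align its columns to the map's marker order.

    The file's first column holds line ids; the remaining column names must be
    exactly the map's marker ids (any order).  Cell symbols are translated via
    *dialect* (default A/B/NA ↔ 0/2/missing).
    """
    df = pd.read_csv(path, dtype=str)
    line_ids = df.iloc[:, 0].to_numpy(dtype=object)
    cols = list(df.columns[1:])
    if set(cols) != set(gmap.marker_ids):
        missing = sorted(set(map(str, gmap.marker_ids)) - set(cols))[:5]
        extra = sorted(set(cols) - set(map(str, gmap.marker_ids)))[:5]
        raise GenotypeError(
            f"genotype columns do not match map (missing {missing}, extra {extra})"
        )
    sym = df[list(map(str, gmap.marker_ids))].to_numpy(dtype=object)
    sym = np.where(pd.isna(sym), "NA", sym)
    codes = np.empty(sym.shape, dtype=np.int8)
    known = np.zeros(sym.shape, dtype=bool)
    for symbol, code in dialect.items():
        hit = sym == symbol
        codes[hit] = code
        known |= hit
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise GenotypeError(
            f"unknown genotype symbol {sym[i, j]!r} for line {line_ids[i]!r}, "
            f"marker {gmap.marker_ids[j]!r}"
        )
    return GenotypeMatrix(line_ids, gmap, codes)


def write_genotypes(
    geno: GenotypeMatrix,
    path: str | Path,
    dialect: Mapping[str, int] = DEFAULT_DIALECT,
) -> None:
    geno.to_frame(dialect).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PlotPhenotypes:
    df = _read_table(path)
    if not {"line", "replicate", "value"}.issubset(df.columns):
        raise ValueError("phenotype file must have columns line,replicate,value")
    return PlotPhenotypes(
        df[["line", "replicate", "value"]].assign(
            line=df["line"].astype(str),
            replicate=df["replicate"].astype(str),
            value=df["value"].astype(float),
        )
    )


def write_phenotypes(pheno: PlotPhenotypes, path: str | Path) -> None:
    pheno.table.to_csv(path, index=False)


def write_table(obj, path: str | Path) -> None:
    """Write any of the package's tabular result types to CSV.

    Column order is deterministic and round-trip safe.  Accepts
    :class:`GeneticMap`, :class:`GenotypeMatrix`, :class:`PlotPhenotypes`,
    a plain :class:`pandas.DataFrame`, or any object exposing ``to_frame()``
    (e.g. kinship matrices and accuracy tables from the analysis modules).
    """
    if isinstance(obj, GeneticMap):
        write_map(obj, path)
    elif isinstance(obj, GenotypeMatrix):
        write_genotypes(obj, path)
    elif isinstance(obj, PlotPhenotypes):
        write_phenotypes(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    elif hasattr(obj, "to_frame"):
        frame = obj.to_frame()
        index = bool(getattr(obj, "_write_index", False))
        frame.to_csv(path, index=index)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
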