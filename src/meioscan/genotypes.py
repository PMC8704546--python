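"""Genome, marker and genotype data model, plus readers/writers for the
standard formats the pipeline touches.

The central container is :class:`GenotypeMatrix`: an ordered grid of
parent-phased calls (parent-1 / parent-2 / missing) for every marker ×
haploid isolate.  Markers are ordered physically along chromosomes; an
optional genetic coordinate (cM) rides along as metadata for QTL scanning.

Coordinate conventions: positions are 1-based inclusive in the data model;
BED output converts to 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: integer call codes used throughout the package
P1: int = 0
P2: int = 1
MISSING: int = -1

#: default TSV call symbols for (P1, P2, MISSING)
DEFAULT_SYMBOLS: tuple[str, str, str] = ("a", "b", "-")


class GenotypeError(ValueError):
    """Raised for malformed genomes, genotype tables or call grids."""


@dataclass(frozen=True)
class ChromosomeDef:
    """A chromosome of the genome: a name and a physical length in bp."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GenotypeError(
                f"chromosome {self.name!r}: length must be positive, got {self.length}"
            )


def validate_genome(chromosomes: Sequence[ChromosomeDef]) -> list[ChromosomeDef]:
    """Check name uniqueness and return the chromosome list."""
    seen: set[str] = set()
    for c in chromosomes:
        if c.name in seen:
            raise GenotypeError(f"duplicate chromosome name {c.name!r}")
        seen.add(c.name)
    return list(chromosomes)


def genome_length(chromosomes: Sequence[ChromosomeDef]) -> int:
    return sum(c.length for c in chromosomes)


@dataclass(frozen=True)
class Marker:
    """A genotyped site: id, chromosome, physical bp and optional cM position."""

    id: str
    chromosome: str
    pos_bp: int
    pos_cM: float | None = None


@dataclass(frozen=True)
class CrossoverEvent:
    """A called crossover: the interval between the two flanking informative
    markers of adjacent, opposite-parent phase runs of one isolate."""

    isolate: str
    chromosome: str
    left_bp: int
    right_bp: int

    def __post_init__(self) -> None:
        if not self.left_bp < self.right_bp:
            raise GenotypeError(
                f"crossover interval must satisfy left<right, got "
                f"{self.left_bp}..{self.right_bp}"
            )

    @property
    def mid_bp(self) -> int:
        """Midpoint (floor) of the breakpoint interval; used for windowing."""
        return (self.left_bp + self.right_bp) // 2


class GenotypeMatrix:
    """Ordered parent-phased calls for markers × haploid isolates.

    Parameters
    ----------
    markers
        Markers sorted by (chromosome block, pos_bp); chromosomes may not
        interleave and positions must be strictly increasing within each
        chromosome.
    isolates
        Isolate IDs, one per call column.
    calls
        ``int8`` array of shape ``(n_markers, n_isolates)`` with values in
        ``{P1, P2, MISSING}``.
    genome
        Optional chromosome definitions; when given, marker coordinates are
        validated against chromosome lengths and chromosome order follows the
        genome rather than order of appearance.
    """

    def __init__(
        self,
        markers: Sequence[Marker],
        isolates: Sequence[str],
        calls: np.ndarray,
        genome: Sequence[ChromosomeDef] | None = None,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(markers), len(isolates)):
            raise GenotypeError(
                f"call grid shape {calls.shape} does not match "
                f"{len(markers)} markers x {len(isolates)} isolates"
            )
        bad = ~np.isin(calls, (P1, P2, MISSING))
        if bad.any():
            raise GenotypeError("call grid contains codes outside {P1, P2, MISSING}")
        if len(set(isolates)) != len(isolates):
            raise GenotypeError("duplicate isolate IDs")

        self.markers: list[Marker] = list(markers)
        self.isolates: list[str] = list(isolates)
        self.calls: np.ndarray = calls
        self.genome: list[ChromosomeDef] | None = (
            validate_genome(genome) if genome is not None else None
        )
        self._validate_marker_order()

    # -- validation ---------------------------------------------------------

    def _validate_marker_order(self) -> None:
        lengths = {c.name: c.length for c in self.genome} if self.genome else None
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_bp = 0
        prev_cm = -np.inf
        for m in self.markers:
            if lengths is not None and m.chromosome not in lengths:
                raise GenotypeError(f"marker {m.id!r}: unknown chromosome {m.chromosome!r}")
            if m.chromosome != prev_chrom:
                if m.chromosome in seen:
                    raise GenotypeError(
                        f"chromosome {m.chromosome!r} interleaved in marker order"
                    )
                seen.add(m.chromosome)
                prev_chrom = m.chromosome
                prev_bp = 0
                prev_cm = -np.inf
            if m.pos_bp <= prev_bp:
                raise GenotypeError(
                    f"marker {m.id!r}: position {m.pos_bp} not strictly increasing "
                    f"on {m.chromosome}"
                )
            if lengths is not None and not 1 <= m.pos_bp <= lengths[m.chromosome]:
                raise GenotypeError(
                    f"marker {m.id!r}: position {m.pos_bp} outside 1..{lengths[m.chromosome]}"
                )
            if m.pos_cM is not None:
                if m.pos_cM < prev_cm:
                    raise GenotypeError(
                        f"marker {m.id!r}: pos_cM decreases along {m.chromosome}"
                    )
                prev_cm = m.pos_cM
            prev_bp = m.pos_bp

    # -- views --------------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in matrix order (genome order when known)."""
        order: list[str] = []
        for m in self.markers:
            if not order or order[-1] != m.chromosome:
                order.append(m.chromosome)
        if self.genome is not None:
            present = set(order)
            return [c.name for c in self.genome if c.name in present]
        return order

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous marker-row slice for each chromosome."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_markers + 1):
            if i == self.n_markers or self.markers[i].chromosome != self.markers[start].chromosome:
                out[self.markers[start].chromosome] = slice(start, i)
                start = i
        return out

    def pos_bp(self) -> np.ndarray:
        return np.array([m.pos_bp for m in self.markers], dtype=np.int64)

    def pos_cM(self) -> np.ndarray | None:
        cm = [m.pos_cM for m in self.markers]
        if any(v is None for v in cm):
            return None
        return np.array(cm, dtype=float)

    def has_cM(self) -> bool:
        return self.pos_cM() is not None


# ---------------------------------------------------------------------------
# genome TSV


def read_genome(path: str | Path) -> list[ChromosomeDef]:
    """Read a two-column (name, length) TSV genome definition."""
    chroms: list[ChromosomeDef] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenotypeError(f"{path}:{lineno}: expected two tab-separated columns")
            name, length_s = parts[0], parts[1]
            try:
                length = int(length_s)
            except ValueError as exc:
                raise GenotypeError(f"{path}:{lineno}: length {length_s!r} not an integer") from exc
            if length <= 0:
                raise GenotypeError(f"{path}:{lineno}: chromosome {name!r} has non-positive length")
            chroms.append(ChromosomeDef(name, length))
    try:
        return validate_genome(chroms)
    except GenotypeError as exc:
        raise GenotypeError(f"{path}: {exc}") from exc


def write_genome(chromosomes: Sequence[ChromosomeDef], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for c in chromosomes:
            fh.write(f"{c.name}\t{c.length}\n")


# ---------------------------------------------------------------------------
# genotype TSV

_META_COLS = ("marker", "chrom", "pos_bp")


def read_genotype_table(
    path: str | Path,
    genome: Sequence[ChromosomeDef],
    symbols: tuple[str, str, str] = DEFAULT_SYMBOLS,
) -> GenotypeMatrix:
    """Read the genotype TSV: marker metadata columns then one call column
    per isolate with symbols (P1, P2, MISSING) = ``symbols``.

    Rows are sorted by (genome chromosome order, pos_bp); duplicate positions
    within a chromosome and unknown symbols or chromosomes are rejected with
    the offending line number.
    """
    genome = validate_genome(genome)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 4 or cols[:3] != list(_META_COLS):
        raise GenotypeError(
            f"{path}: header must start with {'/'.join(_META_COLS)}, got {cols[:3]}"
        )
    has_cm = len(cols) > 3 and cols[3] == "pos_cM"
    iso_start = 4 if has_cm else 3
    isolates = cols[iso_start:]
    if not isolates:
        raise GenotypeError(f"{path}: no isolate columns")

    chrom_order = {c.name: i for i, c in enumerate(genome)}
    sym_to_code = {symbols[0]: P1, symbols[1]: P2, symbols[2]: MISSING}

    # line numbers in the file: header is line 1
    df = df.assign(_line=np.arange(2, len(df) + 2))
    for _, row in df.iterrows():
        if row["chrom"] not in chrom_order:
            raise GenotypeError(
                f"{path}:{row['_line']}: unknown chromosome {row['chrom']!r}"
            )
    df["_corder"] = df["chrom"].map(chrom_order)
    df["_pos"] = df["pos_bp"].astype(np.int64)
    dup = df.duplicated(subset=["chrom", "_pos"], keep=False)
    if dup.any():
        line = int(df.loc[dup, "_line"].iloc[0])
        raise GenotypeError(f"{path}:{line}: duplicate position on {df.loc[dup, 'chrom'].iloc[0]}")
    df = df.sort_values(["_corder", "_pos"], kind="stable").reset_index(drop=True)

    calls = np.empty((len(df), len(isolates)), dtype=np.int8)
    for j, iso in enumerate(isolates):
        col = df[iso]
        for i, sym in enumerate(col):
            code = sym_to_code.get(sym)
            if code is None:
                raise GenotypeError(
                    f"{path}:{int(df['_line'].iloc[i])}: illegal call symbol {sym!r} "
                    f"for isolate {iso!r}"
                )
            calls[i, j] = code

    markers = [
        Marker(
            id=row["marker"],
            chromosome=row["chrom"],
            pos_bp=int(row["_pos"]),
            pos_cM=float(row["pos_cM"]) if has_cm else None,
        )
        for _, row in df.iterrows()
    ]
    return GenotypeMatrix(markers, isolates, calls, genome=genome)


def write_genotype_table(
    matrix: GenotypeMatrix,
    path: str | Path,
    symbols: tuple[str, str, str] = DEFAULT_SYMBOLS,
) -> None:
    """Write the genotype TSV (inverse of :func:`read_genotype_table`)."""
    code_to_sym = {P1: symbols[0], P2: symbols[1], MISSING: symbols[2]}
    has_cm = matrix.has_cM()
    with open(path, "wt", encoding="utf-8") as fh:
        header = ["marker", "chrom", "pos_bp"] + (["pos_cM"] if has_cm else []) + matrix.isolates
        fh.write("\t".join(header) + "\n")
        for i, m in enumerate(matrix.markers):
            row = [m.id, m.chromosome, str(m.pos_bp)]
            if has_cm:
                row.append(repr(float(m.pos_cM)))
            row.extend(code_to_sym[int(c)] for c in matrix.calls[i])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF (phased-by-parentage) import


def read_vcf_phased(
    path: str | Path,
    parent1: str,
    parent2: str,
    genome: Sequence[ChromosomeDef] | None = None,
) -> GenotypeMatrix:
    """Build a parent-phased matrix from a VCF with both parents and progeny.

    Only biallelic sites where the two parents carry fixed, different alleles
    are informative and retained.  A progeny call matching the parent-1 allele
    becomes P1, matching parent-2 becomes P2; heterozygous or no-call becomes
    MISSING.
    """
    from cyvcf2 import VCF  # deferred: optional input path

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for p in (parent1, parent2):
        if p not in samples:
            raise GenotypeError(f"sample {p!r} not found in {path}")
    i1, i2 = samples.index(parent1), samples.index(parent2)
    progeny_idx = [k for k, s in enumerate(samples) if s not in (parent1, parent2)]
    progeny = [samples[k] for k in progeny_idx]

    def sample_allele(gt_entry: list) -> int | None:
        """Allele index for a haploid or homozygous call; None if het/missing."""
        alleles = [a for a in gt_entry[:-1] if a is not None]
        if not alleles or any(a < 0 for a in alleles):
            return None
        if len(set(alleles)) != 1:
            return None
        return int(alleles[0])

    markers: list[Marker] = []
    rows: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gts = v.genotypes
        a1 = sample_allele(gts[i1])
        a2 = sample_allele(gts[i2])
        if a1 is None or a2 is None or a1 == a2:
            continue  # parents not fixed for different alleles
        row = np.full(len(progeny), MISSING, dtype=np.int8)
        for out_j, k in enumerate(progeny_idx):
            a = sample_allele(gts[k])
            if a == a1:
                row[out_j] = P1
            elif a == a2:
                row[out_j] = P2
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        markers.append(Marker(id=mid, chromosome=v.CHROM, pos_bp=int(v.POS)))
        rows.append(row)

    calls = np.vstack(rows) if rows else np.empty((0, len(progeny)), dtype=np.int8)
    return GenotypeMatrix(markers, progeny, calls, genome=genome)


# ---------------------------------------------------------------------------
# BED output

BED_HEADER = "#chrom\tstart\tend\tname"


def write_events_bed(events: Iterable[CrossoverEvent], path: str | Path) -> None:
    """Write crossover events as sorted BED4 intervals [left_bp-1, right_bp)."""
    recs = sorted(events, key=lambda e: (e.chromosome, e.left_bp, e.right_bp, e.isolate))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(BED_HEADER + "\n")
        for e in recs:
            fh.write(f"{e.chromosome}\t{e.left_bp - 1}\t{e.right_bp}\t{e.isolate}\n")


def read_events_bed(path: str | Path) -> list[CrossoverEvent]:
    """Read BED4 intervals written by :func:`write_events_bed`."""
    out: list[CrossoverEvent] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            out.append(
                CrossoverEvent(
                    isolate=name,
                    chromosome=chrom,
                    left_bp=int(start) + 1,
                    right_bp=int(end),
                )
            )
    return out
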