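"""Readers and writers for the tabular and tree formats the pipeline touches.

Coordinate convention: files use 1-based inclusive coordinates (the Ensembl
convention of the source assemblies); in memory everything is 0-based
half-open; writers restate 1-based inclusive.  All tables are TSV, UTF-8,
with ``#`` comment lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "GeneRecord",
    "GeneMap",
    "OrthologTable",
    "SignedGenome",
    "MapFormatError",
    "read_gene_map",
    "write_gene_map",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_arrangements",
    "write_arrangements",
    "read_species_tree",
    "marker_name",
    "marker_sign",
    "reverse_chromosome",
]


class MapFormatError(ValueError):
    """Raised on malformed or inconsistent input tables."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene on one chromosome, 0-based half-open internally."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"  # '+', '-' or 'unknown' (FISH gives no strand)
    segment_label: str | None = None  # painting segment, e.g. "C7"
    provenance: str = "current_study"  # or "previous"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise MapFormatError("empty gene_id")
        if not self.chromosome:
            raise MapFormatError(f"gene {self.gene_id}: empty chromosome")
        if not self.start < self.end:
            raise MapFormatError(
                f"gene {self.gene_id}: start must precede end "
                f"(got {self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise MapFormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneMap:
    """Ordered gene -> (chromosome, position) assignments for one species."""

    species: str
    records: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        seen: dict[str, GeneRecord] = {}
        for rec in self.records:
            if rec.gene_id in seen:
                raise MapFormatError(
                    f"duplicate gene {rec.gene_id!r}: "
                    f"{seen[rec.gene_id].chromosome}:{seen[rec.gene_id].start} "
                    f"and {rec.chromosome}:{rec.start}"
                )
            seen[rec.gene_id] = rec
        object.__setattr__(
            self,
            "records",
            tuple(sorted(self.records, key=lambda r: (r.chromosome, r.start, r.gene_id))),
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, gene_id: str) -> GeneRecord | None:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec
        return None

    @property
    def chromosomes(self) -> tuple[str, ...]:
        out: list[str] = []
        for rec in self.records:
            if not out or out[-1] != rec.chromosome:
                out.append(rec.chromosome)
        return tuple(dict.fromkeys(out))

    def on_chromosome(self, chromosome: str) -> tuple[GeneRecord, ...]:
        return tuple(r for r in self.records if r.chromosome == chromosome)


@dataclass(frozen=True)
class OrthologTable:
    """Per-gene positions in two genomes (species A and B).

    ``data`` columns: gene_id, chrom_a, start_a, end_a, chrom_b, start_b,
    end_b.  Missing species-B assignments are NaN/None (genes unplaced in
    the B assembly); block detection excludes them with a warning.
    """

    species_a: str
    species_b: str
    data: pd.DataFrame

    COLUMNS = ("gene_id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise MapFormatError(f"ortholog table missing columns: {missing}")
        if self.data["gene_id"].duplicated().any():
            dups = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"]
            raise MapFormatError(f"duplicate gene ids: {sorted(set(dups))}")
        bad = self.data.dropna(subset=["start_a"]).query("start_a >= end_a")
        if len(bad):
            raise MapFormatError(f"start >= end for genes {list(bad['gene_id'])}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class SignedGenome:
    """Chromosomes as ordered lists of signed markers.

    A marker is a plain string (e.g. ``C7`` or ``C1a``); a leading ``-``
    marks reverse orientation.  Each marker occurs at most once genome-wide.
    """

    species: str
    chromosomes: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            if not chrom:
                raise MapFormatError(f"{self.species}: empty chromosome")
            for m in chrom:
                name = marker_name(m)
                if not name:
                    raise MapFormatError(f"{self.species}: empty marker symbol")
                if name in seen:
                    raise MapFormatError(f"{self.species}: marker {name!r} repeated")
                seen.add(name)

    @property
    def markers(self) -> frozenset[str]:
        return frozenset(marker_name(m) for chrom in self.chromosomes for m in chrom)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)


def marker_name(signed: str) -> str:
    return signed[1:] if signed.startswith("-") else signed


def marker_sign(signed: str) -> int:
    return -1 if signed.startswith("-") else 1


def reverse_chromosome(chrom: Sequence[str]) -> tuple[str, ...]:
    """Reverse a chromosome's written order, flipping every marker sign."""
    out = []
    for m in reversed(chrom):
        out.append(marker_name(m) if m.startswith("-") else "-" + m)
    return tuple(out)


# ---------------------------------------------------------------------------
# gene maps
# ---------------------------------------------------------------------------

_GENE_MAP_ALIASES = {
    "gene": "gene_id",
    "gene_id": "gene_id",
    "chromosome": "chromosome",
    "chrom": "chromosome",
    "chr": "chromosome",
    "start": "start",
    "position": "start",
    "pos": "start",
    "end": "end",
    "strand": "strand",
    "segment": "segment_label",
    "segment_label": "segment_label",
    "provenance": "provenance",
}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_gene_map(path, species: str | None = None) -> GeneMap:
    """Read a TSV gene map (1-based inclusive coordinates) into a GeneMap.

    The header must name at least gene/chromosome/position columns; ``end``
    is optional (point assignments from FISH get a 1 bp interval).
    """
    path = Path(path)
    df = _read_tsv(path)
    cols = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _GENE_MAP_ALIASES:
            cols[_GENE_MAP_ALIASES[key]] = col
    for required in ("gene_id", "chromosome", "start"):
        if required not in cols:
            raise MapFormatError(f"{path}: no column for {required!r} in header {list(df.columns)}")
    records = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            start1 = int(row[cols["start"]])
            end1 = int(row[cols["end"]]) if "end" in cols and not pd.isna(row[cols["end"]]) else start1
        except (TypeError, ValueError) as exc:
            raise MapFormatError(f"{path}, line {line_no}: malformed coordinates ({exc})") from None
        try:
            records.append(
                GeneRecord(
                    gene_id=str(row[cols["gene_id"]]),
                    chromosome=str(row[cols["chromosome"]]),
                    start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=str(row[cols["strand"]]) if "strand" in cols and not pd.isna(row[cols["strand"]]) else "unknown",
                    segment_label=None
                    if "segment_label" not in cols or pd.isna(row[cols["segment_label"]])
                    else str(row[cols["segment_label"]]),
                    provenance=str(row[cols["provenance"]])
                    if "provenance" in cols and not pd.isna(row[cols["provenance"]])
                    else "current_study",
                )
            )
        except MapFormatError as exc:
            raise MapFormatError(f"{path}, line {line_no}: {exc}") from None
    return GeneMap(species=species or path.stem, records=tuple(records))


def write_gene_map(gene_map: GeneMap, path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "chromosome": r.chromosome,
            "start": r.start + 1,  # back to 1-based inclusive
            "end": r.end,
            "strand": r.strand,
            "segment_label": "" if r.segment_label is None else r.segment_label,
            "provenance": r.provenance,
        }
        for r in gene_map.records
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand", "segment_label", "provenance"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog tables
# ---------------------------------------------------------------------------

def read_ortholog_table(path, species_a: str = "A", species_b: str = "B") -> OrthologTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in OrthologTable.COLUMNS if c not in df.columns]
    if missing:
        raise MapFormatError(f"{path}: missing columns {missing}")
    df = df.copy()
    for col in ("start_a", "end_a", "start_b", "end_b"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # 1-based inclusive -> 0-based half-open
    df["start_a"] = df["start_a"] - 1
    df["start_b"] = df["start_b"] - 1
    return OrthologTable(species_a=species_a, species_b=species_b, data=df.reset_index(drop=True))


def write_ortholog_table(table: OrthologTable, path) -> None:
    df = table.data.copy()
    df["start_a"] = df["start_a"] + 1
    df["start_b"] = df["start_b"] + 1
    for col in ("start_a", "end_a", "start_b", "end_b"):
        df[col] = df[col].astype("Int64")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signed-genome arrangement files
# ---------------------------------------------------------------------------

def read_arrangements(path) -> list[SignedGenome]:
    """Read a segment-arrangement file: one line per chromosome.

    Format: ``species<TAB>chromosome<TAB>signed markers separated by spaces``.
    Lines starting with ``#`` are comments.  Chromosome order follows file
    order; species grouped by first appearance.
    """
    path = Path(path)
    per_species: dict[str, list[tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MapFormatError(f"{path}, line {line_no}: expected 3 tab-separated fields")
            species, _chrom, markers = parts
            chrom = tuple(markers.split())
            if not chrom:
                raise MapFormatError(f"{path}, line {line_no}: chromosome with no markers")
            per_species.setdefault(species, []).append(chrom)
    genomes = []
    for species, chroms in per_species.items():
        try:
            genomes.append(SignedGenome(species=species, chromosomes=tuple(chroms)))
        except MapFormatError as exc:
            raise MapFormatError(f"{path}: {exc}") from None
    return genomes


def write_arrangements(genomes: Iterable[SignedGenome], path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for g in genomes:
            for i, chrom in enumerate(g.chromosomes, start=1):
                fh.write(f"{g.species}\tchr{i}\t{' '.join(chrom)}\n")


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

def read_species_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick species tree (path or newick string)."""
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        tree = dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=str(source), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree
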