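"""Conserved synteny-block detection between two genomes.

A block is a maximal run of genes consecutive along species A (the species
whose assembly anchors the comparison) whose species-B chromosome is
constant.  Gene order *within* species B is deliberately not required to be
conserved: blocks built this way are considerably fewer and larger than
order-conserved blocks, which is what makes end-targeted FISH mapping
efficient.  Internal B-order monotonicity is recorded per block as
``order_conserved`` but never splits a block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import OrthologTable

__all__ = [
    "SyntenyBlock",
    "ProbeTarget",
    "detect_blocks",
    "summarize_blocks",
    "subtotal_blocks",
    "select_probe_targets",
]


@dataclass(frozen=True)
class SyntenyBlock:
    id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    genes: tuple[str, ...]
    order_conserved: bool

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("block with no genes")
        if self.start_a > self.end_a:
            raise ValueError(f"block {self.id}: start > end")

    @property
    def span_bp(self) -> int:
        return self.end_a - self.start_a

    @property
    def span_mb(self) -> float:
        return self.span_bp / 1e6


@dataclass(frozen=True)
class ProbeTarget:
    block_id: str
    gene_id: str
    role: str  # left_end | right_end | single


def detect_blocks(table: OrthologTable, min_span_kb: float = 100.0) -> list[SyntenyBlock]:
    """Detect conserved blocks as maximal constant-B-chromosome runs along A.

    Genes without a species-B assignment are excluded with a warning (they
    mirror genes unplaced in the B assembly).  Blocks whose species-A span
    falls below ``min_span_kb`` are discarded after run construction.
    """
    df = table.data
    unplaced = df[df["chrom_b"].isna() | df["start_b"].isna()]
    if len(unplaced):
        warnings.warn(
            f"{len(unplaced)} gene(s) without a {table.species_b} assignment "
            f"excluded from block detection: {sorted(unplaced['gene_id'])[:10]}",
            stacklevel=2,
        )
    df = df.dropna(subset=["chrom_b", "start_b"]).sort_values(
        ["chrom_a", "start_a", "gene_id"], kind="mergesort"
    )
    blocks: list[SyntenyBlock] = []
    run: list[pd.Series] = []

    def flush() -> None:
        if not run:
            return
        starts_b = [r["start_b"] for r in run]
        ascending = all(b >= a for a, b in zip(starts_b, starts_b[1:]))
        descending = all(b <= a for a, b in zip(starts_b, starts_b[1:]))
        blocks.append(
            SyntenyBlock(
                id=f"blk{len(blocks) + 1}",
                chrom_a=str(run[0]["chrom_a"]),
                start_a=int(min(r["start_a"] for r in run)),
                end_a=int(max(r["end_a"] for r in run)),
                chrom_b=str(run[0]["chrom_b"]),
                genes=tuple(r["gene_id"] for r in run),
                order_conserved=ascending or descending,
            )
        )
        run.clear()

    for _, row in df.iterrows():
        if run and (row["chrom_a"] != run[-1]["chrom_a"] or row["chrom_b"] != run[-1]["chrom_b"]):
            flush()
        run.append(row)
    flush()
    min_span_bp = min_span_kb * 1e3
    return [b for b in blocks if b.span_bp >= min_span_bp]


def summarize_blocks(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Per-chromosome block counts and span statistics, plus an Overall row.

    Mirrors the shape of a per-chromosome conserved-block table: columns
    chromosome, n_blocks, smallest_mb, largest_mb, mean_mb.  Spans are
    species-A megabases, reported to two decimals.
    """
    columns = ["chromosome", "n_blocks", "smallest_mb", "largest_mb", "mean_mb"]
    if not blocks:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(
        {"chromosome": [b.chrom_a for b in blocks], "span_mb": [b.span_mb for b in blocks]}
    )
    rows = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        rows.append(
            {
                "chromosome": chrom,
                "n_blocks": len(grp),
                "smallest_mb": round(grp["span_mb"].min(), 2),
                "largest_mb": round(grp["span_mb"].max(), 2),
                "mean_mb": round(grp["span_mb"].mean(), 2),
            }
        )
    rows.append(
        {
            "chromosome": "Overall",
            "n_blocks": len(df),
            "smallest_mb": round(df["span_mb"].min(), 2),
            "largest_mb": round(df["span_mb"].max(), 2),
            "mean_mb": round(df["span_mb"].mean(), 2),
        }
    )
    return pd.DataFrame(rows, columns=columns)


def subtotal_blocks(summary: pd.DataFrame, chromosomes: list[str]) -> int:
    """Block count summed over a chromosome subset of a block summary."""
    sub = summary[summary["chromosome"].isin(chromosomes)]
    return int(sub["n_blocks"].sum())


def select_probe_targets(
    blocks: list[SyntenyBlock],
    large_threshold_mb: float = 3.0,
    table: OrthologTable | None = None,
) -> list[ProbeTarget]:
    """Choose FISH probe target genes per block.

    Blocks spanning more than ``large_threshold_mb`` contribute the first and
    last gene along species A (both ends get a probe); smaller blocks (span
    <= threshold, the boundary case included) contribute the single gene
    nearest the block midpoint, ties broken toward the earlier gene along A.
    When the ortholog ``table`` is supplied the midpoint is the species-A
    coordinate midpoint; otherwise the ordinal midpoint of the gene run.
    """
    midpoints: dict[str, float] = {}
    if table is not None:
        for _, row in table.data.dropna(subset=["start_a"]).iterrows():
            midpoints[row["gene_id"]] = (row["start_a"] + row["end_a"]) / 2.0
    targets: list[ProbeTarget] = []
    for block in blocks:
        if block.span_mb > large_threshold_mb and len(block.genes) >= 2:
            targets.append(ProbeTarget(block.id, block.genes[0], "left_end"))
            targets.append(ProbeTarget(block.id, block.genes[-1], "right_end"))
        else:
            targets.append(ProbeTarget(block.id, _midpoint_gene(block, midpoints), "single"))
    return targets


def _midpoint_gene(block: SyntenyBlock, midpoints: dict[str, float]) -> str:
    if midpoints and all(g in midpoints for g in block.genes):
        centre = (block.start_a + block.end_a) / 2.0
        # min() is stable, so the earlier gene along A wins exact ties
        return min(block.genes, key=lambda g: abs(midpoints[g] - centre))
    n = len(block.genes)
    return block.genes[(n - 1) // 2]
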