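"""Oriented conserved-segment delineation between two gene maps.

Given two maps over a shared gene universe (orthology implied by identical
gene ids), a homology segment is a maximal run of genes consecutive in map
A whose images in map B are consecutive on a single B chromosome with a
consistent direction.  Consecutiveness in B is ordinal — defined on B's
gene-order ranks restricted to the shared universe — because FISH maps are
reliable in order but not in base-pair distance.  Segment labels from
cross-species chromosome painting (C1..C18, X) are then assigned by
majority vote, and boundaries between differently labelled neighbours are
emitted with an ambiguity status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .io import GeneMap

__all__ = [
    "HomologySegment",
    "BoundaryCall",
    "build_segments",
    "count_segments",
    "assign_painting",
]


@dataclass(frozen=True)
class HomologySegment:
    id: str
    chrom_a: str
    chrom_b: str
    genes: tuple[str, ...]
    orientation: str  # '+', '-', or 'unoriented' (singletons)
    painting_label: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("segment with no genes")
        if len(self.genes) == 1 and self.orientation != "unoriented":
            raise ValueError("singleton segments are unoriented")


@dataclass(frozen=True)
class BoundaryCall:
    chromosome: str
    left_gene: str
    right_gene: str
    left_label: str
    right_label: str
    status: str  # definitive | ambiguous

    def __post_init__(self) -> None:
        if self.left_label == self.right_label:
            raise ValueError("boundary between identical labels")


def build_segments(map_a: GeneMap, map_b: GeneMap) -> list[HomologySegment]:
    """Delineate oriented conserved segments between two gene maps.

    A direction change, B-chromosome change, or non-adjacency of B ranks
    starts a new segment; every shared gene lands in exactly one segment.
    Genes present in only one map are excluded with a warning.
    """
    ids_a = {r.gene_id for r in map_a.records}
    ids_b = {r.gene_id for r in map_b.records}
    shared = ids_a & ids_b
    only = sorted((ids_a | ids_b) - shared)
    if only:
        warnings.warn(f"{len(only)} gene(s) present in only one map excluded: {only[:10]}", stacklevel=2)

    # ordinal rank of each shared gene within its B chromosome
    rank_b: dict[str, tuple[str, int]] = {}
    for chrom in map_b.chromosomes:
        shared_run = [r for r in map_b.on_chromosome(chrom) if r.gene_id in shared]
        for i, rec in enumerate(shared_run):
            rank_b[rec.gene_id] = (chrom, i)

    segments: list[HomologySegment] = []

    def flush(run: list[str], chrom_a: str) -> None:
        if not run:
            return
        if len(run) == 1:
            orientation = "unoriented"
        else:
            orientation = "+" if rank_b[run[1]][1] > rank_b[run[0]][1] else "-"
        segments.append(
            HomologySegment(
                id=f"seg{len(segments) + 1}",
                chrom_a=chrom_a,
                chrom_b=rank_b[run[0]][0],
                genes=tuple(run),
                orientation=orientation,
            )
        )

    for chrom_a in map_a.chromosomes:
        run: list[str] = []
        direction = 0  # 0 undecided, +1 ascending, -1 descending
        for rec in map_a.on_chromosome(chrom_a):
            g = rec.gene_id
            if g not in shared:
                continue
            if not run:
                run = [g]
                direction = 0
                continue
            prev_chrom, prev_rank = rank_b[run[-1]]
            cur_chrom, cur_rank = rank_b[g]
            step = cur_rank - prev_rank
            extendable = cur_chrom == prev_chrom and abs(step) == 1 and (direction == 0 or step == direction)
            if extendable:
                run.append(g)
                direction = step
            else:
                flush(run, chrom_a)
                run = [g]
                direction = 0
        flush(run, chrom_a)
    return segments


def count_segments(segments: list[HomologySegment]) -> int:
    """Cardinality — exposed because the segment count is a headline statistic."""
    return len(segments)


def assign_painting(
    segments: list[HomologySegment],
    labels: dict[str, str],
    ambiguity_window: int = 3,
) -> tuple[list[HomologySegment], list[BoundaryCall]]:
    """Assign painting-segment labels and call boundaries between them.

    Each segment takes the majority label of its genes (ties broken
    lexicographically; genes labelled "unknown" abstain).  A boundary is
    emitted between A-adjacent segments with different labels.  It is
    ``ambiguous`` when either flanking segment contains minority-label genes
    or when two or more labels alternate within ``ambiguity_window`` genes
    of the junction; otherwise ``definitive``.
    """
    labelled: list[HomologySegment] = []
    impurity: list[bool] = []
    for seg in segments:
        votes: dict[str, int] = {}
        for g in seg.genes:
            lab = labels.get(g, "unknown")
            if lab != "unknown":
                votes[lab] = votes.get(lab, 0) + 1
        if votes:
            best = max(votes.values())
            label = min(l for l, v in votes.items() if v == best)
            impure = len(votes) > 1
        else:
            label, impure = None, False
        labelled.append(
            HomologySegment(
                id=seg.id,
                chrom_a=seg.chrom_a,
                chrom_b=seg.chrom_b,
                genes=seg.genes,
                orientation=seg.orientation,
                painting_label=label,
            )
        )
        impurity.append(impure)

    boundaries: list[BoundaryCall] = []
    for i in range(len(labelled) - 1):
        left, right = labelled[i], labelled[i + 1]
        if left.chrom_a != right.chrom_a:
            continue
        if left.painting_label is None or right.painting_label is None:
            continue
        if left.painting_label == right.painting_label:
            continue
        window = [
            labels.get(g, "unknown")
            for g in (left.genes[-ambiguity_window:] + right.genes[:ambiguity_window])
        ]
        window = [w for w in window if w != "unknown"]
        alternating = _n_label_switches(window) > 1
        status = "ambiguous" if (impurity[i] or impurity[i + 1] or alternating) else "definitive"
        boundaries.append(
            BoundaryCall(
                chromosome=left.chrom_a,
                left_gene=left.genes[-1],
                right_gene=right.genes[0],
                left_label=left.painting_label,
                right_label=right.painting_label,
                status=status,
            )
        )
    return labelled, boundaries


def _n_label_switches(window: list[str]) -> int:
    return sum(1 for a, b in zip(window, window[1:]) if a != b)
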