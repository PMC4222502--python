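"""Assembly and accounting of a species cytogenetic gene map.

Combines probe-localization results from the current round of FISH mapping
with previously published assignments, summarizes gene counts per
chromosome, flags genes whose observed chromosome contradicts the location
expected from a reference assembly, and groups genes lying closer than the
FISH resolution limit (~1 Mb on condensed metaphase chromosomes) into
order-uncertain runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .io import GeneMap, GeneRecord, MapFormatError

__all__ = [
    "Discrepancy",
    "DiscrepancyReport",
    "merge_maps",
    "summarize_map",
    "flag_discrepancies",
    "order_confidence",
]


@dataclass(frozen=True)
class Discrepancy:
    gene_id: str
    expected_chromosome: str
    observed_chromosome: str
    classification: str  # transposition_candidate | assembly_error_candidate

    def __post_init__(self) -> None:
        if self.expected_chromosome == self.observed_chromosome:
            raise ValueError(f"{self.gene_id}: expected == observed is not a discrepancy")


@dataclass(frozen=True)
class DiscrepancyReport:
    """Genes conflicting with expectation, plus genes resolving blank spots.

    ``discrepancies``: observed chromosome not homologous to the expected
    one.  ``novel_genes``: genes with no expected location at all — they fill
    regions where cross-species homology was previously unassigned.
    """

    discrepancies: tuple[Discrepancy, ...]
    novel_genes: tuple[str, ...]


def merge_maps(current: GeneMap, previous: GeneMap) -> GeneMap:
    """Union of a current-study map with previously published assignments.

    A gene present in both maps at the same location collapses to a single
    record credited to the earlier study; the same gene at two different
    locations is a hard conflict and raises.
    """
    if current.species != previous.species:
        raise MapFormatError(
            f"cannot merge maps for different species: {current.species!r} vs {previous.species!r}"
        )
    prev_by_id = {r.gene_id: r for r in previous.records}
    merged: list[GeneRecord] = []
    for rec in previous.records:
        merged.append(replace(rec, provenance="previous"))
    for rec in current.records:
        if rec.gene_id in prev_by_id:
            other = prev_by_id[rec.gene_id]
            if (rec.chromosome, rec.start, rec.end) != (other.chromosome, other.start, other.end):
                raise MapFormatError(
                    f"gene {rec.gene_id!r} assigned to two locations: "
                    f"{other.chromosome}:{other.start + 1}-{other.end} (previous) and "
                    f"{rec.chromosome}:{rec.start + 1}-{rec.end} (current)"
                )
            continue  # idempotent union; provenance stays "previous"
        merged.append(replace(rec, provenance="current_study"))
    return GeneMap(species=current.species, records=tuple(merged))


def summarize_map(gene_map: GeneMap, predicted_sizes: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-chromosome gene counts by provenance, plus a Total row.

    ``predicted_sizes`` (Mb per chromosome) are pass-through metadata from
    flow-sorting / assembly estimates, never computed here.
    """
    columns = ["chromosome", "predicted_size_mb", "n_current", "n_previous", "n_total"]
    sizes = predicted_sizes or {}
    counts: dict[str, dict[str, int]] = {}
    for rec in gene_map.records:
        entry = counts.setdefault(rec.chromosome, {"current_study": 0, "previous": 0})
        key = "previous" if rec.provenance == "previous" else "current_study"
        entry[key] += 1
    rows = []
    for chrom in sorted(counts, key=_chrom_sort_key):
        rows.append(
            {
                "chromosome": chrom,
                "predicted_size_mb": sizes.get(chrom, float("nan")),
                "n_current": counts[chrom]["current_study"],
                "n_previous": counts[chrom]["previous"],
                "n_total": counts[chrom]["current_study"] + counts[chrom]["previous"],
            }
        )
    total = {
        "chromosome": "Total",
        "predicted_size_mb": sum(sizes.values()) if sizes else float("nan"),
        "n_current": sum(r["n_current"] for r in rows),
        "n_previous": sum(r["n_previous"] for r in rows),
        "n_total": sum(r["n_total"] for r in rows),
    }
    rows.append(total)
    return pd.DataFrame(rows, columns=columns)


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def flag_discrepancies(
    observed: GeneMap,
    expected: GeneMap,
    homology: dict[str, set[str]],
) -> DiscrepancyReport:
    """Report genes whose observed chromosome contradicts the expected one.

    ``homology`` maps each expected-species chromosome to the (possibly
    several) observed-species chromosomes homologous to it.  A gene is a
    discrepancy when its observed chromosome is not among those.  The
    classification is advisory: when a discordant gene's nearest neighbours
    in the expected map are also discordant the whole region looks moved
    (transposition candidate); an isolated discordant gene more likely
    reflects a misplacement in the reference assembly.
    """
    expected_by_id = {r.gene_id: r for r in expected.records}
    discordant_ids: set[str] = set()
    novel: list[str] = []
    for rec in observed.records:
        exp = expected_by_id.get(rec.gene_id)
        if exp is None:
            novel.append(rec.gene_id)
            continue
        allowed = homology.get(exp.chromosome, set())
        if rec.chromosome not in allowed:
            discordant_ids.add(rec.gene_id)

    # neighbour context in the expected map for classification
    neighbours: dict[str, list[str]] = {}
    for chrom in expected.chromosomes:
        run = expected.on_chromosome(chrom)
        for i, rec in enumerate(run):
            ns = []
            if i > 0:
                ns.append(run[i - 1].gene_id)
            if i + 1 < len(run):
                ns.append(run[i + 1].gene_id)
            neighbours[rec.gene_id] = ns

    discrepancies = []
    for rec in observed.records:
        if rec.gene_id not in discordant_ids:
            continue
        exp = expected_by_id[rec.gene_id]
        neighbour_discordant = any(n in discordant_ids for n in neighbours.get(rec.gene_id, []))
        discrepancies.append(
            Discrepancy(
                gene_id=rec.gene_id,
                expected_chromosome=exp.chromosome,
                observed_chromosome=rec.chromosome,
                classification="transposition_candidate"
                if neighbour_discordant
                else "assembly_error_candidate",
            )
        )
    return DiscrepancyReport(discrepancies=tuple(discrepancies), novel_genes=tuple(novel))


def order_confidence(gene_map: GeneMap, resolution_mb: float = 1.0) -> list[tuple[str, ...]]:
    """Group genes into order-certain runs given the FISH resolution limit.

    Consecutive genes on one chromosome whose midpoints lie closer than
    ``resolution_mb`` are merged into one order-uncertain group (transitive
    closure of the below-resolution relation); groups never span
    chromosomes.  Returns gene-id groups in map order; singletons are
    order-certain.
    """
    resolution_bp = resolution_mb * 1e6
    groups: list[tuple[str, ...]] = []
    for chrom in gene_map.chromosomes:
        run = gene_map.on_chromosome(chrom)
        current = [run[0].gene_id]
        for prev, rec in zip(run, run[1:]):
            if abs(rec.midpoint - prev.midpoint) < resolution_bp:
                current.append(rec.gene_id)
            else:
                groups.append(tuple(current))
                current = [rec.gene_id]
        groups.append(tuple(current))
    return groups
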