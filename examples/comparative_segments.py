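"""Delineate oriented conserved segments between two gene maps.

Two 12-gene maps differing by one inversion fragment into three oriented
segments; painting labels are then assigned by majority vote and the
segment boundaries called definitive or ambiguous.
"""

import karyorec as kr
from karyorec.io import GeneMap, GeneRecord


def order_map(species, order):
    return GeneMap(species, tuple(
        GeneRecord(g, "1", i * 2_000_000, i * 2_000_000 + 1000) for i, g in enumerate(order)
    ))


genes = [f"g{i}" for i in range(12)]
map_a = order_map("wallaby_like", genes)
map_b = order_map("opossum_like", genes[:4] + genes[4:9][::-1] + genes[9:])

segments = kr.build_segments(map_a, map_b)
print(f"{kr.count_segments(segments)} conserved segments "
      "(one inversion splits a chromosome into three oriented runs):")
for s in segments:
    print(f"  {s.id}: {s.chrom_a} -> {s.chrom_b} [{s.orientation}] {' '.join(s.genes)}")

# painting labels: first half C8, second half C9, with one C9 gene
# sitting inside the C8 flank -> that boundary becomes ambiguous
labels = {g: ("C8" if i < 6 else "C9") for i, g in enumerate(genes)}
labels["g5"] = "C9"
labelled, boundaries = kr.assign_painting(segments, labels)
print("\nboundaries between painting segments:")
for b in boundaries:
    print(f"  {b.left_label}|{b.right_label} between {b.left_gene} and {b.right_gene}: {b.status}")
print("(minority-label genes on a flank downgrade a boundary to 'ambiguous')")
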