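"""Cytogenetic-map accounting and discrepancy flagging.

Summarizes the packaged wallaby-style gene map per chromosome by provenance
(newly mapped vs previously published), then shows how a gene observed on
an unexpected chromosome is flagged against a chromosome-homology table.
"""

import karyorec as kr
from karyorec import fixtures as fx
from karyorec.io import GeneMap, GeneRecord

gene_map, sizes = fx.wallaby_map_fixture()
summary = kr.summarize_map(gene_map, sizes)
print("wallaby map accounting (genes per chromosome by provenance):")
print(summary.to_string(index=False))
total = summary[summary["chromosome"] == "Total"].iloc[0]
print(f"\n{total['n_current']} genes newly assigned + {total['n_previous']} previous "
      f"= {total['n_total']} genes on the map")

# discrepancy demo: a gene expected (via opossum homology) on chromosome 3
# is observed on 2p - either a transposition or a reference-assembly error
observed = GeneMap("wallaby", (
    GeneRecord("AIP", "2p", 1_000_000, 1_001_000),
    GeneRecord("NEIGHBOUR", "3", 5_000_000, 5_001_000),
))
expected = GeneMap("opossum", (
    GeneRecord("AIP", "mdo5", 10_000_000, 10_001_000),
    GeneRecord("NEIGHBOUR", "mdo5", 11_000_000, 11_001_000),
))
report = kr.flag_discrepancies(observed, expected, {"mdo5": {"3"}})
print("\ndiscrepancies against the reference assembly:")
for d in report.discrepancies:
    print(f"  {d.gene_id}: expected on a chromosome homologous to {d.expected_chromosome}, "
          f"observed on {d.observed_chromosome} -> {d.classification}")
print("(an isolated discordant gene points at the assembly; a discordant",
      "neighbourhood points at a real transposition)")
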