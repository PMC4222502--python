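"""Map merging, accounting, discrepancy flagging and order confidence."""

import numpy as np
import pytest

from karyorec.cytomap import flag_discrepancies, merge_maps, order_confidence, summarize_map
from karyorec.io import GeneMap, GeneRecord, MapFormatError


def make_map(entries, species="wallaby", provenance="current_study"):
    records = tuple(
        GeneRecord(gene_id=g, chromosome=c, start=s, end=s + 1000, provenance=provenance)
        for g, c, s in entries
    )
    return GeneMap(species=species, records=records)


def random_map(rng, n_genes, n_chroms=4, species="wallaby", provenance="current_study"):
    entries = [
        (f"g{i}", str(1 + int(rng.integers(n_chroms))), int(rng.integers(0, 100_000_000)))
        for i in range(n_genes)
    ]
    return make_map(entries, species=species, provenance=provenance)


class TestMerge:
    def test_disjoint_union_keeps_provenance(self):
        current = make_map([(f"c{i}", "1", i * 10_000) for i in range(5)])
        previous = make_map([(f"p{i}", "2", i * 10_000) for i in range(3)], provenance="previous")
        merged = merge_maps(current, previous)
        assert len(merged) == 8
        assert {r.provenance for r in merged if r.gene_id.startswith("c")} == {"current_study"}
        assert {r.provenance for r in merged if r.gene_id.startswith("p")} == {"previous"}

    def test_empty_previous_is_identity(self):
        current = make_map([("a", "1", 0), ("b", "1", 5000)])
        merged = merge_maps(current, GeneMap(species="wallaby", records=()))
        assert [r.gene_id for r in merged] == ["a", "b"]

    def test_shared_gene_same_location_collapses_to_previous(self):
        current = make_map([("a", "1", 0)])
        previous = make_map([("a", "1", 0)], provenance="previous")
        merged = merge_maps(current, previous)
        assert len(merged) == 1 and merged.records[0].provenance == "previous"

    def test_conflicting_double_assignment_raises(self):
        current = make_map([("a", "1", 0)])
        previous = make_map([("a", "2", 5000)], provenance="previous")
        with pytest.raises(MapFormatError, match="two locations"):
            merge_maps(current, previous)

    def test_merge_order_insensitive_on_disjoint_maps(self):
        rng = np.random.default_rng(7)
        a = random_map(rng, 10)
        b = make_map([(f"x{i}", "3", i * 1000) for i in range(6)], provenance="previous")
        left = merge_maps(a, b)
        right_records = {r.gene_id for r in merge_maps(make_map([], species="wallaby"), b).records}
        assert {r.gene_id for r in left.records} == {r.gene_id for r in a.records} | right_records


class TestSummary:
    def test_totals_row_equals_column_sums_on_random_maps(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            cur = random_map(rng, int(rng.integers(5, 40)))
            prev = make_map(
                [(f"q{i}", str(1 + i % 3), i * 1000) for i in range(int(rng.integers(0, 20)))],
                provenance="previous",
            )
            s = summarize_map(merge_maps(cur, prev))
            body = s[s["chromosome"] != "Total"]
            total = s[s["chromosome"] == "Total"].iloc[0]
            for col in ("n_current", "n_previous", "n_total"):
                assert total[col] == body[col].sum()
            assert (body["n_total"] == body["n_current"] + body["n_previous"]).all()

    def test_empty_map_summary(self):
        s = summarize_map(GeneMap(species="x", records=()))
        assert s[s["chromosome"] == "Total"].iloc[0]["n_total"] == 0


class TestDiscrepancies:
    def test_relocated_gene_flagged(self):
        """A gene expected (via homology) on chr3 but observed on chr2p."""
        observed = make_map([("AIP", "2p", 0), ("NEAR", "3", 0)])
        expected = make_map([("AIP", "mdo5", 0), ("NEAR", "mdo5", 50_000_000)], species="opossum")
        homology = {"mdo5": {"3"}}
        report = flag_discrepancies(observed, expected, homology)
        assert [d.gene_id for d in report.discrepancies] == ["AIP"]
        d = report.discrepancies[0]
        assert (d.expected_chromosome, d.observed_chromosome) == ("mdo5", "2p")
        assert d.classification == "assembly_error_candidate"  # neighbours concordant

    def test_concordant_map_clean(self):
        observed = make_map([("a", "1", 0), ("b", "2", 0)])
        expected = make_map([("a", "m1", 0), ("b", "m2", 0)], species="opossum")
        report = flag_discrepancies(observed, expected, {"m1": {"1"}, "m2": {"2"}})
        assert report.discrepancies == () and report.novel_genes == ()

    def test_novel_genes_reported_separately(self):
        observed = make_map([("IGF2", "2p", 0)])
        expected = make_map([], species="opossum")
        report = flag_discrepancies(observed, expected, {})
        assert report.novel_genes == ("IGF2",)

    def test_planted_relocations_recovered_exactly(self):
        """100-gene concordant map with 5 planted moves -> exactly those 5."""
        rng = np.random.default_rng(42)
        n, chroms = 100, ["1", "2", "3", "4"]
        expected_entries = [(f"g{i}", f"m{chroms[i % 4]}", i * 1_000_000) for i in range(n)]
        homology = {f"m{c}": {c} for c in chroms}
        planted = sorted(rng.choice(n, size=5, replace=False))
        observed_entries = []
        for i in range(n):
            home = chroms[i % 4]
            if i in planted:
                home = chroms[(i + 1) % 4]  # move to a non-homologous chromosome
            observed_entries.append((f"g{i}", home, i * 1_000_000))
        report = flag_discrepancies(make_map(observed_entries), make_map(expected_entries, species="e"), homology)
        assert sorted(d.gene_id for d in report.discrepancies) == sorted(f"g{i}" for i in planted)

    def test_neighbour_discordance_gives_transposition_label(self):
        observed = make_map([("a", "9", 0), ("b", "9", 1_000_000), ("c", "1", 2_000_000)])
        expected = make_map([("a", "m1", 0), ("b", "m1", 10_000), ("c", "m1", 20_000)], species="e")
        report = flag_discrepancies(observed, expected, {"m1": {"1"}})
        by_gene = {d.gene_id: d.classification for d in report.discrepancies}
        assert by_gene == {"a": "transposition_candidate", "b": "transposition_candidate"}


class TestOrderConfidence:
    def test_below_resolution_groups(self):
        gm = make_map([(f"g{i}", "1", i * 500_000) for i in range(4)])
        assert order_confidence(gm, resolution_mb=1.0) == [("g0", "g1", "g2", "g3")]

    def test_well_separated_genes_are_singletons(self):
        gm = make_map([(f"g{i}", "1", i * 5_000_000) for i in range(4)])
        assert order_confidence(gm, resolution_mb=1.0) == [("g0",), ("g1",), ("g2",), ("g3",)]

    def test_groups_never_span_chromosomes(self):
        gm = make_map([("a", "1", 0), ("b", "2", 100)])
        assert order_confidence(gm, resolution_mb=1.0) == [("a",), ("b",)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.integers(0, 30_000_000, size=20))
        gm = make_map([(f"g{i}", "1", int(p)) for i, p in enumerate(positions)])
        groups = order_confidence(gm, resolution_mb=1.0)
        # oracle: transitive closure of the <1 Mb midpoint relation
        recs = sorted(gm.records, key=lambda r: r.start)
        oracle, current = [], [recs[0]]
        for prev, rec in zip(recs, recs[1:]):
            if abs(rec.midpoint - prev.midpoint) < 1e6:
                current.append(rec)
            else:
                oracle.append(tuple(r.gene_id for r in current))
                current = [rec]
        oracle.append(tuple(r.gene_id for r in current))
        assert groups == oracle
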