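"""Adjacency encoding, DCJ distance vs BFS, parsimony weights vs exhaustive
enumeration, CAR assembly structure, and the marsupial fixture."""

import itertools

import numpy as np
import pytest

import karyorec.fixtures as fx
from karyorec.io import SignedGenome, read_species_tree, reverse_chromosome
from karyorec.reconstruction import (
    HEAD,
    TAIL,
    adjacency_mpr_weights,
    assemble_cars,
    dcj_distance,
    diploid_number,
    genome_to_adjacencies,
    infer_events,
    internal_adjacencies,
    reconstruct_ancestor,
)
from conftest import (
    all_signed_genomes,
    bfs_dcj_distances,
    canonical_genome,
    exhaustive_mpr_states,
    random_signed_genome,
)


class TestAdjacencies:
    def test_chromosome_encoding(self):
        g = SignedGenome("dunnart", (("C10", "C12", "C11"),))
        internal = internal_adjacencies(g)
        assert internal == {
            frozenset({("C10", HEAD), ("C12", TAIL)}),
            frozenset({("C12", HEAD), ("C11", TAIL)}),
        }
        assert len(genome_to_adjacencies(g)) == 4  # 2 internal + 2 telomeric

    def test_single_marker_chromosome(self):
        g = SignedGenome("x", (("C7",),))
        adjs = genome_to_adjacencies(g)
        assert all(len(a) == 1 for a in adjs) and len(adjs) == 2

    def test_reversal_invariance_and_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = random_signed_genome(rng, int(rng.integers(2, 10)))
            flipped = SignedGenome(g.species, tuple(reverse_chromosome(c) for c in g.chromosomes))
            assert genome_to_adjacencies(g) == genome_to_adjacencies(flipped)
            n_internal = sum(len(c) - 1 for c in g.chromosomes)
            assert len(internal_adjacencies(g)) == n_internal


class TestDCJ:
    def test_identity_and_fission(self):
        a = SignedGenome("a", (("m1", "m2", "m3"),))
        b = SignedGenome("b", (("m1", "m2"), ("m3",)))
        assert dcj_distance(a, a) == 0
        assert dcj_distance(a, b) == 1

    def test_marker_mismatch_raises(self):
        a = SignedGenome("a", (("m1",),))
        b = SignedGenome("b", (("m2",),))
        with pytest.raises(ValueError, match="marker sets differ"):
            dcj_distance(a, b)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_all_pairs_match_bfs_oracle_small(self, n):
        """Every genome pair over <=3 markers matches BFS shortest path."""
        markers = tuple(f"m{i + 1}" for i in range(n))
        genomes = [SignedGenome("g", chroms) for chroms in all_signed_genomes(markers)]
        for ga in genomes:
            dist = bfs_dcj_distances(ga)
            for gb in genomes:
                key = genome_to_adjacencies(gb)
                assert dcj_distance(ga, gb) == dist[key]

    @pytest.mark.parametrize("n,seed", [(4, 0), (4, 1), (5, 2), (5, 3)])
    def test_source_to_all_matches_bfs_oracle(self, n, seed):
        """BFS sweep from a random source vs the formula for every genome."""
        rng = np.random.default_rng(seed)
        source = random_signed_genome(rng, n, species="src")
        dist = bfs_dcj_distances(source)
        markers = tuple(f"m{i + 1}" for i in range(n))
        for chroms in all_signed_genomes(markers):
            target = SignedGenome("t", chroms)
            assert dcj_distance(source, target) == dist[genome_to_adjacencies(target)]

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            a, b, c = (random_signed_genome(rng, n, species=s) for s in "abc")
            dab, dba = dcj_distance(a, b), dcj_distance(b, a)
            assert dab == dba  # symmetry
            assert dcj_distance(a, a) == 0
            assert dcj_distance(a, c) <= dab + dcj_distance(b, c)  # triangle

    def test_zero_iff_equal_up_to_order_and_reversal(self):
        a = SignedGenome("a", (("m1", "m2"), ("m3",)))
        b = SignedGenome("b", (("m3",), reverse_chromosome(("m1", "m2"))))
        assert dcj_distance(a, b) == 0
        c = SignedGenome("c", (("m2", "m1"), ("m3",)))
        assert dcj_distance(a, c) > 0


class TestParsimonyWeights:
    @pytest.mark.parametrize("seed", range(8))
    def test_mpr_weights_match_exhaustive_enumeration(self, seed):
        """4 ingroup leaves + outgroup over <=6 markers vs brute force."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        tree = read_species_tree("(((L1,L2)N1,(L3,L4)N2)Ingroup,Out)Root;")
        genomes = {
            name: random_signed_genome(rng, n, species=name)
            for name in ("L1", "L2", "L3", "L4", "Out")
        }
        weights = adjacency_mpr_weights(tree, genomes, "Ingroup", outgroup="Out")
        target = next(nd for nd in tree.preorder_node_iter() if nd.label == "Ingroup")
        adj_sets = {name: internal_adjacencies(g) for name, g in genomes.items()}
        for adj, weight in weights.items():
            leaf_states = {}
            for name, g in genomes.items():
                if any(m not in g.markers for m, _ in adj):
                    leaf_states[name] = {0, 1}
                else:
                    leaf_states[name] = {1} if adj in adj_sets[name] else {0}
            states = exhaustive_mpr_states(tree, leaf_states, target)
            if states == {1}:
                expected = 1.0
            elif states == {0, 1}:
                expected = 1.0 if adj in adj_sets["Out"] else 0.5
            else:
                expected = 0.0
            assert weight == expected, (adj, weight, expected)

    def test_identical_leaves_give_weight_one_everywhere(self):
        g = SignedGenome("template", (("C1", "C2"), ("C3",)))
        tree = read_species_tree("(((A,B)N1,C)N2,D)Root;")
        genomes = {s: SignedGenome(s, g.chromosomes) for s in "ABCD"}
        weights = adjacency_mpr_weights(tree, genomes, "N2", outgroup="D")
        assert set(weights.values()) == {1.0}


class TestCarAssembly:
    def test_structural_invariants_on_random_weight_sets(self):
        """No extremity reused, no cycles, CARs partition the markers."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            markers = {f"m{i + 1}" for i in range(n)}
            candidates = {}
            names = sorted(markers)
            for _k in range(n * 2):
                m1, m2 = rng.choice(names, size=2, replace=False)
                e1 = (str(m1), HEAD if rng.integers(2) else TAIL)
                e2 = (str(m2), HEAD if rng.integers(2) else TAIL)
                candidates[frozenset({e1, e2})] = float(rng.choice([0.5, 1.0]))
            k = assemble_cars(candidates, markers, node="anc", sex_markers=frozenset())
            flat = [m.lstrip("-") for car in k.cars for m in car]
            assert sorted(flat) == sorted(markers)  # partition
            used = [e for adj in k.weights for e in adj]
            assert len(used) == len(set(used))  # no extremity reused

    def test_cycle_closing_adjacency_skipped(self):
        adj = {
            frozenset({("a", HEAD), ("b", TAIL)}): 1.0,
            frozenset({("b", HEAD), ("a", TAIL)}): 1.0,  # would close a circle
        }
        k = assemble_cars(adj, {"a", "b"})
        assert k.n_cars == 1 and len(k.skipped_cycles) == 1

    def test_sex_marker_pregrouping(self):
        adj = {frozenset({("X", HEAD), ("m1", TAIL)}): 1.0}
        k = assemble_cars(adj, {"X", "m1"})
        assert k.n_cars == 2  # X never joined to an autosomal marker

    def test_tie_break_is_deterministic(self):
        adj = {
            frozenset({("a", HEAD), ("b", TAIL)}): 0.5,
            frozenset({("a", HEAD), ("c", TAIL)}): 0.5,
        }
        k1 = assemble_cars(dict(adj), {"a", "b", "c"})
        k2 = assemble_cars(dict(reversed(list(adj.items()))), {"a", "b", "c"})
        assert k1.cars == k2.cars


class TestReconstruction:
    def test_identical_leaves_return_that_genome(self):
        template = SignedGenome("t", (("C1", "C2", "C3"), ("C4",)))
        for newick in ("(((A,B)N1,C)N2,D)Root;", "((A,(B,C)N1)N2,D)Root;"):
            tree = read_species_tree(newick)
            genomes = [SignedGenome(s, template.chromosomes) for s in "ABCD"]
            k = reconstruct_ancestor(tree, genomes, "N2", outgroup="D", sex_markers=frozenset())
            assert canonical_genome(k.cars) == canonical_genome(template.chromosomes)

    def test_marsupial_fixture_gives_seven_cars_2n14(self):
        """The packaged segment arrangements with the chicken outgroup
        reconstruct the six-autosome-plus-X ancestral marsupial karyotype."""
        k = reconstruct_ancestor(
            fx.marsupial_tree(), fx.marsupial_genomes(), fx.MARSUPIAL_ROOT, outgroup=fx.OUTGROUP
        )
        assert k.n_cars == 7
        assert diploid_number(k) == 14
        cars = set(k.cars)
        assert ("C10", "C12", "C11") in cars  # the worked three-segment chromosome
        assert ("C2", "C1a", "C4a", "C3", "C1b", "C4b", "C5", "C6") in cars
        assert ("C8", "C7", "C9") in cars
        assert ("X",) in cars

    def test_missing_node_raises(self):
        tree = read_species_tree("((A,B)N1,C)Root;")
        genomes = [SignedGenome(s, (("m1",),)) for s in "ABC"]
        with pytest.raises(ValueError, match="nope"):
            reconstruct_ancestor(tree, genomes, "nope")


class TestEvents:
    def test_fission_reported_from_split_car(self):
        anc = assemble_cars(
            {
                frozenset({("C10", HEAD), ("C12", TAIL)}): 1.0,
                frozenset({("C12", HEAD), ("C11", TAIL)}): 1.0,
            },
            {"C10", "C11", "C12"},
            node="anc",
        )
        extant = SignedGenome("opossum_like", (("C10", "C12"), ("C11",)))
        ev = infer_events(anc, extant)
        assert ev.fissions == 1 and ev.fusions == 0
        assert ev.dcj_distance == 1 and ev.inversions_or_other == 0

    def test_equal_genomes_all_zero(self):
        anc = assemble_cars({frozenset({("a", HEAD), ("b", TAIL)}): 1.0}, {"a", "b"}, node="anc")
        ev = infer_events(anc, anc.as_genome("same"))
        assert (ev.dcj_distance, ev.fissions, ev.fusions, ev.inversions_or_other) == (0, 0, 0, 0)
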