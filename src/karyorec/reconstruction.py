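"""Ancestral karyotype reconstruction by adjacency parsimony.

Signed genomes are decomposed into adjacencies between marker extremities
(``head``/``tail``); each candidate adjacency observed in any extant genome
is treated as a binary presence/absence character and scored by
minimum-change parsimony on the species tree, with the outgroup breaking
ambiguity at the target node toward presence (the way chicken gene order
arbitrates between alternative marsupial arrangements).  Supported
adjacencies are then assembled greedily into contiguous ancestral regions
(CARs) — linear paths, never cycles — and the diploid number follows as
twice the CAR count.  Rearrangement distances between genomes use the
double-cut-and-join (DCJ) model, computed from the adjacency-graph
cycle/path decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .io import SignedGenome, marker_name, marker_sign, reverse_chromosome

__all__ = [
    "Extremity",
    "Adjacency",
    "AncestralKaryotype",
    "EventScenario",
    "genome_to_adjacencies",
    "internal_adjacencies",
    "adjacency_mpr_weights",
    "assemble_cars",
    "reconstruct_ancestor",
    "dcj_distance",
    "infer_events",
    "diploid_number",
]

HEAD = "h"
TAIL = "t"

#: an extremity is (marker, 'h'|'t'); an adjacency is a frozenset of one
#: extremity (telomeric) or two extremities (internal junction)
Extremity = tuple[str, str]
Adjacency = frozenset


def _extremities(signed: str) -> tuple[Extremity, Extremity]:
    """(leading, trailing) extremity of a signed marker read left to right."""
    name = marker_name(signed)
    if marker_sign(signed) > 0:
        return (name, TAIL), (name, HEAD)
    return (name, HEAD), (name, TAIL)


def genome_to_adjacencies(genome: SignedGenome) -> frozenset[Adjacency]:
    """Adjacency set of a signed genome.

    A chromosome of k markers yields k-1 internal adjacencies plus 2
    telomeric ones (modelled as singleton sets).  Reversing a chromosome's
    written order yields the identical set.
    """
    adjacencies: set[Adjacency] = set()
    for chrom in genome.chromosomes:
        first_lead, prev_trail = _extremities(chrom[0])
        adjacencies.add(frozenset({first_lead}))
        for signed in chrom[1:]:
            lead, trail = _extremities(signed)
            adjacencies.add(frozenset({prev_trail, lead}))
            prev_trail = trail
        adjacencies.add(frozenset({prev_trail}))
    return frozenset(adjacencies)


def internal_adjacencies(genome: SignedGenome) -> frozenset[Adjacency]:
    """Marker-marker adjacencies only (telomeric singletons dropped)."""
    return frozenset(a for a in genome_to_adjacencies(genome) if len(a) == 2)


# ---------------------------------------------------------------------------
# parsimony scoring of adjacency presence/absence
# ---------------------------------------------------------------------------

def _mpr_state_set(
    tree: dendropy.Tree,
    leaf_states: dict[str, set[int]],
    target: dendropy.Node,
) -> set[int]:
    """States at ``target`` attained by some minimum-change labelling.

    Exact most-parsimonious-reconstruction state set for a binary character
    under unit change costs, via subtree/rest-of-tree cost messages
    (equivalent to exhaustively enumerating internal labelings).  Leaves
    with both states allowed (missing data) cost nothing either way.
    """
    BIG = 10**9

    down: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            allowed = leaf_states[node.taxon.label]
            down[node] = [0 if s in allowed else BIG for s in (0, 1)]
        else:
            costs = [0, 0]
            for child in node.child_nodes():
                for s in (0, 1):
                    costs[s] += min(down[child][s], down[child][1 - s] + 1)
            down[node] = costs

    up: dict[dendropy.Node, list[int]] = {tree.seed_node: [0, 0]}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        sib_costs = [0, 0]
        for sib in parent.child_nodes():
            if sib is node:
                continue
            for s in (0, 1):
                sib_costs[s] += min(down[sib][s], down[sib][1 - s] + 1)
        up[node] = [
            min(up[parent][sp] + (1 if sp != s else 0) + sib_costs[sp] for sp in (0, 1))
            for s in (0, 1)
        ]

    totals = [down[target][s] + up[target][s] for s in (0, 1)]
    best = min(totals)
    return {s for s in (0, 1) if totals[s] == best}


def adjacency_mpr_weights(
    tree: dendropy.Tree,
    genomes: dict[str, SignedGenome],
    node_label: str,
    outgroup: str | None = None,
) -> dict[Adjacency, float]:
    """Support weight in [0, 1] for every candidate internal adjacency.

    Candidates are the union of internal adjacencies over all genomes,
    restricted to markers seen in at least one ingroup (non-outgroup)
    genome.  Per adjacency: unambiguously present at the target node ->
    1.0; ambiguous but present in the outgroup genome -> 1.0 (outgroup
    arbitration); otherwise ambiguous -> 0.5; unambiguously absent -> 0.0.
    A leaf whose genome lacks either marker of the adjacency contributes no
    evidence (missing data).
    """
    target = _find_node(tree, node_label)
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(genomes) - leaf_labels
    if missing:
        raise ValueError(f"genomes with no matching tree leaf: {sorted(missing)}")

    ingroup_markers: set[str] = set()
    for name, g in genomes.items():
        if name != outgroup:
            ingroup_markers |= g.markers

    adjacency_sets = {name: internal_adjacencies(g) for name, g in genomes.items()}
    marker_sets = {name: g.markers for name, g in genomes.items()}
    candidates: set[Adjacency] = set()
    for adjs in adjacency_sets.values():
        for adj in adjs:
            if all(m in ingroup_markers for m, _ in adj):
                candidates.add(adj)

    weights: dict[Adjacency, float] = {}
    for adj in sorted(candidates, key=_adjacency_sort_key):
        leaf_states: dict[str, set[int]] = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            if label not in genomes:
                leaf_states[label] = {0, 1}  # no genome: missing data
                continue
            if any(m not in marker_sets[label] for m, _ in adj):
                leaf_states[label] = {0, 1}  # marker absent: no evidence
            elif adj in adjacency_sets[label]:
                leaf_states[label] = {1}
            else:
                leaf_states[label] = {0}
        states = _mpr_state_set(tree, leaf_states, target)
        if states == {1}:
            weights[adj] = 1.0
        elif states == {0, 1}:
            if outgroup is not None and adj in adjacency_sets.get(outgroup, frozenset()):
                weights[adj] = 1.0
            else:
                weights[adj] = 0.5
        else:
            weights[adj] = 0.0
    return weights


def _find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node.label == label or (node.taxon is not None and node.taxon.label == label):
            return node
    raise ValueError(f"node {label!r} not found in tree")


def _adjacency_sort_key(adj: Adjacency):
    return tuple(sorted(adj))


# ---------------------------------------------------------------------------
# CAR assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralKaryotype:
    """A set of CARs with per-adjacency support weights."""

    node: str
    cars: tuple[tuple[str, ...], ...]  # ordered signed-marker lists
    weights: dict  # Adjacency -> weight actually used
    skipped_cycles: tuple = ()

    @property
    def n_cars(self) -> int:
        return len(self.cars)

    @property
    def markers(self) -> frozenset[str]:
        return frozenset(marker_name(m) for car in self.cars for m in car)

    def as_genome(self, species: str | None = None) -> SignedGenome:
        return SignedGenome(species=species or self.node, chromosomes=self.cars)


def assemble_cars(
    weights: dict[Adjacency, float],
    markers: set[str],
    node: str = "ancestor",
    sex_markers: frozenset[str] = frozenset({"X"}),
) -> AncestralKaryotype:
    """Greedy CAR assembly from weighted adjacencies.

    Adjacencies are taken in (weight desc, lexicographic extremity pair asc)
    order; one is accepted iff both extremities are free and acceptance does
    not close a cycle (chromosomes are linear).  Zero-weight adjacencies are
    never used.  Sex-linked markers are hard pre-grouped: an adjacency
    joining a sex marker to an autosomal one is rejected, keeping the X a
    single unit.
    """
    parent: dict[str, str] = {m: m for m in markers}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used_extremity: set[Extremity] = set()
    neighbour: dict[Extremity, Extremity] = {}
    accepted: dict[Adjacency, float] = {}
    skipped: list[Adjacency] = []

    order = sorted(weights.items(), key=lambda kv: (-kv[1], _adjacency_sort_key(kv[0])))
    for adj, weight in order:
        if weight <= 0 or len(adj) != 2:
            continue
        (m1, _e1), (m2, _e2) = sorted(adj)
        if m1 not in markers or m2 not in markers:
            continue
        if (m1 in sex_markers) != (m2 in sex_markers):
            continue  # X pre-grouping: never join sex and autosomal markers
        ext1, ext2 = sorted(adj)
        if ext1 in used_extremity or ext2 in used_extremity:
            continue
        if find(m1) == find(m2):
            skipped.append(adj)  # would close a circular CAR
            continue
        parent[find(m1)] = find(m2)
        used_extremity.update((ext1, ext2))
        neighbour[ext1] = ext2
        neighbour[ext2] = ext1
        accepted[adj] = weight

    cars = _paths_to_cars(markers, neighbour)
    return AncestralKaryotype(node=node, cars=cars, weights=accepted, skipped_cycles=tuple(skipped))


def _paths_to_cars(markers: set[str], neighbour: dict[Extremity, Extremity]) -> tuple[tuple[str, ...], ...]:
    """Turn the accepted adjacency paths into ordered signed marker lists."""
    visited: set[str] = set()
    cars: list[tuple[str, ...]] = []
    # start each walk at a marker with a free extremity (path endpoint)
    endpoints = sorted(
        m for m in markers if (m, TAIL) not in neighbour or (m, HEAD) not in neighbour
    )
    for start in endpoints:
        if start in visited:
            continue
        # enter at the free extremity; prefer tail so isolated markers are '+'
        entry = (start, TAIL) if (start, TAIL) not in neighbour else (start, HEAD)
        car: list[str] = []
        m, ext = start, entry
        while True:
            visited.add(m)
            car.append(m if ext == (m, TAIL) else "-" + m)
            exit_ext = (m, HEAD) if ext == (m, TAIL) else (m, TAIL)
            nxt = neighbour.get(exit_ext)
            if nxt is None:
                break
            m, ext = nxt[0], nxt
        cars.append(_canonical_car(car))
    return tuple(sorted(cars))


def _canonical_car(car: list[str]) -> tuple[str, ...]:
    forward = tuple(car)
    backward = reverse_chromosome(car)
    # deterministic orientation: mostly-forward reading, then lexicographic
    key = lambda c: (sum(m.startswith("-") for m in c), c)
    return min(forward, backward, key=key)


def reconstruct_ancestor(
    tree: dendropy.Tree,
    genomes: list[SignedGenome],
    node: str,
    outgroup: str | None = None,
    sex_markers: frozenset[str] = frozenset({"X"}),
) -> AncestralKaryotype:
    """Reconstruct the karyotype at an internal tree node.

    Pipeline: candidate adjacencies from the union of extant genomes ->
    minimum-change parsimony weight per adjacency with outgroup arbitration
    -> greedy linear CAR assembly.  Markers are the union over ingroup
    genomes; a genome lacking a marker contributes no evidence about it.
    """
    by_name = {g.species: g for g in genomes}
    if len(by_name) != len(genomes):
        raise ValueError("duplicate species among genomes")
    weights = adjacency_mpr_weights(tree, by_name, node, outgroup=outgroup)
    markers: set[str] = set()
    for name, g in by_name.items():
        if name != outgroup:
            markers |= g.markers
    return assemble_cars(weights, markers, node=node, sex_markers=sex_markers)


def diploid_number(karyotype: AncestralKaryotype) -> int:
    """2 x CAR count: each CAR is one chromosome pair (the X counts once as
    a CAR, encoding the sex pair)."""
    return 2 * karyotype.n_cars


# ---------------------------------------------------------------------------
# DCJ distance and event scenarios
# ---------------------------------------------------------------------------

def dcj_distance(a: SignedGenome, b: SignedGenome) -> int:
    """Minimal double-cut-and-join operations transforming ``a`` into ``b``.

    Computed from the adjacency-graph decomposition: d = N - C - I/2 where
    N is the marker count, C the number of cycles and I the number of
    odd-length paths.  Symmetric; zero iff the genomes are equal up to
    chromosome order and whole-chromosome reversal.
    """
    if a.markers != b.markers:
        raise ValueError(
            f"marker sets differ: only in {a.species}: {sorted(a.markers - b.markers)}, "
            f"only in {b.species}: {sorted(b.markers - a.markers)}"
        )
    n = len(a.markers)
    adj_a = genome_to_adjacencies(a)
    adj_b = genome_to_adjacencies(b)

    # map extremity -> containing adjacency per genome
    where_a: dict[Extremity, Adjacency] = {}
    for adj in adj_a:
        for ext in adj:
            where_a[ext] = adj
    where_b: dict[Extremity, Adjacency] = {}
    for adj in adj_b:
        for ext in adj:
            where_b[ext] = adj

    # walk components of the adjacency graph (vertices: adjacencies of a and
    # b; edges: shared extremities); each component is a cycle or a path
    seen: set[tuple[str, Adjacency]] = set()
    cycles = 0
    odd_paths = 0
    for start in sorted(adj_a | adj_b, key=_adjacency_sort_key):
        for side0 in ("a", "b"):
            if (start not in (adj_a if side0 == "a" else adj_b)) or ((side0, start) in seen):
                continue
            component: list[tuple[str, Adjacency]] = []
            stack = [(side0, start)]
            while stack:
                side, adj = stack.pop()
                if (side, adj) in seen:
                    continue
                seen.add((side, adj))
                component.append((side, adj))
                other = where_b if side == "a" else where_a
                other_side = "b" if side == "a" else "a"
                for ext in adj:
                    stack.append((other_side, other[ext]))
            # every extremity of an a-side vertex is one edge of the component
            n_edges = sum(len(adj) for side, adj in component if side == "a")
            n_vertices = len(component)
            if n_edges == n_vertices:  # as many edges as vertices: cycle
                cycles += 1
            else:  # path: vertices = edges + 1
                if n_edges % 2 == 1:
                    odd_paths += 1
    assert odd_paths % 2 == 0
    return n - cycles - odd_paths // 2


@dataclass(frozen=True)
class EventScenario:
    source: str
    target: str
    dcj_distance: int
    net_chromosome_change: int
    fusions: int
    fissions: int
    inversions_or_other: int
    narrative: str = ""

    def __post_init__(self) -> None:
        if self.dcj_distance < abs(self.net_chromosome_change):
            raise ValueError("DCJ distance below net chromosome change")
        if min(self.fusions, self.fissions, self.inversions_or_other) < 0:
            raise ValueError("negative event count")


def infer_events(ancestor: AncestralKaryotype, extant: SignedGenome) -> EventScenario:
    """Minimal event accounting from an ancestral karyotype to an extant genome.

    Net chromosome-number change fixes the fission/fusion balance; the
    remaining DCJ operations are inversions or other intrachromosomal
    rearrangements.
    """
    anc = ancestor.as_genome()
    d = dcj_distance(anc, extant)
    net = extant.n_chromosomes - ancestor.n_cars
    fissions = max(0, net)
    fusions = max(0, -net)
    other = d - fissions - fusions
    narrative = (
        f"{ancestor.node} -> {extant.species}: {d} DCJ operation(s); "
        f"{fissions} fission(s), {fusions} fusion(s), "
        f"{other} inversion(s) or other intrachromosomal event(s)"
    )
    return EventScenario(
        source=ancestor.node,
        target=extant.species,
        dcj_distance=d,
        net_chromosome_change=net,
        fusions=fusions,
        fissions=fissions,
        inversions_or_other=other,
        narrative=narrative,
    )
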