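"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately take the dumbest correct route (exhaustive
enumeration, breadth-first search, brute-force scans) so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hsettings

from karyorec.io import OrthologTable, SignedGenome, reverse_chromosome

_hsettings.register_profile("repro", derandomize=True, deadline=None)
_hsettings.load_profile("repro")


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------

def random_signed_genome(rng: np.random.Generator, n_markers: int, species: str = "g") -> SignedGenome:
    """Random partition of n signed markers into linear chromosomes."""
    markers = [f"m{i + 1}" for i in range(n_markers)]
    rng.shuffle(markers)
    signed = [m if rng.integers(2) else f"-{m}" for m in markers]
    n_chroms = int(rng.integers(1, n_markers + 1))
    cuts = sorted(rng.choice(np.arange(1, n_markers), size=n_chroms - 1, replace=False)) if n_chroms > 1 else []
    chroms, prev = [], 0
    for cut in list(cuts) + [n_markers]:
        chroms.append(tuple(signed[prev:cut]))
        prev = cut
    return SignedGenome(species=species, chromosomes=tuple(chroms))


def random_ortholog_table(rng: np.random.Generator, n_genes: int) -> OrthologTable:
    """Random two-species gene position table with clustered B chromosomes."""
    rows = []
    pos_b: dict[str, int] = {}
    for i in range(n_genes):
        chrom_a = f"A{rng.integers(1, 4)}"
        chrom_b = f"B{rng.integers(1, 4)}"
        start_a = int(rng.integers(0, 5_000_000))
        start_b = pos_b.get(chrom_b, 0) + int(rng.integers(1, 500_000))
        pos_b[chrom_b] = start_b
        rows.append(
            {
                "gene_id": f"g{i + 1}",
                "chrom_a": chrom_a,
                "start_a": start_a,
                "end_a": start_a + int(rng.integers(1_000, 50_000)),
                "chrom_b": chrom_b,
                "start_b": start_b,
                "end_b": start_b + 10_000,
            }
        )
    df = pd.DataFrame(rows, columns=list(OrthologTable.COLUMNS))
    return OrthologTable(species_a="A", species_b="B", data=df)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_blocks(table: OrthologTable) -> list[tuple[str, tuple[str, ...]]]:
    """All maximal constant-B-chromosome runs along species A.

    Returns (chrom_b, gene tuple) per run, built by checking every candidate
    interval of the A-sorted gene list rather than by a linear scan.
    """
    df = (
        table.data.dropna(subset=["chrom_b", "start_b"])
        .sort_values(["chrom_a", "start_a", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    n = len(df)

    def valid(i: int, j: int) -> bool:  # inclusive interval [i, j]
        sub = df.iloc[i : j + 1]
        return sub["chrom_a"].nunique() == 1 and sub["chrom_b"].nunique() == 1

    runs = []
    for i in range(n):
        for j in range(i, n):
            if not valid(i, j):
                continue
            if i > 0 and valid(i - 1, j):
                continue
            if j < n - 1 and valid(i, j + 1):
                continue
            runs.append((str(df.iloc[i]["chrom_b"]), tuple(df.iloc[i : j + 1]["gene_id"])))
    return runs


def brute_force_segments(order_a: list[str], rank_b: dict[str, tuple[str, int]]) -> list[tuple[str, ...]]:
    """All maximal A-intervals whose B images are consecutive, one-directional."""

    def valid(i: int, j: int) -> bool:
        genes = order_a[i : j + 1]
        chroms = {rank_b[g][0] for g in genes}
        if len(chroms) != 1:
            return False
        ranks = [rank_b[g][1] for g in genes]
        steps = [b - a for a, b in zip(ranks, ranks[1:])]
        return all(s == 1 for s in steps) or all(s == -1 for s in steps) or not steps

    n = len(order_a)
    out = []
    for i in range(n):
        for j in range(i, n):
            if not valid(i, j):
                continue
            if i > 0 and valid(i - 1, j):
                continue
            if j < n - 1 and valid(i, j + 1):
                continue
            out.append(tuple(order_a[i : j + 1]))
    return out


def canonical_genome(chromosomes) -> frozenset:
    """Genome identity up to chromosome order and whole-chromosome reversal."""
    return frozenset(min(tuple(ch), reverse_chromosome(ch)) for ch in chromosomes)


def all_signed_genomes(markers: tuple[str, ...]):
    """Every linear signed genome over the markers, canonicalized (no dups)."""
    seen = set()
    n = len(markers)
    for perm in itertools.permutations(markers):
        for signs in itertools.product((1, -1), repeat=n):
            signed = tuple(m if s > 0 else f"-{m}" for m, s in zip(perm, signs))
            for split_mask in range(2 ** (n - 1)) if n > 1 else [0]:
                chroms, current = [], [signed[0]]
                for k in range(1, n):
                    if split_mask >> (k - 1) & 1:
                        chroms.append(tuple(current))
                        current = [signed[k]]
                    else:
                        current.append(signed[k])
                chroms.append(tuple(current))
                canon = canonical_genome(chroms)
                if canon not in seen:
                    seen.add(canon)
                    yield tuple(sorted(canon))


def bfs_dcj_distances(source: SignedGenome) -> dict[frozenset, int]:
    """Single-source BFS over DCJ moves; distance to every reachable genome.

    States are adjacency sets (telomeres as singletons); neighbours come
    from every way of cutting one or two adjacencies and rejoining.
    """
    from karyorec.reconstruction import genome_to_adjacencies

    start = genome_to_adjacencies(source)
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for state in frontier:
            for neighbour in _dcj_neighbours(state):
                if neighbour not in dist:
                    dist[neighbour] = dist[state] + 1
                    nxt.append(neighbour)
        frontier = nxt
    return dist


def _dcj_neighbours(state: frozenset):
    adjacencies = sorted(state, key=lambda a: tuple(sorted(a)))
    for idx1 in range(len(adjacencies)):
        p = adjacencies[idx1]
        # cut one internal adjacency into two telomeres
        if len(p) == 2:
            e1, e2 = sorted(p)
            yield (state - {p}) | {frozenset({e1}), frozenset({e2})}
        for idx2 in range(idx1 + 1, len(adjacencies)):
            q = adjacencies[idx2]
            exts = sorted(p | q)
            if len(p) == 1 and len(q) == 1:
                # join two telomeres
                yield (state - {p, q}) | {frozenset(exts)}
                continue
            # general DCJ: repartition the extremities of p and q
            for group in _repartitions(tuple(sorted(p)), tuple(sorted(q))):
                yield (state - {p, q}) | group


def _repartitions(p: tuple, q: tuple):
    if len(p) == 2 and len(q) == 2:
        a, b = p
        c, d = q
        yield frozenset({frozenset({a, c}), frozenset({b, d})})
        yield frozenset({frozenset({a, d}), frozenset({b, c})})
    elif len(p) == 2 and len(q) == 1:
        a, b = p
        (c,) = q
        yield frozenset({frozenset({a, c}), frozenset({b})})
        yield frozenset({frozenset({b, c}), frozenset({a})})
    elif len(p) == 1 and len(q) == 2:
        yield from _repartitions(q, p)


def exhaustive_mpr_states(tree, leaf_states: dict[str, set[int]], target) -> set[int]:
    """Minimum-change state set at ``target`` by enumerating all labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    best_cost = None
    best_states: set[int] = set()
    leaf_options = [sorted(leaf_states[l.taxon.label]) for l in leaves]
    for internal_combo in itertools.product((0, 1), repeat=len(internals)):
        assignment = dict(zip(internals, internal_combo))
        # choose each leaf state greedily: with <=2 options just enumerate
        for leaf_combo in itertools.product(*leaf_options):
            assignment.update(dict(zip(leaves, leaf_combo)))
            cost = 0
            for node in tree.preorder_node_iter():
                if node.parent_node is not None and assignment[node] != assignment[node.parent_node]:
                    cost += 1
            if best_cost is None or cost < best_cost:
                best_cost = cost
                best_states = {assignment[target]}
            elif cost == best_cost:
                best_states.add(assignment[target])
    return best_states
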