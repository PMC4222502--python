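"""Signed-genome evolution simulator along a species tree.

Evolves an ancestral signed genome down a tree under inversion / fission /
fusion / translocation, logging every event so any node genome can be
replayed exactly.  Event counts per branch are Poisson in the branch length
(optionally truncated); event types are drawn from a configurable mix,
renormalized when a type is impossible in the current state (fusion with
one chromosome left, fission of single-marker chromosomes).  Per-branch
random substreams are derived by stable hashing of node labels, so tree
traversal order cannot change results.

The simulator also expands marker-level genomes into gene-level ortholog
tables, and scores reconstructed ancestors against logged truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import OrthologTable, SignedGenome, marker_name, marker_sign, reverse_chromosome
from .reconstruction import AncestralKaryotype, internal_adjacencies

__all__ = [
    "SimConfig",
    "Event",
    "History",
    "SimulationResult",
    "simulate",
    "apply_event",
    "replay",
    "make_ortholog_table",
    "recovery_report",
    "adjacency_recovery_experiment",
]

EVENT_TYPES = ("inversion", "fission", "fusion", "translocation")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    tree: dendropy.Tree
    ancestor: SignedGenome
    rate: float = 1.0  # expected events per unit branch length
    event_mix: dict = field(
        default_factory=lambda: {"inversion": 0.6, "fission": 0.2, "fusion": 0.2, "translocation": 0.0}
    )
    max_events_per_branch: int | None = None  # truncate Poisson draw if set

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        total = sum(self.event_mix.get(t, 0.0) for t in EVENT_TYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event mix must sum to 1 (got {total})")
        unknown = set(self.event_mix) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")


@dataclass(frozen=True)
class Event:
    kind: str
    detail: tuple  # breakpoints, see apply_event
    genome_hash: str  # hash of the genome right after the event


@dataclass(frozen=True)
class History:
    """Ordered per-branch event records, keyed by child-node label."""

    branch_events: dict  # label -> tuple[Event, ...]


@dataclass(frozen=True)
class SimulationResult:
    leaf_genomes: dict  # label -> SignedGenome
    node_genomes: dict  # internal label -> SignedGenome
    history: History


def _genome_hash(genome: SignedGenome) -> str:
    canonical = sorted(min(ch, reverse_chromosome(ch)) for ch in genome.chromosomes)
    return hashlib.sha256(repr(canonical).encode()).hexdigest()[:16]


def _branch_rng(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


# ---------------------------------------------------------------------------
# single events
# ---------------------------------------------------------------------------

def apply_event(chromosomes: list[tuple[str, ...]], event_kind: str, detail: tuple) -> list[tuple[str, ...]]:
    """Apply one event; ``detail`` encodes the breakpoints.

    inversion: (chrom_idx, i, j) reverses markers [i, j) with sign flips.
    fission: (chrom_idx, i) splits before marker i (0 < i < len).
    fusion: (idx1, flip1, idx2, flip2) joins (possibly reversed) chromosomes.
    translocation: (idx1, i, idx2, j) reciprocal exchange of suffixes.
    """
    chromosomes = list(chromosomes)
    if event_kind == "inversion":
        c, i, j = detail
        chrom = chromosomes[c]
        chromosomes[c] = chrom[:i] + reverse_chromosome(chrom[i:j]) + chrom[j:]
    elif event_kind == "fission":
        c, i = detail
        chrom = chromosomes[c]
        chromosomes[c : c + 1] = [chrom[:i], chrom[i:]]
    elif event_kind == "fusion":
        c1, flip1, c2, flip2 = detail
        left = reverse_chromosome(chromosomes[c1]) if flip1 else chromosomes[c1]
        right = reverse_chromosome(chromosomes[c2]) if flip2 else chromosomes[c2]
        merged = left + right
        for idx in sorted((c1, c2), reverse=True):
            del chromosomes[idx]
        chromosomes.append(merged)
    elif event_kind == "translocation":
        c1, i, c2, j = detail
        a, b = chromosomes[c1], chromosomes[c2]
        chromosomes[c1] = a[:i] + b[j:]
        chromosomes[c2] = b[:j] + a[i:]
        chromosomes = [ch for ch in chromosomes if ch]
    else:
        raise ValueError(f"unknown event kind {event_kind!r}")
    return [ch for ch in chromosomes if ch]


def _available_types(mix: dict, chromosomes: list[tuple[str, ...]]) -> dict:
    avail = dict(mix)
    if len(chromosomes) < 2:
        avail["fusion"] = 0.0
        avail["translocation"] = 0.0
    if all(len(ch) < 2 for ch in chromosomes):
        avail["fission"] = 0.0
        avail["inversion"] = 0.0  # single-marker inversion is a no-op we skip
    total = sum(avail.get(t, 0.0) for t in EVENT_TYPES)
    if total <= 0:
        raise ValueError(
            "requested event mix impossible for current genome state "
            f"({len(chromosomes)} chromosome(s))"
        )
    return {t: avail.get(t, 0.0) / total for t in EVENT_TYPES}


def _draw_event(rng: np.random.Generator, mix: dict, chromosomes: list[tuple[str, ...]]) -> tuple[str, tuple]:
    avail = _available_types(mix, chromosomes)
    kind = rng.choice(EVENT_TYPES, p=[avail[t] for t in EVENT_TYPES])
    kind = str(kind)
    if kind == "inversion":
        eligible = [k for k, ch in enumerate(chromosomes) if len(ch) >= 1]
        # allow single-marker chromosomes only if nothing longer exists? a
        # 1-marker inversion just flips a sign, which is observable, keep it
        c = int(rng.choice(eligible))
        n = len(chromosomes[c])
        i = int(rng.integers(0, n))
        j = int(rng.integers(i + 1, n + 1))
        return "inversion", (c, i, j)
    if kind == "fission":
        eligible = [k for k, ch in enumerate(chromosomes) if len(ch) >= 2]
        c = int(rng.choice(eligible))
        i = int(rng.integers(1, len(chromosomes[c])))
        return "fission", (c, i)
    if kind == "fusion":
        c1, c2 = (int(x) for x in rng.choice(len(chromosomes), size=2, replace=False))
        return "fusion", (c1, bool(rng.integers(2)), c2, bool(rng.integers(2)))
    # translocation: reciprocal suffix exchange (cut points may be at ends)
    c1, c2 = (int(x) for x in rng.choice(len(chromosomes), size=2, replace=False))
    i = int(rng.integers(0, len(chromosomes[c1]) + 1))
    j = int(rng.integers(0, len(chromosomes[c2]) + 1))
    return "translocation", (c1, i, c2, j)


# ---------------------------------------------------------------------------
# tree-wide simulation
# ---------------------------------------------------------------------------

def _node_label(node: dendropy.Node, counter: list[int]) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    label = f"node{counter[0]}"
    node.label = label
    return label


def simulate(cfg: SimConfig) -> SimulationResult:
    """Evolve the ancestor down the tree; fully reproducible from the seed."""
    counter = [0]
    genomes: dict[str, SignedGenome] = {}
    branch_events: dict[str, tuple[Event, ...]] = {}
    leaf_genomes: dict[str, SignedGenome] = {}
    node_genomes: dict[str, SignedGenome] = {}

    root = cfg.tree.seed_node
    root_label = _node_label(root, counter)
    genomes[root_label] = SignedGenome(species=root_label, chromosomes=cfg.ancestor.chromosomes)
    node_genomes[root_label] = genomes[root_label]

    for node in cfg.tree.preorder_node_iter():
        label = _node_label(node, counter)
        if node is root:
            continue
        parent_label = _node_label(node.parent_node, counter)
        parent_genome = genomes[parent_label]
        rng = _branch_rng(cfg.seed, label)
        edge_len = node.edge.length if node.edge.length is not None else 1.0
        n_events = int(rng.poisson(cfg.rate * edge_len))
        if cfg.max_events_per_branch is not None:
            n_events = min(n_events, cfg.max_events_per_branch)
        chromosomes = list(parent_genome.chromosomes)
        events: list[Event] = []
        for _ in range(n_events):
            kind, detail = _draw_event(rng, cfg.event_mix, chromosomes)
            chromosomes = apply_event(chromosomes, kind, detail)
            genome = SignedGenome(species=label, chromosomes=tuple(chromosomes))
            events.append(Event(kind=kind, detail=detail, genome_hash=_genome_hash(genome)))
        genome = SignedGenome(species=label, chromosomes=tuple(chromosomes))
        genomes[label] = genome
        branch_events[label] = tuple(events)
        if node.is_leaf():
            leaf_genomes[label] = genome
        else:
            node_genomes[label] = genome
    return SimulationResult(
        leaf_genomes=leaf_genomes,
        node_genomes=node_genomes,
        history=History(branch_events=branch_events),
    )


def replay(cfg: SimConfig, history: History) -> dict[str, SignedGenome]:
    """Re-apply logged events from the ancestor; must reproduce every node."""
    counter = [0]
    genomes: dict[str, SignedGenome] = {}
    root_label = _node_label(cfg.tree.seed_node, counter)
    genomes[root_label] = SignedGenome(species=root_label, chromosomes=cfg.ancestor.chromosomes)
    for node in cfg.tree.preorder_node_iter():
        label = _node_label(node, counter)
        if node is cfg.tree.seed_node:
            continue
        parent_label = _node_label(node.parent_node, counter)
        chromosomes = list(genomes[parent_label].chromosomes)
        for event in history.branch_events.get(label, ()):
            chromosomes = apply_event(chromosomes, event.kind, event.detail)
            check = SignedGenome(species=label, chromosomes=tuple(chromosomes))
            if _genome_hash(check) != event.genome_hash:
                raise ValueError(f"replay mismatch at {label} after {event.kind}{event.detail}")
        genomes[label] = SignedGenome(species=label, chromosomes=tuple(chromosomes))
    return genomes


# ---------------------------------------------------------------------------
# gene-level expansion and recovery metrics
# ---------------------------------------------------------------------------

def make_ortholog_table(
    genome_a: SignedGenome,
    genome_b: SignedGenome,
    genes_per_marker: int = 5,
    marker_length_mb: float = 16.2,
) -> OrthologTable:
    """Expand two marker-level genomes into a gene-level ortholog table.

    Each marker carries ``genes_per_marker`` evenly spaced genes; chromosome
    coordinates are laid out additively marker by marker.  A reversed marker
    presents its genes in reverse order on the opposite strand, so block and
    segment detection on the output recovers the marker-level structure.
    """
    if genome_a.markers != genome_b.markers:
        raise ValueError("genomes must share markers")
    marker_bp = int(marker_length_mb * 1e6)
    gene_len = max(1, marker_bp // (genes_per_marker * 10))
    step = marker_bp // genes_per_marker

    def layout(genome: SignedGenome) -> dict[str, tuple[str, int, int, str]]:
        out: dict[str, tuple[str, int, int, str]] = {}
        for ci, chrom in enumerate(genome.chromosomes, start=1):
            offset = 0
            for signed in chrom:
                name = marker_name(signed)
                forward = marker_sign(signed) > 0
                for k in range(genes_per_marker):
                    gene = f"{name}_g{k + 1}"
                    pos_in_marker = k if forward else genes_per_marker - 1 - k
                    start = offset + pos_in_marker * step
                    out[gene] = (f"chr{ci}", start, start + gene_len, "+" if forward else "-")
                offset += marker_bp
        return out

    layout_a = layout(genome_a)
    layout_b = layout(genome_b)
    rows = []
    for gene in sorted(layout_a):
        ca, sa, ea, _stra = layout_a[gene]
        cb, sb, eb, _strb = layout_b[gene]
        rows.append(
            {"gene_id": gene, "chrom_a": ca, "start_a": sa, "end_a": ea, "chrom_b": cb, "start_b": sb, "end_b": eb}
        )
    df = pd.DataFrame(rows, columns=list(OrthologTable.COLUMNS))
    return OrthologTable(species_a=genome_a.species, species_b=genome_b.species, data=df)


_EXPERIMENT_TREE = "((((L1,L2)A,(L3,L4)B)AB,(L5,L6)C)Ingroup,OG)Root;"


def adjacency_recovery_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    n_markers: int = 19,
    rate: float = 1.0,
    max_events_per_branch: int = 2,
    event_mix: dict | None = None,
) -> pd.DataFrame:
    """Simulate-and-reconstruct benchmark for ancestral adjacency recovery.

    Each replicate evolves a 19-marker, 7-chromosome ancestral genome down a
    fixed tree of 6 ingroup leaves plus an outgroup (unit branch lengths,
    at most ``max_events_per_branch`` events per branch), reconstructs the
    ingroup ancestor by adjacency parsimony, and scores it against the
    logged truth.  Returns one row of metrics per replicate.
    """
    if event_mix is None:
        event_mix = {"inversion": 0.6, "fission": 0.2, "fusion": 0.2, "translocation": 0.0}
    from .io import read_species_tree
    from .reconstruction import reconstruct_ancestor

    # 7 chromosomes of 19 markers, mirroring the karyotype scale studied
    sizes = (4, 3, 3, 3, 2, 2, 2)
    assert sum(sizes) == 19
    chroms, k = [], 0
    for size in sizes[: max(1, len(sizes))]:
        if k >= n_markers:
            break
        chroms.append(tuple(f"m{k + i + 1}" for i in range(min(size, n_markers - k))))
        k += size
    while k < n_markers:  # n_markers beyond 19: extra singletons
        chroms.append((f"m{k + 1}",))
        k += 1
    ancestor = SignedGenome("ancestor", tuple(chroms))

    rows = []
    for rep in range(n_replicates):
        rep_seed = int.from_bytes(
            hashlib.sha256(f"recovery:{seed}:{rep}".encode()).digest()[:4], "big"
        ) % (2**31)
        tree = read_species_tree(_EXPERIMENT_TREE)
        cfg = SimConfig(
            seed=rep_seed,
            tree=tree,
            ancestor=ancestor,
            rate=rate,
            event_mix=event_mix,
            max_events_per_branch=max_events_per_branch,
        )
        result = simulate(cfg)
        truth = result.node_genomes["Ingroup"]
        genomes = list(result.leaf_genomes.values())
        estimate = reconstruct_ancestor(
            tree, genomes, "Ingroup", outgroup="OG", sex_markers=frozenset()
        )
        metrics = recovery_report(truth, estimate)
        metrics["replicate"] = rep
        rows.append(metrics)
    return pd.DataFrame(rows)


def recovery_report(truth: SignedGenome, estimate: AncestralKaryotype) -> dict[str, float]:
    """Adjacency precision/recall of an estimate against a logged truth genome.

    Precision = |estimated ∩ true internal adjacencies| / |estimated|;
    recall analogous; car_count_error = CARs(estimate) - chromosomes(truth).
    An empty estimated adjacency set has precision 1.0 by convention.
    """
    true_adj = internal_adjacencies(truth)
    est_adj = internal_adjacencies(estimate.as_genome())
    tp = len(true_adj & est_adj)
    precision = tp / len(est_adj) if est_adj else 1.0
    recall = tp / len(true_adj) if true_adj else 1.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "car_count_error": estimate.n_cars - truth.n_chromosomes,
    }
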