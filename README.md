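# karyorec

Comparative gene-map construction and ancestral karyotype reconstruction
for marsupial genomes.

Marsupial karyotypes are built from 19 chromosome segments (C1–C18 plus
the X) that cross-species chromosome painting shows to be conserved across
the whole infraclass. Whether the ancestral marsupial carried them on
2n = 14 or 2n = 22 chromosomes was debated for decades. `karyorec`
implements the comparative-mapping pipeline that resolves this kind of
question computationally: it detects large conserved synteny blocks
between two assembled genomes, accounts for a FISH-based cytogenetic map,
delineates oriented conserved segments between two gene maps, and
reconstructs ancestral karyotypes at named internal nodes of a species
tree from signed segment arrangements, using an outgroup (chicken) to
polarize ancestral versus derived junctions. A signed-genome rearrangement
simulator provides ground-truth histories so every stage is testable
offline.

Intended users: comparative cytogeneticists and genome-evolution
researchers working with gene maps and painting data in non-model species.

## The method

A genome is a set of linear chromosomes over signed markers (conserved
segments). Each chromosome contributes *adjacencies* between marker
extremities (head/tail). For an internal tree node of interest:

1. every adjacency observed in any extant genome becomes a binary
   presence/absence character;
2. each character is scored by minimum-change (Fitch) parsimony over the
   tree — exact most-parsimonious state sets are computed, and an
   adjacency that is ambiguous at the node is resolved toward *present*
   when the outgroup genome carries it — giving a support weight
   w ∈ {0, ½, 1};
3. supported adjacencies are assembled greedily (weight-descending,
   deterministic tie-break) into contiguous ancestral regions (CARs):
   linear paths in which no extremity is used twice and no cycle forms;
4. the diploid number is 2 × the CAR count (the X is kept a single unit).

Rearrangement costs between genomes use the double-cut-and-join (DCJ)
model, `d = N − C − I/2`, from the adjacency-graph cycle/path
decomposition; the net chromosome-number change splits a scenario into
fissions/fusions plus residual inversions.

Synteny blocks between two assemblies are maximal runs of genes
consecutive in one species whose partner chromosome is constant —
deliberately *not* requiring internal order conservation, which yields the
few large blocks that make end-targeted FISH mapping efficient (probes at
both ends of blocks > 3 Mb, one mid-block gene otherwise).

## Worked example

```sh
python examples/reconstruct_marsupial_ancestor.py
```

reconstructs the marsupial root from the packaged segment arrangements of
six species (dunnart, common and South American opossums, brushtail
possum, rufous bettong, tammar wallaby) with chicken outgroup adjacencies,
and prints:

```
ancestral marsupial karyotype at node 'MarsupialAncestor':
  CAR1: C10 C12 C11
  CAR2: C13 C14
  CAR3: C15 C16
  CAR4: C17 C18
  CAR5: C2 C1a C4a C3 C1b C4b C5 C6
  CAR6: C8 C7 C9
  CAR7: X
7 CARs -> diploid number 2n = 14
```

Seven CARs — six autosome pairs plus the X — support the low diploid
number: the ancestral marsupial karyotype was 2n = 14, with the higher
diploid numbers of extant species derived mainly by fission (the event
accounting printed below the karyotype shows, e.g., nine fissions toward
the 2n = 32 rufous bettong and mostly inversions toward the wallaby).

Other examples cover block detection and probe selection
(`detect_blocks_and_probes.py`), map accounting and discrepancy flagging
(`map_accounting.py`), conserved-segment delineation
(`comparative_segments.py`) and simulation-based validation
(`simulate_and_recover.py`). The same stages are reachable from a shell
via the `karyorec` command (`blocks`, `probes`, `mapsum`, `discrepancies`,
`compare`, `reconstruct`, `simulate`, `evaluate`).

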