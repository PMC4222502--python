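# Methods

## Scope and data model

`karyorec` works at two resolutions. At *gene* resolution it handles
ortholog position tables (two genomes' coordinates per gene) and
cytogenetic gene maps (one chromosome + position per gene, with a
provenance tag and an optional painting-segment label). At *marker*
resolution it handles signed genomes: linear chromosomes over signed
markers, where a marker is a conserved chromosome segment (C1–C18, X, or
sub-segments such as C1a). Coordinates are 1-based inclusive in files
(the Ensembl convention), 0-based half-open in memory; strand may be
`unknown`, because FISH localizations carry no orientation at gene level.

## Synteny-block detection

Blocks are maximal runs of genes consecutive along the anchoring species
(A) whose partner-species (B) chromosome is constant. Internal B order is
recorded (`order_conserved`) but never splits a block: requiring order
conservation multiplies block counts several-fold and defeats the purpose
of end-targeted probe design. Genes without a B assignment are excluded
with a warning. Blocks whose A span falls below `min_span_kb` (default
100 kb, matching the block-size floor of the synteny browser the input
tables come from) are dropped after run construction; the filter is a
parameter because published accountings retain some sub-100 kb blocks.
Probe selection: blocks spanning strictly more than `large_threshold_mb`
(default 3 Mb) contribute first and last gene; smaller blocks (boundary
case included, since the published rule reads "> 3 Mb" for two-end
targeting) contribute the gene nearest the coordinate midpoint, ties to
the earlier gene.

## Cytogenetic-map accounting

Merging a current-study map with previously published assignments is a
provenance-keeping union; a gene placed at two different locations is a
hard error, and a gene confirmed at the same location is credited to the
earlier study. Discrepancy flagging takes a chromosome-homology table
(expected-species chromosome → set of observed-species chromosomes) and
reports genes observed off their homologous chromosome; genes with no
expected location are reported separately as resolving previously blank
regions. Classification is advisory: a discordant gene whose expected-map
neighbours are also discordant is a `transposition_candidate`, an isolated
one an `assembly_error_candidate` — single-gene conflicts are at least as
likely to be reference-assembly errors as real moves, and the package
leaves the call to the user. Because FISH on condensed metaphase
chromosomes resolves only loci separated by roughly a megabase,
`order_confidence` groups consecutive genes closer than `resolution_mb`
(default 1 Mb, midpoint distance, transitive closure) into explicitly
order-uncertain runs rather than pretending to a linear order the data
cannot support.

## Conserved-segment delineation

Between two gene maps sharing a gene universe, a homology segment is a
maximal run of genes consecutive in A whose B images are consecutive on
one B chromosome with a consistent direction. Consecutiveness in B is
*ordinal* — B-order ranks restricted to the shared universe — not a
base-pair gap threshold, because cytogenetic maps are reliable in order
but not in distance. Singleton segments are `unoriented`. Painting labels
are assigned per segment by majority vote of gene labels (`unknown`
abstains; ties break lexicographically); boundaries are emitted between
A-adjacent segments with different labels and downgraded from
`definitive` to `ambiguous` when a flank contains minority-label genes or
when labels alternate within a window of `ambiguity_window` genes
(default 3) of the junction — the window size operationalizes the
qualitative "could not be conclusively placed" calls that arise where two
segments are repeatedly rearranged together.

## Ancestral reconstruction

Candidate adjacencies are the union of marker–marker junctions over all
extant genomes (telomeric junctions carry no linkage information and are
not scored). Each is a binary character on the rooted species tree.
Support is computed as the exact most-parsimonious-reconstruction state
set at the target node under unit change costs, via subtree and
rest-of-tree cost messages; this equals exhaustive enumeration of
minimum-change labelings (and is tested against it). A leaf whose genome
lacks either marker contributes no evidence (both states allowed at zero
cost) — this is how a partial outgroup participates without imputation.
Weights: unambiguously present 1.0; ambiguous 0.5, promoted to 1.0 when
the designated outgroup genome carries the adjacency (outgroup
arbitration, the computational form of using chicken gene order as the
guide); unambiguously absent 0.0 and excluded.

CAR assembly is greedy and deterministic: adjacencies sorted by weight
descending, then lexicographically by extremity pair; accepted iff both
extremities are free and no cycle would form (chromosomes are linear;
cycle-closing adjacencies are recorded as skipped). Reproducibility was
preferred over search-based optimality at this problem size, where the
greedy assembly is exact whenever the weight-1 adjacency set is itself
consistent. Sex-linked markers (default `{"X"}`) are hard pre-grouped: an
adjacency joining a sex marker to an autosome is rejected, keeping the X
a unit as painting treats it. The diploid number is 2 × CAR count, the X
CAR counting once.

DCJ distance uses the standard adjacency-graph decomposition,
`d = N − C − I/2` with C cycles and I odd paths; it is validated against
breadth-first search over actual DCJ moves. Event scenarios take the net
chromosome-number change as the fission/fusion count and attribute the
remaining operations to inversions or other intrachromosomal events —
a lower bound in the DCJ economy, not a claimed literal history.

The therian-level karyotype is exposed only as a coarse fixture of
human-segment groupings (19 chromosomes by default; a `split_hsa19`
switch gives the 2n = 18 alternative in which the HSA19-derived material
occupies two chromosomes instead of three). Marker-level therian content
is not resolvable from segment-granularity maps, and the package does not
pretend otherwise.

## The packaged marsupial fixture

Six ingroup species are encoded at painting-segment granularity with C1
and C4 split into a/b sub-segments genome-wide so marker sets harmonize
(the dunnart interleaves them; elsewhere the parts sit adjacent).
Chromosome contents and the explicitly published orders (dunnart
C2-C1a-C4a-C3-C1b-C4b-C5-C6 and C10-C12-C11; opossum C8-C7-C9 and
C13-C14; the common opossum's C4-C5-C6 and C3-C1-C2; the wallaby's eight
chromosome assignments; the documented C13/C14, C15/C16 and C17/C18
splits) are taken as stated; remaining within-chromosome orders and the
completion to each species' published diploid number (22, 18, 20, 14, 32,
16) are reconstructed from the painting/G-banding literature and flagged
as such in the source. The chicken outgroup is encoded as a synthetic
adjacency donor carrying exactly the junctions chicken gene order
supports (C10-C12-C11; the C1–C6 linkage; C8-C7-C9; C13-C14; C15-C16;
C17-C18) over the markers it shares; it has no X marker. The species tree
is the accepted topology (didelphids sister to Australidelphia; dunnart,
then possum, then the two macropodiforms) with unit branch lengths, since
none are published. On this fixture the pipeline yields 7 CARs (2n = 14)
with every accepted adjacency at weight 1.0.

The accounting fixtures are synthetic by construction: the block fixture
reproduces the published per-chromosome block *counts* (208 overall, 154
on the six newly analysed autosomes) and smallest/largest spans, with
intermediate spans drawn log-uniformly — per-row mean spans are therefore
not reproduced (nor reproducible: the published per-row figures are not
mutually consistent, e.g. a chromosome whose mean equals its largest
block across 18 blocks). The map fixture reproduces the published
per-chromosome provenance counts (242 current, 312 previous, 554 total)
with placeholder gene ids.

## Simulator

The simulator evolves a signed ancestor down a rooted tree. Event counts
per branch are Poisson(rate × branch length), optionally truncated;
types are drawn from a mix over inversion/fission/fusion/translocation,
renormalized when a type is impossible in the current state (fusion or
translocation with one chromosome, fission with only single-marker
chromosomes); a mix that leaves nothing possible raises. Translocation
(reciprocal suffix exchange) completes the classical event set but
defaults to probability 0, matching the inversion/fission/fusion
vocabulary of marsupial chromosome evolution. Per-branch random
substreams are derived by hashing the seed with the node label, so
traversal order cannot change results, and every event is logged with a
post-event genome hash; replaying a history must reproduce each node
genome exactly. Marker content is conserved — no gain, loss or
duplication — which matches the painting-segment world but means the
simulator says nothing about segmental duplication or centromere
repositioning in real genomes.

Gene-level expansion lays `genes_per_marker` evenly spaced genes along
each marker (default length 16.2 Mb, a realistic conserved-block scale),
reversing order and strand inside reversed markers, so block and segment
detection on the output can recover the marker-level structure.

## Validation conditions and what they show

The recovery benchmark simulates 100 replicates of a 19-marker,
7-chromosome ancestor down a fixed 6-ingroup-leaf tree plus outgroup,
unit branch lengths, at most 2 events per branch, mix
inversion:fission:fusion = 0.6:0.2:0.2, and reconstructs the ingroup
ancestor from the leaves. Median adjacency precision and recall are 1.0
and median CAR-count error 0 under these conditions. This shows the
parsimony-plus-greedy pipeline is consistent at the rearrangement density
typical of marsupial segment data; it does not bound performance under
breakpoint reuse, much higher rates, or marker sets that do not
harmonize. The DCJ oracle checks run exhaustively over all genome pairs
on up to 3 markers and as full single-source BFS sweeps (source versus
every genome in the space) on 4–5 markers; parsimony weights are checked
against exhaustive labeling enumeration on 4-leaf-plus-outgroup trees
over up to 6 markers; block and segment detection are checked against
brute-force maximal-run enumeration on 200 random instances.

## Numerical and degenerate-input choices

Mb values are reported to two decimals and compared numerically. Empty
inputs yield empty outputs (header-only tables, zero-row summaries)
rather than errors. Duplicate gene ids, repeated markers, conflicting
double assignments and marker-set mismatches are hard errors naming the
offending items. All randomness flows from explicit integer seeds;
outputs carry a version + config-hash provenance header and no
timestamps, so identical invocations are byte-identical.
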