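"""Reconstruct the ancestral marsupial karyotype from the packaged fixture.

Uses the segment arrangements of six marsupial species (painting segments
C1-C18 plus X, with C1/C4 carried as sub-segments) and chicken-derived
outgroup adjacencies to infer the karyotype at the marsupial root, then
counts the rearrangement events separating each extant genome from it.
"""

import karyorec as kr
from karyorec import fixtures as fx

tree = fx.marsupial_tree()
genomes = fx.marsupial_genomes()

karyotype = kr.reconstruct_ancestor(tree, genomes, fx.MARSUPIAL_ROOT, outgroup=fx.OUTGROUP)

print(f"ancestral marsupial karyotype at node {karyotype.node!r}:")
for i, car in enumerate(karyotype.cars, start=1):
    print(f"  CAR{i}: {' '.join(car)}")
print(f"{karyotype.n_cars} CARs -> diploid number 2n = {kr.diploid_number(karyotype)}")
print("(six autosome pairs plus the X pair, the low-diploid-number ancestor)")

print("\nevents from the ancestor to each extant genome (DCJ accounting):")
for genome in genomes:
    if genome.species == fx.OUTGROUP:
        continue
    scenario = kr.infer_events(karyotype, genome)
    print(f"  {scenario.narrative}")
print("(fissions dominate toward high-2n species; inversions do the rest)")
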