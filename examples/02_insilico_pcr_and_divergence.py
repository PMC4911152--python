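"""Mock amplicons and nearest-neighbour distances (the barcode gap).

Crops references to the region a degenerate primer pair amplifies, then
computes mean interspecific p-distances and each species' nearest
neighbour distance (NND).  Markers whose NNDs sit above the identity
threshold margin can discriminate species; those below cannot.
"""

from markereval.divergence import (nearest_neighbour_distances,
                                   species_distance_matrix)
from markereval.insilico_pcr import extract_amplicons
from markereval.synthetic_data import generate_references, generate_taxonomy
from markereval.workflow import default_config

taxonomy = generate_taxonomy(4, 2, 3, 2, seed=7)
markers = default_config(seed=7).markers
refdbs, _ = generate_references(taxonomy, [m.profile for m in markers], seed=7)

for mc in markers:
    amplicons, skip_log = extract_amplicons(refdbs[mc.name], mc.profile.primers)
    groups: dict[str, list[str]] = {}
    for a in amplicons:
        groups.setdefault(a.truth.species, []).append(a.sequence)
    dm = species_distance_matrix(groups)
    nnd = nearest_neighbour_distances(dm)
    print(f"{mc.name:>5}: {len(amplicons):3d} amplicons "
          f"({len(skip_log)} skipped), median NND "
          f"{nnd['nnd'].median():.3f} over {len(nnd)} species")

print("\nMedian NND tracks each marker's planted congeneric divergence;"
      "\nspecies whose NND is ~0 share an amplicon with a congener and"
      "\ncannot be told apart by this marker.")
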