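"""Area geography: reading centroid + adjacency files and deriving structure.

Builds a small county-like map from the bundled example files, then derives
the ICAR structure matrix (graph Laplacian) used by the spatial prior and
the great-circle distance matrix used to grow circular scan windows.
"""

from pathlib import Path

import numpy as np

from spatialprev import distance_matrix, read_area_map, structure_matrix

here = Path(__file__).parent
amap = read_area_map(here / "data" / "centroids.csv", here / "data" / "adjacency.gal")

print(f"{amap.n_areas} areas: {', '.join(amap.area_ids)}")
print(f"neighbours of {amap.area_ids[0]}: {sorted(amap.neighbors[amap.area_ids[0]])}")

sm = structure_matrix(amap)
print(f"\nstructure matrix Q ({sm.n_components} connected component(s)):")
print(sm.Q.astype(int))
print("row sums (always zero):", sm.Q.sum(axis=1).astype(int))

d = distance_matrix(amap)
i, j = np.unravel_index(np.argmax(d), d.shape)
print(f"\nlargest centroid separation: {amap.area_ids[i]} - {amap.area_ids[j]}"
      f" = {d[i, j]:.1f} km")
# Q encodes which areas the ICAR prior smooths together; the distances order
# areas around each scan-window centre.
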