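"""Spectral screening: dedup, fragment prescreen and clustering.

Twelve jittered copies of the same water geometry (as if harvested from
twelve trajectories) collapse to a single unique structure; a stretched
van der Waals H2 dimer is rejected by the weighted spectral-gap filter;
and clustering reduces many candidates to one representative per
distinct reaction.
"""

import numpy as np

from mechkit.bbfs import TSCandidate
from mechkit.geometry import Geometry
from mechkit.molgraph import build_connectivity, build_weighted, laplacian_spectrum
from mechkit.screen import cluster_candidates, dedup, prescreen_fragmented

rng = np.random.default_rng(11)

water = Geometry.from_symbols(
    ["O", "H", "H"], [[0, 0, 0], [0.76, 0.59, 0], [-0.76, 0.59, 0]]
)


def candidate(geom):
    cg = build_connectivity(geom)
    return TSCandidate(window=(0, 0), events=(), geometry=geom,
                       active_atoms=frozenset(), reactant_graph=cg,
                       product_graph=cg, boundary_flag=False, source="demo")


copies = [
    candidate(water.with_coords(water.coords + rng.normal(0, 0.0001, (3, 3))))
    for _ in range(12)
]
unique = dedup(copies)
print(f"dedup: {len(copies)} jittered copies -> {len(unique)} unique structure(s)")

# a weakly bound pair of H2 molecules at 1.9x the covalent reference distance
r_hh = 1.2 * 0.62
d = 1.9 * r_hh
dimer = Geometry.from_symbols(
    ["H", "H", "H", "H"],
    [[0, 0, 0], [0.70, 0, 0], [0.70 + d, 0, 0], [1.40 + d, 0, 0]],
)
gap = laplacian_spectrum(build_weighted(dimer)).spectral_gap
kept, discarded = prescreen_fragmented([candidate(water), candidate(dimer)])
print(f"vdW dimer weighted spectral gap = {gap:.4f} (below the 0.1 default)")
print(f"prescreen: kept {len(kept)}, discarded {len(discarded)}")

clusters = cluster_candidates(copies)
print(f"clustering: {len(copies)} candidates -> {len(clusters)} cluster(s); "
      f"representative index {clusters[0].representative}")
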