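"""Spectral screening of transition-state candidates.

Three filters, all driven by eigenvalue spectra so they are invariant to
rotation, translation and permutation of like atoms:

* ``dedup`` removes redundant candidates: two structures are duplicates when
  the sorted spectra of their atomic-number-labeled adjacency matrices A_Z
  agree element-wise within a tolerance.  The labeled matrix (not raw SPRINT
  coordinates) is used because SPRINT values cannot distinguish structures
  in which two unlike atoms have swapped positions.
* ``prescreen_fragmented`` discards fragmented or van der Waals structures
  using the weighted Laplacian: more than one fragment (low-eigenvalue
  multiplicity) or a small weighted spectral gap marks a weakly bound
  assembly of no kinetic interest.
* ``cluster_candidates`` groups candidates by the spectrum of the averaged
  reactant/product adjacency (labeled), picking the member closest to each
  cluster centroid as the single representative to hand to a downstream
  saddle-point optimizer — reducing M harvested structures to N <= M
  optimizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bbfs import TSCandidate
from .geometry import Geometry
from .molgraph import (
    LabeledGraph,
    build_connectivity,
    build_labeled,
    build_weighted,
    laplacian_spectrum,
    ZERO_TOL_WEIGHTED,
)

__all__ = [
    "CandidateCluster",
    "dedup",
    "prescreen_fragmented",
    "cluster_candidates",
    "labeled_spectrum",
    "DEFAULT_SPECTRUM_TOL",
    "DEFAULT_GAP_MIN",
]

#: Absolute per-eigenvalue tolerance for spectrum equality.
DEFAULT_SPECTRUM_TOL = 1e-3
#: Minimum weighted spectral gap for a candidate to count as covalently intact.
DEFAULT_GAP_MIN = 0.1


@dataclass
class CandidateCluster:
    members: list[int]
    representative: int
    signature: np.ndarray


def labeled_spectrum(geom: Geometry, weighted: bool = True) -> np.ndarray:
    """Sorted eigenvalues of the A_Z matrix of a geometry."""
    graph = build_weighted(geom) if weighted else build_connectivity(geom)
    return build_labeled(graph, geom.atoms).spectrum()


def _composition(geom: Geometry) -> tuple:
    return tuple(sorted(geom.symbols))


def _spectra_equal(s1: np.ndarray, s2: np.ndarray, tol: float) -> bool:
    return s1.shape == s2.shape and bool(np.all(np.abs(s1 - s2) <= tol))


def dedup(
    candidates: list[TSCandidate],
    tol: float = DEFAULT_SPECTRUM_TOL,
    weighted: bool = True,
) -> list[TSCandidate]:
    """Keep one representative (first in input order) per duplicate spectrum.

    Duplicates are defined by element-wise agreement of the sorted A_Z
    eigenvalue spectra of the candidate geometries.  The weighted variant
    is the default: on a binary adjacency, topologically equivalent sites
    (e.g. the leaves of a star) stay isospectral even after an unlike-atom
    swap, whereas the distance-weighted matrix separates them.  All
    candidates must share the same atom composition.
    """
    if not candidates:
        return []
    comp0 = _composition(candidates[0].geometry)
    for c in candidates[1:]:
        if _composition(c.geometry) != comp0:
            raise ValueError(
                f"composition mismatch: {comp0} vs {_composition(c.geometry)}"
            )
    kept: list[TSCandidate] = []
    kept_spectra: list[np.ndarray] = []
    for cand in candidates:
        spec = labeled_spectrum(cand.geometry, weighted=weighted)
        if not any(_spectra_equal(spec, s, tol) for s in kept_spectra):
            kept.append(cand)
            kept_spectra.append(spec)
    return kept


def prescreen_fragmented(
    candidates: list[TSCandidate],
    lambda1w_max: float = ZERO_TOL_WEIGHTED,
    gap_min: float = DEFAULT_GAP_MIN,
) -> tuple[list[TSCandidate], list[TSCandidate]]:
    """Split candidates into (kept, discarded) by Laplacian criteria.

    Discarded when the unweighted Laplacian shows more than one fragment
    (zero-eigenvalue multiplicity, equivalent to graph connectivity), when
    the weighted Laplacian has extra eigenvalues below ``lambda1w_max``, or
    when the weighted spectral gap falls below ``gap_min`` (a weakly bound
    van der Waals assembly even if nominally connected).
    """
    kept, discarded = [], []
    for cand in candidates:
        binary = laplacian_spectrum(build_connectivity(cand.geometry))
        wsummary = laplacian_spectrum(
            build_weighted(cand.geometry), zero_tol=lambda1w_max
        )
        fragmented = binary.n_fragments > 1 or wsummary.n_fragments > 1
        if fragmented or wsummary.spectral_gap < gap_min:
            discarded.append(cand)
        else:
            kept.append(cand)
    return kept, discarded


def _average_signature(cand: TSCandidate) -> np.ndarray:
    """Sorted spectrum of the labeled average of reactant/product adjacencies."""
    A_avg = 0.5 * (cand.reactant_graph.A + cand.product_graph.A)
    AZ = A_avg.copy()
    for i, atom in enumerate(cand.geometry.atoms):
        AZ[i, i] = 1.0 + atom.Z / 10.0
    return LabeledGraph(AZ=AZ).spectrum()


def cluster_candidates(
    candidates: list[TSCandidate],
    tol: float = DEFAULT_SPECTRUM_TOL,
) -> list[CandidateCluster]:
    """Bucket candidates by the averaged-adjacency spectrum.

    Deterministic greedy bucketing in input (trajectory) order: a candidate
    joins the first cluster whose founding signature matches element-wise
    within ``tol``, else founds a new cluster.  The representative is the
    member whose signature is closest (Euclidean) to the cluster mean,
    ties broken by lowest index.
    """
    signatures = [_average_signature(c) for c in candidates]
    clusters: list[list[int]] = []
    founders: list[np.ndarray] = []
    for idx, sig in enumerate(signatures):
        for c_idx, f_sig in enumerate(founders):
            if _spectra_equal(sig, f_sig, tol):
                clusters[c_idx].append(idx)
                break
        else:
            clusters.append([idx])
            founders.append(sig)
    out = []
    for members in clusters:
        mean = np.mean([signatures[m] for m in members], axis=0)
        dists = [float(np.linalg.norm(signatures[m] - mean)) for m in members]
        rep = members[int(np.argmin(dists))]
        out.append(CandidateCluster(members=members, representative=rep, signature=mean))
    return out
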