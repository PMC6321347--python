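"""Molecular connectivity graphs and their spectral descriptors.

Bonding is purely geometric: two atoms are bonded when their distance is
below a reference length taken as ``scale`` (default 1.2, i.e. 20% slack)
times the sum of their covalent radii.  On top of the resulting binary
adjacency matrix A the module builds

* a weighted adjacency A^w with smooth rational-function entries in [0, 1]
  (a bond-order surrogate),
* an atomic-number-labeled matrix A_Z with ``1 + Z_i/10`` on the diagonal,
  whose eigenvalue spectrum distinguishes structures that differ by a swap
  of unlike atoms,
* the graph Laplacian L = D - A, whose zero-eigenvalue multiplicity counts
  molecular fragments and whose smallest non-zero eigenvalue (the spectral
  gap) flags weakly bound van der Waals assemblies,
* SPRINT coordinates, per-atom descriptors from the principal eigenpair of
  A^w that are invariant under rotation, translation and atom permutation.

No bond-order perception, valence rules or periodic boundary conditions are
applied; the model is gas-phase geometry only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .geometry import Geometry

__all__ = [
    "ConnectivityGraph",
    "WeightedGraph",
    "LabeledGraph",
    "SpectralSummary",
    "build_connectivity",
    "build_weighted",
    "build_labeled",
    "laplacian_spectrum",
    "count_fragments",
    "sprint_coordinates",
    "reference_distances",
]

#: Default slack over the sum of covalent radii for the bond criterion.
DEFAULT_SCALE = 1.2
#: Eigenvalues below this are "zero" for unweighted Laplacians.
ZERO_TOL_UNWEIGHTED = 1e-6
#: Fragmentation threshold on low eigenvalues of a weighted Laplacian.
ZERO_TOL_WEIGHTED = 1e-4


@dataclass
class ConnectivityGraph:
    """Binary adjacency matrix plus the reference-distance matrix (Angstrom)."""

    A: np.ndarray
    r_ref: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        _check_symmetric(self.A)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        return self.A


@dataclass
class WeightedGraph:
    """Smooth adjacency with entries in [0, 1]; exponents default (6, 12)."""

    Aw: np.ndarray
    n_exp: int = 6
    m_exp: int = 12
    r_ref: np.ndarray | None = None

    def __post_init__(self):
        self.Aw = np.asarray(self.Aw, dtype=float)
        _check_symmetric(self.Aw)

    @property
    def n(self) -> int:
        return self.Aw.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        return self.Aw


@dataclass
class LabeledGraph:
    """Adjacency with ``1 + Z_i/10`` on the diagonal (atom-identity aware)."""

    AZ: np.ndarray
    weighted: bool = False

    def __post_init__(self):
        self.AZ = np.asarray(self.AZ, dtype=float)

    def spectrum(self) -> np.ndarray:
        """Sorted (ascending) eigenvalues; permutation-invariant descriptor."""
        return np.sort(scipy.linalg.eigvalsh(self.AZ))


@dataclass
class SpectralSummary:
    """Laplacian eigenvalues, fragment count, spectral gap, SPRINT vector."""

    eigenvalues: np.ndarray
    n_fragments: int
    spectral_gap: float
    sprint: np.ndarray | None = None


def _check_symmetric(M: np.ndarray, tol: float = 1e-10) -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=tol):
        raise ValueError("matrix must be symmetric")


def reference_distances(geom: Geometry, scale: float = DEFAULT_SCALE) -> np.ndarray:
    """r_ref[i,j] = scale * (r_cov_i + r_cov_j); zero diagonal."""
    if scale <= 1.0:
        raise ValueError(f"scale must exceed 1 (got {scale})")
    r_cov = np.array([a.r_cov for a in geom.atoms])
    r_ref = scale * (r_cov[:, None] + r_cov[None, :])
    np.fill_diagonal(r_ref, 0.0)
    return r_ref


def build_connectivity(geom: Geometry, scale: float = DEFAULT_SCALE) -> ConnectivityGraph:
    """Binary bond matrix: a_ij = 1 iff r_ij < scale*(r_cov_i + r_cov_j)."""
    r = geom.distances()
    r_ref = reference_distances(geom, scale)
    A = (r < r_ref).astype(float)
    np.fill_diagonal(A, 0.0)
    return ConnectivityGraph(A=A, r_ref=r_ref)


def build_weighted(
    geom: Geometry,
    n_exp: int = 6,
    m_exp: int = 12,
    scale: float = DEFAULT_SCALE,
) -> WeightedGraph:
    """Smooth bond-order surrogate a^w_ij = (1 - x^n)/(1 - x^m), x = r/r_ref.

    For the default m = 2n the expression reduces to the everywhere-continuous
    closed form 1/(1 + x^n), which is used directly; otherwise the removable
    singularity at x = 1 is filled with the algebraic limit n/m.
    """
    if n_exp < 1 or m_exp <= n_exp:
        raise ValueError(f"need 1 <= n_exp < m_exp, got ({n_exp}, {m_exp})")
    r = geom.distances()
    n_at = geom.n_atoms
    off = ~np.eye(n_at, dtype=bool)
    if np.any(r[off] == 0.0):
        i, j = np.argwhere((r == 0.0) & off)[0]
        raise ValueError(f"coincident atoms {i} and {j} (zero distance)")
    r_ref = reference_distances(geom, scale)
    x = np.ones_like(r)
    x[off] = r[off] / r_ref[off]
    if m_exp == 2 * n_exp:
        Aw = 1.0 / (1.0 + x**n_exp)
    else:
        num = 1.0 - x**n_exp
        den = 1.0 - x**m_exp
        with np.errstate(divide="ignore", invalid="ignore"):
            Aw = np.where(den != 0.0, num / den, n_exp / m_exp)
    np.fill_diagonal(Aw, 0.0)
    return WeightedGraph(Aw=Aw, n_exp=n_exp, m_exp=m_exp, r_ref=r_ref)


def build_labeled(graph: ConnectivityGraph | WeightedGraph, atoms) -> LabeledGraph:
    """Put 1 + Z_i/10 on the diagonal of the given adjacency."""
    M = graph.matrix
    if M.shape[0] != len(atoms):
        raise ValueError(
            f"graph has dimension {M.shape[0]} but {len(atoms)} atoms were given"
        )
    AZ = M.copy()
    for i, atom in enumerate(atoms):
        AZ[i, i] = 1.0 + atom.Z / 10.0
    return LabeledGraph(AZ=AZ, weighted=isinstance(graph, WeightedGraph))


def laplacian_spectrum(
    graph: ConnectivityGraph | WeightedGraph,
    zero_tol: float | None = None,
) -> SpectralSummary:
    """Eigenvalues of L = D - A, fragment count and spectral gap.

    For an unweighted graph the fragment count is the number of (near-)zero
    eigenvalues; for a weighted graph eigenvalues below a configurable upper
    threshold are treated as zero for the purpose of fragment detection.
    """
    weighted = isinstance(graph, WeightedGraph)
    if zero_tol is None:
        zero_tol = ZERO_TOL_WEIGHTED if weighted else ZERO_TOL_UNWEIGHTED
    A = graph.matrix
    _check_symmetric(A)
    L = np.diag(A.sum(axis=1)) - A
    eig = np.sort(scipy.linalg.eigvalsh(L))
    n_frag = int(np.sum(eig < zero_tol))
    n_frag = max(n_frag, 1)
    above = eig[eig >= zero_tol]
    gap = float(above[0]) if above.size else 0.0
    return SpectralSummary(eigenvalues=eig, n_fragments=n_frag, spectral_gap=gap)


def count_fragments(
    geom: Geometry, scale: float = DEFAULT_SCALE
) -> tuple[int, np.ndarray]:
    """Fragment count (Laplacian zero-eigenvalue multiplicity) and atom labels.

    The count comes from the Laplacian spectrum; the per-atom component
    labels come from sparse-graph traversal of the same adjacency.  The two
    agree for any binary adjacency matrix.
    """
    graph = build_connectivity(geom, scale)
    summary = laplacian_spectrum(graph)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(graph.A), directed=False
    )
    if n_comp != summary.n_fragments:  # pragma: no cover - internal consistency
        raise RuntimeError(
            f"Laplacian fragment count {summary.n_fragments} disagrees with "
            f"traversal count {n_comp}"
        )
    return summary.n_fragments, labels


def sprint_coordinates(wgraph: WeightedGraph, atoms=None) -> np.ndarray:
    """SPRINT coordinates s_i = sqrt(N) * lambda_max * v_i from A^w.

    ``v`` is the non-negative unit principal eigenvector (Perron-Frobenius).
    Disconnected graphs are handled per connected component, each with its
    own principal eigenpair and component size N.  When ``atoms`` is given
    the values are sorted within groups of identical elements (position by
    ascending element symbol, values ascending within each group); otherwise
    the full vector is returned sorted ascending.
    """
    Aw = wgraph.matrix
    n = Aw.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    # split into components using a thresholded binary support
    support = (Aw > ZERO_TOL_WEIGHTED).astype(int)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(support), directed=False
    )
    s = np.zeros(n)
    for c in range(n_comp):
        idx = np.where(labels == c)[0]
        block = Aw[np.ix_(idx, idx)]
        if len(idx) == 1:
            s[idx] = 0.0
            continue
        w, v = scipy.linalg.eigh(block)
        lam = w[-1]
        vec = v[:, -1]
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec)  # Perron vector is non-negative up to sign
        s[idx] = np.sqrt(len(idx)) * lam * vec
    if atoms is not None:
        symbols = np.array([a.symbol for a in atoms])
        out = np.empty(n)
        pos = 0
        for sym in sorted(set(symbols)):
            vals = np.sort(s[symbols == sym])
            out[pos : pos + len(vals)] = vals
            pos += len(vals)
        return out
    return np.sort(s)
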