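"""Normalized graph Laplacian and its leading eigenmodes.

The symmetric normalized Laplacian L = I - D^{-1/2} A D^{-1/2} of a
connected weighted graph is positive semi-definite with spectrum in
[0, 2]; its eigenvalues act as graph frequencies and its eigenvectors
("eigenmodes") as the Fourier basis for signals on the nodes. The
first eigenvalue is 0 with eigenvector proportional to D^{1/2} 1, a
degree-shaped constant mode. Spatial variability of a mode is measured
by its total variation x^T L x (which equals the eigenvalue for a unit
eigenvector) or by the weighted zero-crossing count over edges.

Only the leading C modes are computed: voxel-wise brain graphs are far
too large for full diagonalization, and the low-frequency end is where
structural and functional signal content concentrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import eigsh

from .graph import BrainGraph

__all__ = [
    "SpectralDecomposition",
    "normalized_laplacian",
    "eigendecompose",
    "total_variation",
    "zero_crossings",
]

# below this size (or when C is a large fraction of N) dense LAPACK wins
_DENSE_CUTOFF = 600


@dataclass
class SpectralDecomposition:
    """Leading eigenpairs of the normalized Laplacian, ascending.

    ``eigenvectors`` is N x C with orthonormal columns; signs are fixed
    so each column's largest-magnitude entry is positive (first such
    entry on ties), making the decomposition deterministic up to
    degenerate eigenspaces.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    graph: BrainGraph | None = None

    @property
    def C(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_nodes(self) -> int:
        return self.eigenvectors.shape[0]


def normalized_laplacian(graph: BrainGraph) -> sparse.csr_matrix:
    """L = I - D^{-1/2} A D^{-1/2}; symmetric, unit diagonal.

    Raises
    ------
    ValueError
        If any degree is non-positive (cannot happen for a graph that
        went through largest-component extraction).
    """
    d = graph.degrees
    if np.any(d <= 0):
        raise ValueError("graph has non-positive degrees; Laplacian undefined")
    inv_sqrt = sparse.diags(1.0 / np.sqrt(d))
    n = graph.n_nodes
    lap = sparse.eye(n, format="csr") - inv_sqrt @ graph.adjacency @ inv_sqrt
    # exact symmetry: the construction is symmetric up to float noise only
    return lap.tocsr()


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vecs), axis=0)  # first maximal entry on ties
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def eigendecompose(
    lap: sparse.spmatrix,
    C: int,
    graph: BrainGraph | None = None,
    seed: int = 0,
    residual_tol: float = 1e-8,
    method: str = "auto",
) -> SpectralDecomposition:
    """The C algebraically smallest eigenpairs of the Laplacian.

    Small problems are diagonalized densely; large ones use
    shift-invert Lanczos about a point just below 0 (the lower spectral
    end of these graphs is dense near 0, where plain Lanczos converges
    poorly). The starting vector is drawn from ``seed`` so the
    computation is reproducible. ``method`` forces "dense" or
    "lanczos" ("auto" picks by problem size).

    Raises
    ------
    ValueError
        If C >= N.
    RuntimeError
        If any eigenpair residual ||L u - lambda u|| exceeds
        ``residual_tol``.
    """
    n = lap.shape[0]
    if not 1 <= C < n:
        raise ValueError(f"need 1 <= C < N, got C={C}, N={n}")
    if method not in ("auto", "dense", "lanczos"):
        raise ValueError(f"unknown method {method!r}")

    if method == "dense" or (
        method == "auto" and (n <= _DENSE_CUTOFF or C > n // 2)
    ):
        evals, evecs = np.linalg.eigh(lap.toarray())
        evals, evecs = evals[:C], evecs[:, :C]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        evals, evecs = eigsh(lap.tocsc(), k=C, sigma=-1e-2, which="LM", v0=v0)
    order = np.argsort(evals)
    evals, evecs = evals[order], evecs[:, order]

    resid = np.linalg.norm(lap @ evecs - evecs * evals, axis=0)
    if np.any(resid > residual_tol):
        raise RuntimeError(
            f"eigenpair residuals up to {resid.max():.3e} exceed {residual_tol:.1e}"
        )
    return SpectralDecomposition(
        eigenvalues=evals, eigenvectors=_fix_signs(evecs), graph=graph
    )


def total_variation(lap: sparse.spmatrix, x: np.ndarray) -> float:
    """Total variation x^T L x of a graph signal (non-negative)."""
    x = np.asarray(x, dtype=float)
    return float(x @ (lap @ x))


def zero_crossings(graph: BrainGraph, u: np.ndarray) -> float:
    """Weighted zero-crossings: sum of a_ij over edges with sign(u_i) != sign(u_j).

    Each undirected edge counts once; an endpoint value of exactly zero
    contributes no crossing (strict sign opposition).
    """
    u = np.asarray(u, dtype=float)
    if len(u) != graph.n_nodes:
        raise ValueError("signal length must equal the node count")
    coo = sparse.triu(graph.adjacency, k=1).tocoo()
    crossing = u[coo.row] * u[coo.col] < 0
    return float(coo.data[crossing].sum())
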