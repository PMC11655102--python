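"""Assembly of the weighted voxel-wise brain graph.

Nodes are the voxels inside the brain mask; edges link lattice-adjacent
voxels under the chosen neighborhood scheme and carry the weight

    a_ij = [P(v_i) P(v_j) / alpha^2] * (p(i, r_ij)/beta_i + p(j, r_ji)/beta_j)

where P is the voxel's anisotropy (FA for the tensor route, QA for the
ODF route), alpha is the maximum anisotropy over the mask, and
beta_k = 2 * max over k's in-mask neighbors of p(k, .). The magnitude
factor suppresses edges through low-anisotropy tissue (e.g. WM-to-CSF)
while the orientation factor rewards coherent diffusion along the edge;
both factors — hence a_ij — lie in [0, 1]. The graph is restricted to
its largest connected component so the Laplacian spectral machinery
sees a single-connected graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .neighborhood import NeighborhoodScheme
from .weights import DiffusionProfile

logger = logging.getLogger(__name__)

__all__ = ["BrainGraph", "assemble_graph", "degrees"]


@dataclass
class BrainGraph:
    """Sparse weighted graph over in-mask voxels.

    Node order is lexicographic in (z, y, x) scan order, recorded in
    ``node_coords`` so 4D signal volumes map onto node vectors
    reproducibly. ``adjacency`` is exactly symmetric with zero diagonal
    and weights in [0, 1]; ``degrees`` are its row sums, strictly
    positive on the retained (single-connected) node set.
    """

    node_coords: np.ndarray
    adjacency: sparse.csr_matrix
    degrees: np.ndarray
    voxel_size: np.ndarray
    shape: tuple
    scheme_connectivity: int
    dropped_voxels: int = 0
    affine: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def node_index_volume(self) -> np.ndarray:
        """3D int volume mapping voxel -> node index (-1 off graph)."""
        vol = np.full(self.shape, -1, dtype=np.int64)
        c = self.node_coords
        vol[c[:, 0], c[:, 1], c[:, 2]] = np.arange(self.n_nodes)
        return vol

    def node_values(self, volume: np.ndarray) -> np.ndarray:
        """Extract a node-ordered vector (or (S, N) stack) from a 3D/4D volume."""
        c = self.node_coords
        if volume.ndim == 3:
            return volume[c[:, 0], c[:, 1], c[:, 2]]
        if volume.ndim == 4:
            return volume[c[:, 0], c[:, 1], c[:, 2], :].T
        raise ValueError("volume must be 3D or 4D")

    def scatter(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter node values back into a 3D (or 4D for 2D input) volume."""
        values = np.asarray(values)
        c = self.node_coords
        if values.ndim == 1:
            vol = np.full(self.shape, fill)
            vol[c[:, 0], c[:, 1], c[:, 2]] = values
        else:
            vol = np.full(self.shape + (values.shape[1],), fill)
            vol[c[:, 0], c[:, 1], c[:, 2], :] = values
        return vol

    def tissue_degree_means(self, labels: np.ndarray) -> dict:
        """Mean node degree per tissue label present on the graph."""
        node_labels = self.node_values(labels)
        return {
            int(lab): float(self.degrees[node_labels == lab].mean())
            for lab in np.unique(node_labels)
        }


def _scan_order(coords: np.ndarray) -> np.ndarray:
    # lexicographic in (z, y, x): z slowest
    return np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))


def assemble_graph(
    profile: DiffusionProfile,
    anisotropy: np.ndarray,
    mask: np.ndarray,
    scheme: NeighborhoodScheme | None = None,
    affine: np.ndarray | None = None,
) -> BrainGraph:
    """Build the weighted adjacency from a diffusion profile.

    Parameters
    ----------
    profile : DiffusionProfile
        Directional diffusion estimates for the in-mask voxels.
    anisotropy : 3D array in [0, 1]
        The magnitude map P (FA or QA), on the same grid as the mask.
    mask : 3D bool array
        Brain mask defining the node set.
    scheme : NeighborhoodScheme, optional
        Defaults to ``profile.scheme``.

    Notes
    -----
    alpha is the maximum anisotropy over the whole mask; beta_k is
    taken over each voxel's own in-mask neighbors. Voxels with an
    all-zero profile (beta = 0) or zero degree are dropped, then the
    largest connected component is kept; the total dropped count is
    recorded and logged.
    """
    scheme = scheme or profile.scheme
    anisotropy = np.asarray(anisotropy, dtype=float)
    if anisotropy.shape != mask.shape:
        raise ValueError("anisotropy and mask must share the same grid")
    if anisotropy.min() < 0 or anisotropy.max() > 1:
        raise ValueError("anisotropy must lie in [0, 1]")

    coords = profile.voxel_coords
    n = len(coords)
    p_mag = anisotropy[coords[:, 0], coords[:, 1], coords[:, 2]]
    alpha = p_mag.max() if n else 0.0
    if alpha == 0:
        raise ValueError("all-zero anisotropy over the mask (alpha = 0)")

    vals = profile.values
    present = profile.neighbor_present
    masked_vals = np.where(present, vals, -np.inf)
    beta = 2.0 * np.max(masked_vals, axis=1)
    usable = np.isfinite(beta) & (beta > 0)
    if not np.all(usable):
        logger.info("dropping %d voxels with empty/zero profiles", (~usable).sum())

    # voxel -> row lookup on the full grid
    row_of = np.full(mask.shape, -1, dtype=np.int64)
    row_of[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(n)

    # direct division by beta (not reciprocal multiplication) keeps the
    # saturated case p/(2*max p) exactly 0.5 in floating point
    beta_safe = np.where(usable, beta, 1.0)

    rows, cols, ww = [], [], []
    seen_pairs = set()
    for d, off in enumerate(scheme.offsets):
        key = tuple(off)
        if tuple(-np.asarray(off)) in seen_pairs:
            continue  # antipodal partner already emitted this undirected edge
        seen_pairs.add(key)
        d_opp = scheme.opposite_index(d)
        has = present[:, d] & usable
        i_idx = np.flatnonzero(has)
        if i_idx.size == 0:
            continue
        nb = coords[i_idx] + off
        j_idx = row_of[nb[:, 0], nb[:, 1], nb[:, 2]]
        ok = (j_idx >= 0) & usable[j_idx]
        i_idx, j_idx = i_idx[ok], j_idx[ok]
        orient = (
            vals[i_idx, d] / beta_safe[i_idx] + vals[j_idx, d_opp] / beta_safe[j_idx]
        )
        w = (p_mag[i_idx] * p_mag[j_idx] / alpha**2) * orient
        rows.append(i_idx)
        cols.append(j_idx)
        ww.append(w)

    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        ww = np.concatenate(ww)
    else:
        rows = cols = np.array([], dtype=int)
        ww = np.array([])
    upper = sparse.coo_matrix((ww, (rows, cols)), shape=(n, n))
    adj = (upper + upper.T).tocsr()
    adj.eliminate_zeros()

    deg = np.asarray(adj.sum(axis=1)).ravel()
    keep = deg > 0
    n_comp, labels = connected_components(adj[keep][:, keep], directed=False)
    comp_sizes = np.bincount(labels)
    in_big = labels == comp_sizes.argmax()
    keep_idx = np.flatnonzero(keep)[in_big]
    dropped = n - keep_idx.size
    if dropped:
        logger.info(
            "kept largest component: %d nodes, dropped %d voxels (%d components)",
            keep_idx.size,
            dropped,
            n_comp,
        )

    sub_coords = coords[keep_idx]
    order = _scan_order(sub_coords)
    keep_idx = keep_idx[order]
    adj = adj[keep_idx][:, keep_idx].tocsr()
    adj.sort_indices()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return BrainGraph(
        node_coords=coords[keep_idx],
        adjacency=adj,
        degrees=deg,
        voxel_size=np.asarray(scheme.voxel_size, dtype=float),
        shape=mask.shape,
        scheme_connectivity=scheme.connectivity,
        dropped_voxels=int(dropped),
        affine=affine,
    )


def degrees(graph: BrainGraph) -> np.ndarray:
    """Row sums of the adjacency (strictly positive on the retained nodes)."""
    return np.asarray(graph.adjacency.sum(axis=1)).ravel()
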