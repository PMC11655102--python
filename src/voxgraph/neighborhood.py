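"""Moore-neighborhood connectivity schemes on the 3D voxel lattice.

A voxel-wise brain graph links each voxel to its lattice neighbors. Two
schemes are supported: 3-connectivity (the 3x3x3 Moore neighborhood, 26
directions) and 5-connectivity (the 5x5x5 neighborhood with outer-shell
offsets that are parallel to an inner offset removed, 98 directions).
The 5-connectivity scheme trades spatial localization for finer angular
resolution of fiber orientations.

Each scheme direction subtends an equal share of the sphere: a solid
angle of 4*pi/26 or 4*pi/98 steradians, used downstream to define the
spherical caps over which ODF amplitudes are averaged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NeighborhoodScheme", "build_scheme"]


@dataclass(frozen=True)
class NeighborhoodScheme:
    """Lattice offsets, physical unit directions and per-direction solid angle.

    Attributes
    ----------
    connectivity : int
        3 or 5.
    offsets : (M, 3) int array
        Lattice steps to each neighbor; closed under negation, no two
        offsets positive multiples of each other. M is 26 or 98.
    directions : (M, 3) float array
        Unit vectors in physical (mm) space: ``offsets * voxel_size``
        normalized. With anisotropic voxels these differ from the
        normalized lattice offsets.
    voxel_size : (3,) float array
        Voxel edge lengths in mm.
    solid_angle : float
        Steradians allotted to each direction: ``4*pi / M``.
    """

    connectivity: int
    offsets: np.ndarray
    directions: np.ndarray
    voxel_size: np.ndarray
    solid_angle: float
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        lookup = {tuple(int(c) for c in off): i for i, off in enumerate(self.offsets)}
        object.__setattr__(self, "_index", lookup)

    def __len__(self) -> int:
        return len(self.offsets)

    def index_of(self, offset) -> int:
        """Index of a lattice offset within the scheme."""
        return self._index[tuple(int(c) for c in offset)]

    def opposite_index(self, i: int) -> int:
        """Index of the antipodal direction -offset[i]."""
        return self._index[tuple(int(-c) for c in self.offsets[i])]

    @property
    def cap_cos_threshold(self) -> float:
        """Cosine of the cap half-angle theta solving 2*pi*(1-cos theta) = solid_angle."""
        return 1.0 - self.solid_angle / (2.0 * np.pi)

    def to_table(self) -> np.ndarray:
        """Plain (M, 7) table: offset triplet, unit direction, solid angle."""
        return np.column_stack(
            [
                self.offsets.astype(float),
                self.directions,
                np.full(len(self), self.solid_angle),
            ]
        )


def _is_parallel_to_inner(offset: tuple) -> bool:
    # an outer offset is "parallel" iff it is a positive integer multiple of an
    # inner (Chebyshev-norm-1) offset; on the 5x5x5 shell that means 2*inner
    arr = np.array(offset)
    if np.max(np.abs(arr)) != 2:
        return False
    half = arr / 2
    return np.allclose(half, np.round(half))


def build_scheme(connectivity: int, voxel_size=(1.0, 1.0, 1.0)) -> NeighborhoodScheme:
    """Build the 3- or 5-connectivity Moore neighborhood scheme.

    Parameters
    ----------
    connectivity : {3, 5}
        Moore neighborhood edge length. 3 keeps all 26 nonzero offsets
        with components in {-1, 0, 1}; 5 adds the 5x5x5 outer shell but
        drops outer offsets that are positive scalar multiples of an
        inner offset (they encode no new direction), leaving 98.
    voxel_size : sequence of 3 floats
        Physical voxel edge lengths (mm), all strictly positive. Used
        only for the `directions`; lattice adjacency ignores it.

    Returns
    -------
    NeighborhoodScheme

    Raises
    ------
    ValueError
        If connectivity is not 3 or 5, or voxel_size is not positive.
    """
    if connectivity not in (3, 5):
        raise ValueError(f"connectivity must be 3 or 5, got {connectivity!r}")
    voxel_size = np.asarray(voxel_size, dtype=float)
    if voxel_size.shape != (3,) or np.any(voxel_size <= 0):
        raise ValueError("voxel_size must be 3 strictly positive floats")

    inner = [off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)]
    if connectivity == 3:
        offsets = inner
    else:
        outer = [
            off
            for off in itertools.product(range(-2, 3), repeat=3)
            if max(abs(c) for c in off) == 2 and not _is_parallel_to_inner(off)
        ]
        offsets = inner + outer

    offsets = np.array(sorted(offsets), dtype=int)
    phys = offsets * voxel_size
    directions = phys / np.linalg.norm(phys, axis=1, keepdims=True)
    solid_angle = 4.0 * np.pi / len(offsets)
    return NeighborhoodScheme(
        connectivity=connectivity,
        offsets=offsets,
        directions=directions,
        voxel_size=voxel_size,
        solid_angle=solid_angle,
    )
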