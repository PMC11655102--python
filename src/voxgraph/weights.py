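"""Per-voxel, per-direction diffusion estimates p(i, r_ij).

Two routes produce the directional diffusion profile that feeds the
edge weights of a voxel-wise brain graph:

* DTI route — the per-voxel tensor T is read as the covariance of a 3D
  Gaussian displacement distribution and evaluated at each neighbor's
  physical displacement r:
  p = (2*pi)^(-3/2) |T|^(-1/2) exp(-r^T T^{-1} r / 2).

* ODF route — the per-voxel ODF, sampled at N_o unit directions, is
  averaged (after sharpening with a power n) over the spherical cap of
  solid angle Omega around each neighbor direction:
  p = mean over cap members of amplitude^n.

The cap half-angle theta solves the exact cap-area equation
2*pi*(1 - cos theta) = Omega, with Omega = 4*pi/26 or 4*pi/98 from the
neighborhood scheme; caps of nearby directions may overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neighborhood import NeighborhoodScheme

__all__ = [
    "DiffusionProfile",
    "CapMembership",
    "dti_profile",
    "cap_membership",
    "odf_profile",
]


@dataclass
class DiffusionProfile:
    """Directional diffusion estimates for every in-mask voxel.

    ``values[v, d]`` is p(i, r_ij) for in-mask voxel v (in the order of
    ``voxel_coords``) and scheme direction d. ``neighbor_present[v, d]``
    flags whether the neighbor voxel in direction d exists (inside the
    grid and the mask); values at absent neighbors are still defined by
    the local tensor/ODF but carry no edge.
    """

    values: np.ndarray
    neighbor_present: np.ndarray
    voxel_coords: np.ndarray
    scheme: NeighborhoodScheme


@dataclass
class CapMembership:
    """For each scheme direction, indices of ODF samples inside its cap."""

    members: list
    scheme: NeighborhoodScheme
    cos_threshold: float

    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])


def _neighbor_presence(mask: np.ndarray, coords: np.ndarray, scheme) -> np.ndarray:
    """(n_voxels, n_dirs) bool: neighbor at coords+offset is in-grid and in-mask."""
    shape = np.array(mask.shape)
    present = np.empty((len(coords), len(scheme)), dtype=bool)
    for d, off in enumerate(scheme.offsets):
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        inside = np.zeros(len(coords), dtype=bool)
        inside[ok] = mask[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
        present[:, d] = inside
    return present


def dti_profile(field, scheme: NeighborhoodScheme) -> DiffusionProfile:
    """Gaussian diffusion profile from a tensor field.

    Evaluates the zero-mean trivariate Gaussian with the voxel's tensor
    as covariance at each neighbor's physical displacement
    r = offset * voxel_size (mm) — the displacement's true length
    enters, so outer-shell neighbors of the 5-connectivity scheme are
    damped by their extra distance.

    Raises
    ------
    ValueError
        If any in-mask tensor is singular or not positive definite; the
        offending voxel coordinates are reported.
    """
    mask = field.phantom.mask
    coords = np.argwhere(mask)
    mats = field.full_matrices()[mask]  # (n, 3, 3)

    try:
        np.linalg.cholesky(mats)
    except np.linalg.LinAlgError:
        evals = np.linalg.eigvalsh(mats)
        bad = coords[np.min(evals, axis=1) <= 0]
        raise ValueError(
            f"non-positive-definite tensors at {len(bad)} in-mask voxels, "
            f"first at voxel {tuple(bad[0])}"
        ) from None

    disp = scheme.offsets * scheme.voxel_size  # (n_dirs, 3), mm
    det = np.linalg.det(mats)
    inv = np.linalg.inv(mats)
    # quadratic form r^T T^{-1} r for every voxel x direction
    q = np.einsum("di,nij,dj->nd", disp, inv, disp)
    norm = (2.0 * np.pi) ** (-1.5) / np.sqrt(det)
    values = norm[:, None] * np.exp(-0.5 * q)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite diffusion profile values (degenerate tensor?)")
    present = _neighbor_presence(mask, coords, scheme)
    return DiffusionProfile(
        values=values, neighbor_present=present, voxel_coords=coords, scheme=scheme
    )


def cap_membership(
    sample_directions: np.ndarray, scheme: NeighborhoodScheme
) -> CapMembership:
    """Assign ODF sample directions to each scheme direction's spherical cap.

    Sample k belongs to direction d's cap iff the angle between them is
    at most arccos(1 - Omega/(2*pi)), i.e. the cap of area Omega on the
    unit sphere. Caps may overlap; every cap must be non-empty.

    Raises
    ------
    ValueError
        If a cap is empty (the sample set is too sparse for the
        scheme), naming the offending direction.
    """
    dirs = np.asarray(sample_directions, dtype=float)
    norms = np.linalg.norm(dirs, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("sample directions must be unit-norm")
    thr = scheme.cap_cos_threshold
    cos = dirs @ scheme.directions.T  # (N_o, n_dirs)
    members = []
    for d in range(len(scheme)):
        idx = np.flatnonzero(cos[:, d] >= thr - 1e-12)
        if idx.size == 0:
            raise ValueError(
                f"empty spherical cap for scheme direction {tuple(scheme.offsets[d])}; "
                "increase the number of ODF sample directions"
            )
        members.append(idx)
    return CapMembership(members=members, scheme=scheme, cos_threshold=thr)


def odf_profile(
    field, scheme: NeighborhoodScheme, exponent_n: float = 2.0
) -> DiffusionProfile:
    """Cap-averaged, power-sharpened diffusion profile from an ODF field.

    p(i, r_ij) = (1/|D_ij|) * sum over cap members k of O_{i,k}^n,
    where D_ij indexes the ODF samples inside the cap around the
    neighbor direction; the cardinality normalization compensates for
    unequal sample counts across caps. The power n > 0 sharpens peaks
    (ODFs discriminate fiber orientations only weakly).
    """
    if exponent_n <= 0:
        raise ValueError("exponent_n must be > 0")
    mask = field.phantom.mask
    coords = np.argwhere(mask)
    amps = field.amplitudes[mask]  # (n, N_o)
    if np.any(amps < 0):
        raise ValueError("negative ODF amplitudes inside the mask")
    caps = cap_membership(field.directions, scheme)
    powered = amps**exponent_n
    values = np.empty((len(coords), len(scheme)))
    for d, idx in enumerate(caps.members):
        values[:, d] = powered[:, idx].mean(axis=1)
    present = _neighbor_presence(mask, coords, scheme)
    return DiffusionProfile(
        values=values, neighbor_present=present, voxel_coords=coords, scheme=scheme
    )
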