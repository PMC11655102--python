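"""Synthetic diffusion phantoms and graph-signal generators.

Desk-scale stand-ins for the inputs a voxel-wise brain-graph analysis
consumes: a three-tissue labeled volume (GM/WM/CSF) with an anisotropy
map, per-voxel diffusion tensor or ODF fields containing one coherent
fiber bundle in an isotropic background, multi-subject cohorts of such
fields on a shared grid, and time series of graph signals with a
prescribed graph-spectral energy profile.

All generators are deterministic given their seed. Tissue contrast is
built in: white-matter voxels carry strictly higher anisotropy than
gray matter and CSF, so that downstream graphs reproduce the expected
ordering of node degrees across tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "TissuePhantom",
    "TensorField",
    "ODFField",
    "GraphSignalSet",
    "make_tissue_phantom",
    "make_tensor_field",
    "make_odf_field",
    "make_graph_signals",
    "make_cohort",
    "fa_from_eigenvalues",
    "sphere_directions",
]

LABEL_OUTSIDE, LABEL_GM, LABEL_WM, LABEL_CSF = 0, 1, 2, 3

# background tissue anisotropy baselines (dimensionless, in [0,1])
_GM_ANISO = 0.12
_CSF_ANISO = 0.05
_ANISO_NOISE_SD = 0.015


class GeometryError(ValueError):
    """Raised when a requested phantom geometry does not fit its grid."""


@dataclass
class TissuePhantom:
    """Labeled tissue volume with anisotropy map.

    labels: 0=outside, 1=GM, 2=WM, 3=CSF. ``anisotropy`` plays the role
    of the FA/QA magnitude map in the edge-weight definition: zero
    outside the mask, high inside the fiber bundle.
    """

    labels: np.ndarray
    voxel_size: np.ndarray
    anisotropy: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def shape(self) -> tuple:
        return self.labels.shape


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors, 6 lower-triangular components.

    Component order along the last axis: Txx, Txy, Tyy, Txz, Tyz, Tzz.
    Every in-mask tensor is symmetric positive definite.
    """

    tensors: np.ndarray
    phantom: TissuePhantom

    def full_matrices(self) -> np.ndarray:
        """(X, Y, Z, 3, 3) symmetric matrices."""
        t = self.tensors
        xx, xy, yy, xz, yz, zz = (t[..., i] for i in range(6))
        return np.stack(
            [
                np.stack([xx, xy, xz], axis=-1),
                np.stack([xy, yy, yz], axis=-1),
                np.stack([xz, yz, zz], axis=-1),
            ],
            axis=-2,
        )

    def fa_map(self) -> np.ndarray:
        """Fractional anisotropy from tensor eigenvalues, zero outside mask."""
        mats = self.full_matrices()[self.phantom.mask]
        evals = np.linalg.eigvalsh(mats)
        fa = np.zeros(self.phantom.shape)
        fa[self.phantom.mask] = fa_from_eigenvalues(evals)
        return fa


@dataclass
class ODFField:
    """Per-voxel ODF sample amplitudes over a fixed direction table.

    ``amplitudes`` has shape (X, Y, Z, N_o); ``directions`` is (N_o, 3)
    unit rows covering the full sphere, closed under negation so the
    ODFs' antipodal symmetry is explicit.
    """

    amplitudes: np.ndarray
    directions: np.ndarray
    phantom: TissuePhantom


@dataclass
class GraphSignalSet:
    """A stack of graph signals: ``signals`` is (S, N), node-ordered."""

    signals: np.ndarray

    @property
    def frame_count(self) -> int:
        return self.signals.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.signals.shape[1]


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Standard fractional anisotropy of diffusion-tensor eigenvalues.

    FA = sqrt(1/2) * sqrt(sum of squared pairwise eigenvalue
    differences) / sqrt(sum of squared eigenvalues), in [0, 1].
    """
    evals = np.asarray(evals, dtype=float)
    l1, l2, l3 = evals[..., 0], evals[..., 1], evals[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5 * num / den)
    return np.nan_to_num(fa)


def _ratio_from_fa(fa):
    """Axial/radial eigenvalue ratio of a prolate tensor with the given FA."""
    fa = np.clip(np.asarray(fa, dtype=float), 0.0, 0.99)
    # solve (rho-1)^2 = fa^2 (rho^2 + 2) for rho >= 1
    return (1.0 + fa * np.sqrt(3.0 - 2.0 * fa**2)) / (1.0 - fa**2)


def sphere_directions(n: int) -> np.ndarray:
    """Antipodally symmetric set of ``n`` (even) unit vectors.

    A Fibonacci spiral covers one hemisphere; the antipodes complete
    the sphere, so u in the set iff -u is.
    """
    if n % 2:
        raise ValueError("n must be even for an antipodally symmetric table")
    m = n // 2
    k = np.arange(m)
    # golden-angle spiral over the upper hemisphere (z in (0, 1])
    z = 1.0 - k / m
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    hemi = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    hemi /= np.linalg.norm(hemi, axis=1, keepdims=True)
    return np.vstack([hemi, -hemi])


def make_tissue_phantom(
    shape,
    voxel_size=(1.0, 1.0, 1.0),
    bundle_axis: int = 0,
    bundle_radius: float = 3.0,
    bundle_anisotropy: float = 0.8,
    seed: int = 0,
) -> TissuePhantom:
    """Three-tissue phantom: a WM cylinder in GM with a CSF rim.

    The outermost voxel layer is outside the mask, the next layer is
    CSF, the interior is GM, and a straight cylindrical bundle of WM
    with the given radius runs through the volume center along
    ``bundle_axis``. Anisotropy is ``bundle_anisotropy`` (plus small
    noise) in the bundle and low elsewhere.

    Raises
    ------
    GeometryError
        If the bundle does not fit inside the GM interior.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise GeometryError(f"shape must be 3 components each >= 8, got {shape}")
    if bundle_axis not in (0, 1, 2):
        raise ValueError("bundle_axis must be 0, 1 or 2")
    cross = [shape[a] for a in range(3) if a != bundle_axis]
    # interior excludes 1 outside + 1 CSF layer on each side
    if bundle_radius >= min(cross) / 2 - 2:
        raise GeometryError(
            f"bundle radius {bundle_radius} does not fit in cross-section {cross}"
        )

    rng = np.random.default_rng(seed)
    labels = np.full(shape, LABEL_GM, dtype=np.int16)
    # outside shell, then CSF rim
    border = np.zeros(shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        border[tuple(sl)] = True
        sl[ax] = shape[ax] - 1
        border[tuple(sl)] = True
    labels[border] = LABEL_OUTSIDE
    interior = ~border
    rim = interior & ~ndimage.binary_erosion(interior)
    labels[rim] = LABEL_CSF

    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    center = [(s - 1) / 2 for s in shape]
    d2 = sum(
        (grids[a] - center[a]) ** 2 for a in range(3) if a != bundle_axis
    )
    bundle = (d2 <= bundle_radius**2) & (labels == LABEL_GM)
    labels[bundle] = LABEL_WM

    base = np.zeros(shape)
    base[labels == LABEL_GM] = _GM_ANISO
    base[labels == LABEL_CSF] = _CSF_ANISO
    base[labels == LABEL_WM] = bundle_anisotropy
    noise = rng.normal(0.0, _ANISO_NOISE_SD, size=shape)
    aniso = np.clip(base + noise, 0.01, 1.0)
    aniso[labels == LABEL_OUTSIDE] = 0.0
    return TissuePhantom(
        labels=labels,
        voxel_size=np.asarray(voxel_size, dtype=float),
        anisotropy=aniso,
    )


def _unit(v, name="bundle_direction"):
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"{name} must be nonzero")
    if abs(norm - 1.0) > 1e-8:
        logger.warning("%s not unit-norm (|v|=%.4g); normalizing", name, norm)
    return v / norm


def _jittered_directions(base_dirs: np.ndarray, jitter_sd: float, rng) -> np.ndarray:
    """Perturb each unit row of base_dirs by ~jitter_sd radians."""
    if jitter_sd == 0:
        return base_dirs
    out = base_dirs + jitter_sd * rng.standard_normal(base_dirs.shape)
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def make_tensor_field(
    phantom: TissuePhantom,
    bundle_direction=(1.0, 0.0, 0.0),
    eigenvalue_ratio: float = 5.0,
    seed: int = 0,
    orientation_jitter_sd: float = 0.03,
    direction_field: np.ndarray | None = None,
) -> TensorField:
    """Per-voxel prolate diffusion tensors for a phantom.

    In-bundle (WM) tensors are axially symmetric with axial/radial
    eigenvalue ratio ``eigenvalue_ratio`` and principal axis along
    ``bundle_direction`` (with small per-voxel angular jitter).
    Background tensors are near-isotropic, with a ratio chosen so their
    FA matches the phantom's anisotropy map, and randomly oriented.
    All tensors share unit mean diffusivity (trace 3; the physical
    diffusivity scale is irrelevant to the edge weights, which
    normalize it out).

    ``direction_field`` (X, Y, Z, 3), if given, overrides the constant
    bundle direction per voxel (used for cohort perturbations).
    """
    if eigenvalue_ratio <= 1:
        raise ValueError("eigenvalue_ratio must be > 1")
    mu = _unit(bundle_direction)
    rng = np.random.default_rng(seed)
    shape = phantom.shape
    mask = phantom.mask
    wm = phantom.labels == LABEL_WM

    axes = np.empty(shape + (3,))
    axes[...] = mu
    if direction_field is not None:
        axes = np.array(direction_field, dtype=float)
        axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
    axes[wm] = _jittered_directions(axes[wm], orientation_jitter_sd, rng)
    bg = mask & ~wm
    axes[bg] = _jittered_directions(
        rng.standard_normal((int(bg.sum()), 3)), 0.0, rng
    ) / 1.0  # random orientations, normalized below
    axes[bg] /= np.linalg.norm(axes[bg], axis=-1, keepdims=True)

    ratio = np.ones(shape)
    ratio[wm] = eigenvalue_ratio
    ratio[bg] = _ratio_from_fa(phantom.anisotropy[bg])

    # prolate tensor l_perp*(I + (rho-1) e e^T), scaled to trace 3
    l_perp = 3.0 / (ratio + 2.0)
    e = axes
    outer = e[..., :, None] * e[..., None, :]
    eye = np.eye(3)
    mats = l_perp[..., None, None] * (
        eye + (ratio - 1.0)[..., None, None] * outer
    )
    tensors = np.zeros(shape + (6,))
    tensors[..., 0] = mats[..., 0, 0]
    tensors[..., 1] = mats[..., 0, 1]
    tensors[..., 2] = mats[..., 1, 1]
    tensors[..., 3] = mats[..., 0, 2]
    tensors[..., 4] = mats[..., 1, 2]
    tensors[..., 5] = mats[..., 2, 2]
    tensors[~mask] = 0.0
    return TensorField(tensors=tensors, phantom=phantom)


def make_odf_field(
    phantom: TissuePhantom,
    bundle_direction=(1.0, 0.0, 0.0),
    sharpness: float = 8.0,
    n_directions: int = 120,
    seed: int = 0,
    orientation_jitter_sd: float = 0.03,
    direction_field: np.ndarray | None = None,
) -> ODFField:
    """Per-voxel ODF samples: Watson-kernel bundle, flat background.

    In-bundle ODF amplitude along unit direction u is
    ``exp(sharpness * ((u . mu)^2 - 1))``, antipodally symmetric and
    peaked at +/-mu; background voxels get the constant ODF. Sample
    directions form an antipodally symmetric table of ``n_directions``
    unit vectors (>= 60 so no neighborhood cap is empty).
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be > 0")
    if n_directions < 60:
        raise ValueError(
            "n_directions must be >= 60 for adequate spherical-cap coverage"
        )
    if n_directions % 2:
        n_directions += 1
    mu = _unit(bundle_direction)
    rng = np.random.default_rng(seed)
    dirs = sphere_directions(n_directions)
    shape = phantom.shape
    mask = phantom.mask
    wm = phantom.labels == LABEL_WM

    amplitudes = np.zeros(shape + (n_directions,))
    amplitudes[mask] = 1.0

    if direction_field is not None:
        peak = np.array(direction_field, dtype=float)[wm]
        peak /= np.linalg.norm(peak, axis=-1, keepdims=True)
    else:
        peak = np.empty((int(wm.sum()), 3))
        peak[...] = mu
    peak = _jittered_directions(peak, orientation_jitter_sd, rng)
    cos2 = (peak @ dirs.T) ** 2  # (n_wm, N_o)
    amplitudes[wm] = np.exp(sharpness * (cos2 - 1.0))
    return ODFField(amplitudes=amplitudes, directions=dirs, phantom=phantom)


def make_graph_signals(
    decomp,
    spectral_exponent: float = 2.0,
    num_frames: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GraphSignalSet:
    """Random graph signals with a power-law graph-spectral energy profile.

    Each frame is a random linear combination of the decomposition's
    eigenmodes with coefficient standard deviation proportional to
    ``i**(-spectral_exponent/2)`` for 1-based mode index i >= 2 (mode 1,
    the degree-shaped constant mode, gets no energy — it is regressed
    out downstream anyway), plus white Gaussian node-space noise of
    standard deviation ``noise_sd``. This mimics the power-law energy
    spectral density that functional MRI signals exhibit on brain
    graphs.
    """
    if decomp.C < 2:
        raise ValueError("decomposition must hold at least 2 modes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    U = decomp.eigenvectors
    n, c = U.shape
    idx = np.arange(1, c + 1, dtype=float)
    sd = idx ** (-spectral_exponent / 2.0)
    sd[0] = 0.0
    coeffs = rng.standard_normal((num_frames, c)) * sd
    signals = coeffs @ U.T
    if noise_sd > 0:
        signals = signals + noise_sd * rng.standard_normal((num_frames, n))
    return GraphSignalSet(signals=signals)


def make_cohort(
    base_phantom_args: dict,
    num_subjects: int = 5,
    perturbation_sd: float = 0.05,
    seed: int = 0,
    model: str = "odf",
    field_args: dict | None = None,
):
    """Multi-subject cohort of diffusion fields on one shared grid.

    Each subject is the base field with smooth random perturbations of
    the anisotropy map and of the bundle peak directions, both of scale
    ``perturbation_sd``; zero perturbation yields identical subjects.
    Sharing the grid makes inter-subject alignment the identity, which
    isolates eigenmode matching from registration error.

    Returns a list of ``ODFField`` (model="odf") or ``TensorField``
    (model="dti").
    """
    if num_subjects < 2:
        raise ValueError("num_subjects must be >= 2")
    if model not in ("odf", "dti"):
        raise ValueError("model must be 'odf' or 'dti'")
    field_args = dict(field_args or {})
    bundle_direction = _unit(field_args.pop("bundle_direction", (1.0, 0.0, 0.0)))
    field_seed = field_args.pop("seed", seed)

    base = make_tissue_phantom(**base_phantom_args)
    rng = np.random.default_rng(seed)
    shape = base.shape
    fields = []
    for _ in range(num_subjects):
        # smooth (correlation length ~2 voxels), unit-sd perturbation fields
        aniso_noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        aniso_noise /= max(aniso_noise.std(), 1e-12)
        # floor keeps every in-mask voxel weight-positive, so all subjects'
        # graphs retain the identical node set (required for matching)
        aniso = np.clip(base.anisotropy + perturbation_sd * aniso_noise, 0.01, 1.0)
        aniso[~base.mask] = 0.0
        subj_phantom = TissuePhantom(
            labels=base.labels, voxel_size=base.voxel_size, anisotropy=aniso
        )
        dir_noise = np.stack(
            [
                ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
                for _ in range(3)
            ],
            axis=-1,
        )
        dir_noise /= max(dir_noise.std(), 1e-12)
        dir_field = np.empty(shape + (3,))
        dir_field[...] = bundle_direction
        dir_field = dir_field + perturbation_sd * dir_noise
        dir_field /= np.linalg.norm(dir_field, axis=-1, keepdims=True)
        if model == "odf":
            fields.append(
                make_odf_field(
                    subj_phantom,
                    bundle_direction=bundle_direction,
                    seed=field_seed,
                    direction_field=dir_field,
                    **field_args,
                )
            )
        else:
            fields.append(
                make_tensor_field(
                    subj_phantom,
                    bundle_direction=bundle_direction,
                    seed=field_seed,
                    direction_field=dir_field,
                    **field_args,
                )
            )
    return fields
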