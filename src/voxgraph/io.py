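"""Readers and writers for the formats the pipeline touches.

Volumes travel as NIfTI-1 (via nibabel, affine preserved); the sparse
adjacency as Matrix Market symmetric coordinate format; node tables,
direction tables, spectra and error statistics as whitespace-delimited
plain text. Companion volumes must share both grid and affine — silent
misalignment is the classic failure mode in voxel-wise work, so the
check is strict (1e-4 on affine entries) and errors name both files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import io as sio
from scipy import sparse

from .graph import BrainGraph
from .phantom import ODFField, TensorField, TissuePhantom
from .spectral import SpectralDecomposition

__all__ = [
    "read_volume",
    "write_volume",
    "check_same_grid",
    "save_phantom",
    "load_phantom",
    "write_graph",
    "read_graph",
    "write_spectrum",
    "read_spectrum",
    "write_energy_spectrum",
    "write_scheme_table",
    "eigenvectors_to_nifti",
]

# lower-triangular component order for 4D tensor volumes
TENSOR_COMPONENTS = ("Txx", "Txy", "Tyy", "Txz", "Tyz", "Tzz")


def _affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    return aff


def read_volume(path):
    """Load a NIfTI volume.

    Returns
    -------
    data : ndarray
    voxel_size : (3,) float array, from the header zooms
    affine : (4, 4) array
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel_size = np.array(img.header.get_zooms()[:3], dtype=float)
    return data, voxel_size, img.affine


def write_volume(path, data, voxel_size=(1.0, 1.0, 1.0), affine=None):
    """Write an array as NIfTI-1 with the given voxel size / affine."""
    if affine is None:
        affine = _affine_from_voxel_size(voxel_size)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_size) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def check_same_grid(path_a, vol_a, aff_a, path_b, vol_b, aff_b, atol=1e-4):
    """Raise if two companion volumes disagree on grid or affine."""
    if vol_a.shape[:3] != vol_b.shape[:3]:
        raise ValueError(
            f"grid mismatch between {path_a} {vol_a.shape[:3]} "
            f"and {path_b} {vol_b.shape[:3]}"
        )
    if not np.allclose(aff_a, aff_b, atol=atol):
        raise ValueError(f"affine mismatch between {path_a} and {path_b}")


def save_phantom(out_dir, phantom: TissuePhantom, field=None):
    """Write a phantom (and optional tensor/ODF field) as NIfTI + text.

    Files: labels.nii.gz, anisotropy.nii.gz, and either tensors.nii.gz
    (6 volumes, lower-triangular order Txx Txy Tyy Txz Tyz Tzz) or
    odf.nii.gz (N_o volumes) with directions.txt (N_o rows x 3 cols).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vs = phantom.voxel_size
    write_volume(out_dir / "labels.nii.gz", phantom.labels.astype(np.int16), vs)
    write_volume(out_dir / "anisotropy.nii.gz", phantom.anisotropy, vs)
    if isinstance(field, TensorField):
        write_volume(out_dir / "tensors.nii.gz", field.tensors, vs)
    elif isinstance(field, ODFField):
        write_volume(out_dir / "odf.nii.gz", field.amplitudes, vs)
        np.savetxt(out_dir / "directions.txt", field.directions, fmt="%.17g")
    elif field is not None:
        raise TypeError(f"unsupported field type {type(field).__name__}")
    return out_dir


def load_phantom(out_dir, model=None):
    """Read back a saved phantom; returns (TissuePhantom, field-or-None)."""
    out_dir = Path(out_dir)
    labels, vs, aff_l = read_volume(out_dir / "labels.nii.gz")
    aniso, _, aff_a = read_volume(out_dir / "anisotropy.nii.gz")
    check_same_grid("labels.nii.gz", labels, aff_l, "anisotropy.nii.gz", aniso, aff_a)
    phantom = TissuePhantom(
        labels=labels.astype(np.int16), voxel_size=vs, anisotropy=aniso
    )
    field = None
    if model == "dti" or (model is None and (out_dir / "tensors.nii.gz").exists()):
        tensors, _, aff_t = read_volume(out_dir / "tensors.nii.gz")
        check_same_grid(
            "labels.nii.gz", labels, aff_l, "tensors.nii.gz", tensors, aff_t
        )
        if tensors.ndim != 4 or tensors.shape[3] != 6:
            raise ValueError(
                f"tensor volume must hold 6 components, got shape {tensors.shape}"
            )
        field = TensorField(tensors=tensors, phantom=phantom)
    elif model == "odf" or (model is None and (out_dir / "odf.nii.gz").exists()):
        amps, _, aff_o = read_volume(out_dir / "odf.nii.gz")
        check_same_grid("labels.nii.gz", labels, aff_l, "odf.nii.gz", amps, aff_o)
        directions = np.loadtxt(out_dir / "directions.txt", ndmin=2)
        if amps.ndim != 4 or amps.shape[3] != directions.shape[0]:
            raise ValueError(
                f"ODF volume count {amps.shape[-1] if amps.ndim == 4 else 'n/a'} "
                f"does not match direction table rows {directions.shape[0]}"
            )
        field = ODFField(amplitudes=amps, directions=directions, phantom=phantom)
    return phantom, field


def write_graph(graph: BrainGraph, out_dir):
    """Persist a graph: adjacency.mtx (symmetric), nodes.txt, degrees.txt, meta.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(
        out_dir / "adjacency.mtx",
        sparse.coo_matrix(graph.adjacency),
        field="real",
        precision=17,
        symmetry="symmetric",
    )
    nodes = np.column_stack([np.arange(graph.n_nodes), graph.node_coords])
    np.savetxt(out_dir / "nodes.txt", nodes, fmt="%d")
    np.savetxt(out_dir / "degrees.txt", graph.degrees, fmt="%.17g")
    meta = {
        "voxel_size": graph.voxel_size.tolist(),
        "shape": list(graph.shape),
        "scheme_connectivity": graph.scheme_connectivity,
        "dropped_voxels": graph.dropped_voxels,
        "affine": None if graph.affine is None else np.asarray(graph.affine).tolist(),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1))
    return out_dir


def read_graph(out_dir) -> BrainGraph:
    """Load a persisted graph; verifies the adjacency is symmetric."""
    out_dir = Path(out_dir)
    adj = sparse.csr_matrix(sio.mmread(out_dir / "adjacency.mtx"))
    if (adj != adj.T).nnz:
        raise ValueError(f"{out_dir / 'adjacency.mtx'} is not symmetric")
    adj.sort_indices()
    nodes = np.loadtxt(out_dir / "nodes.txt", dtype=int, ndmin=2)
    if nodes.shape[0] != adj.shape[0]:
        raise ValueError("node table row count does not match adjacency dimension")
    meta = json.loads((out_dir / "meta.json").read_text())
    return BrainGraph(
        node_coords=nodes[:, 1:4],
        adjacency=adj,
        degrees=np.asarray(adj.sum(axis=1)).ravel(),
        voxel_size=np.array(meta["voxel_size"]),
        shape=tuple(meta["shape"]),
        scheme_connectivity=meta["scheme_connectivity"],
        dropped_voxels=meta["dropped_voxels"],
        affine=None if meta["affine"] is None else np.array(meta["affine"]),
    )


def write_spectrum(decomp: SpectralDecomposition, out_dir, graph=None):
    """Write eigenvalues as text, eigenvectors as .npy and (optionally) NIfTI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "eigenvalues.txt", decomp.eigenvalues, fmt="%.17g")
    np.save(out_dir / "eigenvectors.npy", decomp.eigenvectors)
    graph = graph or decomp.graph
    if graph is not None:
        write_volume(
            out_dir / "eigenmodes.nii.gz",
            eigenvectors_to_nifti_array(graph, decomp.eigenvectors),
            graph.voxel_size,
            affine=graph.affine,
        )
    return out_dir


def read_spectrum(out_dir, graph=None) -> SpectralDecomposition:
    out_dir = Path(out_dir)
    return SpectralDecomposition(
        eigenvalues=np.loadtxt(out_dir / "eigenvalues.txt", ndmin=1),
        eigenvectors=np.load(out_dir / "eigenvectors.npy"),
        graph=graph,
    )


def eigenvectors_to_nifti_array(graph: BrainGraph, vectors: np.ndarray) -> np.ndarray:
    """4D array, one volume per mode, node values scattered to voxels."""
    return graph.scatter(vectors)


def eigenvectors_to_nifti(graph: BrainGraph, vectors: np.ndarray, path):
    write_volume(
        path, eigenvectors_to_nifti_array(graph, vectors), graph.voxel_size,
        affine=graph.affine,
    )


def write_energy_spectrum(spectrum, path):
    """Plain-text table: 1-based spectral index, EESD, cumulative EESD."""
    idx = np.arange(1, spectrum.C + 1)
    table = np.column_stack([idx, spectrum.eesd, spectrum.cumulative])
    np.savetxt(
        path, table, fmt=("%d", "%.17g", "%.17g"), header="index eesd cumulative"
    )


def write_scheme_table(scheme, path):
    """Plain-text scheme export: offset triplet, unit direction, solid angle."""
    np.savetxt(
        path,
        scheme.to_table(),
        fmt=["%d"] * 3 + ["%.17g"] * 4,
        header="ox oy oz dx dy dz solid_angle",
    )


def write_error_stats(stats, path):
    """Plain-text table: K, mu, sigma, draws."""
    np.savetxt(
        path, stats.as_table(), fmt=("%d", "%.17g", "%.17g", "%d"),
        header="K mu sigma draws",
    )
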