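import numpy as np
import pytest

import voxgraph as vg


@pytest.fixture(scope="session")
def scheme3():
    return vg.build_scheme(3)


@pytest.fixture(scope="session")
def scheme5():
    return vg.build_scheme(5)


@pytest.fixture(scope="session")
def phantom12():
    """Small standard phantom: 12^3 grid, bundle along x."""
    return vg.make_tissue_phantom((12, 12, 12), bundle_axis=0, bundle_radius=3.0, seed=1)


@pytest.fixture(scope="session")
def dti_graph12(phantom12, scheme3):
    """DTI-3 graph on the 12^3 phantom (~1000 nodes)."""
    field = vg.make_tensor_field(phantom12, (1.0, 0.0, 0.0), 5.0, seed=1)
    profile = vg.dti_profile(field, scheme3)
    return vg.assemble_graph(profile, phantom12.anisotropy, phantom12.mask, scheme3)


@pytest.fixture(scope="session")
def dti_decomp12(dti_graph12):
    lap = vg.normalized_laplacian(dti_graph12)
    return vg.eigendecompose(lap, 40, graph=dti_graph12, seed=0)


@pytest.fixture(scope="session")
def toy_graph():
    """Tiny 2x2x2 all-mask graph with isotropic tensors (8 nodes)."""
    phantom = _toy_phantom()
    scheme = vg.build_scheme(3)
    field = _isotropic_field(phantom)
    profile = vg.dti_profile(field, scheme)
    return vg.assemble_graph(profile, phantom.anisotropy, phantom.mask, scheme)


def _toy_phantom(aniso=0.5):
    labels = np.full((2, 2, 2), 2, dtype=np.int16)
    a = np.full((2, 2, 2), aniso)
    return vg.TissuePhantom(
        labels=labels, voxel_size=np.ones(3), anisotropy=a
    )


def _isotropic_field(phantom, sigma2=1.0):
    tensors = np.zeros(phantom.shape + (6,))
    tensors[..., 0] = sigma2  # Txx
    tensors[..., 2] = sigma2  # Tyy
    tensors[..., 5] = sigma2  # Tzz
    return vg.TensorField(tensors=tensors, phantom=phantom)
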