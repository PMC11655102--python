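"""Graph signal processing: GFT, energy spectral density, null models.

A 3D image frame restricted to the graph's nodes is a graph signal
x in R^N. Its graph Fourier transform is the projection onto the
Laplacian eigenmodes, x~ = U^T x, and |x~[i]|^2 is the energy carried
by mode i. For an ensemble of frames (e.g. an fMRI run) the per-mode
energies are averaged into the ensemble energy spectral density (EESD)
after each frame is demeaned — its component along the first
(degree-shaped) eigenmode removed — and scaled to unit energy, so the
EESD of a full spectrum sums to 1 and its first entry is exactly 0.

Two null models destroy the structure the EESD is sensitive to:
node-wise shuffling keeps each frame's value distribution but destroys
spatial order, and white Gaussian noise spreads energy uniformly —
about 1/(N-1) per mode once the first mode is regressed out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import GraphSignalSet
from .spectral import SpectralDecomposition

logger = logging.getLogger(__name__)

__all__ = [
    "EnergySpectrum",
    "gft",
    "inverse_gft",
    "demean_normalize",
    "eesd",
    "shuffle_null",
    "gaussian_null",
]


@dataclass
class EnergySpectrum:
    """Ensemble energy spectral density over the first C spectral indices.

    ``eesd[i]`` is the mean (over frames) energy at 1-based spectral
    index i+1; entry 0 is exactly zero by the demeaning step.
    ``cumulative`` is its running sum. ``excluded_frames`` counts frames
    dropped as degenerate (parallel to the first eigenmode).
    """

    eesd: np.ndarray
    frame_count: int
    excluded_frames: int = 0

    @property
    def C(self) -> int:
        return len(self.eesd)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.eesd)


def gft(U: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Graph Fourier transform: coefficients U^T x.

    With the full eigenvector matrix this is unitary (Parseval holds
    and the inverse transform reconstructs x exactly); with a partial
    basis the inverse reconstructs the orthogonal projection of x onto
    the spanned subspace.
    """
    return np.asarray(U).T @ np.asarray(x, dtype=float)


def inverse_gft(U: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Inverse GFT: U @ coeffs."""
    return np.asarray(U) @ np.asarray(coeffs, dtype=float)


def demean_normalize(x: np.ndarray, u1: np.ndarray) -> np.ndarray:
    """Remove the first-eigenmode component and scale to unit norm.

    Guarantees the result is orthogonal to u1 with unit Euclidean
    norm, so its GFT energy at index 1 is zero and total energy is 1.

    Raises
    ------
    ValueError
        If x is (numerically) parallel to u1, leaving a zero residual.
    """
    x = np.asarray(x, dtype=float)
    u1 = np.asarray(u1, dtype=float)
    resid = x - (u1 @ x) * u1
    norm = np.linalg.norm(resid)
    if norm <= 1e-12 * max(np.linalg.norm(x), 1.0):
        raise ValueError("signal is parallel to the first eigenmode (zero residual)")
    return resid / norm


def eesd(
    signals: GraphSignalSet,
    decomp: SpectralDecomposition,
    C: int | None = None,
) -> EnergySpectrum:
    """Ensemble energy spectral density of a signal set.

    Each frame is demeaned/normalized, transformed, and its squared
    coefficients averaged across frames index-wise. Frames parallel to
    the first eigenmode are excluded (logged); the first spectral index
    is exactly zero by construction.

    Raises
    ------
    ValueError
        If C exceeds the decomposition's mode count or every frame is
        degenerate.
    """
    C = decomp.C if C is None else int(C)
    if not 1 <= C <= decomp.C:
        raise ValueError(f"need 1 <= C <= {decomp.C}, got {C}")
    U = decomp.eigenvectors[:, :C]
    u1 = decomp.eigenvectors[:, 0]
    energies = []
    excluded = 0
    for x in signals.signals:
        try:
            xbar = demean_normalize(x, u1)
        except ValueError:
            excluded += 1
            continue
        coeffs = gft(U, xbar)
        energies.append(coeffs**2)
    if not energies:
        raise ValueError("all frames are degenerate (parallel to the first eigenmode)")
    if excluded:
        logger.info("excluded %d degenerate frames from the ensemble", excluded)
    mean_e = np.mean(energies, axis=0)
    mean_e[0] = 0.0  # exact by the demeaning guarantee
    return EnergySpectrum(
        eesd=mean_e, frame_count=len(energies), excluded_frames=excluded
    )


def shuffle_null(signals: GraphSignalSet, seed: int = 0) -> GraphSignalSet:
    """Destroy spatial order: independently permute each frame across nodes.

    Each output frame holds exactly the input frame's values in a
    random node order, so value distributions are preserved while the
    spatial dependencies the graph encodes are broken.
    """
    rng = np.random.default_rng(seed)
    out = np.empty_like(signals.signals)
    for k, x in enumerate(signals.signals):
        out[k] = x[rng.permutation(len(x))]
    return GraphSignalSet(signals=out)


def gaussian_null(N: int, S: int, seed: int = 0) -> GraphSignalSet:
    """S frames of independent standard normal values on N nodes."""
    rng = np.random.default_rng(seed)
    return GraphSignalSet(signals=rng.standard_normal((S, N)))
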