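"""Procrustes-based alignment of eigenmodes across subjects.

Laplacian eigenmodes computed independently per subject are only
defined up to sign, and modes with close eigenvalues may swap order or
mix. To compare eigenmodes across a cohort sharing one voxel grid,
each subject's first K modes are treated as an N x K matrix and
aligned to a running group average by a signed column permutation: the
orthogonal Procrustes rotation between the two matrices is computed,
and the nearest signed permutation is extracted from it by exact
linear assignment. Iterating reorder-then-average over subjects
(Algorithm: initialize the average at subject 1, sweep until the
permutations stabilize) removes the bias of the initial average.

Residual mismatch between two subjects is the Procrustes error
E(K) = 1/2 * sqrt(sum of squared off-diagonal column-cosines), zero
iff the matched modes are mutually orthogonal across subjects; a
bootstrap over random subject pairs maps E as a function of K, whose
gap to the random-orthonormal null quantifies how much subject-
specific structure the eigenmodes carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "EigenmodeSet",
    "MatchResult",
    "ProcrustesErrorStats",
    "procrustes_reorder",
    "group_match",
    "procrustes_error",
    "bootstrap_validation",
    "random_orthonormal_set",
]

_ORTHO_TOL = 1e-6


@dataclass
class EigenmodeSet:
    """N x K eigenmode matrix of one subject; columns near-orthonormal."""

    matrix: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("eigenmode matrix must be 2D (N x K)")

    @property
    def K(self) -> int:
        return self.matrix.shape[1]

    @property
    def is_orthonormal(self) -> bool:
        g = self.matrix.T @ self.matrix
        return bool(np.max(np.abs(g - np.eye(self.K))) <= _ORTHO_TOL)

    def truncated(self, K: int) -> "EigenmodeSet":
        if K > self.K:
            raise ValueError(f"K={K} exceeds available modes ({self.K})")
        return EigenmodeSet(matrix=self.matrix[:, :K], subject_id=self.subject_id)


@dataclass
class MatchResult:
    """Outcome of group-level eigenmode matching."""

    reordered_sets: list
    group_average: np.ndarray
    permutations: list
    signs: list
    iterations_run: int


@dataclass
class ProcrustesErrorStats:
    """Bootstrap mean/sd of the pairwise Procrustes error per K."""

    K_grid: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    draws: int

    def as_table(self) -> np.ndarray:
        return np.column_stack(
            [self.K_grid, self.mu, self.sigma, np.full(len(self.K_grid), self.draws)]
        )


def procrustes_reorder(X_ref: np.ndarray, X_m: np.ndarray):
    """Signed column permutation of X_m best matching X_ref.

    The orthogonal Procrustes rotation R minimizing ||X_m R - X_ref||_F
    is computed from the SVD of X_m^T X_ref; because a strict column
    reordering (not a dense rotation) is wanted, the signed permutation
    nearest to R is extracted by maximizing the total |R| entries over
    an exact linear assignment, with each matched sign chosen to make
    the agreement non-negative.

    Returns
    -------
    perm : (K,) int array
        Output column j is column ``perm[j]`` of X_m.
    signs : (K,) array of +/-1.
    reordered : N x K array
        ``signs * X_m[:, perm]``.
    """
    X_ref = np.asarray(X_ref, dtype=float)
    X_m = np.asarray(X_m, dtype=float)
    if X_ref.shape != X_m.shape:
        raise ValueError(f"shape mismatch: {X_ref.shape} vs {X_m.shape}")
    u, _, vt = np.linalg.svd(X_m.T @ X_ref)
    rot = u @ vt  # rows: columns of X_m; cols: target positions
    rows, cols = linear_sum_assignment(-np.abs(rot))
    perm = np.empty(X_m.shape[1], dtype=int)
    perm[cols] = rows
    signs = np.sign(rot[perm, np.arange(len(perm))])
    signs[signs == 0] = 1.0
    return perm, signs, X_m[:, perm] * signs


def group_match(sets: list, J: int | None = None, max_iter: int = 20) -> MatchResult:
    """Iterative group-level matching of eigenmode sets.

    Initializes the group average at subject 1's matrix, then sweeps:
    reorder every subject against the average, recompute the average
    as the plain element-wise mean of the reordered matrices. With
    ``J`` given, exactly J sweeps are run; otherwise sweeps continue
    until a full pass applies only identity permutations with positive
    signs (capped at ``max_iter``). Averaged columns are deliberately
    not re-orthonormalized — the cosine-based matching is norm
    invariant.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 subjects")
    mats = [np.array(s.matrix, dtype=float) for s in sets]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"subjects must share N and K, got shapes {shapes}")
    k = mats[0].shape[1]
    cum_perm = [np.arange(k) for _ in mats]
    cum_sign = [np.ones(k) for _ in mats]
    x_avg = mats[0].copy()
    n_iter = max_iter if J is None else J
    iterations = 0
    for _ in range(n_iter):
        iterations += 1
        changed = False
        for m in range(len(mats)):
            perm, signs, reordered = procrustes_reorder(x_avg, mats[m])
            if np.any(perm != np.arange(k)) or np.any(signs < 0):
                changed = True
            mats[m] = reordered
            cum_perm[m] = cum_perm[m][perm]
            cum_sign[m] = cum_sign[m][perm] * signs
        x_avg = np.mean(mats, axis=0)
        if J is None and not changed:
            break
    reordered_sets = [
        EigenmodeSet(matrix=mats[m], subject_id=sets[m].subject_id)
        for m in range(len(mats))
    ]
    return MatchResult(
        reordered_sets=reordered_sets,
        group_average=x_avg,
        permutations=cum_perm,
        signs=cum_sign,
        iterations_run=iterations,
    )


def procrustes_error(X_m: np.ndarray, X_n: np.ndarray) -> float:
    """Half the Frobenius norm of the off-diagonal column-cosine matrix.

    Zero iff every mode of one subject is orthogonal to every
    non-matching mode of the other; symmetric in its arguments.

    Raises
    ------
    ValueError
        On shape mismatch or a zero-norm column.
    """
    X_m = np.asarray(X_m, dtype=float)
    X_n = np.asarray(X_n, dtype=float)
    if X_m.shape != X_n.shape:
        raise ValueError(f"shape mismatch: {X_m.shape} vs {X_n.shape}")
    nm = np.linalg.norm(X_m, axis=0)
    nn = np.linalg.norm(X_n, axis=0)
    if np.any(nm == 0) or np.any(nn == 0):
        raise ValueError("zero-norm eigenmode column")
    cos = (X_m / nm).T @ (X_n / nn)
    # zero the diagonal in place: subtracting the diagonal sum from the total
    # cancels catastrophically when the matched cosines are near 1
    np.fill_diagonal(cos, 0.0)
    return float(0.5 * np.sqrt((cos**2).sum()))


def bootstrap_validation(
    sets: list,
    K_grid=None,
    draws: int = 1000,
    seed: int = 0,
    J: int | None = None,
) -> ProcrustesErrorStats:
    """Bootstrap the pairwise Procrustes error over a grid of K.

    For each K: repeatedly sample a random subject pair (without
    replacement within a draw), match the pair's first K modes, and
    record the post-match error; report the mean and standard
    deviation over draws. The reference study grid is
    K = 100, 200, ..., 1000 with 1000 draws; both are configurable for
    smaller cohorts.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 subjects")
    shared_k = min(s.K for s in sets)
    if K_grid is None:
        K_grid = np.arange(100, 1001, 100)
    K_grid = np.asarray(K_grid, dtype=int)
    bad = K_grid[K_grid > shared_k]
    if bad.size:
        raise ValueError(f"K={bad[0]} exceeds the shared mode count ({shared_k})")
    rng = np.random.default_rng(seed)
    mu = np.empty(len(K_grid))
    sigma = np.empty(len(K_grid))
    for ki, k in enumerate(K_grid):
        eps = np.empty(draws)
        for j in range(draws):
            m, n = rng.choice(len(sets), size=2, replace=False)
            pair = [sets[m].truncated(k), sets[n].truncated(k)]
            result = group_match(pair, J=J)
            eps[j] = procrustes_error(
                result.reordered_sets[0].matrix, result.reordered_sets[1].matrix
            )
        mu[ki] = eps.mean()
        sigma[ki] = eps.std(ddof=1) if draws > 1 else 0.0
    return ProcrustesErrorStats(K_grid=K_grid, mu=mu, sigma=sigma, draws=draws)


def random_orthonormal_set(N: int, K: int, seed: int = 0, subject_id: str = "null"):
    """Random orthonormal N x K matrix (QR of a Gaussian), as a null subject."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((N, K)))
    q *= np.sign(np.diag(r))  # make the factorization (hence q) well-defined
    return EigenmodeSet(matrix=q, subject_id=subject_id)
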