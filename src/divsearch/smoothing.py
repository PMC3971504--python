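"""Surface inpainting: weighted penalized least squares in the DCT domain.

Given sparse measured sensitivities on the lattice, the full surface is
estimated by minimizing

    F(yhat) = ||W^(1/2) (yhat - y)||^2 + s * ||D yhat||^2,

where W is a diagonal reliability weight (1 at measured cells, 0 at
missing cells), D is the lattice Laplacian with Neumann (reflective)
boundaries, and s >= 0 trades fidelity for smoothness.  The type-2 DCT
diagonalizes D, so the minimizer can be iterated cheaply on the full
tensor:  yhat <- IDCT( Gamma * DCT( W*(y - yhat) + yhat ) ) with
Gamma = 1 / (1 + s * Lambda^2).  A direct dense solver of the same normal
equations is provided as an oracle for small grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.fft import dctn, idctn
from scipy.ndimage import distance_transform_edt


@dataclass
class SmootherProblem:
    """Inputs of one smoothing solve.

    y : full-grid tensor with missing entries set to 0.
    weights : same-shape tensor, 1 at measured cells and 0 at missing ones.
    s : smoothing parameter; small values force near-interpolation of the
        measured cells.
    n_iters : fixed-point iteration budget (default 100).
    tol : early-stop threshold on max |change| per iteration.
    """

    y: np.ndarray
    weights: np.ndarray
    s: float = 1e-3
    n_iters: int = 100
    tol: float = 1e-9

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.y.shape != self.weights.shape:
            raise ValueError("y and weights must share a shape")
        if np.any((self.weights != 0) & (self.weights != 1)):
            raise ValueError("weights must be 0 (missing) or 1 (measured)")
        if self.s < 0:
            raise ValueError(f"smoothing parameter must be >= 0, got {self.s}")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")


@dataclass
class SurfaceEstimate:
    """Full-grid estimate plus the mask and parameters that produced it."""

    values: np.ndarray
    known_mask: np.ndarray
    problem: SmootherProblem


def penalty_eigenvalues(shape: tuple[int, ...]) -> np.ndarray:
    """Eigenvalues of the (negated) Neumann lattice Laplacian in DCT basis.

    Entry at multi-index (k1,...,kn) is sum_i 2 - 2*cos(pi*k_i/N_i); the
    zero-frequency entry is 0, so constants are never penalized.
    """
    if any(N < 1 for N in shape):
        raise ValueError("all axis sizes must be >= 1")
    lam = np.zeros(shape)
    for axis, N in enumerate(shape):
        axis_lam = 2.0 - 2.0 * np.cos(np.pi * np.arange(N) / N)
        lam = lam + axis_lam.reshape(
            [-1 if a == axis else 1 for a in range(len(shape))]
        )
    return lam


def _nearest_known_fill(y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Initial guess: every missing cell copies its nearest measured cell."""
    if mask.all():
        return y.copy()
    _, idx = distance_transform_edt(mask == 0, return_indices=True)
    return y[tuple(idx)]


def objective(problem: SmootherProblem, yhat: np.ndarray) -> float:
    """F(yhat) = weighted residual sum of squares + s * roughness penalty."""
    w = problem.weights
    rss = float((w * (yhat - problem.y) ** 2).sum())
    lam = penalty_eigenvalues(yhat.shape)
    coeffs = dctn(yhat, norm="ortho")
    penalty = float((lam**2 * coeffs**2).sum())
    return rss + problem.s * penalty


def estimate_surface(problem: SmootherProblem) -> SurfaceEstimate:
    """Iterative DCT-domain solve of the penalized least-squares problem.

    Starts from a nearest-known-neighbor fill (a good start matters when the
    iteration count is fixed) and stops early once the update falls below
    ``tol`` in max norm.  At the fixed point the iterate satisfies
    (W + s * D'D) yhat = W y, the normal equations of F.
    """
    w = problem.weights
    if not w.any():
        raise ValueError("at least one measured point is required")
    gamma = 1.0 / (1.0 + problem.s * penalty_eigenvalues(problem.y.shape) ** 2)
    yhat = _nearest_known_fill(problem.y, w)
    for _ in range(problem.n_iters):
        new = idctn(gamma * dctn(w * (problem.y - yhat) + yhat, norm="ortho"),
                    norm="ortho")
        delta = float(np.abs(new - yhat).max())
        yhat = new
        if delta < problem.tol:
            break
    return SurfaceEstimate(values=yhat, known_mask=w.copy(), problem=problem)


def _neumann_laplacian_1d(N: int) -> sp.csr_matrix:
    """Second-difference matrix with reflective ends (diagonalized by DCT-2)."""
    if N == 1:
        return sp.csr_matrix((1, 1))
    main = np.full(N, -2.0)
    main[0] = main[-1] = -1.0
    off = np.ones(N - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def _lattice_laplacian(shape: tuple[int, ...]) -> sp.csr_matrix:
    """Kronecker-sum Laplacian of the full lattice, Neumann boundaries."""
    op = None
    for N in shape:
        lap1 = _neumann_laplacian_1d(N)
        if op is None:
            op = lap1
        else:
            op = sp.kron(op, sp.identity(N, format="csr")) + sp.kron(
                sp.identity(op.shape[0], format="csr"), lap1
            )
    return op.tocsr()


def brute_force_smoother(problem: SmootherProblem) -> SurfaceEstimate:
    """Exact minimizer of F by a direct solve of (W + s*D'D) yhat = W y.

    Dense/sparse oracle for small grids (<= 10**4 cells); independent of the
    DCT iteration, sharing only the boundary convention.
    """
    shape = problem.y.shape
    size = problem.y.size
    if size > 10**4:
        raise ValueError("brute_force_smoother is limited to grids <= 10^4 cells")
    if not problem.weights.any():
        raise ValueError("at least one measured point is required")
    lap = _lattice_laplacian(shape)
    w = sp.diags(problem.weights.reshape(-1))
    system = (w + problem.s * (lap.T @ lap)).tocsc()
    rhs = problem.weights.reshape(-1) * problem.y.reshape(-1)
    if problem.s == 0 and not problem.weights.all():
        raise ValueError(
            "singular system: with missing points the penalty must be active "
            "(use s > 0)"
        )
    yhat = spla.spsolve(system, rhs)
    return SurfaceEstimate(
        values=yhat.reshape(shape), known_mask=problem.weights.copy(),
        problem=problem,
    )
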