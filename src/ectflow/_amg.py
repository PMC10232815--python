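"""Smoothed-aggregation multigrid preconditioner for the voxel Laplacian.

The conductance Laplacian lives on a regular voxel grid, so aggregation is
geometric: 2×2×2 voxel blocks form the coarse unknowns at every level, the
tentative piecewise-constant prolongator is smoothed by one damped-Jacobi
step, and coarse operators are Galerkin products.  Used as a single V-cycle
inside conjugate gradients; with symmetric (equal pre/post damped-Jacobi)
smoothing the cycle is a symmetric positive-definite preconditioner.

Everything is deterministic: no randomness enters setup or application.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, sparse

__all__ = ["SmoothedAggregationMG"]


def _aggregate(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group unknowns into 2×2×2 blocks of their voxel coordinates."""
    key = coords // 2
    code = (key[:, 0].astype(np.int64) << 42) | (key[:, 1].astype(np.int64) << 21) \
        | key[:, 2].astype(np.int64)
    uniq, inv = np.unique(code, return_inverse=True)
    ccoords = np.stack([(uniq >> 42) & 0x1FFFFF, (uniq >> 21) & 0x1FFFFF,
                        uniq & 0x1FFFFF], axis=1).astype(coords.dtype)
    return inv, ccoords


def _rho_dinv_a(A: sparse.csr_matrix, dinv: np.ndarray, n_iter: int = 10) -> float:
    """Power-iteration estimate of the spectral radius of D⁻¹A."""
    x = np.ones(A.shape[0])
    x /= np.linalg.norm(x)
    rho = 1.0
    for _ in range(n_iter):
        y = dinv * (A @ x)
        norm = np.linalg.norm(y)
        if norm == 0:
            return 1.0
        rho = norm
        x = y / norm
    return float(rho)


class SmoothedAggregationMG:
    """V-cycle preconditioner for an SPD conductance Laplacian.

    Parameters
    ----------
    A
        Sparse SPD matrix (CSR).
    coords
        Integer (n, 3) voxel coordinates of the unknowns, used for geometric
        aggregation; merged super-nodes may carry any representative voxel.
    max_coarse
        Stop coarsening below this many unknowns and factorise directly.
    """

    def __init__(self, A: sparse.csr_matrix, coords: np.ndarray,
                 max_coarse: int = 1200, n_smooth: int = 1,
                 omega_p: float = 4.0 / 3.0, omega_s: float = 0.85):
        self.n_smooth = n_smooth
        self.levels: list[dict] = []
        A = A.tocsr()
        coords = np.asarray(coords)
        for _ in range(25):
            n = A.shape[0]
            if n <= max_coarse:
                break
            inv, ccoords = _aggregate(coords)
            nc = len(ccoords)
            if nc >= n:  # aggregation stalled; fall back to direct solve
                break
            P0 = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), inv)), shape=(n, nc))
            dinv = 1.0 / np.maximum(A.diagonal(), 1e-300)
            rho = _rho_dinv_a(A, dinv)
            AP = A @ P0
            P = (P0 - sparse.diags(dinv * (omega_p / rho)) @ AP).tocsr()
            self.levels.append({
                "A": A, "P": P, "dinv": dinv, "tau": omega_s / rho,
            })
            A = (P.T @ (A @ P)).tocsr()
            coords = ccoords // 2
        self.coarse_cho = linalg.cho_factor(A.toarray(), lower=True)

    # -- application --------------------------------------------------------

    def _smooth(self, lvl: dict, x: np.ndarray, b: np.ndarray) -> np.ndarray:
        for _ in range(self.n_smooth):
            x = x + lvl["tau"] * lvl["dinv"] * (b - lvl["A"] @ x)
        return x

    def _vcycle(self, level: int, b: np.ndarray) -> np.ndarray:
        if level == len(self.levels):
            return linalg.cho_solve(self.coarse_cho, b)
        lvl = self.levels[level]
        x = lvl["tau"] * lvl["dinv"] * b  # zero initial guess pre-smooth
        for _ in range(self.n_smooth - 1):
            x = x + lvl["tau"] * lvl["dinv"] * (b - lvl["A"] @ x)
        r = b - lvl["A"] @ x
        x = x + lvl["P"] @ self._vcycle(level + 1, lvl["P"].T @ r)
        return self._smooth(lvl, x, b)

    def __call__(self, b: np.ndarray) -> np.ndarray:
        return self._vcycle(0, b)

    def as_linear_operator(self):
        n = (self.levels[0]["A"] if self.levels else
             sparse.eye(len(self.coarse_cho[0]))).shape[0]
        return sparse.linalg.LinearOperator((n, n), matvec=self.__call__)
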