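"""SVD eigengenes and the low-rank eigen-genomic decomposition.

Writing the expression matrix as X = U S V^T, the rows of V^T are the
*eigengenes* — characteristic temporal profiles shared across the genome.
Keeping the first r of them gives X ~= W V_r with gene loadings
W = U_r S_r, an r-dimensional state-space in which the system dynamics
are estimated.  The rank is chosen as the smallest r whose squared
singular values capture a set fraction of the total covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix

__all__ = ["EigenSystem", "compute_eigensystem", "reconstruction_error"]


@dataclass
class EigenSystem:
    """Truncated SVD of an expression matrix.

    Attributes
    ----------
    singular_values : ndarray
        All singular values, descending.
    eigengenes : ndarray, shape (r, n_times)
        First r right singular vectors (orthonormal rows): the temporal
        state trajectories V_r.
    loadings : ndarray, shape (n_genes, r)
        W = U_r * diag(s_r); X ~= loadings @ eigengenes.
    rank : int
    covariance_captured : float
        sum(s_i^2, i<=r) / sum(s_i^2).
    times : ndarray
        Sampling grid in minutes (uniform).
    gene_ids : list of str
    """

    singular_values: np.ndarray
    eigengenes: np.ndarray
    loadings: np.ndarray
    rank: int
    covariance_captured: float
    times: np.ndarray
    gene_ids: list[str]

    @property
    def tau(self) -> float:
        return float(self.times[1] - self.times[0])


def _as_values(x: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(x, ExpressionMatrix):
        if x.missing_mask.any():
            raise ValueError("expression matrix still has missing values; impute first")
        return x.values
    return np.asarray(x, dtype=float)


def compute_eigensystem(
    x: ExpressionMatrix,
    rank: int | str = "auto",
    var_threshold: float = 0.98,
) -> EigenSystem:
    """SVD the matrix and truncate to ``rank`` components.

    With ``rank="auto"`` the smallest rank capturing at least
    ``var_threshold`` of the covariance (sum of squared singular values)
    is selected.  Singular-vector signs are fixed so that the
    largest-magnitude entry of each eigengene is positive, making the
    decomposition deterministic across runs and LAPACK builds.
    """
    vals = _as_values(x)
    n, m = vals.shape
    if not np.any(vals):
        raise ValueError("all-zero expression matrix")
    if not (0 < var_threshold <= 1):
        raise ValueError("var_threshold must be in (0, 1]")
    u, s, vt = np.linalg.svd(vals, full_matrices=False)

    # deterministic orientation: dominant entry of each eigengene positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]

    total = float(np.sum(s**2))
    cumfrac = np.cumsum(s**2) / total
    if rank == "auto":
        r = int(np.searchsorted(cumfrac, var_threshold - 1e-12) + 1)
        r = min(r, len(s))
    else:
        r = int(rank)
        if r < 1 or r > min(n, m):
            raise ValueError(f"rank must be in [1, {min(n, m)}]")
    loadings = u[:, :r] * s[:r]
    if isinstance(x, ExpressionMatrix):
        times, gene_ids = x.times.copy(), list(x.gene_ids)
    else:
        times = np.arange(m, dtype=float)
        gene_ids = [f"row{i}" for i in range(n)]
    return EigenSystem(
        singular_values=s,
        eigengenes=vt[:r],
        loadings=loadings,
        rank=r,
        covariance_captured=float(cumfrac[r - 1]),
        times=times,
        gene_ids=gene_ids,
    )


def reconstruction_error(es: EigenSystem, x: ExpressionMatrix | np.ndarray) -> float:
    """Relative squared Frobenius residual of the rank-r reconstruction.

    Equals ``1 - covariance_captured`` up to numerical round-off.
    """
    vals = _as_values(x)
    if vals.shape != (es.loadings.shape[0], es.eigengenes.shape[1]):
        raise ValueError("shape mismatch between eigensystem and matrix")
    resid = vals - es.loadings @ es.eigengenes
    return float(np.linalg.norm(resid) ** 2 / np.linalg.norm(vals) ** 2)
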