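"""Filtering, SVD imputation and row normalization of expression matrices.

The standard pipeline for a microarray time course is: drop genes with too
many missing samples, fill the remaining gaps with an iterative low-rank
SVD reconstruction, then scale each gene's trajectory to unit Euclidean
norm so that downstream analysis sees shapes rather than absolute levels.
Channel-level intensity filtering belongs upstream (it needs raw
two-channel scanner data); this module accepts a pre-filtered matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix

__all__ = [
    "PreprocessConfig",
    "filter_missing",
    "impute_missing_svd",
    "normalize_rows",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Settings for the filter -> impute -> normalize pipeline."""

    max_missing: int = 3
    impute_rank: int = 5
    impute_tol: float = 1e-6
    impute_max_iter: int = 100
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")
        if self.impute_rank < 1:
            raise ValueError("impute_rank must be >= 1")


def filter_missing(x: ExpressionMatrix, max_missing: int = 3) -> ExpressionMatrix:
    """Drop genes with more than ``max_missing`` missing samples."""
    counts = x.missing_mask.sum(axis=1)
    keep = counts <= max_missing
    if not keep.any():
        raise ValueError("all genes removed by the missing-sample filter")
    ids = [g for g, k in zip(x.gene_ids, keep) if k]
    return ExpressionMatrix(ids, x.times.copy(), x.values[keep], x.missing_mask[keep])


def impute_missing_svd(
    x: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Fill missing entries with an iterative rank-k SVD reconstruction.

    Missing cells are initialized with their gene's observed mean, then the
    loop alternates a rank-k truncated SVD with overwriting the missing
    cells by the reconstruction, until the relative Frobenius change of
    the imputed entries drops below ``impute_tol``.  Observed entries are
    never modified.
    """
    cfg = cfg or PreprocessConfig()
    mask = x.missing_mask
    if not mask.any():
        out = x.copy()
        out.missing_mask[:] = False
        return out
    if mask.all(axis=1).any():
        bad = [g for g, m in zip(x.gene_ids, mask.all(axis=1)) if m]
        raise ValueError(f"gene(s) with all samples missing: {bad[:5]}")

    k = min(cfg.impute_rank, min(x.values.shape))
    vals = x.values.copy()
    row_obs_mean = np.where(
        (~mask).sum(axis=1) > 0,
        np.nansum(np.where(mask, np.nan, vals), axis=1) / np.maximum((~mask).sum(axis=1), 1),
        0.0,
    )
    vals[mask] = np.broadcast_to(row_obs_mean[:, None], vals.shape)[mask]

    converged = False
    for it in range(1, cfg.impute_max_iter + 1):
        u, s, vt = np.linalg.svd(vals, full_matrices=False)
        recon = (u[:, :k] * s[:k]) @ vt[:k]
        new = recon[mask]
        old = vals[mask]
        denom = np.linalg.norm(old)
        change = np.linalg.norm(new - old) / denom if denom > 0 else np.linalg.norm(new)
        vals[mask] = new
        if change < cfg.impute_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SVD imputation did not converge in {cfg.impute_max_iter} iterations "
            f"(last relative change {change:.2e}); returning current estimate",
            RuntimeWarning,
        )
    return ExpressionMatrix(
        list(x.gene_ids), x.times.copy(), vals, np.zeros_like(mask, dtype=bool)
    )


def normalize_rows(x: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene's trajectory to unit Euclidean norm."""
    if x.missing_mask.any():
        raise ValueError("normalize_rows requires a complete matrix (impute first)")
    norms = np.linalg.norm(x.values, axis=1)
    zero = norms == 0
    if zero.any():
        bad = [g for g, z in zip(x.gene_ids, zero) if z]
        raise ValueError(f"cannot normalize all-zero gene(s): {bad[:5]}")
    return ExpressionMatrix(
        list(x.gene_ids),
        x.times.copy(),
        x.values / norms[:, None],
        np.zeros_like(x.missing_mask),
    )


def preprocess(x: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Run filter -> impute -> (optional) normalize."""
    cfg = cfg or PreprocessConfig()
    out = filter_missing(x, cfg.max_missing)
    out = impute_missing_svd(out, cfg)
    if cfg.normalize:
        out = normalize_rows(out)
    return out
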