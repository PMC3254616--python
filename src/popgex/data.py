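"""Expression-matrix container and tab-separated I/O.

The basic object throughout the package is a gene x time matrix sampled on
an equally spaced time grid (in minutes).  Missing values are carried as an
explicit boolean mask so that filtering and imputation can reason about
them without sentinel magic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: strings treated as missing values when reading expression tables
MISSING_SENTINELS = ("", "NA", "NaN", "nan", "null", "NULL")

_SPACING_RTOL = 1e-8


def _check_uniform_spacing(times: np.ndarray) -> float:
    """Return the (constant) sampling interval tau, or raise ValueError."""
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need at least two time points")
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        raise ValueError("time grid must be strictly increasing")
    tau = float(diffs[0])
    if not np.allclose(diffs, tau, rtol=_SPACING_RTOL, atol=0):
        raise ValueError(
            "time points must be equally spaced (propagator estimation "
            "assumes a constant sampling interval)"
        )
    return tau


@dataclass
class ExpressionMatrix:
    """Gene x time expression values on a uniform time grid.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers, one per gene.
    times : array-like of float
        Sampling times in minutes; strictly increasing, constant spacing.
    values : ndarray, shape (n_genes, n_times)
        Expression values.  Entries flagged by ``missing_mask`` are
        ignored by downstream code regardless of their numeric content.
    missing_mask : ndarray of bool, optional
        True where the measurement is missing.  Defaults to the NaN
        pattern of ``values``.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match value rows")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene identifiers")
        if self.times.shape != (m,):
            raise ValueError("times length does not match value columns")
        self.tau = _check_uniform_spacing(self.times)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")
            self.missing_mask = self.missing_mask | np.isnan(self.values)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            self.times.copy(),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame (genes x times) with NaN at missing entries."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.gene_ids, columns=self.times)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        times = np.asarray([float(c) for c in df.columns])
        return cls(list(df.index), times, df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path, gene_column: str = "gene") -> None:
        df = self.to_frame()
        df.columns = [f"t{_fmt_time(t)}" for t in self.times]
        df.index.name = gene_column
        df.to_csv(path, sep="\t", na_rep="NA")


def _fmt_time(t: float) -> str:
    return f"{t:g}"


def _parse_time_header(col: str) -> float:
    s = col.strip()
    if s and s[0] in "tT":
        s = s[1:]
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"cannot parse time point from column header {col!r}") from exc


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression table.

    The first column holds gene identifiers; remaining column headers are
    time points in minutes (a leading ``t`` is allowed).  Empty cells and
    the sentinels NA / NaN / null mark missing measurements.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(MISSING_SENTINELS),
        keep_default_na=False,
    )
    if df.shape[1] < 2:
        raise ValueError("expression table needs at least two time columns")
    times = np.asarray([_parse_time_header(c) for c in df.columns])
    values = df.to_numpy(dtype=float)
    return ExpressionMatrix(list(df.index), times, values)
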