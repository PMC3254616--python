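"""Statistical comparisons, threshold selection and recovery evaluation.

Covers the analyses used to judge a POP run: two-sample comparisons of
amplitude distributions (Welch t, variance-ratio F, permutation test of
the mean difference), survival-curve based selection of an amplitude
threshold for calling periodically expressed genes, recovery of simulated
amplitudes/phases, circular phase medians per annotation group, and plain
set-overlap reporting against other gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .dynamics import GenePopTable
from .simulate import SimulationTruth

__all__ = [
    "TwoSampleResult",
    "PermutationResult",
    "ThresholdReport",
    "RecoveryReport",
    "two_sample_tests",
    "permutation_test",
    "survival_curve",
    "detect_threshold",
    "evaluate_recovery",
    "median_phase_by_group",
    "circular_median",
    "set_overlap_report",
]


@dataclass
class TwoSampleResult:
    welch_t_p: float
    f_test_p: float
    mean_a: float
    mean_b: float
    t_statistic: float
    f_statistic: float


def two_sample_tests(a, b) -> TwoSampleResult:
    """Welch's unequal-variance t test plus a two-sided variance-ratio F test.

    The F statistic puts the larger sample variance in the numerator and
    the two-sided p doubles the upper tail (capped at 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    t_res = scipy.stats.ttest_ind(a, b, equal_var=False)
    if va >= vb:
        f_stat, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        f_stat, dfn, dfd = vb / va, b.size - 1, a.size - 1
    f_p = min(1.0, 2.0 * scipy.stats.f.sf(f_stat, dfn, dfd))
    return TwoSampleResult(
        welch_t_p=float(t_res.pvalue),
        f_test_p=float(f_p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(t_res.statistic),
        f_statistic=float(f_stat),
    )


@dataclass
class PermutationResult:
    p_value: float  # proportion of permuted differences >= observed
    p_value_plus_one: float  # (k+1)/(n+1) small-sample variant
    observed: float
    n_perm: int

    def __float__(self) -> float:
        return self.p_value


def permutation_test(
    amplitudes, set_idx, n_perm: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Permutation test of mean(set) - mean(rest) being large.

    Resamples ``len(set_idx)`` genes without replacement ``n_perm`` times;
    the p-value is the proportion of permuted mean differences greater
    than or equal to the observed one.  The (k+1)/(n+1) variant, which
    can never be exactly zero, is reported alongside.
    """
    amplitudes = np.asarray(amplitudes, float)
    set_idx = np.asarray(set_idx, int)
    n = amplitudes.size
    k = set_idx.size
    if k == 0 or k >= n:
        raise ValueError("reference set must be a non-empty proper subset")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mask = np.zeros(n, bool)
    mask[set_idx] = True
    observed = amplitudes[mask].mean() - amplitudes[~mask].mean()

    rng = np.random.default_rng(seed)
    total = amplitudes.sum()
    count = 0
    # mean difference is a monotone function of the subset sum:
    # diff = s/k - (total-s)/(n-k)
    for _ in range(n_perm):
        s = amplitudes[rng.choice(n, size=k, replace=False)].sum()
        diff = s / k - (total - s) / (n - k)
        if diff >= observed - 1e-12 * max(1.0, abs(observed)):
            count += 1
    return PermutationResult(
        p_value=count / n_perm,
        p_value_plus_one=(count + 1) / (n_perm + 1),
        observed=float(observed),
        n_perm=n_perm,
    )


def survival_curve(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """S(a) = P(value > a) evaluated on ``grid``."""
    values = np.asarray(values, float)
    return (values[None, :] > np.asarray(grid, float)[:, None]).mean(axis=1)


@dataclass
class ThresholdReport:
    grid: np.ndarray
    s_all: np.ndarray  # survival of all genes
    s_excl: np.ndarray  # survival excluding the reference set
    threshold: float | None  # detected amplitude cutoff (None if no gap)
    n_above: int | None  # genes with amplitude > threshold
    min_gap: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"amplitude": self.grid, "s_all": self.s_all, "s_excl": self.s_excl}
        )


def detect_threshold(
    amplitudes,
    reference_idx,
    min_gap: float = 0.05,
    grid: np.ndarray | None = None,
) -> ThresholdReport:
    """Amplitude cutoff from the gap between two survival curves.

    Compares P(amplitude > a) over all genes with the same curve computed
    after removing a reference set of known periodic genes.  The detected
    threshold is the smallest grid amplitude at which the relative gap
    (S_all - S_excl)/S_all reaches ``min_gap`` and stays there for every
    larger grid point where S_all > 0.  The exported curves are the
    primary product — the automatic pick is a convenience for scripting,
    with visual inspection of the plot as the authoritative procedure.
    """
    amplitudes = np.asarray(amplitudes, float)
    reference_idx = np.asarray(reference_idx, int)
    n = amplitudes.size
    if reference_idx.size == 0 or reference_idx.size >= n:
        raise ValueError("reference set must be a non-empty proper subset")
    mask = np.zeros(n, bool)
    mask[reference_idx] = True
    if grid is None:
        hi = float(amplitudes.max())
        grid = np.linspace(0.0, hi, 512, endpoint=False)
    grid = np.asarray(grid, float)
    s_all = survival_curve(amplitudes, grid)
    s_excl = survival_curve(amplitudes[~mask], grid)

    with np.errstate(divide="ignore", invalid="ignore"):
        rel_gap = np.where(s_all > 0, (s_all - s_excl) / s_all, np.nan)
    ok = np.where(s_all > 0, rel_gap >= min_gap, True)  # vacuous once S_all hits 0
    # smallest grid point from which the gap condition holds onwards
    holds_onward = np.flip(np.logical_and.accumulate(np.flip(ok)))
    candidates = np.nonzero(holds_onward & (s_all > 0) & (rel_gap >= min_gap))[0]
    if candidates.size:
        threshold = float(grid[candidates[0]])
        n_above = int((amplitudes > threshold).sum())
    else:
        threshold, n_above = None, None
    return ThresholdReport(
        grid=grid,
        s_all=s_all,
        s_excl=s_excl,
        threshold=threshold,
        n_above=n_above,
        min_gap=min_gap,
    )


@dataclass
class RecoveryReport:
    amplitude_pearson: float
    phase_sine_pearson_raw: float
    phase_sine_pearson_aligned: float
    phase_offset_deg: float  # global offset maximizing the aligned value
    n_genes: int


def _sine_corr(theta_rad: np.ndarray, phi_rad: np.ndarray, offset_rad: float) -> float:
    return float(np.corrcoef(np.sin(theta_rad + offset_rad), np.sin(phi_rad))[0, 1])


def evaluate_recovery(table: GenePopTable, truth: SimulationTruth) -> RecoveryReport:
    """Correlate recovered POP amplitudes/phases with simulated truth.

    Amplitudes are compared by plain Pearson correlation (POP amplitudes
    carry an arbitrary overall scale, which correlation ignores).  Phases
    are compared through their sines, both as-is and after applying the
    single global phase offset that maximizes the correlation: the
    eigenvector gauge and the kinetic response lag shift all recovered
    phases by a near-common rotation that is not part of the per-gene
    signal.
    """
    if table.gene_ids != truth.gene_ids:
        raise ValueError("gene sets of table and truth differ or are misaligned")
    if len(table.gene_ids) < 3:
        raise ValueError("need at least three genes")
    amp_r = float(np.corrcoef(table.amplitude, truth.amplitude)[0, 1])
    theta = np.radians(table.phase_deg)
    phi = truth.phase
    raw = _sine_corr(theta, phi, 0.0)
    grid = np.radians(np.arange(0.0, 360.0, 1.0))
    vals = [_sine_corr(theta, phi, g) for g in grid]
    best = int(np.argmax(vals))
    res = scipy.optimize.minimize_scalar(
        lambda o: -_sine_corr(theta, phi, o),
        bounds=(grid[best] - np.radians(1.5), grid[best] + np.radians(1.5)),
        method="bounded",
    )
    aligned = max(raw, float(vals[best]), float(-res.fun))
    offset = float(np.degrees(res.x) % 360.0)
    return RecoveryReport(
        amplitude_pearson=amp_r,
        phase_sine_pearson_raw=raw,
        phase_sine_pearson_aligned=aligned,
        phase_offset_deg=offset,
        n_genes=len(table.gene_ids),
    )


def circular_median(phases_deg) -> float:
    """Angle minimizing the summed arc distance to the data, in [0, 360).

    The minimizer is searched over the data points themselves (for summed
    arc distance an optimum is always attained at a data point); ties go
    to the smallest angle.
    """
    phases = np.asarray(phases_deg, float) % 360.0
    if phases.size == 0:
        raise ValueError("no phases given")
    diffs = np.abs(phases[:, None] - phases[None, :])
    arc = np.minimum(diffs, 360.0 - diffs)
    costs = arc.sum(axis=1)
    order = np.lexsort((phases, costs))
    return float(phases[order[0]])


def median_phase_by_group(table: GenePopTable, groups: dict[str, str]) -> pd.DataFrame:
    """Circular and ordinary median POP phase per annotation label.

    ``groups`` maps gene id -> label; genes absent from the table are
    ignored, but a label with no genes present raises.
    """
    idx = {g: i for i, g in enumerate(table.gene_ids)}
    by_label: dict[str, list[float]] = {}
    for gene, label in groups.items():
        if gene in idx:
            by_label.setdefault(label, []).append(float(table.phase_deg[idx[gene]]))
    missing = set(groups.values()) - set(by_label)
    if missing:
        raise ValueError(f"label(s) with no genes present in table: {sorted(missing)}")
    rows = []
    for label in sorted(by_label):
        ph = np.array(by_label[label])
        rows.append(
            {
                "label": label,
                "n_genes": ph.size,
                "circular_median_deg": circular_median(ph),
                "ordinary_median_deg": float(np.median(ph)),
            }
        )
    return pd.DataFrame(rows).set_index("label")


def set_overlap_report(sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise intersection / difference cardinalities of named gene sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = set(sets[a]), set(sets[b])
            rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "n_a": len(sa),
                    "n_b": len(sb),
                    "intersection": len(sa & sb),
                    "only_a": len(sa - sb),
                    "only_b": len(sb - sa),
                }
            )
    return pd.DataFrame(rows)
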