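"""Linear system estimation and principal-oscillation-pattern extraction.

The eigengene trajectories V(t_k) are modelled as snapshots of a linear
dynamical system dV/dt = B_r V.  The one-step propagator
Phi ~= exp(B_r * tau) is estimated by least squares from consecutive
snapshot pairs, converted to the continuous-time matrix B_r (matrix
logarithm, or a first-order Euler difference), and eigendecomposed.

A complex conjugate eigenvalue pair sigma +- i*omega of B_r contributes a
rotation: with eigenvector e, the patterns p1 = Re(e) and p2 = -Im(e)
span a plane in state space on which trajectories cycle
p1 -> p2 -> -p1 -> -p2 -> p1 with period 2*pi/omega.  These are the
principal oscillation patterns (POPs).  Mapping them through the gene
loadings W gives genome-wide patterns, and each gene's coefficient pair
on them — in polar coordinates an oscillation amplitude and a phase —
quantifies how strongly, and at which point of the cycle, that gene
oscillates.  Real eigenvalues are non-oscillatory decay modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .eigensystem import EigenSystem

__all__ = [
    "Propagator",
    "SystemMatrix",
    "PopPair",
    "DecayMode",
    "PopDecomposition",
    "GenePopTable",
    "estimate_propagator",
    "propagator_to_system",
    "extract_pops",
    "amplitude_phase",
]

_PAIR_TOL = 1e-9  # relative threshold for treating an eigenvalue as complex


@dataclass
class Propagator:
    """One-step linear map V(t_{k+1}) ~= Phi V(t_k)."""

    phi: np.ndarray
    tau: float
    fit_residual: float  # Frobenius norm of one-step prediction error


@dataclass
class SystemMatrix:
    """Continuous-time system matrix B_r with dV/dt = B_r V."""

    matrix: np.ndarray
    tau: float
    method: str  # "matrix-log" or "euler"


@dataclass
class PopPair:
    """One complex conjugate eigenvalue pair and its oscillation patterns."""

    eigenvalue: complex  # sigma + i*omega with omega > 0
    period: float  # minutes, 2*pi/omega
    p1: np.ndarray  # Re(e), eigen-space pattern
    p2: np.ndarray  # -Im(e)
    gene_p1: np.ndarray  # W @ p1
    gene_p2: np.ndarray  # W @ p2
    energy: float  # expression variance carried by this pair's trajectory
    rank_index: int = 0
    aliased: bool = False  # period at or below the Nyquist limit 2*tau
    gene_ids: list[str] = field(default_factory=list)
    loadings: np.ndarray | None = None

    @property
    def omega(self) -> float:
        return float(self.eigenvalue.imag)

    @property
    def growth_rate(self) -> float:
        return float(self.eigenvalue.real)


@dataclass
class DecayMode:
    """A real eigenvalue: exponential relaxation with no oscillation."""

    eigenvalue: float
    pattern: np.ndarray
    energy: float

    @property
    def halflife(self) -> float:
        """e-folding-derived half-life in minutes (inf for a neutral mode)."""
        lam = self.eigenvalue
        return float(np.inf) if lam >= 0 else float(np.log(2.0) / -lam)


@dataclass
class PopDecomposition:
    """All POP pairs plus the real decay modes of a system matrix."""

    pairs: list[PopPair]
    decay_modes: list[DecayMode]

    @property
    def leading(self) -> PopPair | None:
        return self.pairs[0] if self.pairs else None

    @property
    def ordered_eigenvalues(self) -> list[complex]:
        """Eigenvalues with oscillatory pairs first (by explained snapshot
        variance, conjugates adjacent), then decay modes slow to fast."""
        out: list[complex] = []
        for p in self.pairs:
            out.append(p.eigenvalue)
            out.append(p.eigenvalue.conjugate())
        for d in self.decay_modes:
            out.append(complex(d.eigenvalue))
        return out


@dataclass
class GenePopTable:
    """Per-gene POP coefficients in Cartesian and polar form."""

    gene_ids: list[str]
    c1: np.ndarray
    c2: np.ndarray
    amplitude: np.ndarray  # r_n = sqrt(c1^2 + c2^2)
    phase_deg: np.ndarray  # theta_n in [0, 360)
    phase_defined: np.ndarray  # False where amplitude == 0
    period: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "c1": self.c1,
                "c2": self.c2,
                "amplitude": self.amplitude,
                "phase_deg": self.phase_deg,
                "phase_defined": self.phase_defined,
            }
        ).set_index("gene")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def estimate_propagator(es: EigenSystem) -> Propagator:
    """Least-squares one-lag fit of the propagator from eigengene snapshots.

    Minimizes sum_k ||V(t_{k+1}) - Phi V(t_k)||^2 over Phi, solved through
    the pseudo-inverse of the lagged snapshot matrix.
    """
    v = es.eigengenes
    r, m = v.shape
    if m < r + 1:
        raise ValueError(f"need at least rank+1 = {r + 1} time points, have {m}")
    v_past, v_future = v[:, :-1], v[:, 1:]
    if np.linalg.matrix_rank(v_past) < r:
        warnings.warn(
            "lagged snapshot matrix is rank deficient; propagator is the "
            "minimum-norm least-squares solution",
            RuntimeWarning,
        )
    phi = v_future @ np.linalg.pinv(v_past)
    residual = float(np.linalg.norm(v_future - phi @ v_past))
    return Propagator(phi=phi, tau=es.tau, fit_residual=residual)


def propagator_to_system(p: Propagator, method: str = "matrix-log") -> SystemMatrix:
    """Convert the discrete propagator to a continuous-time matrix.

    ``matrix-log`` uses B_r = logm(Phi)/tau (exact when the data really
    follow a linear ODE sampled at interval tau); it requires that no
    eigenvalue of Phi lies on the closed negative real axis, where the
    principal logarithm is undefined.  ``euler`` uses the first-order
    difference B_r = (Phi - I)/tau.
    """
    if method not in ("matrix-log", "euler"):
        raise ValueError(f"unknown discretization method {method!r}")
    if method == "euler":
        b = (p.phi - np.eye(p.phi.shape[0])) / p.tau
        return SystemMatrix(matrix=b, tau=p.tau, method=method)
    mu = np.linalg.eigvals(p.phi)
    scale = max(1.0, float(np.abs(mu).max()))
    on_branch_cut = (mu.real <= 0) & (np.abs(mu.imag) < 1e-12 * scale)
    if on_branch_cut.any():
        raise ValueError(
            "propagator has an eigenvalue on the closed negative real axis; "
            "the principal matrix logarithm is undefined — use method='euler'"
        )
    logm = scipy.linalg.logm(p.phi)
    if np.abs(np.imag(logm)).max() > 1e-8 * max(1.0, np.abs(logm).max()):
        warnings.warn("matrix logarithm has a non-trivial imaginary part; taking Re")
    b = np.real(logm) / p.tau
    return SystemMatrix(matrix=b, tau=p.tau, method="matrix-log")


def _mode_coefficients(eigvecs: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Coefficients z_j(t_k) of the snapshots in the eigenvector basis."""
    try:
        return np.linalg.solve(eigvecs, v)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(eigvecs) @ v


def extract_pops(
    b: SystemMatrix,
    es: EigenSystem,
    which: str | int = "all",
) -> PopDecomposition:
    """Eigendecompose B_r and collect POP pairs and decay modes.

    Each complex pair's eigenvector is scaled to unit norm and rotated so
    that its coefficient at the first snapshot is real and non-negative
    (a gauge fixing; per-gene amplitudes do not depend on it, phases only
    through a common offset).  Pairs are ordered by the expression-data
    variance their coefficient trajectory carries (their eigengene
    contribution mapped through the loadings), ties broken by frequency;
    real eigenvalues are reported as decay modes, slowest first.
    """
    bm = b.matrix
    eigvals, eigvecs = np.linalg.eig(bm)
    v = es.eigengenes
    z = _mode_coefficients(eigvecs, v)
    scale = max(1.0, float(np.abs(eigvals).max()))

    pairs: list[PopPair] = []
    decay: list[DecayMode] = []
    for j, lam in enumerate(eigvals):
        if abs(lam.imag) <= _PAIR_TOL * scale:
            e = np.real(eigvecs[:, j])
            nrm = np.linalg.norm(e)
            e = e / nrm if nrm > 0 else e
            zj = np.real(z[j]) * nrm
            # variance of the expression data carried by this mode
            energy = float(np.linalg.norm(es.loadings @ e) ** 2 * np.sum(zj**2))
            decay.append(DecayMode(eigenvalue=float(lam.real), pattern=e, energy=energy))
            continue
        if lam.imag < 0:
            continue  # keep only the omega > 0 representative of each pair
        e = eigvecs[:, j] / np.linalg.norm(eigvecs[:, j])
        zj = z[j] * np.linalg.norm(eigvecs[:, j])  # coefficients for unit-norm e
        # gauge: rotate so the first-snapshot coefficient is real, >= 0
        z0 = zj[0]
        if abs(z0) > 0:
            c = z0 / abs(z0)
            e = e * c
            zj = zj / c
        omega = float(lam.imag)
        period = 2.0 * np.pi / omega
        aliased = period <= 2.0 * b.tau
        if aliased:
            warnings.warn(
                f"POP period {period:.3g} min is at or below the Nyquist "
                f"limit {2 * b.tau:.3g} min and is unreliable",
                RuntimeWarning,
            )
        # contribution of the pair to the snapshots, 2*Re(z_j(t) e_j),
        # weighted through the gene loadings: ordering reflects variance
        # of the expression data, not of the unit-norm eigengenes, so
        # low-singular-value noise modes cannot outrank the signal pair
        contrib = 2.0 * np.real(np.outer(e, zj))
        energy = float(np.linalg.norm(es.loadings @ contrib) ** 2)
        p1, p2 = np.real(e), -np.imag(e)
        pairs.append(
            PopPair(
                eigenvalue=complex(lam),
                period=period,
                p1=p1,
                p2=p2,
                gene_p1=es.loadings @ p1,
                gene_p2=es.loadings @ p2,
                energy=energy,
                aliased=aliased,
                gene_ids=list(es.gene_ids),
                loadings=es.loadings,
            )
        )

    pairs.sort(key=lambda p: (-p.energy, -p.omega))
    for i, p in enumerate(pairs):
        p.rank_index = i
    decay.sort(key=lambda d: -d.eigenvalue)  # slow (near-zero) decay first

    if which == "all":
        return PopDecomposition(pairs=pairs, decay_modes=decay)
    if which == "leading":
        return PopDecomposition(pairs=pairs[:1], decay_modes=decay)
    idx = int(which)
    if idx < 0 or idx >= len(pairs):
        raise IndexError(f"POP pair index {idx} out of range ({len(pairs)} pairs)")
    return PopDecomposition(pairs=[pairs[idx]], decay_modes=decay)


def _polar_table(
    gene_ids: list[str], c1: np.ndarray, c2: np.ndarray, period: float
) -> GenePopTable:
    amplitude = np.hypot(c1, c2)
    defined = amplitude > 0
    phase = np.degrees(np.arctan2(c2, c1)) % 360.0
    phase[~defined] = 0.0
    return GenePopTable(
        gene_ids=gene_ids,
        c1=c1,
        c2=c2,
        amplitude=amplitude,
        phase_deg=phase,
        phase_defined=defined,
        period=period,
    )


def amplitude_phase(pair: PopPair, method: str = "direct") -> GenePopTable:
    """Per-gene oscillation amplitude and phase from a POP pair.

    ``direct`` (default) reads each gene's coefficients straight off the
    gene-space patterns: c1_n = (W p1)_n, c2_n = (W p2)_n.  Because the
    oscillatory part of gene n's trajectory is 2*Re(z(t) * (w_n . e)),
    sqrt(c1_n^2 + c2_n^2) = |w_n . e| is exactly proportional to that
    gene's oscillation amplitude at frequency omega, whether or not p1
    and p2 are orthogonal.

    ``projection`` instead projects each gene's loading vector onto an
    orthonormalized basis of span{p1, p2} (Gram-Schmidt, p1 first).  The
    two conventions coincide when p1 and p2 are orthogonal with equal
    norms; ``projection`` additionally picks up non-oscillatory loading
    components that happen to lie in the POP plane, so ``direct`` is the
    faithful readout of the oscillation and the default.
    """
    if method == "direct":
        c1, c2 = pair.gene_p1.copy(), pair.gene_p2.copy()
    elif method == "projection":
        if pair.loadings is None:
            raise ValueError("pair does not carry loadings; cannot project")
        u1 = pair.p1 / np.linalg.norm(pair.p1)
        w2 = pair.p2 - (pair.p2 @ u1) * u1
        n2 = np.linalg.norm(w2)
        if n2 == 0:
            raise ValueError("degenerate POP pair: p1 and p2 are collinear")
        u2 = w2 / n2
        c1 = pair.loadings @ u1
        c2 = pair.loadings @ u2
    else:
        raise ValueError(f"unknown coefficient method {method!r}")
    gene_ids = pair.gene_ids or [f"g{i}" for i in range(len(c1))]
    return _polar_table(gene_ids, c1, c2, pair.period)
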