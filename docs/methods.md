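# Methods

## Model

`popgex` treats a genome-wide expression time course as snapshots of a
linear time-invariant system.  The full state equation `dX/dt = B X`
(with `X(t) ∈ R^N` the expression of all N genes) is never estimated:
with M ≪ N time points the N×N system matrix is hopelessly
underdetermined.  The data are instead reduced by (uncentered) SVD,
`X ≈ W V_r`, and the dynamics are estimated for the r-dimensional
eigengene state, `dV/dt = B_r V`.  The genomic system matrix is then
implicitly `W B_r W⁺`; it is never materialized.

Estimation proceeds through the one-step propagator.  For a uniform
sampling interval τ the exact discretization of the linear ODE is
`V(t_{k+1}) = exp(B_r τ) V(t_k)`, so the propagator `Φ` is fitted by
ordinary least squares over all consecutive snapshot pairs
(`Φ = V_future V_past⁺`) and converted back with the principal matrix
logarithm, `B_r = logm(Φ)/τ`.  A first-order alternative
(`B_r = (Φ − I)/τ`, `discretization="euler"`) is provided for propagators
with eigenvalues on the closed negative real axis, where the principal
logarithm is undefined.  For period estimation the two differ: only the
matrix logarithm maps a sampled rotation back to its exact angular
frequency, which is why it is the default.

A complex conjugate eigenvalue pair σ ± iω of `B_r` (eigenvector e)
contributes a rotation with period 2π/ω on the plane spanned by
`p1 = Re(e)` and `p2 = −Im(e)` — the principal oscillation patterns.
The oscillatory part of gene n is `2·Re(z(t)·(w_n·e))` with `w_n` the
gene's loading row and `z(t)` the pair's complex coefficient, so the
per-gene Cartesian coefficients are read directly off the gene-space
patterns, `(c1_n, c2_n) = ((W p1)_n, (W p2)_n)`, and
`r_n = |w_n·e| = √(c1² + c2²)` is exactly proportional to the gene's
oscillation amplitude at frequency ω whether or not p1 ⊥ p2.  An
alternative convention (`coeff_method="projection"`: orthogonal
projection of `w_n` onto span{p1, p2}) is provided for comparison; it
coincides with the direct readout when p1 and p2 are orthogonal with
equal norms, but additionally captures non-oscillatory loading
components that happen to lie in the POP plane — on uncentered
expression data the dominant baseline component makes this a poor
amplitude estimator, which is why the direct convention is the default.

### Conventions and tie-breaks

- **SVD orientation.** Singular-vector signs are arbitrary; each
  component is flipped so the largest-magnitude entry of the eigengene
  is positive.  Results are thereby deterministic across runs.
- **Eigenvector gauge.** e is scaled to unit norm and rotated by a unit
  complex number so that the pair's coefficient at the first snapshot is
  real and non-negative.  Per-gene amplitudes are invariant to this
  choice; phases shift only by a common constant (asserted by a property
  test), so only gauge-invariant quantities are meaningful — which is
  also why phase recovery is evaluated up to a global offset.
- **Mode ordering.** POP pairs are ranked by the expression variance
  their coefficient trajectory carries: the pair's eigengene-space
  contribution `2·Re(z(t) e)` mapped through the loadings W.  Weighting
  through W matters — the eigengene snapshots themselves are unit-norm,
  so in snapshot space a noise mode weighs as much as a signal mode and
  can outrank it.  Ties break toward higher frequency.  Real eigenvalues
  are listed after the pairs as decay modes, slowest first.
- **Phase convention.** θ = atan2(c2, c1) in degrees, folded to
  [0°, 360°).  Genes with exactly zero amplitude get θ = 0 and a
  `phase_defined = False` flag.
- **Nyquist guard.** A pair whose period is ≤ 2τ cannot be resolved at
  the sampling interval; it is reported but flagged `aliased` with a
  runtime warning.
- **Rank selection.** `rank="auto"` keeps the smallest r whose squared
  singular values capture ≥ 98% of the covariance.  On uncentered data
  the near-constant baseline component alone can cross that threshold,
  so analyses targeting low-variance oscillatory structure should pass
  an explicit rank (the analyses here use r = 5 throughout).

## Synthetic data generator

Each gene follows the standard kinetic model
`dx/dt = P(t) − λ x` with production
`P(t) = b (1 + A cos(ω t + φ)) + ε(t)`:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 4000 | number of genes |
| `times` | 0, 7, …, 119 min | 18 uniform samples, two ~60-min cell cycles |
| `period` | 30 min | driving oscillation period (ω = 2π/30 rad/min) |
| `amplitude_range` | [0, 0.1] | per-gene A ~ uniform; keeps expression positive |
| phase | — | φ ~ uniform on [0, 2π) |
| `baseline` | 1.0 | production rate b (arbitrary units/min) |
| `halflife_log_mean/sd` | ln 20, 0.5 | lognormal mRNA half-lives, median 20 min |
| `noise_fraction` | 0.10 | sd of ε as a fraction of b |
| `substeps` | 100 | noise redraw interval = τ/100 |

λ = ln 2 / half-life.  The half-life defaults approximate genome-wide
decay measurements in budding yeast (median ≈ 20 min, roughly 2-fold
log-scatter); both are configurable.  Trajectories start at the
noiseless periodic steady state, so no relaxation transient contaminates
the 18 samples.  Integration is exact per sub-step: the sinusoidal
production response is propagated analytically, while the Gaussian noise
term is redrawn every τ/100 and held constant across the sub-step (a
piecewise-constant stand-in for white production noise).  In the
noiseless limit the sampled values equal the closed-form steady-state
sinusoid
`x(t) = b/λ + bA/√(λ²+ω²)·cos(ωt + φ − atan2(ω, λ))`
to machine precision, which the test suite verifies against an
independent RK4 integration.

What the generator emulates — and what it does not.  It reproduces the
features that matter for POP estimation: a shared oscillation frequency
with gene-specific amplitude and phase, realistic decay-rate dispersion,
production noise, positivity and a dominant baseline.  It does not model
count noise or measurement error on x itself, regulatory coupling
between genes, amplitude damping as synchrony decays, missing values, or
unequal sampling.  Passing recovery tests on these data therefore show
that the estimator chain is correct for a system that truly is linear
with one shared frequency; they do not show robustness to desynchrony or
to gene–gene dynamical heterogeneity in real cultures.

Two consequences of the kinetic model are worth noting when interpreting
recovery numbers.  The expression-level amplitude of a gene is
`bA/√(λ²+ω²)`, not A: the decay-rate spread introduces a mild gene-wise
modulation (a few percent here), which is why amplitude correlations of
≈ 0.99 rather than 1.0 are expected.  Likewise each gene's expression
phase lags its production phase by `atan2(ω, λ)` (≈ 65–87° across the
half-life distribution), which combines with the eigenvector gauge into
a near-common rotation of all recovered phases — the motivation for
reporting sine-phase correlation both raw and after the best global
offset.

## Preprocessing

Real matrices pass filter → impute → normalize:

- genes with more than `max_missing` (default 3) missing samples are
  dropped;
- remaining gaps are filled by iterative low-rank completion:
  initialize missing cells with the gene's observed mean, then
  alternate a rank-k truncated SVD (k defaults to the downstream
  eigengene rank) with overwriting the missing cells by the
  reconstruction until the relative Frobenius change of the imputed
  entries falls below 1e-6 (at most 100 iterations; non-convergence
  warns and returns the current estimate).  Observed entries are never
  modified;
- each gene's trajectory is scaled to unit Euclidean norm (so the
  analysis sees temporal shape, not absolute level).  Normalization is
  applied to real data; simulated data are analyzed unnormalized, since
  the generator's amplitude ground truth lives on the raw scale.

Channel-intensity filtering of two-color arrays requires raw scanner
data and is out of scope; the package accepts a pre-filtered matrix.

## Statistics

- Welch's unequal-variance t test (two-sided) compares amplitude means
  between a gene set and its complement; a two-sided variance-ratio F
  test (larger variance in the numerator, upper tail doubled) checks
  variance equality.
- The permutation test draws the set size without replacement, recomputes
  the mean difference, and reports the proportion of permuted differences
  ≥ the observed one; the (k+1)/(n+1) variant is reported alongside since
  pure resampling can return exactly 0.
- Threshold selection computes survival curves P(amplitude > a) with and
  without a reference set of known periodic genes on a common grid (512
  points spanning the amplitude range) and picks the smallest a where the
  relative gap (S_all − S_excl)/S_all reaches `min_gap` (default 0.05)
  and stays there.  The curves and their plot are the primary output;
  the automatic pick is a scripting convenience, and for sharply
  separated sets a stricter `min_gap` moves the cutoff toward the edge
  of the background support.
- Phase medians per annotation group are circular medians (minimizer of
  summed arc distance, attained at a data point; ties to the smallest
  angle), with the ordinary median exported alongside for comparison.

## Problem sizes

The bundled analyses run the generator at its default 4000 genes for the
headline recovery numbers and at 400–1000 genes inside the test suite,
which resolves the same 30-minute period and recovery correlations while
keeping the full suite in a few seconds on one core.

## Known limitations

- Uniform sampling is required; interpolate unevenly sampled series
  upstream if needed.
- One linear system for the whole genome: gene-specific dynamics beyond
  the shared modes are not modelled.
- The amplitude threshold is dataset-specific by construction; the
  survival-curve gap only transfers across datasets with a comparable
  reference set.
- With several oscillatory pairs the per-gene table reflects the leading
  pair only (other pairs are available from the decomposition).
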