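# popgex — principal-oscillation-pattern analysis of gene expression

`popgex` identifies periodically expressed genes in genome-wide expression
time courses (e.g. cell-cycle-synchronized yeast cultures) by estimating a
linear dynamical model of the whole system rather than fitting each gene
one at a time.  It is aimed at computational biologists analyzing
equally-spaced bulk or pseudo-bulk expression time series, and at
methodologists who want a fully simulatable test bed for oscillation
detection.

## The method

The expression state is modelled by the state equation `dX/dt = B X` with
`X(t)` the vector of all gene expression levels.  Because time points are
far fewer than genes, `B` cannot be estimated directly; instead the data
matrix is reduced by SVD, `X ≈ W V_r`, where the rows of `V_r` are the
first `r` *eigengenes* (characteristic temporal profiles) and `W` the
gene loadings.  The low-dimensional system `dV/dt = B_r V` is estimated
from consecutive snapshots:

1. **Propagator**: least-squares fit of `Φ` with `V(t_{k+1}) ≈ Φ V(t_k)`,
   via the pseudo-inverse of the lagged snapshot matrix.
2. **Continuous system**: `B_r = logm(Φ)/τ` for sampling interval `τ`
   (or a first-order Euler difference).
3. **Principal oscillation patterns**: each complex conjugate eigenvalue
   pair `σ ± iω` of `B_r`, with eigenvector `e`, defines patterns
   `p1 = Re(e)`, `p2 = −Im(e)` spanning a plane on which the dynamics
   rotate with period `2π/ω`.  Mapped through the loadings, `P1 = W p1`
   and `P2 = W p2` are genome-wide oscillation patterns.
4. **Per-gene amplitude and phase**: gene `n`'s coefficients
   `(c1_n, c2_n) = (P1_n, P2_n)` are converted to polar form
   `r_n = √(c1_n² + c2_n²)`, `θ_n = atan2(c2_n, c1_n)`.  A large `r_n`
   means strong oscillation at frequency `ω`; `θ_n` marks where in the
   cycle the gene peaks.  Real eigenvalues are non-oscillatory decay
   modes and are reported separately.

On top of this the package provides the surrounding workflow: an
ODE-based simulator with exported ground truth, missing-value filtering,
iterative SVD imputation and row normalization, Welch/F/permutation
comparisons of amplitude distributions, survival-curve threshold
selection for calling periodic genes, circular phase medians per
annotation group, and plots.

## Worked example

```python
from popgex import SimulationConfig, simulate_dataset, POPModel, evaluate_recovery

x, truth = simulate_dataset(SimulationConfig(n_genes=1000, seed=1))
res = POPModel(x, rank=5).fit()
print(res.summary())
```

```
                 Principal Oscillation Pattern Analysis
========================================================================
No. genes: 1000         No. time points: 18     Interval: 7 min
Rank: 5                 Covariance captured: 100.00%
Discretization: matrix-log Propagator residual: 2.314e-01
------------------------------------------------------------------------
Mode                  Eigenvalue (1/min)        Period (min)  Energy
POP pair 1            -0.0002 ± 0.2093i      30.03         670
POP pair 2            +0.0040 ± 0.0390i      161.12        59.9
decay (slow)          +0.0000                --            2.36e+07
------------------------------------------------------------------------
Leading-pair gene amplitudes: mean 0.4999, max 1.0606 (n=1000)
```

The simulator drove every gene with a 30-minute oscillation; the leading
pair recovers a 30.03-minute period.  The huge-energy slow decay mode is
the near-constant baseline component of uncentered expression data, and
the second, low-energy pair is a noise mode.  Checking the per-gene
readout against the generator's ground truth:

```python
rep = evaluate_recovery(res.gene_table, truth)
print(rep.amplitude_pearson, rep.phase_sine_pearson_aligned)
```

```
amplitude Pearson r = 0.990
sine-phase Pearson r (raw/aligned) = -0.138 / 0.962
global phase offset = 99.7 deg
```

Recovered amplitudes correlate at 0.99 with the planted ones; after
removing the single global phase rotation (eigenvector gauge plus the
kinetic response lag — here 99.7°), the sines of the phases correlate at
0.96.  `res.gene_table.to_frame()` gives the per-gene table
(c1, c2, amplitude, phase in degrees), `res.plot_polar()` the polar
phase map.

The same pipeline is scriptable from the shell:

```sh
popgex simulate --n-genes 4000 --seed 1 --out expr.tsv --truth truth.tsv
popgex analyze expr.tsv --rank 5 --out-prefix run1
popgex evaluate run1.pops.tsv --truth truth.tsv
popgex threshold run1.pops.tsv --reference known_genes.txt --plot curves.png
```

Real datasets enter as tab-separated gene × time tables
(`popgex.load_expression`), typically after
`popgex preprocess` (drop genes with more than 3 missing samples,
SVD-impute the rest, scale rows to unit norm).

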