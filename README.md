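# diffmix

Ensemble mixture modeling for differential analysis of high-throughput
genomic data: gene expression, DNA methylation, and differential
protein–DNA binding (ChIP-seq), or any other setting that reduces to a
per-unit normalized difference score between two conditions.

## The problem and the model

Given per-unit scores `y_i` (typically log-ratios between two
conditions, one per gene / probe / region), the task is to decide which
units are *differential*. Different platforms produce differently shaped
score distributions, so `diffmix` does not commit to one parametric
form. It fits an ensemble of three classes of two-level finite
mixtures,

    f(y) = (1 − π) f0(y) + π f1(y),

where `f1` captures overdispersed (differential-leaning) scores and
`f0 = Σ_k γ_k N(μ_k, σ_k²)` the centrally located bulk:

| class  | f1 (differential family)            | f0            |
|--------|-------------------------------------|---------------|
| NUDGE  | uniform on `[min y, max y]`         | single normal |
| iNUDGE | uniform on `[min y, max y]`         | K normals     |
| GNG    | two shifted exponential tails       | K normals     |

Parameters are estimated by EM on a weighted log-likelihood
`Σ_i w_i log f(y_i)`, where the weights `w_i ∈ [0, 1]` (lower-half
Huber function of the standardized average log-intensity, `c = 1.345`)
downgrade scores measured at low intensity. The order `K` is chosen
within each class by BIC, and the winning class across the ensemble by
AIC — parsimony where it protects against singular normal components,
flexibility where a too-simple model would cost power.

Classification is in two steps. A normal component is labeled
differential when one of its 2σ tails reaches the outlier region of the
data, `|μ_k| + 2σ_k > 1.5 · IQR(y)`; `f1` is always differential. Each
unit then gets a local false discovery rate

    fdr(y_i) = f_nd(y_i) / f(y_i),

the density share of the nondifferential components, and is called
differential when `fdr(y_i) / w_i ≤ z0` (default `z0 = 0.1`), so
downweighted units need stronger evidence.

A built-in generator reproduces the two-channel microarray simulation
design used to validate the approach (uniform control log-expression on
(15, 30), intensity-dependent noise, three effect-size laws, bounded
null log-ratios) with known ground truth, and a replicate driver
reports TPR/FPR per model class.

## Worked example

```python
import diffmix as dm

sim = dm.simulate_dataset(dm.SimConfig(n=4000, g_law="exponential", seed=42))
model = dm.DifferentialMixture(sim.y, intensity=sim.u, ids=sim.ids)
res = model.fit(seed=0)
print(res.summary())
```

```
Ensemble mixture model results
================================================================
best class:          iNUDGE   (K = 2)
n observations:      4000
weighted loglik:     -2209.4051
BIC / AIC:           -4468.57 / -4430.81
converged:           True (70 iterations)
differential normals: [0]   (IQR = 0.3820)
calls at z0=0.1: 359 of 4000
----------------------------------------------------------------
parameter         estimate       std err
pi                 0.00775
gamma[0]           0.11518
mu[0]             -0.14841
mu[1]              0.00157
sigma2[0]          5.59494
sigma2[1]          0.06006
fixed: a = -10.3371, b = 9.0785
================================================================
```

AIC picked iNUDGE with two normals: a narrow component (σ² ≈ 0.06)
holding the nondifferential bulk and a wide one (σ² ≈ 5.6) that the IQR
rule labels differential — it is this labeled component, not the almost
empty uniform (π ≈ 0.008), that carries most of the differential mass.
359 of 4000 units are called. Scoring against the generator's truth:

```python
tpr, fpr = dm.evaluate(res.calls, sim.truth)   # (0.892, 0.0006)
```

`res.to_frame()` gives the per-unit table (id, y, w, fdr, fdr/w, call),
`res.criteria_table()` the BIC/AIC scan, `res.bse` approximate sandwich
standard errors, `res.qq_table()` / `res.plot_density()` goodness-of-fit
views, and `res.simulate(n)` draws from the fitted density.

The same pipeline is available from the shell:

```sh
diffmix simulate --n 10000 --g-law exponential --seed 7 --out sim.tsv
diffmix fit sim.tsv --seed 0 --out-prefix run    # JSON report + unit table
diffmix replicate --g-law uniform --n-reps 10 --seed 0 --out reps.tsv
diffmix evaluate run.units.tsv --truth-file sim.tsv
```

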