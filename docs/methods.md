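# Methods

## Model

Scores `y_i` (one per gene / probe / region; normalized log-ratios
between two conditions) are modeled as a two-level finite mixture
`f(y) = (1 − π) f0(y) + π f1(y)`. Three classes are fitted:

* **NUDGE** — `f0 = N(μ, σ²)`, `f1 = U[a, b]`, with `a = min y`,
  `b = max y`.
* **iNUDGE** — `f0 = Σ_{k=1..K} γ_k N(μ_k, σ_k²)`, same uniform `f1`.
* **GNG** — the same K-normal `f0`; `f1` is a pair of shifted
  exponentials: density `(1/β1) exp(−(−y − ξ1)/β1)` for `y < −ξ1`
  (mixing weight ρ) and `(1/β2) exp(−(y − ξ2)/β2)` for `y > ξ2`
  (weight 1 − ρ), zero in between. `β1, β2` are scale (mean-excess)
  parameters.

The uniform bounds are fixed at the data range and not updated by EM —
the MLE of uniform bounds inside a mixture is unstable, and the range
convention makes `f1` a proper "anything, anywhere" background. The
exponential offsets are treated as known, estimated once as
`ξ1 = |max of the negative scores|`, `ξ2 = min of the positive scores`,
and held fixed throughout EM. An alternative would be to re-estimate
them each iteration from the current responsibility split; we do not,
because the resulting support changes make the likelihood
discontinuous across iterations. Consequence: fitted `β`s measure the
mean excess beyond the *estimated* offsets, which for data with scores
on both sides of zero are typically near 0; recovery experiments
should compare `ξ + β` (the tail mean) rather than `β` alone when the
generating offsets are not near the estimator's convention.

## Robustness weights

A log-ratio computed from two dim measurements is noisier than the
same log-ratio from bright ones, so the likelihood is weighted:
`l(Ψ) = Σ_i w_i log f(y_i; Ψ)`. With `u_i` the average log-intensity
standardized to mean 0 and sd 1 (sample sd, ddof = 1), the default
weight is the lower-half Huber function, `w(u) = 1` for `u > −c` and
`c/|u|` below, `c = 1.345`. A smooth lower-half bisquare-style
alternative is provided — 1 above `−c`, `(1 − ((u + c)/taper)²)²` on
`[−c − taper, −c]` (taper 4.685), 0 below — as are upper-half mirrors
and two-tailed (pointwise-minimum) variants for designs where high
intensities are the suspect ones. Weights are prespecified data, not
parameters: estimation treats them as fixed, and all M-step updates
are invariant to rescaling them.

## EM, initialization, restarts

E- and M-steps are the standard responsibility-weighted closed forms
for the weighted likelihood (responsibilities multiplied by `w_i` in
every M-step sum; `π̂` is the weighted responsibility share of `f1`
against `Σ w_i`). Iteration stops when the maximum absolute change
over the free scalar parameters drops below `tol = 1e-5`, or after
`max_iter = 2000` iterations.

Defaults that matter:

| parameter | default | meaning |
|---|---|---|
| `tol` | 1e-5 | max-abs parameter-change stopping rule |
| `max_iter` | 2000 | EM iteration cap per run |
| `n_restarts` | 5 | starting points per fit |
| `short_run_iters` | 100 | exploratory cap per restart (em-EM) |
| `K_max` | 6 | largest normal order scanned |
| `c` | 1.345 | Huber tuning constant |
| `z0` | 0.1 | fdr/w call threshold |

Mixture likelihoods are multimodal, so each fit runs `n_restarts`
starting points: the first from the configured initializer (K-means on
`y` by default; evenly spaced quantiles and uniform-random means are
alternatives; `π` starts at 0.1, `ρ` at 0.5, `β` at 1), the rest from
random starts under seeds derived from the master seed. Restarts use
the *em-EM* strategy: every start runs at most `short_run_iters`
iterations, the start with the best weighted log-likelihood continues
to convergence (ties to the earliest restart). This spends iterations
where they matter; setting `short_run_iters ≥ max_iter` recovers
plain full-length restarts. Everything is deterministic given
(data, config, seed).

Numerical safeguards: component variances are clamped at
`1e-6 · var(y)` and hitting the floor records a potential-singularity
warning (unequal-variance normal mixtures have unbounded likelihood
spikes); a component whose total weighted responsibility falls below
1e-10 keeps its previous parameters ("frozen", warned) rather than
being deleted, so K stays meaningful for BIC; `β`s are floored at
1e-8; zero total density at any point (possible only with invalid
support settings) raises an error naming the offending unit.

## Model selection

Within a class, K = 1..`K_max` (NUDGE: K = 1 only) and BIC
(`2 l − p log n`, maximize) picks K; across the three class winners,
AIC (`2 l − 2p`) picks the overall model. The stronger within-class
penalty avoids overfitting the normal order (and the singularity risk
that comes with it); the milder across-class penalty avoids defaulting
to an overly simple class. Free-parameter counts: NUDGE 3, iNUDGE 3K,
GNG 3K + 3; the fixed `a, b, ξ1, ξ2` are not counted. The sample size
in BIC is the number of observations `n`, not `Σ w_i`, consistent with
treating the weights as fixed known constants. Ties break toward
smaller K within class, and toward the richer differential family
(GNG over iNUDGE over NUDGE) across classes.

## Classification

A normal component is labeled differential when
`|μ_k| + 2 σ_k > 1.5 · IQR(y)` (strict; IQR from unweighted empirical
quartiles with linear interpolation). Both constants are exposed
(`tail_sd`, `iqr_mult`) since the call set is sensitive to them, but
the defaults above are the method's definition. `f1` is always
differential. The local fdr is the nondifferential density share
`(1 − π) Σ_{k nondiff} γ_k N(y; μ_k, σ_k²) / f(y)`, and unit `i` is
called when `fdr(y_i)/w_i ≤ z0`; zero-weight units are never called.
With no nondifferential component the fdr is identically zero — every
unit would be called, which is the correct degenerate reading, but in
practice indicates the labeling threshold is too low for the data.

## Synthetic data generator

The generator emulates a two-channel microarray comparison with known
truth. Differential units: control log-expression `x1 ~ U(15, 30)`;
treatment `x2 = x1 + Z + (2B − 1) G` with `Z ~ N(0, 0.7 − 0.02 x1)`
(the second argument read as a *variance*, giving sd 0.32–0.63,
decreasing in expression; a config switch reads it as an sd instead,
preserving the same direction), `B ~ Bernoulli(1/2)`, and effect size
`G` from one of three laws: `1 + Exponential(scale 1.4286)`,
`U(1, 4)`, or `N(2.5, 0.75²)`. Nondifferential units: `x2 = x1 + d`
with `|d| ≤ 1`, where `d` comes either from a user-supplied pool of
real null log-ratios (`null_source="pool_file"`) or, by default, from
a parametric stand-in `N(0, 0.25²)` truncated to `[−1, 1]`. Defaults:
n = 10,000 units, 10% differential. The analysis input is
`y = x2 − x1` with intensity `u = (x1 + x2)/2`.

What the stand-in does *not* emulate — and therefore what passing
simulations do and do not show: real microarray null log-ratios are
leptokurtic, slightly asymmetric, and often multimodal, while the
stand-in is exactly Gaussian with thin (truncated) tails. Three
consequences observed consistently in our replicate studies:

1. A single narrow normal suffices for the stand-in null, so BIC keeps
   K small and the null's extreme tail (|y| near the truncation bound,
   ≈ 4σ) is covered by *differential* components; the handful of null
   units landing there (a few per 9,000) can be called, so the
   false-positive rate is very small (~1e-4–1e-3) but not exactly
   zero. With a heavy-tailed empirical null, extra nondifferential
   normals cover that region and such calls are suppressed.
2. With the null this easy, the uniform-background iNUDGE usually
   matches GNG's likelihood within a few points, and AIC's 3-parameter
   edge for iNUDGE means GNG is not reliably preferred even when the
   differential tails are genuinely exponential.
3. NUDGE's single normal fits the Gaussian stand-in null essentially
   perfectly, so NUDGE is far more competitive here than on real,
   non-Gaussian nulls, where its one-component `f0` is the binding
   constraint.

Users wanting a faithful null should supply real null differences via
`pool_file`. The truncation bound, stand-in sd, sample sizes and
differential fraction are all config fields.

## Replicate studies and problem sizes

`run_replicates` simulates, weights, fits all classes, selects,
classifies at `z0`, and scores TPR/FPR per class and for the ensemble
pick, deterministically from a master seed. The package's validation
studies use 10 replicates per effect-size law at n = 10,000 — enough
to see the selection and power patterns while keeping a full study in
the minutes range; a single ensemble fit (13 class/K combinations × 5
restarts) takes ~15 s at n = 10,000 on one core.

## Standard errors

`EnsembleResults.bse` reports sandwich (robust) standard errors from
numerically differentiated per-observation weighted scores: central
differences of `log f(y_i; θ)` in the free parameters, bread from the
Jacobian of the total weighted score, meat from the outer product of
per-observation weighted scores. They are approximate — EM terminates
on parameter change, boundary estimates (π near 0, floored variances,
frozen components) violate the interior-optimum assumption and come
back as NaN — and are meant for orientation, not formal inference.

## Known limitations

* Two-condition designs only; the method consumes one difference score
  per unit and assumes the data are already normalized.
* Uniform bounds tied to the observed range make the NUDGE/iNUDGE
  likelihood (mildly) dependent on the sample extremes.
* The IQR labeling rule is a hard threshold; components near the
  boundary flip labels under small perturbations, and the call set
  inherits that sensitivity.
* No penalized-likelihood regularization of component variances; the
  variance floor plus BIC parsimony is the only protection against
  singular components.
* Local fdr is per-unit; no global FDR / q-value summaries.
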