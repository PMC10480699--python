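# Methods

## Model and assumptions

All inference is phylogenetic generalized least squares (PGLS). For `n`
species with trait vector `y` and design matrix `X` (intercept plus
transformed predictors), the model is `y = Xβ + ε` with
`ε ~ N(0, σ²·C(λ))`. `C` is the Brownian-motion variance–covariance (VCV)
matrix of the phylogeny: `C[i,j]` is the branch length shared by the
root-to-tip paths of species *i* and *j* (equivalently the depth of their
most recent common ancestor), `C[i,i]` the root-to-tip distance. Pagel's λ
rescales the off-diagonal entries, `C(λ) = λ·C + (1−λ)·diag(C)`, a convex
combination of PSD matrices and hence PSD throughout `λ ∈ [0, 1]`; λ = 0 is
the star-phylogeny (iid) limit and λ = 1 full Brownian covariance. The
model assumes the tree is rooted with branch lengths on every non-root
edge; it does not require ultrametricity (non-ultrametric trees produce a
warning because tip variances then differ, but the GLS remains defined). A
branch length on the root, which arises when pruning to a clade below the
original root, is treated as a stem shared by every tip and enters all VCV
entries; this is what makes pruning commute exactly with taking the VCV
submatrix.

Species matching between trees and trait tables is canonical:
case-insensitive, with spaces and underscores interchangeable, because the
two kinds of file rarely agree on conventions.

## Estimation and statistics

λ is estimated by maximum likelihood on [0, 1]: the profile log-likelihood
(β profiled out by GLS, σ² by its ML estimate RSS/n, computed via Cholesky
whitening) is evaluated on a 0.01 grid and the best cell is refined with a
bounded Brent search (xatol 1e-6); the refinement is never allowed to do
worse than the grid, and boundary estimates of exactly 0 or 1 are common
and legitimate. The grid pre-scan matters because the profile likelihood
can be multimodal; a purely local optimiser started from a fixed value can
(and in our cross-checks against an independent implementation did) settle
on a lower mode.

At λ̂, β̂ is the GLS estimate and standard errors use the *conventional*
residual variance RSS/(n−k) in the whitened space rather than the ML
denominator n, so t = β̂/se matches ordinary regression conventions with
df = n−k. R² is computed against an intercept-only GLS null evaluated at
the focal model's λ̂ (1 − RSS_model/RSS_null in the whitened space), which
keeps nested comparisons coherent; whether the null should instead carry
its own λ̂ is a genuinely open convention — the difference is in the third
decimal in our checks — and we chose the shared-λ̂ form. Adjusted R²
applies the usual (n−1)/(n−k) correction and may be negative. The
whole-model F is the nested comparison against the same null with
(k−1, n−k) df; with a single predictor F = t². Partial R² for one
predictor is 1 − RSS_full/RSS_reduced with each model keeping its own λ̂.

Directional hypotheses are declared per predictor in the model spec; a
declared sign yields a one-tailed p (P(T ≥ t) for "+", P(T ≤ t) for "−"),
otherwise two-tailed. Significance is α = 0.05, with p ≤ 0.1 reported
descriptively as a trend.

Transforms (`none`, `log`, `sqrt`, and `log1p` as the zero-tolerant log)
are applied per variable before fitting; `log` of a non-positive value is a
hard error naming the offending species, and when residual diagnostics fall
back to `log1p` for a zero-containing outcome the +1 offset is announced
with a warning. Residual normality is checked by Shapiro–Wilk on the
whitened residuals (skipped with a notice below n = 8); when it fails, the
transforms are retried in the order none → log → sqrt and the first whose
refit passes p > 0.05 is recommended.

Minimum sample rule: no model is fitted with fewer than 5 complete-data
species, or fewer than 5 species in either category of a binary (0/1)
predictor. Missing data are handled by listwise deletion per model, which
is why N varies across models in a pipeline run. Rank-deficient designs
and zero-variance outcomes are hard errors, reported as "untestable" where
a pipeline step catches them.

## The DD:AD statistic

Minimum annual travel distance is the circumference of the circle whose
area equals the annual home range, `AD = 2·√(π·AHR)` — a deliberately
conservative, shape-agnostic lower bound that makes species comparable —
and `DD:AD = DD/AD`. The ratio is dimensionless, strictly increasing in DD,
strictly decreasing in AHR, and undefined (missing, with a warning) at
AHR = 0. Inputs are species-level medians; aggregating multiple field
studies into those medians is upstream of this package.

## The stepwise pipeline

The pipeline is deliberately manual (no AIC-based selection): sample sizes
and transformations differ across variables, so each step is an explicit
hypothesis test.

1. *Assumption checks*: the welfare outcome must still show the AHR
   association (one-tailed, wider-ranging worse), and, when a column is
   supplied, juvenile mortality must track infant mortality.
2. *Screening*: each candidate is regressed on log-AHR (two-tailed by
   default; the direction is immaterial to a two-variable association
   test). AHR is always log-transformed — it spans orders of magnitude.
   Candidates below minimum-N are marked `skipped`, never dropped silently.
3. *Collinearity*: pairwise PGLS among confirmed candidates at α = 0.05;
   untestable pairs are marked, not guessed.
4. *Univariate welfare models*, one-tailed where a sign is predicted.
5. *Mediation*: each univariately significant candidate is refitted with
   AHR. `independent_predictor` ⇔ the candidate stays significant in the
   joint model; `byproduct_of_AHR` ⇔ it was significant alone but loses
   significance next to AHR; `shared` covers candidates with no univariate
   effect to explain. "Reduced but not eliminated" is reported
   descriptively (change in t) but does not affect classification.
6. *Combined collinear model*: when ≥ 2 surviving predictors were flagged
   collinear, one joint model (with AHR) identifies the term(s) that stay
   significant; those are the pipeline's final predictors.
7. *Mortality models*: per candidate, a univariate fit and an
   altriciality-controlled fit, with the candidate's partial R² against an
   altriciality-only reduced model on the same species.

Husbandry-robustness refits are expressible as ordinary add-covariate
models with user-supplied columns; constructing or coding husbandry
variables is out of scope.

## Influence and treeblock diagnostics

Leave-one-out influence refits the model with each species removed
(deletions that would break minimum-N are skipped), and standardises the
shift in each slope: `(β̂₋ᵢ − β̂_full) / SD({β̂₋ⱼ})`, the denominator being
the SD of the leave-one-out estimate distribution per term (a full-model-SE
denominator is selectable). |difference| > 2 on any slope flags the
species, and the model without each flagged species is attached with its
own re-estimated λ̂. When the leave-one-out spread is numerically zero
(relative 1e-12; e.g. noiseless collinear data) the record is marked
degenerate and nothing is flagged. λ is re-estimated in every deletion and
every treeblock refit, never frozen, since reduced models can have very
different signal. Treeblock summaries report median/min/max of (β, t, p)
per term over trees, the λ̂ range, the fraction of trees significant at α,
and a stability verdict at 95%.

## The synthetic-data generator

The generator emulates the structure of a Carnivora comparative study so
that every pipeline stage has a testable ground truth. A pure-birth (Yule)
tree (unit birth rate; the interval after the last split drawn from the
n-lineage waiting time so tips are contemporaneous) is rescaled to unit
depth. Traits are drawn from the exact model PGLS assumes — multivariate
normal with covariance σ²·C(λ_true) — and a user-specified DAG of linear
effects builds derived traits and outcomes in latent units, each target
receiving its own λ-structured noise draw. Display scales are loosely
matched to the biology: AHR spans about four orders of magnitude
(10^(0.5+z) km²), DD:AD roughly 0.03–1.2 (exp(−1.6 + 0.55·z)) with the
daily-distance column back-derived so that the annotated DD:AD reproduces
the latent driver exactly, a binary predation trait is thresholded at a
configured prevalence, and outcomes are emitted directly on the analysis
(transformed) scale to avoid back-transform ambiguity. Missing values are
scattered per column at configurable rates. Everything derives from one
integer seed; identical configurations give byte-identical CSV output.

Default study conditions: 40 species, λ_true = 0.5, unit diffusion rate,
10% missingness per column. The `strong_preset` plants DD:AD as the sole
welfare driver (route-tracing slope −1.4 on the latent log DD:AD, about
R² 0.6 against unit noise; mortality slope −0.9 plus an altriciality
effect 0.6) with allometric slopes of ±0.8–1.0 linking the confirmed
correlates to log-AHR, and two correlates left unlinked so screening has
true negatives. The `null_preset` leaves every trait independent.

What the generator does *not* emulate: measurement error and
within-species variance in trait medians, non-Gaussian trait
distributions, biased (non-random) missingness, topological uncertainty
in the tree, and the meta-analytic provenance of real welfare data.
Passing tests therefore demonstrate correctness of the statistical
machinery under the model's own assumptions, not robustness of the
biological conclusions to violations of them.

## Problem sizes and numerical choices

Test-suite and acceptance-script simulations use 30–100 tips with 100–500
replicates per check, sizes chosen to keep Monte-Carlo error comfortably
inside the asserted bands; the parameter-recovery study uses 100-tip trees
with 300–500 replicates. Cholesky factorisation is used everywhere (an
explicit-inverse GLS path exists only as a test oracle); a numerically
singular C(λ) raises an error suggesting a diagonal jitter rather than
applying one silently. Ties on the λ grid resolve to the smallest λ. The
trait-simulation Cholesky adds 1e-12 to the diagonal to tolerate
zero-length cherries.

## Known limitations

- Plug-in λ: treating the GLS t as exact with df = n−k after estimating λ
  is the field's standard practice but is mildly anticonservative at small
  n — under a global null at the default 40-species conditions the
  pipeline's tests reject somewhat above the nominal 5%, most visibly for
  multi-predictor models (the type-I acceptance check measures this
  directly; with λ fixed at its true value the same tests are calibrated).
  This matches the behaviour of reference GLS implementations on identical
  data and is inherent to the method, not corrected for here.
- λ̂ is also mildly biased toward 0 at these sample sizes (mean ≈ 0.42 at
  true 0.5 on 100-tip trees, as the acceptance script reports).
- Only Pagel's λ is offered as a correlation structure (no OU or κ/δ), and
  binary traits are handled by linear (0/1) PGLS rather than a
  phylogenetic logistic model — adequate for association screening, not
  for prevalence estimation.
- Tree handling is limited to parsing, validation, pruning and VCV
  construction; no inference, dating or rerooting.
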