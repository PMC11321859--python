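# Methods

`shapedyn` implements joint Bayesian inference of a time-calibrated tree
and piecewise-constant diversification/sampling rates for *dated,
continuous-trait samples* — the setting of artefact (or fossil) series
where each sample is a 2-D outline shape with a radiocarbon-derived age.
This note documents the models, the numerical choices, what the synthetic
data emulate, and the package's known limitations.

## Outline shapes to continuous characters

Raw closed outlines are centred, scaled to unit centroid size (root mean
squared distance of the points to the centroid), rotated by a per-specimen
angle, and re-indexed so a designated homologous point comes first.
Orientation and starting point are *inputs*: artefact orientation is a
judgement call made by the analyst, so the package never infers it.

Elliptic Fourier analysis (EFA) decomposes each closed polygon into
per-harmonic coefficients (a_n, b_n, c_n, d_n), parameterizing the curve
by chord length; the integrals are evaluated exactly for the
piecewise-linear polygon. Harmonic power is (a² + b² + c² + d²)/2, and the
harmonic count is the smallest H whose cumulative power reaches a stated
fraction (0.999 by default) of the outline's full-resolution power.
Flattened coefficient vectors are reduced by centred (covariance) PCA —
no per-column rescaling, since all coefficients share units — giving
de-correlated PC scores as phylogenetic characters. With n specimens the
centred PCA has rank at most n − 1; the package reports the true rank
rather than padding axes.

**Parameterization caveat.** A curve reconstructed from truncated EFA
coefficients and re-decomposed does not return exactly the same
coefficients: the forward transform re-parameterizes by chord length while
the reconstruction samples the Fourier parameter uniformly. The discrepancy
is first order in the shape's speed non-uniformity; measured on
near-circular blade-like shapes it is roughly 4–30% of the deviation from
circularity and contracts under iteration. Round-trip identities are
therefore exact only on constant-speed curves (circles), and trait
round-trip tests use tolerances of that order. This does not affect the
forward pipeline (outline → traits), which never reconstructs.

## Chronology

A lab date (14C age ± error) is calibrated against a curve (calendar age,
14C age, curve error) by scoring every grid age with the normal density of
the measured age around the linearly interpolated curve mean, variance
lab² + curve², then normalizing by the trapezoid rule on the curve's native
grid (no spline — reproducibility over smoothness). Multi-date locales are
combined into a summed probability distribution (SPD), the pointwise sum
renormalized. Point ages are SPD medians; age uncertainty is the envelope
of the 68.27% highest-density region (a central interval is available —
`sigma_range(..., method="central")` — the field's tools do not agree on
the convention, and the HPD is the default here). Ages are expressed in ka
BP (years/1000, rounded half-even to 3 decimals). Climate bins follow the
Greenland event stratigraphy — GS-2, GI-1, GS-1, Holocene — bounded at
14.6, 12.9 and 11.7 ka BP, each boundary belonging to the older bin.

## Tree model

The fossilized birth–death (FBD) process starts from one lineage at the
origin and runs toward the present: birth λ, death μ, sampling ψ (per ka),
all piecewise constant over the climate bins (skyline), with extant
sampling probability ρ = 0 because every sample predates the window close.
Samples with sampled descendants are degree-2 *sampled ancestors*;
zero-length side branches in Newick files are only a rendering.

The density of the sampled tree multiplies, per event, λ·q(t) for
bifurcations, ψ·p0(t)/q(t) for terminal samples, ψ for sampled ancestors,
and q(origin), optionally divided by 1 − p0(origin) to condition on
observing at least one sample (the default; the density also conditions on
the origin time). p0(t) is the probability that a lineage alive at age t
leaves no sample; q(t) is the observed-lineage factor. Both solve a
Riccati equation with closed-form solutions inside each interval; the
skyline stitches the per-interval solutions together continuously, working
from the present backwards. Degenerate corners (λ = 0, or λ = μ with
ψ = 0) use the limiting solutions. With equal rates in all intervals the
skyline reduces to the constant-rate density to 1e-10, and the
constant-rate density matches an independently coded closed form on random
sampled-ancestor trees.

Priors: Exp(10) on every λ, μ, ψ (mean 0.1/ka, the magnitude typical of
macroevolutionary rates — ages in ka make rates per ka); improper U(0, ∞)
on the origin (zero log-density contribution; the origin must exceed the
root age); uniform tip-age priors within each sample's calibrated
one-sigma interval.

Diversification d = λ − μ and turnover t = μ/λ are recomputed row-wise
from the posterior trace before summarizing.

### Observation windows that close before the present

The empirical setting ends at ~11 ka BP: no samples are possible later.
Rather than carry an 11.7-ka empty tail (which would dilute the youngest
interval's rates), inference re-expresses ages relative to the close of
the observation window (`shift_for_inference`), so the process "present"
is the youngest possible sampling moment and the skyline boundaries shift
accordingly. Reported ages are shifted back.

## Trait model and clocks

Traits follow a correlated Brownian motion: over a branch of duration τ
with clock rate r the trait vector gains a N(0, τ·r·Σ) increment, where
Σ is the equicorrelation matrix with per-trait variance rates σ²
(positive-definite iff the shared correlation exceeds −1/(k−1)). The root
trait values are parameters (prior N(0, 2) per trait); σ² has a lognormal
prior with log-space location 1 and scale 0.3 (a real-space-mean
parameterization is provided, since the two conventions are both in use);
the correlation is U(−1, 1) with non-positive-definite states rejected.

The likelihood is a pruning pass: messages (mean, variance per trait) flow
post-order; the traits are first rotated into Σ's eigenbasis so each
transformed trait is an independent univariate Brownian motion and the
messages vectorize. Sampled ancestors contribute point observations along
lineages. The pass equals the dense matrix-normal density (shared-path
matrix ⊗ Σ) to 1e-8 on random trees. A sample sitting exactly at the root
would pin the root state (a degenerate density); such states evaluate to
−inf and are thereby excluded from the posterior.

Clocks: a strict clock; an uncorrelated lognormal clock (ULNC) whose
branch rates are i.i.d. lognormal with real-space mean M (prior Exp(10))
and log-space s.d. S (prior Gamma(0.54, scale 0.38), mean ≈ 0.2); and a
two-category clock (nCat2) with two estimated rate values (Exp(5) priors)
and uniform per-branch assignments. The overall clock is shared across
traits. Every node owns the branch above it; the root owns the origin
stem, whose rate enters the clock prior only (no trait evolution above
the root) — this keeps the rate dimension fixed under topology moves.

## MCMC

A plain Metropolis–Hastings kernel with fixed tuning (no adaptation).
Moves: multiplicative scaling of every positive scalar; an independence
redraw of single skyline rates from their exponential priors (the
Hastings ratio cancels the prior, so acceptance depends on the tree
density alone — this mixes weakly informed rates and the near-zero tail
far better than scaling); uniform slides of tip/sampled-ancestor ages
within their calibrated bounds and of node ages within their topology
windows; an origin-gap scaler; a tree-height scaler (all bifurcation ages
and the origin, samples fixed); a likelihood-invariant rate↔variance swap
(all branch rates up, all σ² down) that walks the clock–variance ridge;
narrow exchange; age-respecting subtree-prune-regraft; and a
reversible-jump toggle between terminal samples and sampled ancestors
(the vanishing bifurcation age is matched by a uniform draw, and the
vanishing branch rate, under the ULNC, by a draw from the clock's
lognormal).

Correctness evidence, all in the test suite or reproduced by
`scripts/acceptance.py`:

* prior-only runs reproduce the analytic Exp(10) rate priors
  (Kolmogorov–Smirnov);
* the sampled-ancestor toggle matches the analytic posterior odds of the
  chain-vs-cherry configuration on a two-sample system;
* SPR and narrow exchange reproduce numerically integrated topology
  probabilities on three fixed-age samples;
* with rates drawn from their priors and a fixed true tree, 95% HPDs
  cover the truths at nominal rates (simulation-based calibration).

The trace follows the phylogenetic log convention: `posterior =
likelihood + prior`, with the FBD tree density counted inside the prior
column, so an *under-the-prior* run (trait likelihood off, likelihood
column constant 0) still estimates diversification rates from the
sampling times. Initialization: a deterministic age-ladder tree over the
dated samples, rates at prior means, the Brownian variance rates at a
method-of-moments value (trait variance over tree depth × clock rate) so
the chain does not spend its whole budget descending the variance ridge —
the start point does not alter the stationary distribution. Chains are
desk-scale (tens of thousands to a few hundred thousand generations);
empirical analyses of this kind run many orders of magnitude longer on
clusters, and the package's convergence report (ESS of prior, posterior
and likelihood, threshold 200, spectral estimator via ArviZ) is the
stopping rule. Log combining discards a 20% burn-in per chain and
concatenates.

## Posterior summaries

Clades are taxon sets (sampled ancestors belong to the clade they attach
to). The MCC tree is the *sampled* tree maximizing the product of its
clade posterior probabilities — no consensus construction — annotated
with clade supports, 95% HPD node-age ranges, and median branch lengths
and rates of matching clades; target heights are kept by default. HPD
intervals are the shortest contiguous sample window. The skyline summary
reports median and 95% HPD of λ, μ, ψ, d, t per climate bin. The
taxa–trait grid reruns scaled-down inference per cell (nested trait
prefixes of the PC axes, stratified nested taxa subsets, one logged seed
per cell) and records the posterior median and variance of the clock rate
plus the MCC metric summaries; per-cell failures are recorded without
stopping the grid.

## What the synthetic data emulate — and what they do not

The study generator (`make_study_scenario`) emulates a Late Glacial
artefact series: four climate bins, an observation window of 18–11 ka BP,
stratified per-bin quotas of 4/8/15 taxa (16/32/60) or all samples
trimmed to 87, shapes evolved as Brownian perturbations of leading
elliptic Fourier coefficients around a blade-like base form (σ² decaying
geometrically across axes, shared correlation 0.25, ULNC clock with mean
1 and s.d. 0.25), and one-to-four lab dates per locale calibrated against
a smooth synthetic wiggly curve. The truth rates make births fastest in
GS-2 and deaths peak in GS-1 — the qualitative regime the skyline is
meant to detect — at magnitudes moderate enough that a posterior under
Exp(10) priors can reach them. Sampling effort scales with the target
taxon count (ψ multipliers 1/1/1.8/2.8 for 16/32/60/87).

Two deliberate departures from a literal reading of the empirical window:
the origin sits at 18 ka BP so that the oldest bin accumulates enough
lineages to satisfy its quota under recoverable rates (a 0.4-ka oldest
bin cannot hold 4–16 samples from a single founding lineage without
rates far outside the priors), and parameter-recovery experiments use
`draw_calibration_scenario`, which draws every parameter from its
inference prior and accepts on sample yield — the only design for which
nominal coverage is a mathematical property rather than a hope. Fixed
"published-magnitude" truths are *not* coverable at nominal rates with a
few dozen samples under Exp(10) priors; the generator's fixed-rate
scenario is therefore used where magnitudes matter (trend and
under-the-prior contrasts) and the prior-predictive scenario where
calibration matters.

The generator does not emulate: knapping mechanics or taphonomy, outline
digitization noise, inter-observer orientation variance, reservoir
effects or stratigraphic phase structure in the dates, or the real
IntCal curve's plateau structure (the synthetic wiggles are smooth
low-frequency sinusoids — enough to exercise multimodal calibration, not
a substitute for IntCal20). Passing tests therefore demonstrate the
statistical machinery, not archaeological fidelity.

## Numerical choices and degenerate inputs

* Rate lookups place interval boundaries in the older interval,
  consistent with the bin convention.
* Equal node ages are avoided by the proposal windows (open intervals);
  sampled-ancestor attachments are the one sanctioned equality.
* Zero-mass calibrations, empty SPD lists, all-zero harmonic power,
  sub-2-specimen PCA, non-positive-definite Σ and samples at age ≤ 0
  with ρ = 0 raise explicit errors; structurally possible but
  zero-probability states (a fossil in a ψ = 0 interval) evaluate to −inf
  instead.
* The FBD evaluator special-cases λ = 0 and the repeated-root corner of
  the Riccati solution.
* Seeds: every stochastic routine takes a seed or Generator; identical
  seeds give byte-identical outputs.

## Known limitations

* Trees with ~60+ taxa need longer chains than the desk-scale defaults to
  pass the ESS-200 rule; the taxa–trait grid at 87 taxa is exploratory at
  these settings.
* μ (death) is weakly identified from sampled trees — a known property of
  the FBD, not of this implementation — so its posterior often resembles
  its prior at these sample sizes.
* The under-the-prior contrast and skyline trend are qualitative
  reproductions at desk scale; magnitudes depend on the synthetic truth.
* Only equicorrelation trait covariance is implemented (one shared
  correlation), matching the single-parameter prior; general Σ would need
  a different prior.
* No Ornstein–Uhlenbeck or early-burst trait models; no diversified
  sampling; no reservoir corrections or marine curves.
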