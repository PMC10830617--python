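# Methods

## The model

Screen times from one questionnaire screen (scale) within one respondent
group are transformed to the log geometric mean time per item,
x_i = ln(t_i)/J (natural log, seconds; `transform="total"` exposes ln(t_i)
for single-screen axes). The transform matters: dispersion on this scale
shrinks as 1/J, so per-item log times on a four-item screen typically have
SDs around 0.1–0.2 even when raw screen times vary several-fold.

Within a cell, x is modelled as a C-component Gaussian mixture with
unequal variances,

    f(x) = Σ_c π_c N(x; μ_c, σ_c²),  Σ π_c = 1,

fitted by EM that maximises the weight-multiplied log-likelihood
Σ_i v_i log f(x_i) with survey weights v_i (normalised to mean 1 per cell),
so an integer weight is exactly equivalent to replicating the observation.
C is selected by BIC = −2·loglik + (3C−1)·ln(n) over C = 1..`max_components`
(default 9); ties go to the smaller C. n is the number of observations, not
the summed weights — with mean-1 weights these coincide in expectation, and
the original analysis leaves the weighted-BIC question open.

If the selected C ≥ 2, the component with the lowest mean is labelled
C/IER (ties: lowest index, logged). The label rests on two assumptions
worth keeping in view: that exactly one component is careless when C ≥ 2,
and that careless log times are themselves normal. π^CIER (the labelled
component's mixture proportion) is the primary prevalence estimate; the
weighted mean posterior is reported alongside as an empirical-share
variant. Attentiveness weights are w_i = 1 − p(z_i = CIER | x_i), computed
in log space (never NaN, even for extreme x). A C = 1 solution means "no
C/IER detected": all weights 1. Unequal variances are essential — observed
decompositions include equal-mean/unequal-variance pairs capturing heavy
tails, which an equal-variance family cannot represent.

The analysis model is a multi-group generalized partial credit model:
category probabilities p(y_ij = k | θ) ∝ exp Σ_{l≤k} a_j(θ − b_jl) with the
l = 0 term ≡ 0; item parameters shared across groups; group 1 fixed to
N(0,1) for identification, remaining group means/SDs free. Marginal
maximum likelihood weights each case's log-likelihood contribution by
w_i·v_i (pseudo-likelihood). Missing responses are skipped in the
within-person product; all-missing rows are dropped from estimation but
kept in the weight output.

The validity statistics are the conventional companions: binary indicators
flagging per-item geometric mean times strictly below 2 s, 1 s, or 30% of
the cell's unweighted mean (NT30 uses the unweighted group mean by its
definition; when all times are equal it can never flag); weighted Pearson
correlations between posteriors and omission counts (pairwise-complete,
≥ 3 pairs, zero-variance cases flagged undefined as NaN rather than
propagated); point-biserial agreement between indicators and posteriors;
and lagged correlations of posteriors over screen-position lags 1..15
(simple mean over available position pairs, unweighted — the original
weighting choice is unstated).

Cell-level C/IER proportions are related to scale characteristics through
a hierarchical random-intercept Beta regression:
π_sg ~ Beta(μ_sg φ, (1−μ_sg) φ), logit(μ_sg) = β_0g + Σ_p β_p x_ps,
β_0g ~ N(μ_β0, σ_β0²). Covariates enter raw (uncentred, unscaled) — slopes
are per screen position, per item, per option, per word. Proportions of
exactly 0 or 1 (possible from the mixture step) are adjusted by
(y(n−1)+0.5)/n before fitting.

## Estimation details

**Mixture EM.** Initialisation is weighted k-means on quantile-spread
seeds with 5 restarts: restart 1 unjittered, restart 2 a deterministic
"low-tail" start seeding a small (5%) lowest component at the 2nd weighted
percentile, restarts 3–5 jittered. The low-tail start exists because plain
quantile seeding reliably misses a ~5% low-mean class, landing in a
variance-split local optimum instead. Every restart runs a 50-iteration
burn-in; only the best candidate by log-likelihood is polished to
convergence (relative log-likelihood change < 1e-8, at most 500
iterations; non-convergence is flagged, not fatal). For n ≤ 200 the
restart set additionally enumerates narrow-component starts at data points
— on small samples the ML optimum of an unequal-variance mixture is often
a near-degenerate spike on a tight cluster, unreachable from broad starts.
Variances are floored at σ² ≥ 1e-4 to keep such spikes finite. Cells need
max(10·C, 50) usable observations; below 50 the cell is treated as C = 1
with a warning. Rows with missing or non-positive times are excluded from
decomposition and given weight 1 with a "not assessed" flag — there is no
evidence basis for downweighting them. Each cell's seed derives
deterministically from the root seed and the cell's identifiers (CRC32
into a SeedSequence), so results are independent of row order.

**GPCM EM.** The latent-trait integral uses 61 rectangle nodes fixed on
[−6, 6] in the reference-group metric for all groups (≥ 21 enforced). A
fixed grid — rather than per-group standardised grids — keeps node
positions constant across EM cycles, which makes the observed-data
log-likelihood exactly monotone; free group parameters are updated by
directly maximising their expected complete-data term on that grid
(initialised at weighted posterior moments, old values kept if no
improvement), and item parameters by L-BFGS with analytic gradients under
the same keep-old-if-worse guard. Convergence: max |parameter change|
< 1e-5 or 1000 cycles. Case weights are normalised to mean 1 internally
(log-likelihood reported on the caller's scale), making estimates exactly
invariant to weight rescaling. Categories never observed with positive
weight are collapsed onto adjacent categories with a logged remapping.

"Standardized" group differences in the fit comparison are reported in the
reference-group N(0,1) metric (difference of means, difference of
variances), with a per-group-SD-scaled mean variant alongside; the
original metric is not defined precisely enough to pick one, so both are
emitted, plus the median absolute difference and middle-50% range across
groups.

**Beta regression.** Bayesian mode: Metropolis-within-Gibbs, 2 chains ×
3000 iterations, first half warm-up; priors N(0, 10) on μ_β0 and slopes,
half-Cauchy(0, 5) on σ_β0 and φ; EAP (posterior mean over pooled
post-warm-up draws) point estimates; split-R̂ per parameter with < 1.05
satisfactory. The sampler uses four refinements over naive blocked random
walks, without which the two near-degenerate posterior directions
(μ_β0 ↔ intercepts translation; slope ↔ intercepts shear) do not mix in
3000 iterations: an exact conjugate-normal Gibbs draw for μ_β0; one
adaptive random-walk scale per slope (posterior scales differ by orders of
magnitude); a Jacobian-1 recentring proposal moving a slope and all group
intercepts jointly; and vectorised elementwise updates for the
intercepts. Proposal scales adapt every 50 warm-up iterations toward
0.30–0.45 acceptance. ML mode integrates the random intercept by adaptive
Gauss–Hermite quadrature (21 nodes, mode/curvature recentred per group;
σ_β0 < 1e-6 treated as a point mass) and optimises the 7-parameter
marginal likelihood by Nelder–Mead on log-transformed scale parameters.

## The synthetic-data generator

The generator emulates a grouped, screen-per-scale questionnaire: per
respondent×scale a latent state (C/IER with configured probability,
default 0.06) selects the log per-item time component — attentive
N(0.76, 0.15²) (~2.1 s/item) versus C/IER N(0.12, 0.15²) (~1.1 s/item),
matching the reported attentive/careless time-per-item means; the 0.15 SD
follows from ln-total-time dispersion ≈ 0.6 on a four-item screen divided
by J. The implied separation d ≈ 4.3 reflects clearly separated observed
decompositions. Attentive responses come from a GPCM at θ_i ~ group
normal (group means 0 to 0.5, SDs 1.0 to 1.2 by default) with 2% random
item omissions; C/IER responses follow a style mix — uniform random (0.5),
straight-lining one uniformly chosen category (0.3), full omission (0.2) —
with 25% per-item omissions in the non-omit styles. Sampling weights are
lognormal(0, 0.25), normalised to mean 1 per group. Scales sit at screen
positions 21–80 with 4 items and 4 options by default. The style mix is a
fixture device spanning the canonical careless patterns, not an empirical
claim about any assessment.

What the generator does **not** emulate — so what passing tests cannot
show: non-normal attentive time distributions (heavy tails, skew),
respondent-persistent C/IER propensity across screens (carelessness is
drawn independently per screen, so lagged-consistency statistics are null
on generated data by design), C/IER correlated with the measured trait,
multiple careless components, or language/input-method timing artifacts.

`minimum_sample_size(d) = 8/d⁴` exposes the rule of thumb for the minimal
sample supporting a univariate Gaussian mixture decomposition at
standardized component separation d (128 at d = 0.5; 5000 at d = 0.2).

## Problem sizes in the test suite

Simulation-backed tests run at sizes chosen to give each property clear
resolution on a single CPU: mixture recovery and null-selection studies at
n = 2000 × 50 replications; end-to-end prevalence recovery at n = 1000 ×
50 replications (mean |error| ≤ 0.03 against the generated 0.06); GPCM
recovery at N = 3000 (J = 6, K = 3, two groups); the contamination study
at N = 4000 per replication × 50, with groups N(0,1) vs N(1.0, 1.2²) — the
group separation is chosen so the shrink-toward-centre bias of the
unadjusted fit (≈ −0.16) clearly exceeds per-replication noise — using 31
quadrature nodes and a 1e-3 parameter tolerance (both far finer than the
effect measured); Beta-regression recovery at G = 30 groups × S = 40
scales.

## Limitations

- With a rare C/IER class (~6%) and separation d ≲ 2 the maximum-likelihood
  two-component solution is often a genuine variance-split of the attentive
  distribution rather than the careless/attentive split; prevalence
  estimates then fail in a way no initialisation can fix. The 8/d⁴ rule
  guards estimation error, not label identifiability.
- Heavy-tailed attentive times can be absorbed as an equal-mean,
  larger-variance component whose mean falls marginally lowest, producing
  implausibly high labelled proportions; decompositions with surprising
  prevalences deserve visual inspection.
- Under pure uniform-random careless responding the MML group means are
  nearly unbiased even without adjustment (flat-likelihood cases shrink to
  the group distribution), so the adjustment's benefit concentrates on
  straight-lining and omission-heavy behaviour and on variance estimates.
- The GPCM quadrature grid is fixed at [−6, 6] in the reference-group
  metric; groups whose trait mass extends beyond ±6 would be truncated.
- ML Beta-regression standard errors are not provided; use the Bayesian
  mode when interval statements are needed.
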