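# Methods

## The survival model

The monitoring design observes, per haul *i*, the total number of fish
sampled as the gear comes onboard (*N<sub>i</sub>*), the number of those
alive at that moment (*N<sub>0,i</sub>*), and the number still alive
*t<sub>i</sub>* hours later when the boat lands (*N<sub>f,i</sub>*).
Survival decomposes into two processes:

* **Immediate survival** *S<sub>0</sub>*, the probability of being alive
  when the gear surfaces, modelled on the logit scale as a linear function
  of haul depth and sea temperature at capture.
* **Delayed mortality** among the initial survivors, with an instantaneous
  rate that decays exponentially from its onboard maximum,
  *m(t) = m<sub>0</sub>·e<sup>−t/τ</sup>*. Integrating gives the cumulative
  hazard *M(t) = m<sub>0</sub>τ(1 − e<sup>−t/τ</sup>)*, so the expected
  surviving fraction approaches the nonzero asymptote
  *e<sup>−m<sub>0</sub>τ</sup>* rather than zero — the observed pattern in
  short-term captivity, which neither a Weibull nor a constant-rate model
  can produce. The long-run rate is pinned at zero deliberately: over a few
  hours, mortality from senescence or captivity artefacts is taken as
  negligible, and whatever is left of it is absorbed by the handling term
  below. *m<sub>0</sub>* is linear in depth and in the temperature of the
  port container (fish warmed in the container die faster).

Observation model: *N<sub>0,i</sub>* ~ Binomial(*N<sub>i</sub>*,
*S<sub>0,i</sub>*) and *N<sub>f,i</sub>* ~ Poisson(*N<sub>0,i</sub>* ·
e<sup>−M(t<sub>i</sub>)</sup>). Binomial and negative-binomial variants of
the port count are available behind the same interface for DIC comparison.
Hauls of one fishing trip share normal random effects on both linear
predictors.

**Centering.** Covariates are centred at sample means before the slopes
apply, so the intercepts are the values at the average haul and are
directly comparable to predictions at the reference level. For predictions
with the shipped fleet-level estimates the reference is 25.7 m and 15.7 °C,
with the container reference equal to the sea reference so that the
reference prediction emulates immediate release.

**Relative survival.** Captive monitoring confounds fishing mortality with
an unknown handling mortality that is additive in the cumulative hazard.
Any constant added to *M* multiplies the survival of every condition by the
same factor and cancels in the ratio to the reference condition; the ratio
is therefore interpretable even though absolute survival is not. The
surface exported by `relative_survival_grid` includes the immediate-
survival ratio as well as the hazard ratio; the two headline effect sizes
(temperature doubling, depth percentage) are computed on the delayed-
mortality channel alone, where they have closed forms
(ln 2/(α₂τ) and 100·(1 − e<sup>−α₁·10·τ</sup>)).

**Degenerate inputs.** The linear link can push *m<sub>0</sub>* negative
for extreme covariates; the likelihood clips it at zero (no delayed
mortality) so e<sup>−M</sup> stays a probability, while the sampler remains
free to explore the unconstrained coefficients. A zero Poisson mean with a
positive survivor count scores −∞ rather than raising.

## Fitting

The joint posterior (coefficients, τ, random-effect SDs, per-trip effects)
is sampled by a blocked adaptive random-walk Metropolis sampler written for
these two hierarchies:

* **Scalar blocks** update one global coordinate against the partial
  conditional density — only the terms that involve that coordinate — so a
  β-update never recomputes the Poisson likelihood and vice versa.
* **Group blocks** update a whole level of random effects at once: units
  (trips, fish) are conditionally independent given the globals, so each
  unit's proposal is accepted on its own per-unit density.
* A **pair block** proposes (α₀, log τ) jointly with a 2×2 proposal
  covariance learned during warmup (scaled 2.38²/2), because the product
  m₀τ is much better identified than its factors and coordinate-wise moves
  crawl along that ridge.
* The vitality fit adds two **translation sweeps** that shift a haul-level
  mean and compensate every fish effect, leaving all fish means (hence the
  likelihood) unchanged; acceptance depends only on the random-effect
  priors. This removes the classic mean-versus-effects ridge of the
  hierarchy.

Proposal scales adapt toward 44% acceptance (28% for the pair) in warmup
batches of 50 and are frozen afterwards; the post-warmup chain is a fixed
Markov kernel. The proposal-noise stream is consumed identically whether a
move is accepted or not, so a fixed seed yields bit-identical draws.

Positive parameters are sampled on the log scale with the Jacobian folded
into the prior terms. Priors: Normal(0, 10¹⁶) on linear coefficients;
Gamma(0.01, rate 0.01) on τ and on random-effect *precisions* (reported as
SDs), with a uniform variant for sensitivity. The gamma hyperparameters
follow the convention of the JAGS-style model this reproduces, where the
second argument is a rate; a (shape 0.01, scale 0.01) reading would give a
prior mean of 10⁻⁴ instead of the intended near-flat density. Default
protocol is 3 chains × 60,000 retained draws with 1-of-50 thinning;
simulation studies use 3 × 5,000 with 1,500 warmup iterations, which the
recovery experiments show is ample for this posterior (all split-R̂ ≤ 1.05
at study scale). Convergence is checked with split-R̂ and effective sample
size (arviz); parameters above the 1.1 threshold trigger a
`ConvergenceWarning`, never a silent pass. DIC is the classic
D̄ + p<sub>D</sub> with p<sub>D</sub> = D̄ − D(θ̄), computed on the
observation-model likelihood conditional on the sampled random effects.

## Tracking

Fish in the 23 cm arena are nearly transparent; segmentation therefore uses
a local (Gaussian-weighted neighbourhood mean minus offset) threshold
rather than a global one, after masking pixels outside the arena disc
(located by Otsu/global threshold on each stack's first frame, or per frame
on request). Blobs outside a configurable area window are treated as
shadows or specks and dropped. Identity is maintained by
minimum-total-Euclidean-distance assignment (Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`) between previous fish positions and
current blob centroids. With fewer blobs than fish, unmatched fish keep
their previous position exactly and are flagged imputed; they re-enter the
assignment in later frames and attach to the nearest unclaimed blob — no
appearance model is attempted, so identity swaps during long occlusions are
possible and are quantified (not hidden) by the occlusion study, which
requires ≥ 80% of crossing scenes to resolve correctly. Imputed frames
contribute zero displacement; the accumulated movement registers in the
frame of reacquisition.

Speeds are displacement × frame rate × mm-per-pixel (the scale follows from
the 230 mm arena diameter), averaged over non-overlapping 60-frame bins to
damp temporal autocorrelation: 2 minutes on each side of the stimulus at
20 fps gives exactly 40 + 40 bins. The stimulus frame is supplied by the
caller (default: stack midpoint); acclimatisation trimming is the caller's
job.

## The vitality model

Binned speeds are Gamma(shape, rate) with shape = v̄²/tol and
rate = v̄/tol, so the mean is v̄ and the variance is tol. The surrounding
text of the source model describes *tol* as an inverse variance while its
formulas use it as a variance; the formulas are implemented verbatim
(dispersion = variance), and `tol_is_variance=False` switches every
dispersion to the precision reading for sensitivity analysis — the haul-
level mean estimates are insensitive to the choice. Dispersions are fish-
and-period specific. Fish means decompose as v̄ᵢ,BEFORE = v_mean.BEFORE +
ΔBᵢ and v̄ᵢ,AFTER = v_mean.BEFORE + ΔBA + ΔAᵢ with ΔBᵢ, ΔAᵢ normal random
effects. Each haul is fitted independently; a single fish cannot separate
the haul mean from its own effect and is rejected. Zero speed bins (outside
gamma support) are floored at half the fish's smallest positive bin and the
substitution is logged per fish in the fit metadata.

## Linkage

Per-haul asymptotic survival estimates (posterior medians; their
uncertainty is deliberately not propagated, matching the original
procedure) are logit-transformed — exact 0/1 is rejected, boundary
estimates must be clamped by the configurable ε (default 10⁻⁴) — and
regressed on v_mean.BEFORE, ΔBA, monitoring time, depth and the two
temperatures by OLS (statsmodels). Backward stepwise selection removes, at
each step, the term whose removal lowers AIC most, stopping when no removal
helps; candidates are scanned in sorted order so the result is independent
of how the terms were listed. The implementation was cross-checked against
R's `step(direction="backward")`: identical term selections on noise and
signal fixtures (the AIC values differ by the constant +2 because R counts
the error variance as a parameter, which cannot affect selection).

## Synthetic data

The generators emulate the study conditions: 19 trips with 2–3 hauls each
(≈47 hauls), fish per haul drawn as round(N(189.6, 84.5)) with a floor of
10, depth U(16, 35) m, sea temperature U(14.5, 16.5) °C, port containers
warmer than the sea by U(0.5, 3.5) °C, monitoring times U(1, 9) h, and
container oxygen U(4, 9) mg/l for exercising the exclusion rule (the
threshold is a configuration parameter; no fixed cut-off is prescribed).
The default generating parameters are the fleet-level estimates, with one
change: the immediate-survival random-effect SD is reduced from 4.07 to
1.0, because with a logit intercept of 5.5 trip effects of SD 4 saturate
immediate survival at 0 or 1 and the parameter carries no recoverable
information at simulation scale. Poisson survivor draws are truncated at
the initial alive count — a generator-side guard only; the fitted
likelihood stays pure Poisson.

Arena scenes are a bright disc on a dark background with dark Gaussian
spots for fish, additive Gaussian noise, and scheduled occlusions that
render two fish as one midpoint blob. The renderer does not emulate real
optics: no lighting gradients, no fish-shaped or partially transparent
targets, no motion blur. Passing tracking tests therefore demonstrate the
geometry and identity logic, not robustness to real video artefacts.

## Problem sizes and numerical choices

Simulation studies use 20 replicates at fleet scale for survival recovery
(3 chains × 5,000 draws), 10 replicates for DIC model comparison (2 × 1,500
on 12-trip sets), 20 ten-fish hauls for vitality recovery (2 × 2,500), and
1,000 random scenes for the assignment-versus-brute-force check (n ≤ 6,
where exhaustive permutation search is feasible). Tracking scenes are
240×240 px; the binned-speed pipeline is exercised on programmed
trajectories of 4,801 frames. Root-finding for the temperature-doubling
effect uses Brent's method on [10⁻⁹, 100] °C. Equal-cost assignment ties
resolve deterministically (lowest fish index). Exponentials of sampled
log-scale parameters are guarded at e⁶⁰⁰ — beyond any prior mass — so
unidentified scales (e.g. τ under zero true mortality) cannot overflow.

## Known limitations

* Absolute survival is not estimable without true controls; everything
  downstream of the fit interprets ratios to the reference condition.
* Species-specific fits are out of scope (the pooled ensemble is modelled).
* The tracker maintains identity by proximity only; it is honest about
  occasional swaps rather than attempting appearance-based re-identification.
* Survival-estimate uncertainty is not propagated into the linkage
  regression.
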