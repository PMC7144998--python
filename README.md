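# gobysurv

Estimating the relative post-release survival of discarded transparent
gobies (*Aphia minuta* and *Pseudaphya ferreri*), the small target species
of the Balearic winter purse-seine fishery. When daily quotas are exceeded
or sorting is unworkable, whole catches are slipped back to the sea with
unknown survival; this package implements the complete computational chain
for estimating that survival from short-term captive monitoring, and for
predicting it cheaply from video-derived behavioural ("vitality") metrics.

The chain has four stages, each usable on its own:

1. **Survival model** (`gobysurv.survival`, `gobysurv.inference`).
   Fish sampled as the gear comes onboard are monitored in a seawater
   container until the boat lands. Immediate survival is binomial with
   `logit(S0) = β0 + β1·Depth + β2·Temp0 + rnd2`; survivors then die at a
   decaying hazard `m(t) = m0·e^(−t/τ)` with
   `m0 = α0 + α1·Depth + α2·Tempf + rnd1`, so the expected count alive
   after `t` hours is Poisson with mean `N0·e^(−M(t))`,
   `M(t) = m0·τ·(1 − e^(−t/τ))`. Asymptotic survival is `S0·e^(−m0·τ)`.
   Hauls from one fishing trip share normal random effects (`rnd1`,
   `rnd2`). Because handling mortality in captivity is unknown but
   additive in `M`, only survival *relative* to a reference haul (the
   fleet-average depth and temperature) is interpreted — the handling term
   cancels in the ratio. The joint posterior is sampled by a blocked
   adaptive random-walk Metropolis sampler with vague priors; observation
   models (Poisson / binomial / negative-binomial port counts) are
   compared by DIC.

2. **Tracking** (`gobysurv.tracking`). Multi-fish centroid tracking in a
   23 cm circular arena: global-threshold arena detection,
   adaptive-threshold (Gaussian-weighted neighbourhood) blob segmentation
   with an area filter, Hungarian minimum-distance assignment of blobs to
   fish, carry-forward of occluded fish, and reduction of trajectories to
   swimming speeds (mm/s) averaged in 60-frame bins — 40 bins before and
   40 after a sound stimulus at 20 fps.

3. **Vitality model** (`gobysurv.vitality`). Binned speeds are gamma
   distributed with `shape = v̄²/tol`, `rate = v̄/tol`; fish means decompose
   into a haul mean before the stimulus (`v_mean.BEFORE`), a haul-level
   before→after shift (`ΔBA`), and fish-level normal random effects per
   period. The posterior medians of `v_mean.BEFORE` and `ΔBA` are the two
   vitality metrics.

4. **Linkage** (`gobysurv.linkage`). Logit-transformed per-haul asymptotic
   survival is regressed on the vitality metrics, monitoring time, depth
   and temperatures by OLS with backward stepwise AIC selection.

`gobysurv.simulate` generates every input the chain consumes — haul tables
with binomial/Poisson counts under known parameters, gamma speed series,
and rendered arena frame stacks with known trajectories and scheduled
occlusions — so the whole pipeline is testable end to end without any
field data.

## Worked example

```python
from gobysurv import survival as sv

params = sv.REFERENCE_ESTIMATES      # published fleet-level posterior medians
print(sv.relative_survival(params, 25.7, 15.7))   # 1.0   (reference haul)
print(sv.relative_survival(params, 35.7, 15.7))   # 0.807 (10 m deeper)
print(sv.mortality_doubling_temperature(params))  # 2.87  (deg C)
print(sv.depth_effect_on_survival_pct(params))    # 19.4  (% per 10 m)
```

Ten metres of extra depth cost about 19% of expected asymptotic survival,
and roughly 2.9 °C of warming doubles the relative asymptotic mortality —
warm late-season water is far more dangerous for released fish than the
modest depth range this fleet works.

The `analysis/` directory holds the numbered drivers that narrate the full
study on synthetic data: `01_simulate_hauls.py` (fleet-scale haul table
with the low-oxygen exclusion rule), `02_fit_survival.py` (posterior
summary, convergence diagnostics and DIC model comparison, e.g.
`tau ≈ 2.48 (1.51–3.77)` against a generating value of 2.57),
`03_relative_survival_surface.py` (depth × temperature surface and
isolines), `04_track_and_extract_speeds.py` (rendered scene → trajectories
→ binned speeds), `05_fit_vitality.py` (per-haul vitality metrics; null
hauls' ΔBA intervals include zero), and `06_link_survival_vitality.py`
(stepwise regression keeping speed, depth and temperatures, dropping ΔBA
and time). Each writes its tables under `results/`.

A thin CLI wraps the same stages: `gobysurv simulate | track |
fit-survival | fit-vitality | predict-surface | link | report`.

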