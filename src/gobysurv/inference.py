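"""MCMC machinery for the survival and vitality models.

The posterior is explored with a blocked adaptive random-walk Metropolis
sampler.  Global parameters (coefficients, time-scale, dispersion SDs) are
updated one at a time against the full joint density; latent random effects
are updated as vectorised blocks whose units (trips, fish) are conditionally
independent given the globals, so a whole level of the hierarchy is proposed
and accepted/rejected per unit in one pass.  Proposal scales adapt per
coordinate during warmup toward a 44% acceptance rate and are frozen
afterwards, keeping the post-warmup chain Markovian.

Positive parameters (tau, random-effect SDs, overdispersion sizes) are
sampled on the log scale with the appropriate Jacobian.  Priors follow the
fitted models' convention: vague normals on linear coefficients, vague gamma
on the hazard time-scale and on random-effect precisions (reported as SDs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from gobysurv.survival import (
    Centering,
    HaulObservation,
    SurvivalParams,
    centering_from_hauls,
)

__all__ = [
    "MCMCConfig",
    "PriorSpec",
    "PosteriorSamples",
    "ScalarBlock",
    "GroupBlock",
    "PairBlock",
    "DirectionBlock",
    "params_from_samples",
    "adaptive_metropolis",
    "fit_survival",
    "summarize",
    "check_convergence",
    "compute_dic",
    "ConvergenceWarning",
]

OBSERVATION_MODELS = ("binom+poisson", "binom+binom", "binom+negbinom")


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when chains fail the split-R-hat check."""


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults reproduce the original fitting protocol (3 chains, 60,000
    retained values per chain after thinning 1-of-50); reduced budgets are
    passed explicitly for simulation studies.  ``n_iter_per_chain`` counts
    retained (post-thinning) draws.
    """

    n_chains: int = 3
    n_iter_per_chain: int = 60_000
    thin: int = 50
    n_warmup: int = 2_000
    seed: int = 0
    init_strategy: str = "random-in-range"  # or "user-supplied"
    init: Mapping[str, float] | None = None
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_iter_per_chain, self.thin, self.n_warmup) <= 0:
            raise ValueError("all MCMC counts must be positive")
        if self.init_strategy not in ("random-in-range", "user-supplied"):
            raise ValueError(f"unknown init strategy {self.init_strategy!r}")


@dataclass
class PriorSpec:
    """Priors for the hierarchical fits.

    Linear coefficients get Normal(0, coef_sd^2) with coef_sd = 1e8
    (variance 1e16).  The hazard time-scale and the random-effect
    *precisions* (1/variance) get Gamma(shape, rate) with the nearly
    noninformative (0.01, 0.01); a uniform variant is available for
    sensitivity checks.
    """

    coef_sd: float = 1e8
    gamma_shape: float = 0.01
    gamma_rate: float = 0.01
    kind: str = "gamma"  # or "uniform"
    uniform_lo: float = 1e-3
    uniform_hi: float = 100.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_rate <= 0 or self.coef_sd <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.kind not in ("gamma", "uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")

    # log densities on the *log* scale (Jacobian included)

    def log_positive(self, u: float) -> float:
        """log p(log x) for x ~ Gamma(shape, rate) (or uniform variant)."""
        if abs(u) > 600.0:  # exp would overflow; density is negligible there
            return -np.inf
        if self.kind == "gamma":
            return self.gamma_shape * u - self.gamma_rate * math.exp(u)
        x = math.exp(u)
        return u if self.uniform_lo < x < self.uniform_hi else -np.inf

    def log_sd_from_precision(self, s: float) -> float:
        """log p(log sigma) when 1/sigma^2 ~ Gamma(shape, rate)."""
        if abs(s) > 300.0:
            return -np.inf
        if self.kind == "gamma":
            return -2.0 * self.gamma_shape * s - self.gamma_rate * math.exp(-2.0 * s)
        sigma = math.exp(s)
        return s if self.uniform_lo < sigma < self.uniform_hi else -np.inf

    def log_coef(self, v: np.ndarray) -> float:
        return float(-0.5 * np.sum((np.asarray(v) / self.coef_sd) ** 2))


@dataclass
class PosteriorSamples:
    """Labelled MCMC draws with chain structure.

    ``draws`` has shape (chain, draw, parameter) on the natural scale.
    ``extra`` carries fit metadata (centering, observation model, and an
    observation-log-likelihood hook used for DIC).
    """

    names: list[str]
    draws: np.ndarray
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must have shape (chain, draw, parameter)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """(chain, draw) array for one parameter."""
        return self.draws[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def map_draws(self, fn: Callable[[np.ndarray], float]) -> np.ndarray:
        """Evaluate a derived quantity at every pooled draw vector."""
        flat = self.draws.reshape(-1, self.draws.shape[2])
        return np.array([fn(v) for v in flat])

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iter, parameter, value."""
        c, d, p = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), d * p),
                "iter": np.tile(np.repeat(np.arange(d), p), c),
                "parameter": np.tile(self.names, c * d),
                "value": self.draws.reshape(-1),
            }
        )

    def to_arviz(self):
        import arviz as az

        return az.from_dict(
            posterior={n: self.draws[:, :, i] for i, n in enumerate(self.names)}
        )


# ---------------------------------------------------------------------------
# blocked adaptive random-walk Metropolis
# ---------------------------------------------------------------------------

@dataclass
class ScalarBlock:
    """One global coordinate with its partial conditional density.

    ``logdens(x)`` returns every term of the joint density that involves
    this coordinate; the Metropolis ratio needs nothing else.
    """

    index: int
    logdens: Callable[[np.ndarray], float]
    scale: float = 0.5


@dataclass
class GroupBlock:
    """A vector of conditionally independent coordinates (one per unit).

    ``logdens(x)`` returns, per unit, every term of the joint density that
    involves that unit's coordinate; units are proposed jointly and accepted
    independently.
    """

    indices: np.ndarray
    logdens: Callable[[np.ndarray], np.ndarray]
    scale: float = 0.5


@dataclass
class PairBlock:
    """Two correlated global coordinates proposed jointly.

    The 2x2 proposal covariance is learned during warmup from the chain's
    own history (scaled by the usual 2.38^2 / dim), which lets the sampler
    move along a posterior ridge that coordinate-wise updates would cross
    slowly.
    """

    indices: tuple[int, int]
    logdens: Callable[[np.ndarray], float]
    scale: float = 1.0


@dataclass
class DirectionBlock:
    """A one-dimensional move along a fixed direction vector.

    Used for translation sweeps in hierarchies (shift a group mean and
    compensate every random effect), where the likelihood is invariant
    along the direction and ``logdens`` only needs the prior terms that
    change.
    """

    direction: np.ndarray
    logdens: Callable[[np.ndarray], float]
    scale: float = 0.5


def adaptive_metropolis(
    blocks: Sequence[ScalarBlock | GroupBlock | PairBlock | DirectionBlock],
    x0: np.ndarray,
    *,
    n_draws: int,
    warmup: int,
    thin: int,
    rng: np.random.Generator,
    target_accept: float = 0.44,
    adapt_window: int = 50,
    log_post: Callable[[np.ndarray], float] | None = None,
) -> np.ndarray:
    """Run one chain; returns (n_draws, dim) post-warmup thinned draws.

    Proposal scales (and the pair-block covariance) adapt during warmup and
    are frozen afterwards.  The proposal-noise stream is consumed
    identically on accept and reject, so a fixed seed yields bit-identical
    output.  ``log_post`` is only used to validate the initial point.
    """
    x = np.array(x0, dtype=float)
    if log_post is not None and not np.isfinite(log_post(x)):
        raise ValueError("initial point has zero posterior density")

    log_scales: list = []
    acc: list = []
    pair_hist: dict[int, list[np.ndarray]] = {}
    pair_chol: dict[int, np.ndarray] = {}
    for bi, b in enumerate(blocks):
        if isinstance(b, GroupBlock):
            log_scales.append(np.full(len(b.indices), np.log(b.scale)))
            acc.append(np.zeros(len(b.indices)))
        else:
            log_scales.append(math.log(b.scale))
            acc.append(0.0)
        if isinstance(b, PairBlock):
            pair_hist[bi] = []
            pair_chol[bi] = np.eye(2) * 0.1

    draws = np.empty((n_draws, x.size))
    kept = 0
    total = warmup + n_draws * thin
    for it in range(total):
        for bi, b in enumerate(blocks):
            if isinstance(b, ScalarBlock):
                i = b.index
                cur = b.logdens(x)
                old = x[i]
                x[i] = old + math.exp(log_scales[bi]) * rng.standard_normal()
                new = b.logdens(x)
                if math.log(rng.random()) < new - cur:
                    acc[bi] += 1
                else:
                    x[i] = old
            elif isinstance(b, DirectionBlock):
                cur = b.logdens(x)
                eps = math.exp(log_scales[bi]) * rng.standard_normal()
                x += eps * b.direction
                new = b.logdens(x)
                if math.log(rng.random()) < new - cur:
                    acc[bi] += 1
                else:
                    x -= eps * b.direction
            elif isinstance(b, PairBlock):
                i, j = b.indices
                cur = b.logdens(x)
                old_i, old_j = x[i], x[j]
                step = math.exp(log_scales[bi]) * (pair_chol[bi] @ rng.standard_normal(2))
                x[i] += step[0]
                x[j] += step[1]
                new = b.logdens(x)
                if math.log(rng.random()) < new - cur:
                    acc[bi] += 1
                else:
                    x[i], x[j] = old_i, old_j
                if it < warmup:
                    pair_hist[bi].append((x[i], x[j]))
            else:
                idx = b.indices
                cur = b.logdens(x)
                old = x[idx].copy()
                x[idx] = old + np.exp(log_scales[bi]) * rng.standard_normal(idx.size)
                new = b.logdens(x)
                with np.errstate(invalid="ignore"):
                    keep = np.log(rng.random(idx.size)) < (new - cur)
                keep &= np.isfinite(new)
                x[idx[~keep]] = old[~keep]
                acc[bi] += keep

        if it < warmup and (it + 1) % adapt_window == 0:
            step = min(0.25, 2.0 / math.sqrt(1.0 + (it + 1) / adapt_window))
            for bi, b in enumerate(blocks):
                rate = acc[bi] / adapt_window
                target = 0.28 if isinstance(b, PairBlock) else target_accept
                log_scales[bi] = log_scales[bi] + step * (rate - target)
                acc[bi] = np.zeros(len(b.indices)) if isinstance(b, GroupBlock) else 0.0
                if isinstance(b, PairBlock) and len(pair_hist[bi]) >= 200:
                    hist = np.asarray(pair_hist[bi][-1000:])
                    cov = np.cov(hist.T) * (2.38**2 / 2.0) + 1e-10 * np.eye(2)
                    try:
                        pair_chol[bi] = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass

        if it >= warmup and (it - warmup) % thin == 0 and kept < n_draws:
            draws[kept] = x
            kept += 1
    return draws


# ---------------------------------------------------------------------------
# survival-model posterior
# ---------------------------------------------------------------------------

class _SurvivalTarget:
    """Vectorised joint density of the survival model over the haul table.

    Parameter vector layout (sampling scale):
      [alpha0, alpha1, alpha2, beta0, beta1, beta2,
       log tau, log sigma1, log sigma2, (log nb_size,)
       rnd1 (per trip), rnd2 (per trip)]
    """

    def __init__(
        self,
        data: Sequence[HaulObservation],
        prior: PriorSpec,
        observation_model: str,
        centering: Centering,
    ):
        self.prior = prior
        self.obs_model = observation_model
        self.centering = centering
        self.trip_ids = sorted({h.trip_id for h in data})
        tidx = {t: j for j, t in enumerate(self.trip_ids)}
        self.J = len(self.trip_ids)
        self.trip = np.array([tidx[h.trip_id] for h in data], dtype=int)
        self.n = np.array([h.n_total for h in data], dtype=float)
        self.n0 = np.array([h.n0_alive for h in data], dtype=float)
        self.nf = np.array([h.nf_alive for h in data], dtype=float)
        self.t = np.array([h.t_hours for h in data])
        self.dd = np.array([h.depth_m for h in data]) - centering.depth_ref
        self.dt0 = np.array([h.temp0_C for h in data]) - centering.temp0_ref
        self.dtf = np.array([h.tempf_C for h in data]) - centering.tempf_ref
        self._lchoose_n0 = gammaln(self.n + 1) - gammaln(self.n0 + 1) - gammaln(self.n - self.n0 + 1)
        self._lgam_nf = gammaln(self.nf + 1)
        self._lchoose_f = gammaln(self.n0 + 1) - gammaln(self.nf + 1) - gammaln(self.n0 - self.nf + 1)
        self._tau_cache: tuple[float | None, np.ndarray | None] = (None, None)
        self.has_size = observation_model == "binom+negbinom"
        self.dim = 9 + (1 if self.has_size else 0) + 2 * self.J
        self.i_rnd1 = np.arange(10 if self.has_size else 9, (10 if self.has_size else 9) + self.J)
        self.i_rnd2 = self.i_rnd1 + self.J
        names = ["alpha0", "alpha1", "alpha2", "beta0", "beta1", "beta2",
                 "tau", "sigma1", "sigma2"]
        if self.has_size:
            names.append("nb_size")
        names += [f"rnd1[{t}]" for t in self.trip_ids]
        names += [f"rnd2[{t}]" for t in self.trip_ids]
        self.names = names

    # -- likelihood pieces ------------------------------------------------

    def _binom_ll(self, x: np.ndarray) -> np.ndarray:
        eta = x[3] + x[4] * self.dd + x[5] * self.dt0 + x[self.i_rnd2][self.trip]
        # stable log s0 / log(1-s0)
        log_s0 = -np.logaddexp(0.0, -eta)
        log_1ms0 = -eta + log_s0
        return self._lchoose_n0 + self.n0 * log_s0 + (self.n - self.n0) * log_1ms0

    def _surv_frac(self, x: np.ndarray) -> np.ndarray:
        m0 = x[0] + x[1] * self.dd + x[2] * self.dtf + x[self.i_rnd1][self.trip]
        m0 = np.maximum(m0, 0.0)
        tau = math.exp(min(x[6], 600.0))  # prior rejects beyond this anyway
        if tau != self._tau_cache[0]:  # decay vector reused across non-tau updates
            self._tau_cache = (tau, tau * -np.expm1(-self.t / tau))
        return np.exp(-m0 * self._tau_cache[1])

    def _final_ll(self, x: np.ndarray) -> np.ndarray:
        frac = self._surv_frac(x)
        if self.obs_model == "binom+binom":
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = np.log(frac)
                log1mp = np.log1p(-frac)
            ll = self._lchoose_f + np.where(self.nf > 0, self.nf * logp, 0.0)
            rest = self.n0 - self.nf
            ll = ll + np.where(rest > 0, rest * log1mp, 0.0)
            return ll
        mu = self.n0 * frac
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.obs_model == "binom+poisson":
                ll = np.where(
                    mu > 0,
                    self.nf * np.log(mu) - mu - self._lgam_nf,
                    np.where(self.nf == 0, 0.0, -np.inf),
                )
            else:  # binom+negbinom, mean mu, size k
                k = math.exp(min(x[9], 600.0))
                ll = np.where(
                    mu > 0,
                    gammaln(self.nf + k) - gammaln(k) - self._lgam_nf
                    + k * np.log(k / (k + mu)) + self.nf * np.log(mu / (k + mu)),
                    np.where(self.nf == 0, 0.0, -np.inf),
                )
        return ll

    def obs_loglik(self, x: np.ndarray) -> float:
        """Observation-model log likelihood (for DIC), given latent effects."""
        return float(np.sum(self._binom_ll(x)) + np.sum(self._final_ll(x)))

    # -- joint density ----------------------------------------------------

    def _re_logdens(self, x: np.ndarray) -> float:
        s1, s2 = math.exp(min(x[7], 600.0)), math.exp(min(x[8], 600.0))
        r1, r2 = x[self.i_rnd1], x[self.i_rnd2]
        return float(
            -self.J * math.log(s1) - 0.5 * np.sum((r1 / s1) ** 2)
            - self.J * math.log(s2) - 0.5 * np.sum((r2 / s2) ** 2)
        )

    def log_post(self, x: np.ndarray) -> float:
        lp = self.prior.log_coef(x[:6])
        lp += self.prior.log_positive(x[6])
        lp += self.prior.log_sd_from_precision(x[7])
        lp += self.prior.log_sd_from_precision(x[8])
        if self.has_size:
            lp += self.prior.log_positive(x[9])
        if not np.isfinite(lp):
            return -np.inf
        lp += self._re_logdens(x)
        lp += self.obs_loglik(x)
        return lp

    # -- per-trip conditionals for the random-effect blocks ---------------

    def rnd1_logdens(self, x: np.ndarray) -> np.ndarray:
        s1 = math.exp(min(x[7], 600.0))
        per_trip = np.bincount(self.trip, weights=self._final_ll(x), minlength=self.J)
        return per_trip - 0.5 * (x[self.i_rnd1] / s1) ** 2

    def rnd2_logdens(self, x: np.ndarray) -> np.ndarray:
        s2 = math.exp(min(x[8], 600.0))
        per_trip = np.bincount(self.trip, weights=self._binom_ll(x), minlength=self.J)
        return per_trip - 0.5 * (x[self.i_rnd2] / s2) ** 2

    def blocks(self) -> list:
        pri = self.prior

        def mortality_side(x, i):
            return float(np.sum(self._final_ll(x))) - 0.5 * (x[i] / pri.coef_sd) ** 2

        def binom_side(x, i):
            return float(np.sum(self._binom_ll(x))) - 0.5 * (x[i] / pri.coef_sd) ** 2

        def alpha0_tau(x):
            return (
                float(np.sum(self._final_ll(x)))
                - 0.5 * (x[0] / pri.coef_sd) ** 2
                + pri.log_positive(x[6])
            )

        def sd1(x):  # log sigma1: random-effect density + precision prior
            s1 = math.exp(min(x[7], 600.0))
            return (
                pri.log_sd_from_precision(x[7])
                - self.J * x[7]
                - 0.5 * float(np.sum(x[self.i_rnd1] ** 2)) / (s1 * s1)
            )

        def sd2(x):
            s2 = math.exp(min(x[8], 600.0))
            return (
                pri.log_sd_from_precision(x[8])
                - self.J * x[8]
                - 0.5 * float(np.sum(x[self.i_rnd2] ** 2)) / (s2 * s2)
            )

        blocks: list = [
            PairBlock((0, 6), alpha0_tau, 0.3),
            ScalarBlock(1, lambda x: mortality_side(x, 1), 0.01),
            ScalarBlock(2, lambda x: mortality_side(x, 2), 0.02),
            ScalarBlock(3, lambda x: binom_side(x, 3), 0.5),
            ScalarBlock(4, lambda x: binom_side(x, 4), 0.05),
            ScalarBlock(5, lambda x: binom_side(x, 5), 0.3),
            ScalarBlock(7, sd1, 0.3),
            ScalarBlock(8, sd2, 0.3),
        ]
        if self.has_size:
            blocks.append(
                ScalarBlock(
                    9,
                    lambda x: float(np.sum(self._final_ll(x))) + pri.log_positive(x[9]),
                    0.5,
                )
            )
        blocks += [
            GroupBlock(self.i_rnd1, self.rnd1_logdens, 0.1),
            GroupBlock(self.i_rnd2, self.rnd2_logdens, 1.0),
        ]
        return blocks

    def initial_point(self, rng: np.random.Generator, config: MCMCConfig) -> np.ndarray:
        x = np.zeros(self.dim)
        if config.init_strategy == "user-supplied":
            if config.init is None:
                raise ValueError("init_strategy 'user-supplied' requires config.init")
            for name, val in config.init.items():
                i = self.names.index(name)
                x[i] = math.log(val) if name in ("tau", "sigma1", "sigma2", "nb_size") else val
            return x
        x[0] = rng.uniform(0.05, 0.6)
        x[1] = rng.uniform(-0.02, 0.02)
        x[2] = rng.uniform(-0.05, 0.1)
        x[3] = rng.uniform(1.0, 5.0)
        x[4] = rng.uniform(-0.2, 0.2)
        x[5] = rng.uniform(-1.0, 1.0)
        x[6] = np.log(rng.uniform(0.8, 6.0))
        x[7] = np.log(rng.uniform(0.05, 0.5))
        x[8] = np.log(rng.uniform(0.5, 4.0))
        if self.has_size:
            x[9] = np.log(rng.uniform(5.0, 50.0))
        return x

    def to_natural(self, draws: np.ndarray) -> np.ndarray:
        out = draws.copy()
        out[..., 6:9] = np.exp(out[..., 6:9])
        if self.has_size:
            out[..., 9] = np.exp(out[..., 9])
        return out

    def from_natural(self, v: np.ndarray) -> np.ndarray:
        x = np.array(v, dtype=float)
        x[6:9] = np.log(x[6:9])
        if self.has_size:
            x[9] = math.log(x[9])
        return x


def _run_chains(target, config: MCMCConfig) -> np.ndarray:
    """Run config.n_chains independent chains; returns sampling-scale draws."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        x0 = target.initial_point(rng, config)
        chains.append(
            adaptive_metropolis(
                target.blocks(),
                x0,
                n_draws=config.n_iter_per_chain,
                warmup=config.n_warmup,
                thin=config.thin,
                rng=rng,
                log_post=target.log_post,
            )
        )
    return np.stack(chains)


def fit_survival(
    data: Sequence[HaulObservation],
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    observation_model: str = "binom+poisson",
    centering: Centering | None = None,
) -> PosteriorSamples:
    """Sample the joint posterior of the survival model.

    The onboard-alive count is Binomial(n_total, S0) in every variant; the
    port-alive count follows ``observation_model``: Poisson (default),
    Binomial, or negative binomial (mean/size parameterisation, one extra
    ``nb_size`` parameter), each with mean n0_alive * exp(-M(t)).
    """
    if observation_model not in OBSERVATION_MODELS:
        raise ValueError(f"observation_model must be one of {OBSERVATION_MODELS}")
    trips = {h.trip_id for h in data}
    if data and len(trips) < 2:
        raise ValueError("need >= 2 trips to identify trip-level random effects")
    if not data and centering is None:
        raise ValueError("prior sampling (empty data) needs an explicit centering")
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    centering = centering or centering_from_hauls(data)
    target = _SurvivalTarget(data, prior, observation_model, centering)
    draws = target.to_natural(_run_chains(target, config))
    samples = PosteriorSamples(
        names=target.names,
        draws=draws,
        extra={
            "centering": centering,
            "observation_model": observation_model,
            "trip_ids": target.trip_ids,
            "obs_loglik": lambda v: target.obs_loglik(target.from_natural(v)),
            "n_obs": len(data),
        },
    )
    _warn_if_unconverged(samples, config.rhat_threshold)
    return samples


def _warn_if_unconverged(samples: PosteriorSamples, threshold: float) -> None:
    if samples.n_chains < 2:
        return
    diag = check_convergence(samples, rhat_threshold=threshold)
    bad = diag.index[diag["flagged"]].tolist()
    if bad:
        warnings.warn(
            f"split-R-hat above {threshold} for: {', '.join(bad)}",
            ConvergenceWarning,
            stacklevel=3,
        )


def params_from_samples(samples: PosteriorSamples) -> SurvivalParams:
    """Posterior-median SurvivalParams (random effects included)."""
    med = {n: float(np.median(samples.pooled(n))) for n in samples.names}
    trip_ids = samples.extra.get("trip_ids", [])
    return SurvivalParams(
        alpha0=med["alpha0"], alpha1=med["alpha1"], alpha2=med["alpha2"],
        beta0=med["beta0"], beta1=med["beta1"], beta2=med["beta2"],
        tau=med["tau"], sigma1=med["sigma1"], sigma2=med["sigma2"],
        rnd1={t: med[f"rnd1[{t}]"] for t in trip_ids},
        rnd2={t: med[f"rnd2[{t}]"] for t in trip_ids},
    )


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------

def summarize(samples: PosteriorSamples, prob: float = 0.95) -> pd.DataFrame:
    """Median and central credible interval per parameter (chains pooled)."""
    if samples.n_draws == 0:
        raise ValueError("no draws to summarise")
    lo, hi = (1.0 - prob) / 2.0, 1.0 - (1.0 - prob) / 2.0
    rows = {}
    for n in samples.names:
        v = samples.pooled(n)
        rows[n] = (np.median(v), np.quantile(v, lo), np.quantile(v, hi))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["median", "lower", "upper"]
    )


def check_convergence(
    samples: PosteriorSamples, rhat_threshold: float = 1.1
) -> pd.DataFrame:
    """Split-R-hat and effective sample size per parameter (via arviz)."""
    import arviz as az

    if samples.n_chains < 2:
        raise ValueError("convergence diagnostics need >= 2 chains")
    idata = samples.to_arviz()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz warns on constant chains
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    df = pd.DataFrame(
        {
            "rhat": [float(rhat[n].values) for n in samples.names],
            "ess": [float(ess[n].values) for n in samples.names],
        },
        index=samples.names,
    )
    df["flagged"] = df["rhat"] > rhat_threshold
    return df


def compute_dic(
    samples: PosteriorSamples,
    log_lik_fn: Callable[[np.ndarray], float] | None = None,
    max_draws: int = 4000,
) -> dict:
    """Deviance information criterion: DIC = Dbar + pD, pD = Dbar - D(mean).

    ``log_lik_fn`` maps a natural-scale draw vector to the observation-model
    log likelihood; defaults to the hook attached by the fitting routine.
    Draws are evenly subsampled to at most ``max_draws`` for the average.
    """
    fn = log_lik_fn or samples.extra.get("obs_loglik")
    if fn is None:
        raise ValueError("no log-likelihood hook available; pass log_lik_fn")
    flat = samples.draws.reshape(-1, samples.draws.shape[2])
    if len(flat) > max_draws:
        flat = flat[:: max(1, len(flat) // max_draws)]
    dev = np.array([-2.0 * fn(v) for v in flat])
    dbar = float(np.mean(dev))
    d_at_mean = -2.0 * fn(flat.mean(axis=0))
    pd_ = dbar - d_at_mean
    return {"dic": dbar + pd_, "pD": pd_, "mean_deviance": dbar}
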