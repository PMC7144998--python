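"""Time-varying mortality model for post-release survival of discarded fish.

The model describes the fate of a sample of small pelagic gobies taken from a
purse-seine haul and monitored in a seawater container until the boat returns
to port.  Two processes act on the sample:

* **immediate mortality** — a fish is dead the moment the gear comes onboard
  with probability ``1 - S0``, where ``logit(S0)`` depends linearly on haul
  depth (barotrauma) and sea temperature;
* **delayed mortality** — among the initial survivors, fish die at an
  instantaneous rate ``m(t) = m0 * exp(-t / tau)`` that decays from its
  onboard maximum ``m0`` toward zero with time-scale ``tau`` (hours), so the
  expected surviving fraction stabilises at ``exp(-m0 * tau)`` instead of
  falling to zero as a Weibull or constant-rate model would force.

``m0`` depends linearly on depth and on the container temperature at port.
Hauls from the same fishing trip share normal random effects on both linear
predictors.  Because captive monitoring confounds fishing mortality with an
unknown, additive handling mortality, only *relative* survival — the ratio of
predicted survival under given conditions to survival at a reference
condition (the fleet-average depth and temperature) — is interpretable; the
handling term cancels in that ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, gammaln

__all__ = [
    "HaulObservation",
    "SurvivalParams",
    "Centering",
    "REFERENCE_ESTIMATES",
    "REFERENCE_CENTERING",
    "cumulative_mortality",
    "expected_survivors",
    "linear_predictors",
    "asymptotic_survival",
    "relative_survival",
    "relative_survival_grid",
    "iso_contours",
    "log_likelihood",
    "filter_hauls",
    "mortality_doubling_temperature",
    "depth_effect_on_survival_pct",
    "centering_from_hauls",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaulObservation:
    """Counts and covariates for one haul — the unit of the survival data.

    ``n_total`` fish were sampled as the gear came onboard (time t0);
    ``n0_alive`` of them were alive at t0 and ``nf_alive`` were still alive
    ``t_hours`` later at port.
    """

    trip_id: str
    haul_id: str
    n_total: int
    n0_alive: int
    nf_alive: int
    t_hours: float
    depth_m: float
    temp0_C: float
    tempf_C: float
    oxygen: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.nf_alive <= self.n0_alive <= self.n_total):
            raise ValueError(
                f"haul {self.haul_id}: require 0 <= nf_alive <= n0_alive <= n_total, "
                f"got nf={self.nf_alive}, n0={self.n0_alive}, n={self.n_total}"
            )
        if self.t_hours <= 0:
            raise ValueError(f"haul {self.haul_id}: t_hours must be > 0")
        if self.depth_m <= 0:
            raise ValueError(f"haul {self.haul_id}: depth_m must be > 0")


@dataclass
class SurvivalParams:
    """Parameters of the survival model.

    ``alpha*`` are the linear coefficients of the onboard mortality rate
    ``m0`` (per hour): intercept, depth slope (per m), port-temperature slope
    (per °C).  ``beta*`` are the coefficients of ``logit(S0)``: intercept,
    depth slope, sea-temperature slope.  ``tau`` is the decay time-scale of
    the hazard (hours).  ``sigma1``/``sigma2`` are the SDs of trip-level
    random effects on ``m0`` and ``logit(S0)``; ``rnd1``/``rnd2`` map trip id
    to the realised effect (empty for a new/unseen trip).
    """

    alpha0: float
    alpha1: float
    alpha2: float
    beta0: float
    beta1: float
    beta2: float
    tau: float
    sigma1: float = 0.0
    sigma2: float = 0.0
    rnd1: Mapping[str, float] = field(default_factory=dict)
    rnd2: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("random-effect SDs must be >= 0")


@dataclass(frozen=True)
class Centering:
    """Reference covariate values; intercepts are interpreted at this point."""

    depth_ref: float
    temp0_ref: float
    tempf_ref: float

    def __post_init__(self) -> None:
        for v in (self.depth_ref, self.temp0_ref, self.tempf_ref):
            if not math.isfinite(v):
                raise ValueError("centering values must be finite")


#: Published posterior medians for the Balearic transparent-goby fishery
#: (Aphia minuta / Pseudaphya ferreri ensemble), usable for predictions.
REFERENCE_ESTIMATES = SurvivalParams(
    alpha0=0.298, alpha1=0.0084, alpha2=0.094,
    beta0=5.520, beta1=0.066, beta2=-0.824,
    tau=2.570, sigma1=0.182, sigma2=4.072,
)

#: Fleet-average conditions of that fishery: 25.7 m depth, 15.7 °C water.
#: The port-container reference equals the sea reference so that predictions
#: at the reference level emulate immediate release.
REFERENCE_CENTERING = Centering(depth_ref=25.7, temp0_ref=15.7, tempf_ref=15.7)


def centering_from_hauls(hauls: Sequence[HaulObservation]) -> Centering:
    """Sample-mean centering, so fitted intercepts sit at the average haul."""
    if not hauls:
        raise ValueError("cannot centre on an empty haul list")
    return Centering(
        depth_ref=float(np.mean([h.depth_m for h in hauls])),
        temp0_ref=float(np.mean([h.temp0_C for h in hauls])),
        tempf_ref=float(np.mean([h.tempf_C for h in hauls])),
    )


# ---------------------------------------------------------------------------
# deterministic model
# ---------------------------------------------------------------------------

def cumulative_mortality(m0, tau, t):
    """Cumulative hazard M(t) = m0 * tau * (1 - exp(-t/tau)).

    Integral of the decaying instantaneous rate m(t) = m0*exp(-t/tau);
    nondecreasing in t and bounded by its asymptote m0*tau.
    """
    m0 = np.asarray(m0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be > 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = m0 * tau * -np.expm1(-t / tau)
    return out if out.ndim else float(out)

def expected_survivors(s0, n0, m0, tau, t):
    """Expected number alive at time t: s0 * n0 * exp(-M(t))."""
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 < 0) or np.any(s0 > 1):
        raise ValueError("s0 must lie in [0, 1]")
    if np.any(np.asarray(n0) < 0):
        raise ValueError("n0 must be >= 0")
    out = s0 * np.asarray(n0, dtype=float) * np.exp(-cumulative_mortality(m0, tau, t))
    return out if out.ndim else float(out)


def linear_predictors(
    params: SurvivalParams,
    depth_m,
    temp0_C,
    tempf_C,
    trip_id: str | None = None,
    centering: Centering = REFERENCE_CENTERING,
    clip_m0: bool = True,
):
    """Evaluate the covariate links: (m0, s0) at the given conditions.

    Covariates are centred before the slopes apply, so the intercepts are the
    values at the reference haul.  An unknown ``trip_id`` (or ``None``)
    predicts for a new trip with random effects at zero.  ``m0`` is clipped
    at 0 from below so exp(-M) stays a probability even for extreme
    covariates outside the sampled envelope.
    """
    r1 = params.rnd1.get(trip_id, 0.0) if trip_id is not None else 0.0
    r2 = params.rnd2.get(trip_id, 0.0) if trip_id is not None else 0.0
    dd = np.asarray(depth_m, dtype=float) - centering.depth_ref
    dt0 = np.asarray(temp0_C, dtype=float) - centering.temp0_ref
    dtf = np.asarray(tempf_C, dtype=float) - centering.tempf_ref
    m0 = params.alpha0 + params.alpha1 * dd + params.alpha2 * dtf + r1
    if clip_m0:
        m0 = np.maximum(m0, 0.0)
    s0 = expit(params.beta0 + params.beta1 * dd + params.beta2 * dt0 + r2)
    if np.ndim(m0) == 0 and np.ndim(s0) == 0:
        return float(m0), float(s0)
    return m0, s0


def asymptotic_survival(s0, m0, tau):
    """Survival probability at large t: s0 * exp(-m0 * tau)."""
    out = np.asarray(s0, dtype=float) * np.exp(-np.asarray(m0, dtype=float) * tau)
    return out if out.ndim else float(out)


def relative_survival(
    params: SurvivalParams,
    depth_m,
    temp_C,
    centering: Centering = REFERENCE_CENTERING,
):
    """Asymptotic survival relative to the reference haul.

    Emulates immediate release by using one water temperature for both the
    sea (t0) and container (port) channels.  Any constant handling mortality
    adds the same term to the cumulative hazard of numerator and denominator
    and cancels; the ratio is 1 at the reference point by construction.
    """
    m0, s0 = linear_predictors(
        params, depth_m, temp_C, temp_C, trip_id=None, centering=centering
    )
    m0_ref, s0_ref = linear_predictors(
        params,
        centering.depth_ref,
        centering.temp0_ref,
        centering.temp0_ref,
        trip_id=None,
        centering=centering,
    )
    num = asymptotic_survival(s0, m0, params.tau)
    den = asymptotic_survival(s0_ref, m0_ref, params.tau)
    out = num / den
    return out if np.ndim(out) else float(out)


def relative_survival_grid(
    params: SurvivalParams,
    depth_range: tuple[float, float] = (16.0, 35.0),
    temp_range: tuple[float, float] = (14.5, 16.5),
    n_grid: int = 101,
    centering: Centering = REFERENCE_CENTERING,
):
    """Relative-survival surface over a depth x temperature grid.

    Returns ``(depths, temps, values)`` with ``values[i, j]`` the relative
    survival at ``depths[i]``, ``temps[j]``.  Default ranges cover the
    sampled envelope of the fishery (~16-35 m, ~14.5-16.5 deg C).
    """
    if depth_range[0] >= depth_range[1] or temp_range[0] >= temp_range[1]:
        raise ValueError("ranges must be nonempty (lo < hi)")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    depths = np.linspace(depth_range[0], depth_range[1], n_grid)
    temps = np.linspace(temp_range[0], temp_range[1], n_grid)
    dd, tt = np.meshgrid(depths, temps, indexing="ij")
    values = relative_survival(params, dd, tt, centering=centering)
    return depths, temps, values


def iso_contours(depths, temps, values, levels: Iterable[float]):
    """Extract iso-ratio contours from a relative-survival grid.

    Returns a dict mapping level -> list of (n, 2) arrays of (depth, temp)
    polyline vertices, in physical units.
    """
    from skimage import measure

    out: dict[float, list[np.ndarray]] = {}
    d0, dstep = depths[0], depths[1] - depths[0]
    t0, tstep = temps[0], temps[1] - temps[0]
    for level in levels:
        segs = measure.find_contours(values, level)
        out[level] = [
            np.column_stack([d0 + s[:, 0] * dstep, t0 + s[:, 1] * tstep]) for s in segs
        ]
    return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def log_likelihood(
    data: Sequence[HaulObservation],
    params: SurvivalParams,
    centering: Centering | None = None,
    hierarchical: bool = True,
) -> float:
    """Joint log density of the haul counts under the survival model.

    Per haul: Binomial(n_total, s0) for the onboard-alive count plus
    Poisson(n0_alive * exp(-M(t))) for the count still alive at port.  With
    ``hierarchical=True`` the normal log density of the trip random effects
    (given sigma1, sigma2) is added, giving the joint density used by the
    sampler.  A zero Poisson mean with a positive count yields ``-inf``.
    """
    if centering is None:
        centering = centering_from_hauls(data)
    total = 0.0
    for h in data:
        m0, s0 = linear_predictors(
            params, h.depth_m, h.temp0_C, h.tempf_C, h.trip_id, centering
        )
        # binomial log-pmf, stable at s0 -> 0/1
        with np.errstate(divide="ignore"):
            log_s0 = np.log(s0)
            log_1ms0 = np.log1p(-s0)
        ll = gammaln(h.n_total + 1) - gammaln(h.n0_alive + 1) - gammaln(h.n_total - h.n0_alive + 1)
        ll += h.n0_alive * log_s0 if h.n0_alive else 0.0
        ll += (h.n_total - h.n0_alive) * log_1ms0 if h.n_total > h.n0_alive else 0.0
        mu = h.n0_alive * math.exp(-cumulative_mortality(m0, params.tau, h.t_hours))
        if mu <= 0:
            ll += 0.0 if h.nf_alive == 0 else -np.inf
        else:
            ll += h.nf_alive * math.log(mu) - mu - gammaln(h.nf_alive + 1)
        total += float(ll)
    if hierarchical:
        for trips, sigma in ((params.rnd1, params.sigma1), (params.rnd2, params.sigma2)):
            for eff in trips.values():
                if sigma == 0:
                    total += 0.0 if eff == 0 else -np.inf
                else:
                    total += -0.5 * math.log(2 * math.pi) - math.log(sigma) - 0.5 * (eff / sigma) ** 2
    return total


def filter_hauls(
    data: Sequence[HaulObservation], min_oxygen: float
) -> tuple[list[HaulObservation], list[dict]]:
    """Drop hauls whose container oxygen at port fell below ``min_oxygen``.

    Low oxygen in the monitoring container invalidates the comparability of
    handling mortality across hauls.  Hauls without a reading are retained
    with a warning.  Returns (retained, exclusion report).
    """
    retained: list[HaulObservation] = []
    report: list[dict] = []
    for h in data:
        if h.oxygen is None:
            warnings.warn(
                f"haul {h.haul_id}: no oxygen reading; retained unchecked", stacklevel=2
            )
            retained.append(h)
        elif h.oxygen < min_oxygen:
            report.append(
                {"haul_id": h.haul_id, "oxygen": h.oxygen,
                 "reason": f"container oxygen {h.oxygen} below threshold {min_oxygen}"}
            )
        else:
            retained.append(h)
    return retained, report


# ---------------------------------------------------------------------------
# derived effect sizes
# ---------------------------------------------------------------------------

def mortality_doubling_temperature(
    params: SurvivalParams,
    centering: Centering = REFERENCE_CENTERING,
    factor: float = 2.0,
) -> float:
    """Temperature increase (deg C) that multiplies relative asymptotic
    mortality by ``factor`` at the average depth.

    Relative asymptotic mortality between temperature T+dT and T is
    exp(M_inf(T+dT) - M_inf(T)) = exp(alpha2 * dT * tau); the root of
    that ratio against ``factor`` is found numerically (closed form
    ln(factor) / (alpha2 * tau)).
    """
    if params.alpha2 * math.log(factor) <= 0:
        raise ValueError("no temperature increase can achieve the requested factor")

    def ratio_minus_factor(dT: float) -> float:
        m0_ref, _ = linear_predictors(
            params, centering.depth_ref, centering.temp0_ref, centering.temp0_ref,
            centering=centering,
        )
        m0_hi, _ = linear_predictors(
            params, centering.depth_ref, centering.temp0_ref + dT,
            centering.temp0_ref + dT, centering=centering,
        )
        return math.exp((m0_hi - m0_ref) * params.tau) - factor

    return float(brentq(ratio_minus_factor, 1e-9, 100.0, xtol=1e-10))


def depth_effect_on_survival_pct(
    params: SurvivalParams,
    delta_depth_m: float = 10.0,
    centering: Centering = REFERENCE_CENTERING,
) -> float:
    """Percent change in asymptotic survival attributable to the delayed-
    mortality channel when depth increases by ``delta_depth_m`` at the
    average temperature: 100 * (1 - exp(-alpha1 * ddepth * tau))."""
    m0_ref, _ = linear_predictors(
        params, centering.depth_ref, centering.temp0_ref, centering.temp0_ref,
        centering=centering,
    )
    m0_deep, _ = linear_predictors(
        params, centering.depth_ref + delta_depth_m, centering.temp0_ref,
        centering.temp0_ref, centering=centering,
    )
    return 100.0 * (1.0 - math.exp(-(m0_deep - m0_ref) * params.tau))
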