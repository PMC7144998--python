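"""Hierarchical gamma model of swimming speed before/after a stimulus.

For each monitored haul, about ten fish are filmed in a circular arena and
their binned swimming speeds (40 bins before and 40 after a sound stimulus,
mm/s) are modelled as gamma distributed.  The gamma is parameterised by a
fish-and-period mean ``v_bar`` and dispersion ``tol`` through
``shape = v_bar^2 / tol`` and ``rate = v_bar / tol``, so the distribution
has mean ``v_bar`` and variance ``tol``.  Fish means decompose into a
haul-level mean speed before the stimulus (``v_mean_before``), a haul-level
before-to-after shift (``delta_BA``), and fish-level normal random effects
in each period.  The haul-level posterior medians of ``v_mean_before`` and
``delta_BA`` are the two vitality metrics carried into the survival-vitality
linkage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SpeedSeries",
    "VitalityParams",
    "gamma_params",
    "fish_means",
    "fit_vitality",
    "vitality_metrics",
    "N_BINS",
]

#: Bins per period: 2 min at 20 frames/s averaged over 60-frame bins.
N_BINS = 40


@dataclass
class SpeedSeries:
    """One fish's binned speeds (mm/s): 40 bins before + 40 after stimulus."""

    haul_id: str
    fish_id: str
    before: np.ndarray
    after: np.ndarray

    def __post_init__(self) -> None:
        self.before = np.asarray(self.before, dtype=float)
        self.after = np.asarray(self.after, dtype=float)
        if self.before.shape != (N_BINS,) or self.after.shape != (N_BINS,):
            raise ValueError(
                f"fish {self.fish_id}: need exactly {N_BINS} bins per period, "
                f"got {self.before.shape[0]} before / {self.after.shape[0]} after"
            )
        if (self.before < 0).any() or (self.after < 0).any():
            raise ValueError(f"fish {self.fish_id}: speeds must be >= 0")


@dataclass
class VitalityParams:
    """Parameters of the speed model for one haul.

    ``v_mean_before`` (mm/s) is the haul-level mean speed before the
    stimulus; ``delta_BA`` the haul-level before-to-after shift; ``delta_B``
    / ``delta_A`` map fish id to its random effect in each period;
    ``tol_iBA`` maps (fish id, period) to the speed dispersion; ``tol_B`` /
    ``tol_A`` are the dispersions of the two random-effect levels.
    """

    v_mean_before: float
    delta_BA: float
    delta_B: Mapping[str, float] = field(default_factory=dict)
    delta_A: Mapping[str, float] = field(default_factory=dict)
    tol_iBA: Mapping[tuple[str, str], float] = field(default_factory=dict)
    tol_B: float = 1.0
    tol_A: float = 1.0

    def __post_init__(self) -> None:
        if self.tol_B <= 0 or self.tol_A <= 0 or any(
            t <= 0 for t in self.tol_iBA.values()
        ):
            raise ValueError("dispersions must be > 0")


def gamma_params(v_bar: float, tol: float) -> tuple[float, float]:
    """(shape, rate) of the speed distribution with mean v_bar, variance tol."""
    if v_bar <= 0 or tol <= 0:
        raise ValueError("v_bar and tol must be > 0")
    return v_bar * v_bar / tol, v_bar / tol


def fish_means(params: VitalityParams, fish_id: str) -> tuple[float, float]:
    """Mean speed of one fish before and after the stimulus."""
    if fish_id not in params.delta_B or fish_id not in params.delta_A:
        raise KeyError(f"unknown fish {fish_id!r}")
    before = params.v_mean_before + params.delta_B[fish_id]
    after = params.v_mean_before + params.delta_BA + params.delta_A[fish_id]
    return before, after


# ---------------------------------------------------------------------------
# posterior target
# ---------------------------------------------------------------------------

class _VitalityTarget:
    """Joint density of the speed model for one haul.

    Parameter layout (sampling scale):
      [v_mean_before, delta_BA, log tol_B, log tol_A,
       delta_B (per fish), delta_A (per fish),
       log tol_before (per fish), log tol_after (per fish)]

    ``tol_is_variance`` selects the printed parameterisation (dispersion =
    variance); the alternative reads every tol as a precision (1/variance).
    """

    def __init__(self, series, prior, tol_is_variance: bool):
        from gobysurv.inference import PriorSpec  # avoid import cycle at module load

        self.prior: PriorSpec = prior
        self.tol_is_variance = tol_is_variance
        self.fish_ids = [s.fish_id for s in series]
        F = self.F = len(series)
        before = np.stack([s.before for s in series])
        after = np.stack([s.after for s in series])
        self.floors: dict[str, float] = {}
        before, after = self._floor_zeros(before, after)
        self.n_bins = before.shape[1]
        self.sum_b = before.sum(axis=1)
        self.sum_a = after.sum(axis=1)
        self.sumlog_b = np.log(before).sum(axis=1)
        self.sumlog_a = np.log(after).sum(axis=1)
        self.dim = 4 + 4 * F
        self.i_dB = np.arange(4, 4 + F)
        self.i_dA = self.i_dB + F
        self.i_tb = self.i_dA + F
        self.i_ta = self.i_tb + F
        self.names = (
            ["v_mean_before", "delta_BA", "tol_B", "tol_A"]
            + [f"delta_B[{f}]" for f in self.fish_ids]
            + [f"delta_A[{f}]" for f in self.fish_ids]
            + [f"tol_before[{f}]" for f in self.fish_ids]
            + [f"tol_after[{f}]" for f in self.fish_ids]
        )

    def _floor_zeros(self, before, after):
        """Gamma support excludes 0: replace zero bins by half the smallest
        positive bin of the same fish (logged per fish)."""
        for i, fid in enumerate(self.fish_ids):
            row = np.concatenate([before[i], after[i]])
            pos = row[row > 0]
            if pos.size == 0:
                raise ValueError(f"fish {fid}: all speed bins are zero")
            if (row == 0).any():
                floor = 0.5 * pos.min()
                self.floors[fid] = floor
                before[i] = np.maximum(before[i], floor)
                after[i] = np.maximum(after[i], floor)
        return before, after

    def _variance(self, tol):
        return tol if self.tol_is_variance else 1.0 / tol

    def _period_ll(self, vbar, log_tol, sums, sumlogs) -> np.ndarray:
        """Per-fish gamma log likelihood of one period's bins."""
        tol_var = self._variance(np.exp(log_tol))
        with np.errstate(divide="ignore", invalid="ignore"):
            shape = vbar * vbar / tol_var
            rate = vbar / tol_var
            ll = (
                self.n_bins * (shape * np.log(rate) - gammaln(shape))
                + (shape - 1.0) * sumlogs
                - rate * sums
            )
        return np.where(vbar > 0, ll, -np.inf)

    def before_ll(self, x) -> np.ndarray:
        return self._period_ll(x[0] + x[self.i_dB], x[self.i_tb], self.sum_b, self.sumlog_b)

    def after_ll(self, x) -> np.ndarray:
        return self._period_ll(
            x[0] + x[1] + x[self.i_dA], x[self.i_ta], self.sum_a, self.sumlog_a
        )

    def obs_loglik(self, x) -> float:
        return float(np.sum(self.before_ll(x)) + np.sum(self.after_ll(x)))

    def _re_sd(self, log_tol: float) -> float:
        return math.sqrt(self._variance(math.exp(min(log_tol, 600.0))))

    def log_post(self, x) -> float:
        lp = self.prior.log_coef(x[:2])
        lp += self.prior.log_positive(x[2]) + self.prior.log_positive(x[3])
        lp += float(np.sum([self.prior.log_positive(u) for u in x[self.i_tb]]))
        lp += float(np.sum([self.prior.log_positive(u) for u in x[self.i_ta]]))
        if not np.isfinite(lp):
            return -np.inf
        sd_b, sd_a = self._re_sd(x[2]), self._re_sd(x[3])
        lp += -self.F * math.log(sd_b) - 0.5 * float(np.sum((x[self.i_dB] / sd_b) ** 2))
        lp += -self.F * math.log(sd_a) - 0.5 * float(np.sum((x[self.i_dA] / sd_a) ** 2))
        lp += self.obs_loglik(x)
        return lp

    # per-fish conditionals for the group blocks

    def dB_logdens(self, x) -> np.ndarray:
        sd = self._re_sd(x[2])
        return self.before_ll(x) - 0.5 * (x[self.i_dB] / sd) ** 2

    def dA_logdens(self, x) -> np.ndarray:
        sd = self._re_sd(x[3])
        return self.after_ll(x) - 0.5 * (x[self.i_dA] / sd) ** 2

    def tb_logdens(self, x) -> np.ndarray:
        pri = np.array([self.prior.log_positive(u) for u in x[self.i_tb]])
        return self.before_ll(x) + pri

    def ta_logdens(self, x) -> np.ndarray:
        pri = np.array([self.prior.log_positive(u) for u in x[self.i_ta]])
        return self.after_ll(x) + pri

    def blocks(self):
        from gobysurv.inference import GroupBlock, ScalarBlock

        pri = self.prior

        def vmean(x):
            return (
                float(np.sum(self.before_ll(x)) + np.sum(self.after_ll(x)))
                - 0.5 * (x[0] / pri.coef_sd) ** 2
            )

        def dba(x):
            return float(np.sum(self.after_ll(x))) - 0.5 * (x[1] / pri.coef_sd) ** 2

        def re_sd_block(i_log_tol, i_effects):
            def logdens(x):
                sd = self._re_sd(x[i_log_tol])
                return (
                    pri.log_positive(x[i_log_tol])
                    - self.F * math.log(sd)
                    - 0.5 * float(np.sum(x[i_effects] ** 2)) / (sd * sd)
                )

            return logdens

        # translation sweeps: shift a haul-level mean and compensate the
        # fish effects so every fish mean (hence the likelihood) is
        # unchanged; only the random-effect and coefficient priors move.
        from gobysurv.inference import DirectionBlock

        d_before = np.zeros(self.dim)
        d_before[0] = 1.0
        d_before[1] = -1.0
        d_before[self.i_dB] = -1.0

        def sweep_before(x):
            sd = self._re_sd(x[2])
            return (
                -0.5 * float(np.sum(x[self.i_dB] ** 2)) / (sd * sd)
                - 0.5 * (x[0] ** 2 + x[1] ** 2) / pri.coef_sd**2
            )

        d_after = np.zeros(self.dim)
        d_after[1] = 1.0
        d_after[self.i_dA] = -1.0

        def sweep_after(x):
            sd = self._re_sd(x[3])
            return (
                -0.5 * float(np.sum(x[self.i_dA] ** 2)) / (sd * sd)
                - 0.5 * (x[1] ** 2) / pri.coef_sd**2
            )

        return [
            ScalarBlock(0, vmean, 0.3),
            ScalarBlock(1, dba, 0.3),
            ScalarBlock(2, re_sd_block(2, self.i_dB), 0.4),
            ScalarBlock(3, re_sd_block(3, self.i_dA), 0.4),
            GroupBlock(self.i_dB, self.dB_logdens, 0.3),
            GroupBlock(self.i_dA, self.dA_logdens, 0.3),
            GroupBlock(self.i_tb, self.tb_logdens, 0.3),
            GroupBlock(self.i_ta, self.ta_logdens, 0.3),
            DirectionBlock(d_before, sweep_before, 0.5),
            DirectionBlock(d_after, sweep_after, 0.5),
        ]

    def initial_point(self, rng, config):
        x = np.zeros(self.dim)
        mean_b = float(np.mean(self.sum_b)) / self.n_bins
        if config.init_strategy == "user-supplied" and config.init is not None:
            for name, val in config.init.items():
                i = self.names.index(name)
                x[i] = math.log(val) if name.startswith("tol") else val
            return x
        x[0] = mean_b * rng.uniform(0.6, 1.4)
        x[1] = rng.uniform(-0.5, 0.5)
        x[2] = np.log(rng.uniform(0.5, 4.0))
        x[3] = np.log(rng.uniform(0.5, 4.0))
        x[self.i_tb] = np.log(rng.uniform(1.0, 8.0, self.F))
        x[self.i_ta] = np.log(rng.uniform(1.0, 8.0, self.F))
        return x

    def to_natural(self, draws):
        out = draws.copy()
        log_idx = np.concatenate([[2, 3], self.i_tb, self.i_ta])
        out[..., log_idx] = np.exp(out[..., log_idx])
        return out

    def from_natural(self, v):
        x = np.array(v, dtype=float)
        log_idx = np.concatenate([[2, 3], self.i_tb, self.i_ta])
        x[log_idx] = np.log(x[log_idx])
        return x


def fit_vitality(
    series: Sequence[SpeedSeries],
    prior=None,
    config=None,
    tol_is_variance: bool = True,
):
    """Sample the joint posterior of the speed model for one haul.

    ``series`` holds the binned speeds of every recorded fish from a single
    haul (>= 2 fish; a single fish cannot separate the haul mean from its
    own random effect).  Returns :class:`~gobysurv.inference.PosteriorSamples`;
    the haul-level vitality metrics are the posterior medians of
    ``v_mean_before`` and ``delta_BA``.
    """
    from gobysurv.inference import (
        MCMCConfig,
        PosteriorSamples,
        PriorSpec,
        _run_chains,
        _warn_if_unconverged,
    )

    if len(series) < 2:
        raise ValueError("need >= 2 fish to identify haul-level means")
    hauls = {s.haul_id for s in series}
    if len(hauls) > 1:
        raise ValueError(f"series mix hauls {sorted(hauls)}; fit one haul at a time")
    if len({s.fish_id for s in series}) != len(series):
        raise ValueError("duplicate fish ids")
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    target = _VitalityTarget(series, prior, tol_is_variance)
    draws = target.to_natural(_run_chains(target, config))
    samples = PosteriorSamples(
        names=target.names,
        draws=draws,
        extra={
            "haul_id": next(iter(hauls)),
            "fish_ids": target.fish_ids,
            "zero_floors": dict(target.floors),
            "obs_loglik": lambda v: target.obs_loglik(target.from_natural(v)),
            "tol_is_variance": tol_is_variance,
        },
    )
    if target.floors:
        warnings.warn(
            f"zero speed bins floored for fish: {sorted(target.floors)}", stacklevel=2
        )
    _warn_if_unconverged(samples, config.rhat_threshold)
    return samples


def vitality_metrics(samples, prob: float = 0.95) -> pd.DataFrame:
    """One-row haul summary: median and CI of v_mean_before and delta_BA."""
    lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
    row = {"haul_id": samples.extra.get("haul_id", "")}
    for name, tag in (("v_mean_before", "v_mean_before"), ("delta_BA", "delta_BA")):
        v = samples.pooled(name)
        row[f"{tag}_med"] = float(np.median(v))
        row[f"{tag}_lo"] = float(np.quantile(v, lo))
        row[f"{tag}_hi"] = float(np.quantile(v, hi))
    return pd.DataFrame([row])
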