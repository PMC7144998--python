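"""Linking estimated post-release survival to vitality metrics.

Per-haul asymptotic survival estimates (posterior medians, logit
transformed) are regressed on the two vitality metrics (mean pre-stimulus
swimming speed and the before-to-after speed shift) and on monitoring time,
depth and the two temperatures, by ordinary least squares.  The model is
pruned by backward stepwise selection on the Akaike information criterion:
at each step the term whose removal lowers AIC most is dropped, until no
removal helps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "HaulSummary",
    "CANDIDATE_TERMS",
    "logit_survival",
    "fit_ols",
    "stepwise_aic",
    "summaries_to_frame",
]

#: Candidate explanatory variables for the survival-vitality regression.
CANDIDATE_TERMS = ("v_mean_before", "delta_BA", "t_hours", "depth_m", "tempf_C", "temp0_C")


@dataclass(frozen=True)
class HaulSummary:
    """Merged per-haul record: survival estimate, vitality metrics, covariates."""

    haul_id: str
    survival_estimate: float
    v_mean_before: float
    delta_BA: float
    t_hours: float
    depth_m: float
    tempf_C: float
    temp0_C: float

    def __post_init__(self) -> None:
        if not 0.0 < self.survival_estimate < 1.0:
            raise ValueError(
                f"haul {self.haul_id}: survival estimate must lie strictly in (0, 1); "
                "clamp boundary estimates with logit_survival(eps=...) first"
            )


def summaries_to_frame(summaries: Sequence[HaulSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries]).set_index("haul_id")


def logit_survival(p, eps: float = 1e-4):
    """Logit of a survival estimate, clamping into [eps, 1-eps].

    Exact 0/1 without clamping (``eps=0``) is rejected: the logit is
    undefined there and a boundary estimate signals an upstream problem.
    """
    p = np.asarray(p, dtype=float)
    if eps < 0 or eps >= 0.5:
        raise ValueError("eps must lie in [0, 0.5)")
    if eps == 0 and ((p <= 0).any() or (p >= 1).any()):
        raise ValueError("survival estimates of exactly 0 or 1 have no logit")
    p = np.clip(p, eps, 1 - eps)
    out = np.log(p / (1 - p))
    return out if out.ndim else float(out)


@dataclass
class OLSFit:
    """Coefficient table (Estimate / Std. Error / t value / P value) + AIC."""

    terms: list[str]
    table: pd.DataFrame
    aic: float
    rss: float
    nobs: int

    @property
    def coef(self) -> pd.Series:
        return self.table["Estimate"]


def fit_ols(y: np.ndarray, X: pd.DataFrame) -> OLSFit:
    """Ordinary least squares with an added intercept.

    ``X`` holds the named explanatory columns (no constant).  AIC is the
    Gaussian-likelihood form n*log(RSS/n) + 2(p+1) + const, consistent
    across compared models.  A rank-deficient design raises, naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if len(y) <= Xc.shape[1]:
        raise ValueError(f"need n > p: n={len(y)}, p={Xc.shape[1]}")
    rank = np.linalg.matrix_rank(np.asarray(Xc, dtype=float))
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    res = sm.OLS(y, Xc).fit()
    table = pd.DataFrame(
        {
            "Estimate": res.params,
            "Std. Error": res.bse,
            "t value": res.tvalues,
            "P value": res.pvalues,
        }
    )
    table.index = ["Intercept" if i == "const" else i for i in Xc.columns]
    return OLSFit(
        terms=[c for c in X.columns],
        table=table,
        aic=float(res.aic),
        rss=float(res.ssr),
        nobs=int(res.nobs),
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns loading on near-null singular directions of the design."""
    A = np.asarray(X, dtype=float)
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    tol = s.max() * max(A.shape) * np.finfo(float).eps
    bad: set[str] = set()
    for k in np.nonzero(s <= tol)[0]:
        load = np.abs(vt[k])
        bad.update(np.asarray(X.columns)[load > 0.1 * load.max()])
    return sorted(bad)


def stepwise_aic(
    full_terms: Sequence[str],
    data: pd.DataFrame,
    response: str = "logit_survival",
) -> OLSFit:
    """Backward stepwise selection by AIC from the full model.

    At each step the removal that lowers AIC most is applied; selection
    stops when no removal lowers AIC.  Ties and the final result are
    independent of the listed order of ``full_terms`` (candidates are
    scanned in sorted order).  The intercept is never dropped.
    """
    y = data[response].to_numpy()
    terms = sorted(full_terms)
    current = fit_ols(y, data[terms])
    while terms:
        best_candidate: tuple[float, str, OLSFit] | None = None
        for term in sorted(terms):
            reduced = [t for t in terms if t != term]
            fit = fit_ols(y, data[reduced])
            if best_candidate is None or fit.aic < best_candidate[0]:
                best_candidate = (fit.aic, term, fit)
        if best_candidate is not None and best_candidate[0] < current.aic:
            terms = [t for t in terms if t != best_candidate[1]]
            current = best_candidate[2]
        else:
            break
    return current
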