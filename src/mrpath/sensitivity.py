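"""Heterogeneity, pleiotropy, influence and directionality diagnostics.

All diagnostics operate on a harmonized single-exposure set: Cochran's Q
against the fixed-effects IVW center, the MR-Egger intercept test for
directional pleiotropy, leave-one-out IVW estimates, plot-ready funnel data
(per-variant ratio vs precision), and a global Steiger direction verdict.
Tables are emitted ready for plotting; no figures are rendered here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EggerEstimator
from .gwas_io import HarmonizedSet
from .univariable import ivw

__all__ = [
    "DiagnosticsReport",
    "cochran_q",
    "egger_intercept",
    "leave_one_out",
    "funnel_data",
    "steiger_direction",
    "diagnostics",
]


@dataclass
class DiagnosticsReport:
    """Bundle of all sensitivity outputs for one fitted univariable MR."""

    cochran_q: float
    q_df: int
    q_pvalue: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pvalue: float | None
    loo_table: pd.DataFrame | None
    funnel_table: pd.DataFrame
    steiger_global: str

    @property
    def pleiotropy_flag(self) -> str:
        if self.egger_intercept_pvalue is None:
            return "not_assessed"
        return (
            "directional_pleiotropy"
            if self.egger_intercept_pvalue < 0.05
            else "no_horizontal_pleiotropy"
        )

    def to_frames(self) -> dict:
        scalar = pd.DataFrame(
            [
                dict(
                    cochran_q=self.cochran_q,
                    q_df=self.q_df,
                    q_pvalue=self.q_pvalue,
                    egger_intercept=self.egger_intercept,
                    egger_intercept_se=self.egger_intercept_se,
                    egger_intercept_pvalue=self.egger_intercept_pvalue,
                    pleiotropy_flag=self.pleiotropy_flag,
                    steiger_global=self.steiger_global,
                )
            ]
        )
        return {"summary": scalar, "loo": self.loo_table, "funnel": self.funnel_table}


def _unpack(h: HarmonizedSet):
    if h.n_exposures != 1:
        raise ValueError("diagnostics require a single-exposure HarmonizedSet")
    return h.beta_x[:, 0], h.se_x[:, 0], h.beta_y, h.se_y


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Heterogeneity of per-variant ratios around the fixed-effects IVW.

    ``Q = sum w_j (r_j - beta_ivw)**2`` with ratio weights
    ``w_j = beta_x**2 / se_y**2``; chi-square reference with k-1 df.
    """
    bx, _, by, sy = _unpack(h)
    if h.k < 2:
        raise ValueError("Cochran's Q needs at least 2 variants")
    w = bx**2 / sy**2
    r = by / bx
    center = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - center) ** 2))
    df = h.k - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept(h: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept with SE and two-sided p (pleiotropy test)."""
    bx, _, by, sy = _unpack(h)
    est = EggerEstimator().fit(bx, by, se_y=sy)
    return est.intercept_, est.intercept_se_, est.intercept_pvalue_


def leave_one_out(h: HarmonizedSet, model: str = "random") -> pd.DataFrame:
    """Per-variant-excluded IVW estimates (k rows, each on k-1 variants).

    ``flagged`` marks rows whose CI no longer contains the sign of the
    full-sample point estimate (i.e. the interval crosses away from it).
    """
    if h.k < 3:
        raise ValueError("leave-one-out needs at least 3 variants")
    full = ivw(h, model=model)
    rows = []
    for i in range(h.k):
        keep = [j for j in range(h.k) if j != i]
        est = ivw(h.subset(keep), model=model)
        sign = np.sign(full.beta)
        flagged = not (est.ci_low <= full.beta <= est.ci_high) and (
            np.sign(est.ci_low) != sign and np.sign(est.ci_high) != sign
        )
        rows.append(
            dict(
                excluded=h.variant_ids[i],
                beta=est.beta,
                se=est.se,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                pvalue=est.pvalue,
                n_snv=est.n_snv,
                flagged=flagged,
            )
        )
    return pd.DataFrame(rows)


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant Wald ratio and precision, plus reference slopes.

    Precision is the reciprocal first-order ratio SE, ``|beta_x| / se_y``.
    The IVW (and, when estimable, Egger) slopes are attached as constant
    columns for plotting vertical reference lines.
    """
    bx, _, by, sy = _unpack(h)
    ratio = by / bx
    precision = np.abs(bx) / sy
    tab = pd.DataFrame(
        {"variant_id": h.variant_ids, "ratio": ratio, "precision": precision}
    )
    if h.k >= 2:
        tab["ivw_slope"] = ivw(h).beta
    if h.k >= 3:
        est = EggerEstimator().fit(bx, by, se_y=sy)
        tab["egger_slope"] = est.coef_[0]
    return tab


def steiger_direction(h: HarmonizedSet) -> str:
    """Global direction verdict: do instruments explain more exposure variance?"""
    from .instruments import steiger_report

    rep = steiger_report(h)
    frac = float(rep["direction_ok"].mean()) if len(rep) else float("nan")
    return "exposure_to_outcome" if frac >= 0.5 else "outcome_to_exposure"


def diagnostics(h: HarmonizedSet) -> DiagnosticsReport:
    """Assemble the full report; members needing k>=3 degrade to None."""
    q, df, p = cochran_q(h)
    if h.k >= 3:
        ic, ic_se, ic_p = egger_intercept(h)
        loo = leave_one_out(h)
    else:
        ic = ic_se = ic_p = None
        loo = None
    return DiagnosticsReport(
        cochran_q=q,
        q_df=df,
        q_pvalue=p,
        egger_intercept=ic,
        egger_intercept_se=ic_se,
        egger_intercept_pvalue=ic_p,
        loo_table=loo,
        funnel_table=funnel_data(h),
        steiger_global=steiger_direction(h),
    )
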