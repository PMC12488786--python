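"""Univariable two-sample MR: one exposure, one outcome, five estimators.

Thin functional layer over :mod:`mrpath.estimators` producing
:class:`MREstimate` records (beta, SE, 95% CI, p, odds ratio, instrument
count) from a :class:`~mrpath.gwas_io.HarmonizedSet`.  ``run_all`` fits the
inverse-variance-weighted, MR-Egger, weighted-median and both mode-based
estimators (or the single-variant Wald ratio when only one instrument
survives) and attaches the sensitivity diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    IVWEstimator,
    EggerEstimator,
    WeightedMedianEstimator,
    ModeEstimator,
    Z_95,
)
from .gwas_io import HarmonizedSet

__all__ = [
    "MREstimate",
    "MRResultSet",
    "beta_to_or",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median_mr",
    "mode_estimate",
    "run_all",
]


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into (OR, 95% lower, 95% upper)."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
    )


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds (or SD) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    or_: float
    or_low: float
    or_high: float
    n_snv: int
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_stats(cls, method: str, beta: float, se: float, pvalue: float, n_snv: int,
                   **extras) -> "MREstimate":
        or_, lo, hi = beta_to_or(beta, se)
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z_95 * se),
            ci_high=float(beta + Z_95 * se),
            pvalue=float(pvalue),
            or_=or_,
            or_low=lo,
            or_high=hi,
            n_snv=int(n_snv),
            extras=extras,
        )

    def as_row(self) -> dict:
        row = dict(
            method=self.method,
            n_snv=self.n_snv,
            beta=self.beta,
            se=self.se,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            or_=self.or_,
            or_low=self.or_low,
            or_high=self.or_high,
            pvalue=self.pvalue,
        )
        return row


@dataclass
class MRResultSet:
    """All requested estimates for one exposure-outcome pair + diagnostics."""

    estimates: dict  # method name -> MREstimate
    diagnostics: object | None = None  # sensitivity.DiagnosticsReport

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_row() for e in self.estimates.values()])


def _unpack(h: HarmonizedSet):
    if h.n_exposures != 1:
        raise ValueError("univariable MR requires a single-exposure HarmonizedSet")
    return h.beta_x[:, 0], h.se_x[:, 0], h.beta_y, h.se_y


def wald_ratio(beta_x, se_x, beta_y, se_y, second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate ``beta_y / beta_x``.

    First-order delta-method SE ``se_y / |beta_x|`` by default; the
    ``second_order`` flag adds the exposure-uncertainty term
    ``beta_y**2 * se_x**2 / beta_x**4``.
    """
    if beta_x == 0:
        raise ValueError("Wald ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    var = se_y**2 / beta_x**2
    if second_order:
        var = var + (beta_y**2 * se_x**2) / beta_x**4
    se = float(np.sqrt(var))
    p = 1.0 if beta == 0 else float(2.0 * stats.norm.sf(abs(beta) / se))
    return MREstimate.from_stats("wald_ratio", beta, se, max(p, 5e-324), 1)


def ivw(h: HarmonizedSet, model: str = "random") -> MREstimate:
    """IVW estimate; a single instrument delegates to the Wald ratio."""
    bx, sx, by, sy = _unpack(h)
    if h.k == 1:
        return wald_ratio(bx[0], sx[0], by[0], sy[0])
    est = IVWEstimator(model=model).fit(bx, by, se_y=sy)
    return MREstimate.from_stats(
        f"ivw_{model}", est.coef_[0], est.se_[0], est.pvalue_[0], h.k,
        q=est.q_, q_df=est.q_df_, q_pvalue=est.q_pvalue_, dispersion=est.dispersion_,
    )


def mr_egger(h: HarmonizedSet, model: str = "random") -> MREstimate:
    """MR-Egger slope; intercept diagnostics ride along in ``extras``."""
    bx, _, by, sy = _unpack(h)
    est = EggerEstimator(model=model).fit(bx, by, se_y=sy)
    return MREstimate.from_stats(
        "mr_egger", est.coef_[0], est.se_[0], est.pvalue_[0], h.k,
        intercept=est.intercept_, intercept_se=est.intercept_se_,
        intercept_pvalue=est.intercept_pvalue_, q=est.q_, q_df=est.q_df_,
    )


def weighted_median_mr(h: HarmonizedSet, n_boot: int = 1000, seed=None) -> MREstimate:
    bx, sx, by, sy = _unpack(h)
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(
        bx, by, se_y=sy, se_x=sx
    )
    return MREstimate.from_stats(
        "weighted_median", est.coef_[0], est.se_[0], est.pvalue_[0], h.k
    )


def mode_estimate(h: HarmonizedSet, kind: str = "weighted", phi: float = 1.0,
                  n_boot: int = 1000, seed=None) -> MREstimate:
    bx, sx, by, sy = _unpack(h)
    est = ModeEstimator(kind=kind, phi=phi, n_boot=n_boot, random_state=seed).fit(
        bx, by, se_y=sy, se_x=sx
    )
    return MREstimate.from_stats(
        f"{kind}_mode", est.coef_[0], est.se_[0], est.pvalue_[0], h.k
    )


def run_all(
    h: HarmonizedSet,
    model: str = "random",
    n_boot: int = 1000,
    seed=None,
    phi: float = 1.0,
    with_diagnostics: bool = True,
) -> MRResultSet:
    """Fit every applicable method and attach sensitivity diagnostics.

    With one surviving instrument only the Wald ratio is reported; with two,
    IVW (and the heterogeneity test) but no Egger/median/mode.  Bootstrap
    seeds are split deterministically from ``seed``.
    """
    bx, sx, by, sy = _unpack(h)
    estimates: dict[str, MREstimate] = {}
    if h.k == 1:
        estimates["wald_ratio"] = wald_ratio(bx[0], sx[0], by[0], sy[0])
        return MRResultSet(estimates=estimates)

    estimates["ivw"] = ivw(h, model=model)
    if h.k >= 3:
        if isinstance(seed, np.random.SeedSequence):
            ss = seed.spawn(3)
        else:
            ss = np.random.SeedSequence(seed).spawn(3)
        estimates["mr_egger"] = mr_egger(h, model=model)
        estimates["weighted_median"] = weighted_median_mr(
            h, n_boot=n_boot, seed=np.random.default_rng(ss[0])
        )
        estimates["weighted_mode"] = mode_estimate(
            h, kind="weighted", phi=phi, n_boot=n_boot, seed=np.random.default_rng(ss[1])
        )
        estimates["simple_mode"] = mode_estimate(
            h, kind="simple", phi=phi, n_boot=n_boot, seed=np.random.default_rng(ss[2])
        )
    diagnostics = None
    if with_diagnostics and h.k >= 2:
        from .sensitivity import diagnostics as _diag

        diagnostics = _diag(h)
    return MRResultSet(estimates=estimates, diagnostics=diagnostics)
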