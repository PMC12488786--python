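"""Multivariable MR: joint instruments for several exposures, direct effects.

``build_union`` assembles the instrument union (each exposure's genome-wide
significant, clumped variants, re-clumped jointly and harmonized across all
exposures and the outcome); ``mvmr_ivw`` / ``mvmr_egger`` / ``mvmr_median``
fit the multivariable weighted regressions and report one estimate per
exposure, the coefficient being that exposure's direct effect conditional on
the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerEstimator,
    IVWEstimator,
    MedianMVMREstimator,
)
from .gwas_io import HarmonizedSet, SummaryDataset, harmonize
from .instruments import (
    InstrumentConfig,
    LDTable,
    clump,
    filter_maf,
    filter_pvalue,
)
from .univariable import MREstimate

__all__ = ["MVMRResult", "build_union", "mvmr_ivw", "mvmr_egger", "mvmr_median",
           "conditional_f", "EstimabilityError"]


class EstimabilityError(ValueError):
    """Too few instruments to identify all exposures' direct effects."""


@dataclass
class MVMRResult:
    """Per-exposure estimates for each requested multivariable method."""

    estimates: dict  # method -> list[MREstimate], ordered like exposures
    exposure_names: list
    n_snv: int
    conditional_f: pd.Series | None = None
    attrition: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, ests in self.estimates.items():
            for name, e in zip(self.exposure_names, ests):
                row = e.as_row()
                row["exposure"] = name
                row["method"] = method
                rows.append(row)
        cols = ["exposure", "method", "n_snv", "beta", "se", "ci_low", "ci_high",
                "or_", "or_low", "or_high", "pvalue"]
        return pd.DataFrame(rows)[cols]


def build_union(
    exposures: list,
    outcome: SummaryDataset,
    ld: LDTable | None = None,
    config: InstrumentConfig | None = None,
    steiger: bool = True,
) -> HarmonizedSet:
    """Joint instrument set harmonized across all exposures and the outcome.

    Candidates are the union of each exposure's significant, clumped
    variants; the union is re-clumped jointly (ranking by the best p-value
    any exposure assigns a variant), harmonized, and variants missing any
    exposure's record are dropped.  MAF and instrument-strength filters
    apply against the first (primary) exposure, as does the optional Steiger
    directionality filter.
    """
    if len(exposures) < 2:
        raise ValueError("multivariable MR requires at least 2 exposures")
    cfg = config or InstrumentConfig()

    per_exposure: list[list] = []
    for ds in exposures:
        ids = filter_pvalue(ds, cfg.p_threshold)
        if ids:
            ids = clump(ds, ids, ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb,
                        missing_ld=cfg.missing_ld)
        per_exposure.append(ids)

    union: list[str] = []
    seen = set()
    for ids in per_exposure:
        for v in ids:
            if v not in seen:
                seen.add(v)
                union.append(v)
    if not union:
        raise EstimabilityError("no genome-wide-significant instruments in any exposure")

    # joint re-clump: rank by the smallest p-value across exposures
    best_p: dict[str, float] = {}
    pos_info: dict[str, tuple] = {}
    for ds in exposures:
        tab = ds.table.set_index("variant_id")
        for v in union:
            if v in tab.index:
                p = float(tab.loc[v, "pvalue"])
                if p < best_p.get(v, np.inf):
                    best_p[v] = p
                pos_info.setdefault(v, (tab.loc[v, "chrom"], int(tab.loc[v, "pos"])))
    rank_frame = pd.DataFrame(
        {
            "variant_id": union,
            "chrom": [pos_info[v][0] for v in union],
            "pos": [pos_info[v][1] for v in union],
            "eaf": np.nan,
            "beta": np.nan,
            "se": 1.0,
            "pvalue": [best_p[v] for v in union],
            "n": 1.0,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
    rank_ds = SummaryDataset.from_frame(
        rank_frame, "union", "continuous", validate=False
    )
    union = clump(rank_ds, union, ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb,
                  missing_ld=cfg.missing_ld)

    # variants must be present (and MAF-adequate) in the primary exposure
    present = [v for v in union if v in exposures[0]]
    present = filter_maf(exposures[0], present, cfg.maf_min, missing=cfg.missing_maf)

    h = harmonize(exposures, outcome, present,
                  palindrome_eaf_window=cfg.palindrome_eaf_window)

    if steiger:
        # each variant is tested against the exposure it best instruments;
        # testing mediator/secondary-exposure instruments against the primary
        # exposure alone would delete them wholesale
        z2_x = (h.beta_x / h.se_x) ** 2
        r2_x = (z2_x / (z2_x + h.n_x - 2.0)).max(axis=1)
        z2_y = (h.beta_y / h.se_y) ** 2
        r2_y = z2_y / (z2_y + h.n_y - 2.0)
        n_best = np.take_along_axis(
            h.n_x, np.argmax(z2_x / (z2_x + h.n_x - 2.0), axis=1)[:, None], axis=1
        ).ravel()
        z = (np.arctanh(np.sqrt(r2_x)) - np.arctanh(np.sqrt(r2_y))) / np.sqrt(
            1.0 / (n_best - 3.0) + 1.0 / (h.n_y - 3.0)
        )
        p = 2.0 * stats.norm.sf(np.abs(z))
        keep = (r2_x > r2_y) | (p >= cfg.steiger_alpha)
        h = h.subset(list(np.flatnonzero(keep)))

    if h.k < h.n_exposures + 1:
        raise EstimabilityError(
            f"instrument union ({h.k}) must exceed the exposure count ({h.n_exposures})"
        )
    return h


def _to_estimates(est, h: HarmonizedSet, method: str, **extras) -> list:
    out = []
    for j in range(h.n_exposures):
        out.append(
            MREstimate.from_stats(
                method, est.coef_[j], est.se_[j], est.pvalue_[j], h.k, **extras
            )
        )
    return out


def mvmr_ivw(h: HarmonizedSet, model: str = "random") -> MVMRResult:
    """Multivariable IVW: weighted zero-intercept multiple regression."""
    est = IVWEstimator(model=model).fit(
        h.beta_x, h.beta_y, se_y=h.se_y, exposure_names=h.exposure_names
    )
    return MVMRResult(
        estimates={"mv_ivw": _to_estimates(est, h, "mv_ivw", q=est.q_, q_df=est.q_df_)},
        exposure_names=list(h.exposure_names),
        n_snv=h.k,
    )


def mvmr_egger(h: HarmonizedSet, model: str = "random") -> MVMRResult:
    """Multivariable MR-Egger: adds a pleiotropy intercept to the fit."""
    est = EggerEstimator(model=model).fit(
        h.beta_x, h.beta_y, se_y=h.se_y, exposure_names=h.exposure_names
    )
    ests = _to_estimates(
        est, h, "mv_egger",
        intercept=est.intercept_, intercept_se=est.intercept_se_,
        intercept_pvalue=est.intercept_pvalue_,
    )
    return MVMRResult(
        estimates={"mv_egger": ests},
        exposure_names=list(h.exposure_names),
        n_snv=h.k,
    )


def mvmr_median(h: HarmonizedSet, n_boot: int = 200, seed=None) -> MVMRResult:
    """Multivariable median: weighted LAD regression, bootstrap SEs."""
    est = MedianMVMREstimator(n_boot=n_boot, random_state=seed).fit(
        h.beta_x, h.beta_y, se_y=h.se_y, se_x=h.se_x, exposure_names=h.exposure_names
    )
    return MVMRResult(
        estimates={"mv_median": _to_estimates(est, h, "mv_median")},
        exposure_names=list(h.exposure_names),
        n_snv=h.k,
    )


def conditional_f(h: HarmonizedSet) -> pd.Series:
    """Approximate per-exposure conditional instrument strength.

    Each exposure's effects are regressed (weights ``1/se_x**2``) on the
    other exposures' effects; the conditional F is the mean squared
    residual z-score.  Computed under the simplifying assumption of
    independent exposure samples — treat as approximate.
    """
    k, m = h.beta_x.shape
    out = {}
    for j in range(m):
        others = [c for c in range(m) if c != j]
        x_j = h.beta_x[:, j]
        if others:
            X = h.beta_x[:, others]
            w = 1.0 / h.se_x[:, j] ** 2
            coef = np.linalg.lstsq(np.sqrt(w)[:, None] * X, np.sqrt(w) * x_j, rcond=None)[0]
            resid = x_j - X @ coef
        else:
            resid = x_j
        name = h.exposure_names[j] if h.exposure_names else f"x{j + 1}"
        out[name] = float(np.mean((resid / h.se_x[:, j]) ** 2))
    return pd.Series(out, name="conditional_f")


def run_mvmr(
    h: HarmonizedSet,
    methods: tuple = ("ivw", "egger", "median"),
    model: str = "random",
    n_boot: int = 200,
    seed=None,
    with_conditional_f: bool = False,
) -> MVMRResult:
    """Fit the requested multivariable methods on one harmonized union."""
    estimates: dict[str, list] = {}
    if "ivw" in methods:
        estimates.update(mvmr_ivw(h, model=model).estimates)
    if "egger" in methods:
        estimates.update(mvmr_egger(h, model=model).estimates)
    if "median" in methods:
        estimates.update(mvmr_median(h, n_boot=n_boot, seed=seed).estimates)
    return MVMRResult(
        estimates=estimates,
        exposure_names=list(h.exposure_names),
        n_snv=h.k,
        conditional_f=conditional_f(h) if with_conditional_f else None,
    )
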