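"""Two-step MR mediation: screen a mediator panel, estimate each survivor's
conditional outcome effect, and decompose the total exposure effect.

Step 1 estimates the exposure's effect on every mediator (``a``) with
univariable IVW on Steiger-filtered instruments, applying a Bonferroni
threshold over the panel and excluding mediators whose Egger-intercept test
indicates directional pleiotropy.  Step 2 estimates each surviving
mediator's effect on the outcome conditional on the exposure (``b``) with
two-exposure multivariable IVW.  The total effect ``c`` (univariable IVW of
exposure on outcome) is decomposed into the indirect path ``a*b`` and the
direct remainder ``c' = c - a*b``; the Sobel test assesses the indirect
effect and the delta method gives a confidence interval for the proportion
mediated ``a*b / c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z_95
from .gwas_io import SummaryDataset, harmonize
from .instruments import (
    EmptyInstrumentSetError,
    InstrumentConfig,
    LDTable,
    ProxyTable,
    clump,
    filter_maf,
    filter_pvalue,
    select_instruments,
    steiger_filter,
)
from .mvmr import build_union, run_mvmr
from .univariable import MREstimate, ivw, run_all

__all__ = [
    "MediationResult",
    "ScreenResult",
    "TwoStepReport",
    "bonferroni_threshold",
    "screen_mediators",
    "mediator_outcome_step",
    "decompose",
    "sign_consistency_filter",
    "run_two_step",
]


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


@dataclass
class MediationResult:
    """Full decomposition for one mediator.

    ``direct_c_prime`` is the difference-method direct effect ``c - a*b``
    (exact by construction); the MVMR exposure coefficient is carried in
    ``mvmr_direct`` as an independent estimate of the same quantity.
    """

    mediator: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    indirect: float
    se_indirect: float
    direct_c_prime: float
    sobel_z: float
    sobel_p: float
    proportion: float | None
    proportion_se: float | None
    proportion_ci: tuple | None
    sign_consistent: bool
    mvmr_direct: float | None = None
    mvmr_direct_se: float | None = None
    n_snv_step2: int | None = None

    def as_row(self) -> dict:
        lo, hi = self.proportion_ci if self.proportion_ci else (None, None)
        return dict(
            mediator=self.mediator, a=self.a, se_a=self.se_a, b=self.b,
            se_b=self.se_b, c=self.c, se_c=self.se_c, indirect=self.indirect,
            se_indirect=self.se_indirect, direct_c_prime=self.direct_c_prime,
            sobel_z=self.sobel_z, sobel_p=self.sobel_p,
            proportion=self.proportion, proportion_se=self.proportion_se,
            proportion_ci_low=lo, proportion_ci_high=hi,
            sign_consistent=self.sign_consistent,
            mvmr_direct=self.mvmr_direct, mvmr_direct_se=self.mvmr_direct_se,
            n_snv_step2=self.n_snv_step2,
        )


def decompose(a, se_a, b, se_b, c, se_c, mediator: str = "") -> MediationResult:
    """Product-of-coefficients decomposition with Sobel test and delta CI.

    indirect = a*b; Sobel variance ``a^2 se_b^2 + b^2 se_a^2``;
    c' = c - a*b (so c' + a*b = c exactly); proportion = a*b/c with
    delta-method variance treating a*b and c as independent (two-sample
    designs provide no covariance).  c = 0 leaves the proportion undefined.
    """
    indirect = a * b
    se_ind = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    if indirect == 0.0:
        sobel_z = 0.0
    elif se_ind == 0.0:
        sobel_z = float(np.inf) * np.sign(indirect)
    else:
        sobel_z = indirect / se_ind
    sobel_p = float(np.clip(2.0 * stats.norm.sf(abs(sobel_z)), 5e-324, 1.0))
    c_prime = c - indirect
    if c == 0.0:
        proportion = proportion_se = ci = None
    else:
        proportion = indirect / c
        if indirect == 0.0:
            # delta form degenerates; variance from the numerator alone
            var = se_ind**2 / c**2
        else:
            # ratio form (se_a/a)^2 + (se_b/b)^2 avoids underflow of a^2 b^2;
            # numpy arithmetic turns extreme ratios into inf rather than raising
            with np.errstate(over="ignore", divide="ignore"):
                rel_ind = np.float64(se_a / a) ** 2 + np.float64(se_b / b) ** 2
                var = float(proportion**2 * (rel_ind + np.float64(se_c / c) ** 2))
        proportion_se = float(np.sqrt(var))
        ci = (proportion - Z_95 * proportion_se, proportion + Z_95 * proportion_se)
    sign_consistent = bool(np.sign(indirect) == np.sign(c)) or indirect == 0.0
    return MediationResult(
        mediator=mediator, a=float(a), se_a=float(se_a), b=float(b),
        se_b=float(se_b), c=float(c), se_c=float(se_c),
        indirect=float(indirect), se_indirect=se_ind,
        direct_c_prime=float(c_prime), sobel_z=float(sobel_z), sobel_p=sobel_p,
        proportion=proportion, proportion_se=proportion_se,
        proportion_ci=ci, sign_consistent=sign_consistent,
    )


@dataclass
class ScreenResult:
    """Step-1 outcome: per-mediator exposure effects and pass flags."""

    table: pd.DataFrame
    bonferroni: float
    alpha: float
    steiger_excluded_total: int

    @property
    def passing(self) -> list:
        mask = self.table["passed"]
        return self.table.loc[mask, "mediator"].tolist()


def screen_mediators(
    exposure: SummaryDataset,
    mediators: dict,
    config: InstrumentConfig | None = None,
    alpha: float = 0.05,
    panel_size: int | None = None,
) -> ScreenResult:
    """Estimate the exposure's effect on every mediator (step 1).

    The exposure's candidate instruments (significance + clumping + MAF) are
    selected once; per mediator they are harmonized and Steiger-filtered
    (tallying excluded variants), then IVW gives the ``a`` estimate.  A
    mediator passes when its p-value clears the Bonferroni threshold over
    the panel; passing mediators with a significant Egger-intercept test
    are excluded as pleiotropic.  Per-mediator failures are logged as rows
    with ``error`` set, never fatal to the panel.
    """
    cfg = config or InstrumentConfig()
    m = panel_size if panel_size is not None else len(mediators)
    threshold = bonferroni_threshold(alpha, m)

    ids = filter_pvalue(exposure, cfg.p_threshold)
    ids = clump(exposure, ids, None, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb,
                missing_ld=cfg.missing_ld) if ids else ids
    ids = filter_maf(exposure, ids, cfg.maf_min, missing=cfg.missing_maf)

    rows = []
    steiger_total = 0
    for name, med in mediators.items():
        try:
            h = harmonize(exposure, med, ids,
                          palindrome_eaf_window=cfg.palindrome_eaf_window)
            kept, _ = steiger_filter(h, alpha=cfg.steiger_alpha, mode=cfg.steiger_mode)
            n_excluded = h.k - len(kept)
            steiger_total += n_excluded
            h = h.subset(kept)
            if h.k == 0:
                raise EmptyInstrumentSetError("steiger")
            est = ivw(h, model="random")
            egger_p = None
            if h.k >= 3:
                from .sensitivity import egger_intercept

                egger_p = egger_intercept(h)[2]
            passed_bonf = est.pvalue < threshold
            pleio = bool(egger_p is not None and egger_p < 0.05)
            rows.append(
                dict(
                    mediator=name, n_snv=h.k, beta=est.beta, se=est.se,
                    pvalue=est.pvalue, steiger_excluded=n_excluded,
                    pass_bonferroni=bool(passed_bonf),
                    egger_intercept_p=egger_p, pleiotropy_excluded=pleio,
                    passed=bool(passed_bonf and not pleio), error=None,
                )
            )
        except Exception as exc:  # per-mediator degradation, panel continues
            rows.append(
                dict(
                    mediator=name, n_snv=0, beta=np.nan, se=np.nan,
                    pvalue=np.nan, steiger_excluded=0, pass_bonferroni=False,
                    egger_intercept_p=np.nan, pleiotropy_excluded=False,
                    passed=False, error=str(exc),
                )
            )
    return ScreenResult(
        table=pd.DataFrame(rows),
        bonferroni=threshold,
        alpha=alpha,
        steiger_excluded_total=steiger_total,
    )


def mediator_outcome_step(
    exposure: SummaryDataset,
    mediator: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDTable | None = None,
    config: InstrumentConfig | None = None,
    methods: tuple = ("ivw", "egger", "median"),
    n_boot: int = 200,
    seed=None,
):
    """Two-exposure MVMR (exposure + mediator -> outcome): step 2.

    Returns ``(b_estimates, direct_estimates, n_snv)`` where each is a dict
    method -> :class:`~mrpath.univariable.MREstimate`; ``b`` is the
    mediator's conditional coefficient, ``direct`` the exposure's.
    """
    try:
        h = build_union([exposure, mediator], outcome, ld=ld, config=config)
    except Exception as exc:
        raise type(exc)(f"mediator {mediator.trait_name!r}: {exc}") from exc
    res = run_mvmr(h, methods=methods, n_boot=n_boot, seed=seed)
    b_est = {m: ests[1] for m, ests in res.estimates.items()}
    direct_est = {m: ests[0] for m, ests in res.estimates.items()}
    return b_est, direct_est, res.n_snv


def sign_consistency_filter(results: list) -> tuple[list, pd.DataFrame]:
    """Drop mediators whose indirect effect opposes the total effect.

    A mediator with ``sign(a*b) != sign(c)`` cannot explain a share of the
    total effect; it is excluded and logged with both signs.  An exactly
    zero indirect effect is retained with a warning (the sign test is
    degenerate there).
    """
    import warnings

    kept, log = [], []
    for r in results:
        if r.indirect == 0.0:
            warnings.warn(
                f"mediator {r.mediator!r}: indirect effect exactly zero; "
                "sign test degenerate, retaining",
                stacklevel=2,
            )
            kept.append(r)
            continue
        if np.sign(r.indirect) == np.sign(r.c):
            kept.append(r)
        else:
            log.append(
                dict(mediator=r.mediator, indirect_sign=float(np.sign(r.indirect)),
                     total_sign=float(np.sign(r.c)))
            )
    return kept, pd.DataFrame(log, columns=["mediator", "indirect_sign", "total_sign"])


@dataclass
class TwoStepReport:
    """Everything the two-step analysis produces, ready to serialize."""

    total_effect: MREstimate
    method_table: pd.DataFrame  # all univariable methods on exposure->outcome
    screen: ScreenResult
    candidate_table: pd.DataFrame  # nominal mediator->outcome univariable MR
    mvmr_table: pd.DataFrame  # step-2 per-mediator, per-method rows
    mediation_table: pd.DataFrame  # decompositions for sign-consistent mediators
    sign_exclusions: pd.DataFrame
    mediation_results: list = field(default_factory=list)
    bonferroni_step2: float | None = None

    def summary_dict(self) -> dict:
        return dict(
            total_effect=self.total_effect.as_row(),
            bonferroni_step1=self.screen.bonferroni,
            bonferroni_step2=self.bonferroni_step2,
            n_mediators_screened=int(len(self.screen.table)),
            n_pass_bonferroni=int(self.screen.table["pass_bonferroni"].sum()),
            n_pleiotropy_excluded=int(self.screen.table["pleiotropy_excluded"].sum()),
            n_mediators_passing=int(len(self.screen.passing)),
            steiger_excluded_total=int(self.screen.steiger_excluded_total),
            n_candidates=int(self.candidate_table["nominal"].sum())
            if len(self.candidate_table)
            else 0,
            sign_excluded=self.sign_exclusions["mediator"].tolist(),
            mediators=[r.as_row() for r in self.mediation_results],
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary_dict(), sort_keys=True, indent=2,
                          default=_jsonable, **kwargs)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_two_step(
    exposure: SummaryDataset,
    mediator_panel: dict,
    outcome: SummaryDataset,
    ld: LDTable | None = None,
    proxies: ProxyTable | None = None,
    config: InstrumentConfig | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
    n_boot: int = 200,
    candidate_alpha: float = 0.05,
) -> TwoStepReport:
    """The full two-step mediation workflow.

    1. total effect ``c``: instrument selection + all univariable methods;
    2. panel screen for ``a`` with Bonferroni over the panel size and
       pleiotropy exclusion;
    3. univariable mediator -> outcome MR; mediators nominally significant
       (p < ``candidate_alpha``) become candidates (the panel-wide
       Bonferroni threshold for this step is reported alongside);
    4. per-candidate two-exposure MVMR for ``b``;
    5. sign-consistency filter and decomposition.

    All bootstrap randomness is split deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    seed_total, seed_step2 = ss.spawn(2)
    cfg = config or InstrumentConfig()

    # step 0: total effect
    _, h_total = select_instruments(exposure, outcome, ld=ld, proxies=proxies, config=cfg)
    total_res = run_all(h_total, n_boot=n_boot, seed=seed_total)
    c_est = total_res.estimates.get("ivw", total_res.estimates.get("wald_ratio"))

    # step 1: screen the panel
    screen = screen_mediators(exposure, mediator_panel, config=cfg, alpha=alpha)
    passing = screen.passing

    # step 2a: nominal univariable mediator -> outcome
    cand_rows = []
    bonf2 = bonferroni_threshold(alpha, max(len(passing), 1))
    for name in passing:
        med = mediator_panel[name]
        try:
            _, h_mo = select_instruments(med, outcome, ld=ld, proxies=proxies, config=cfg)
            est = ivw(h_mo, model="random")
            cand_rows.append(
                dict(mediator=name, n_snv=est.n_snv, beta=est.beta, se=est.se,
                     or_=est.or_, or_low=est.or_low, or_high=est.or_high,
                     pvalue=est.pvalue, nominal=bool(est.pvalue < candidate_alpha),
                     pass_bonferroni=bool(est.pvalue < bonf2), error=None)
            )
        except Exception as exc:
            cand_rows.append(
                dict(mediator=name, n_snv=0, beta=np.nan, se=np.nan, or_=np.nan,
                     or_low=np.nan, or_high=np.nan, pvalue=np.nan, nominal=False,
                     pass_bonferroni=False, error=str(exc))
            )
    candidate_table = pd.DataFrame(
        cand_rows,
        columns=["mediator", "n_snv", "beta", "se", "or_", "or_low", "or_high",
                 "pvalue", "nominal", "pass_bonferroni", "error"],
    )
    candidates = candidate_table.loc[candidate_table["nominal"], "mediator"].tolist()

    # step 2b: MVMR per candidate
    screen_idx = screen.table.set_index("mediator")
    med_seeds = seed_step2.spawn(max(len(candidates), 1))
    mvmr_rows, decomps = [], []
    for name, med_seed in zip(candidates, med_seeds):
        med = mediator_panel[name]
        try:
            b_est, direct_est, n_snv = mediator_outcome_step(
                exposure, med, outcome, ld=ld, config=cfg, n_boot=n_boot,
                seed=np.random.default_rng(med_seed),
            )
        except Exception as exc:
            mvmr_rows.append(dict(mediator=name, method="mv_ivw", n_snv=0,
                                  beta=np.nan, se=np.nan, or_=np.nan, or_low=np.nan,
                                  or_high=np.nan, pvalue=np.nan, error=str(exc)))
            continue
        for method, est in b_est.items():
            mvmr_rows.append(
                dict(mediator=name, method=method, n_snv=est.n_snv, beta=est.beta,
                     se=est.se, or_=est.or_, or_low=est.or_low, or_high=est.or_high,
                     pvalue=est.pvalue, error=None)
            )
        a_row = screen_idx.loc[name]
        headline_b = b_est["mv_ivw"]
        headline_direct = direct_est["mv_ivw"]
        res = decompose(
            a=float(a_row["beta"]), se_a=float(a_row["se"]),
            b=headline_b.beta, se_b=headline_b.se,
            c=c_est.beta, se_c=c_est.se, mediator=name,
        )
        res.mvmr_direct = headline_direct.beta
        res.mvmr_direct_se = headline_direct.se
        res.n_snv_step2 = n_snv
        decomps.append(res)

    kept, sign_log = sign_consistency_filter(decomps)
    mediation_table = pd.DataFrame(
        [r.as_row() for r in kept],
        columns=list(decompose(0.0, 1.0, 0.0, 1.0, 1.0, 1.0).as_row().keys()),
    )
    return TwoStepReport(
        total_effect=c_est,
        method_table=total_res.to_frame(),
        screen=screen,
        candidate_table=candidate_table,
        mvmr_table=pd.DataFrame(
            mvmr_rows,
            columns=["mediator", "method", "n_snv", "beta", "se", "or_", "or_low",
                     "or_high", "pvalue", "error"],
        ),
        mediation_table=mediation_table,
        sign_exclusions=sign_log,
        mediation_results=kept,
        bonferroni_step2=bonf2,
    )
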