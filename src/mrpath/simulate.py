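"""Synthetic GWAS summary statistics with known causal structure.

The generator draws per-variant summary statistics directly (no
individual-level genotypes) under the linear structural model the whole
package assumes::

    exposure  X:  instrument j has true effect gamma_j
    mediator  M_i:  delta_ij = a_i * gamma_j            (at exposure SNVs)
                    delta_ij = m_ij                     (at M_i's own SNVs)
    outcome   Y:  Gamma_j = c' * gamma_j + sum_i b_i * delta_ij + alpha_j

with ``alpha_j`` horizontal-pleiotropy effects for a configurable fraction of
instruments.  Standard errors follow the usual summary-statistic
approximation ``se = 1 / sqrt(2 n p (1 - p))`` from sample size and allele
frequency; observed betas are the true effects plus Normal noise at that
scale (optionally over-dispersed to mimic between-variant heterogeneity).
Each trait's "cohort" receives independent sampling noise, so the
two-sample assumption of the estimators holds by construction.

The total causal effect of the exposure on the outcome is
``theta_total = c' + sum_i a_i * b_i``, and the truth proportions mediated
are ``a_i * b_i / theta_total`` — both recorded in :class:`SimulationTruth`
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryDataset

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_pair",
    "simulate_mediation",
    "simulate_panel",
    "harmonized_from_truth",
]

_NONPALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_TINY_P = 5e-324  # smallest subnormal double; keeps p-values inside (0, 1]


@dataclass
class SimulationConfig:
    """Generating parameters of the structural model.

    Sample sizes default to the consortium scales of the motivating study
    design (exposure biobank ~441k, NMR metabolite panel ~115k, outcome
    case-control ~138k).  ``f_true_range`` controls instrument strength: the
    true per-instrument F statistic is drawn uniformly from it.
    """

    n_snv: int = 36  # exposure instruments
    n_null_snv: int = 300  # non-associated background variants
    n_x: int = 440_735
    n_m: int = 115_078
    n_y: int = 138_086
    theta_total: float = float(np.log(0.956))  # total causal effect c
    a_vec: tuple = ()  # exposure -> mediator effects
    b_vec: tuple = ()  # mediator -> outcome effects
    c_prime: float | None = None  # direct effect; derived if None
    pleiotropy: tuple = (0.0, 0.0, 0.0)  # (fraction invalid, mean, sd)
    heterogeneity_scale: float = 1.0  # multiplicative SE over-dispersion on Y
    maf_range: tuple = (0.05, 0.5)
    f_true_range: tuple = (300.0, 2500.0)
    n_mediator_snv: int = 110  # mediator-specific instruments each
    mediator_f_range: tuple = (100.0, 200.0)
    # F ranges define true effect sizes relative to these cohort sizes
    # (defaulting to n_x / n_m); fixing them decouples the biology from the
    # analyzed sample size, so precision scales with n as in real data
    f_reference_n: int | None = None
    mediator_f_reference_n: int | None = None
    mediator_u_sd: float = 0.0  # extra per-SNV noise on delta at exposure SNVs
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        frac, _, sd = self.pleiotropy
        if not (0.0 <= frac <= 1.0):
            raise ValueError("pleiotropy fraction must lie in [0, 1]")
        if sd < 0:
            raise ValueError("pleiotropy sd must be non-negative")
        for n in (self.n_x, self.n_m, self.n_y):
            if n <= 3:
                raise ValueError("sample sizes must exceed 3")
        if len(self.a_vec) != len(self.b_vec):
            raise ValueError("a_vec and b_vec must have equal length")
        ab = float(np.dot(self.a_vec, self.b_vec)) if self.a_vec else 0.0
        if self.c_prime is None:
            self.c_prime = self.theta_total - ab
        elif abs(self.c_prime + ab - self.theta_total) > 1e-10:
            raise ValueError(
                "theta_total must equal c_prime + sum(a_i*b_i) when the chain "
                "is the sole causal pathway"
            )

    @property
    def truth_proportions(self) -> np.ndarray:
        a = np.asarray(self.a_vec, float)
        b = np.asarray(self.b_vec, float)
        return a * b / self.theta_total


@dataclass
class SimulationTruth:
    """Realized per-SNV effects plus the generating configuration."""

    config: SimulationConfig
    gamma: np.ndarray  # true exposure effects (instruments only)
    alpha: np.ndarray  # horizontal-pleiotropy effects on the outcome
    instrument_ids: list
    mediator_instrument_ids: dict = field(default_factory=dict)
    mediator_a: dict = field(default_factory=dict)
    mediator_b: dict = field(default_factory=dict)
    reverse_instances: list = field(default_factory=list)  # (mediator, snv)
    pleiotropic_mediators: list = field(default_factory=list)

    @property
    def proportions(self) -> np.ndarray:
        return self.config.truth_proportions

    def to_dict(self) -> dict:
        d = asdict(self.config)
        d.update(
            gamma=list(map(float, self.gamma)),
            alpha=list(map(float, self.alpha)),
            instrument_ids=list(self.instrument_ids),
            proportions=list(map(float, np.atleast_1d(self.proportions))),
        )
        return d


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _TINY_P, 1.0)


def _draw_alleles(rng: np.random.Generator, k: int, palindromic_fraction: float):
    pal = rng.random(k) < palindromic_fraction
    ea = np.empty(k, dtype="U1")
    oa = np.empty(k, dtype="U1")
    idx_np = rng.integers(0, len(_NONPALINDROMIC), size=k)
    idx_p = rng.integers(0, len(_PALINDROMIC), size=k)
    for i in range(k):
        ea[i], oa[i] = _PALINDROMIC[idx_p[i]] if pal[i] else _NONPALINDROMIC[idx_np[i]]
    return ea, oa


def _layout(n_total: int):
    """Chromosome/position grid spacing variants >10 Mb apart on each chromosome."""
    idx = np.arange(n_total)
    chrom = (idx % 22 + 1).astype(str)
    pos = (idx // 22 + 1) * 20_000_000 + 1
    return chrom, pos


def _observe(
    rng: np.random.Generator,
    true_beta: np.ndarray,
    eaf: np.ndarray,
    n: int,
    dispersion: float = 1.0,
) -> pd.DataFrame:
    """Observed (beta, se, pvalue) for one cohort given true effects."""
    se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    beta = rng.normal(true_beta, dispersion * se)
    return pd.DataFrame({"beta": beta, "se": se, "pvalue": _pvalues(beta, se), "n": float(n)})


class _Universe:
    """Shared SNV scaffold (ids, alleles, frequencies, true exposure effects)."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator, n_extra: int = 0):
        self.config = config
        k, k0 = config.n_snv, config.n_null_snv
        total = k + n_extra + k0
        self.n_total = total
        self.ids = np.array([f"rs{i + 1:07d}" for i in range(total)])
        self.chrom, self.pos = _layout(total)
        self.ea, self.oa = _draw_alleles(rng, total, config.palindromic_fraction)
        maf = rng.uniform(*config.maf_range, size=total)
        flip = rng.random(total) < 0.5
        self.eaf = np.where(flip, 1.0 - maf, maf)

        # True exposure effects: instruments get F ~ U(f_true_range) in the
        # reference cohort's SE units, random sign; everything else is null.
        n_ref = config.f_reference_n or config.n_x
        se_x = 1.0 / np.sqrt(2.0 * n_ref * self.eaf * (1.0 - self.eaf))
        z_true = np.sqrt(rng.uniform(*config.f_true_range, size=k))
        sign = rng.choice([-1.0, 1.0], size=k)
        self.gamma = np.zeros(total)
        self.gamma[:k] = sign * z_true * se_x[:k]
        self.instrument_slice = slice(0, k)
        self.extra_slice = slice(k, k + n_extra)

    def dataset(
        self,
        rng: np.random.Generator,
        name: str,
        trait_type: str,
        true_beta: np.ndarray,
        n: int,
        dispersion: float = 1.0,
    ) -> SummaryDataset:
        obs = _observe(rng, true_beta, self.eaf, n, dispersion)
        frame = pd.DataFrame(
            {
                "variant_id": self.ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "effect_allele": self.ea,
                "other_allele": self.oa,
                "eaf": self.eaf,
                "beta": obs["beta"],
                "se": obs["se"],
                "pvalue": obs["pvalue"],
                "n": obs["n"],
            }
        )
        return SummaryDataset.from_frame(frame, name, trait_type, validate=False)


def _pleiotropy_effects(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-instrument direct outcome effects for the invalid fraction."""
    k = config.n_snv
    frac, mu, sd = config.pleiotropy
    alpha = np.zeros(k)
    n_invalid = int(round(frac * k))
    if n_invalid:
        which = rng.choice(k, size=n_invalid, replace=False)
        alpha[which] = rng.normal(mu, sd, size=n_invalid)
    return alpha


def harmonized_from_truth(datasets, outcome, variant_ids):
    """Vectorized alignment of simulated datasets on known instrument ids.

    Simulated cohorts share allele labels and orientation by construction,
    so alignment reduces to a row lookup; this bypasses the per-variant
    harmonization logic for Monte-Carlo studies where it would dominate the
    run time.  ``datasets`` is one exposure dataset or a list of them.
    """
    from .gwas_io import FLAG_ALIGNED, HarmonizedSet

    if isinstance(datasets, SummaryDataset):
        datasets = [datasets]
    ids = list(variant_ids)
    subs = [d.loc(ids) for d in datasets]
    out = outcome.loc(ids)
    return HarmonizedSet(
        variant_ids=ids,
        beta_x=np.column_stack([s["beta"].to_numpy() for s in subs]),
        se_x=np.column_stack([s["se"].to_numpy() for s in subs]),
        beta_y=out["beta"].to_numpy(),
        se_y=out["se"].to_numpy(),
        eaf=subs[0]["eaf"].to_numpy(),
        n_x=np.column_stack([s["n"].to_numpy() for s in subs]),
        n_y=out["n"].to_numpy(),
        flags={v: FLAG_ALIGNED for v in ids},
        exposure_names=[d.trait_name for d in datasets],
        outcome_name=outcome.trait_name,
    )


def simulate_pair(config: SimulationConfig, seed: int | None = None):
    """Exposure/outcome dataset pair under a direct causal effect.

    The outcome's true per-instrument effect is
    ``theta_total * gamma_j + alpha_j``; mediators are ignored.  Returns
    ``(exposure, outcome, truth)``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    uni = _Universe(config, rng)
    alpha = _pleiotropy_effects(config, rng)
    gamma_y = config.theta_total * uni.gamma
    # pleiotropy is directional *relative to the exposure-increasing allele*:
    # apply it in the orientation of the exposure effect, else a nonzero
    # mean cancels across the random allele orientations
    gamma_y[uni.instrument_slice] += alpha * np.sign(uni.gamma[uni.instrument_slice])
    exposure = uni.dataset(rng, "exposure", "binary", uni.gamma, config.n_x)
    outcome = uni.dataset(
        rng, "outcome", "binary", gamma_y, config.n_y, config.heterogeneity_scale
    )
    truth = SimulationTruth(
        config=config,
        gamma=uni.gamma[uni.instrument_slice].copy(),
        alpha=alpha,
        instrument_ids=list(uni.ids[uni.instrument_slice]),
    )
    return exposure, outcome, truth


def _mediation_universe(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_mediators: int,
    a_by_mediator: np.ndarray,
    b_by_mediator: np.ndarray,
    with_own_instruments: np.ndarray,
    mediator_names: list,
    reverse_instances: list | None = None,
    pleiotropic: list | None = None,
):
    """Core generator shared by :func:`simulate_mediation` / :func:`simulate_panel`.

    ``with_own_instruments`` marks mediators that receive their own
    ``n_mediator_snv`` specific instruments (needed for multivariable models);
    screening-only mediators carry effects at the exposure instruments alone.
    """
    n_own = int(with_own_instruments.sum()) * config.n_mediator_snv
    uni = _Universe(config, rng, n_extra=n_own)
    k = config.n_snv
    alpha = _pleiotropy_effects(config, rng)
    reverse_instances = reverse_instances or []
    pleiotropic = pleiotropic or []

    # mediator-specific instruments: carve up the extra block
    n_m_ref = config.mediator_f_reference_n or config.n_m
    se_m = 1.0 / np.sqrt(2.0 * n_m_ref * uni.eaf * (1.0 - uni.eaf))
    own_ids: dict[str, list] = {}
    own_effect = np.zeros((uni.n_total, n_mediators))
    cursor = uni.extra_slice.start
    for i in range(n_mediators):
        if not with_own_instruments[i]:
            continue
        sl = slice(cursor, cursor + config.n_mediator_snv)
        cursor += config.n_mediator_snv
        z = np.sqrt(rng.uniform(*config.mediator_f_range, size=config.n_mediator_snv))
        sgn = rng.choice([-1.0, 1.0], size=config.n_mediator_snv)
        own_effect[sl, i] = sgn * z * se_m[sl]
        own_ids[mediator_names[i]] = list(uni.ids[sl])

    # true mediator effects at every SNV
    delta = np.outer(uni.gamma, a_by_mediator) + own_effect
    if config.mediator_u_sd > 0:
        delta[:k, :] += rng.normal(0.0, config.mediator_u_sd, size=(k, n_mediators))

    # planted reverse-causality: a mediator shows an outsized effect at an
    # exposure instrument, so its variance explained exceeds the exposure's
    rev_z = {}
    for (mi, sj) in reverse_instances:
        z_x = abs(uni.gamma[sj]) / (
            1.0 / np.sqrt(2.0 * config.n_x * uni.eaf[sj] * (1.0 - uni.eaf[sj]))
        )
        rev = rng.choice([-1.0, 1.0]) * 1.5 * z_x * se_m[sj]
        delta[sj, mi] = rev
        rev_z[(mi, sj)] = rev

    # one (or more) mediators whose exposure-SNV effects carry a directional
    # pleiotropy offset, to be caught by the Egger-intercept exclusion;
    # "directional" means aligned with the oriented exposure effect, so the
    # offset survives the beta_x >= 0 canonicalization of the Egger fit
    for mi in pleiotropic:
        delta[:k, mi] += 0.01 * np.sign(uni.gamma[:k])

    gamma_y = config.c_prime * uni.gamma + delta @ b_by_mediator
    gamma_y[uni.instrument_slice] += alpha * np.sign(uni.gamma[uni.instrument_slice])

    exposure = uni.dataset(rng, "exposure", "binary", uni.gamma, config.n_x)
    mediators = {
        mediator_names[i]: uni.dataset(
            rng, mediator_names[i], "continuous", delta[:, i], config.n_m
        )
        for i in range(n_mediators)
    }
    outcome = uni.dataset(
        rng, "outcome", "binary", gamma_y, config.n_y, config.heterogeneity_scale
    )
    truth = SimulationTruth(
        config=config,
        gamma=uni.gamma[uni.instrument_slice].copy(),
        alpha=alpha,
        instrument_ids=list(uni.ids[uni.instrument_slice]),
        mediator_instrument_ids=own_ids,
        mediator_a={mediator_names[i]: float(a_by_mediator[i]) for i in range(n_mediators)},
        mediator_b={mediator_names[i]: float(b_by_mediator[i]) for i in range(n_mediators)},
        reverse_instances=[(mediator_names[mi], uni.ids[sj]) for mi, sj in reverse_instances],
        pleiotropic_mediators=[mediator_names[mi] for mi in pleiotropic],
    )
    return exposure, mediators, outcome, truth


def simulate_mediation(config: SimulationConfig, seed: int | None = None):
    """Exposure, mediator(s) and outcome cohorts under the full causal chain.

    Every mediator listed in ``config.a_vec``/``b_vec`` receives its own
    specific instruments so that multivariable models are identifiable.
    Returns ``(exposure, mediators: dict, outcome, truth)``.
    """
    if not config.a_vec:
        raise ValueError("simulate_mediation requires a_vec/b_vec to be set")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_med = len(config.a_vec)
    names = [f"mediator_{i + 1}" for i in range(n_med)]
    return _mediation_universe(
        config,
        rng,
        n_mediators=n_med,
        a_by_mediator=np.asarray(config.a_vec, float),
        b_by_mediator=np.asarray(config.b_vec, float),
        with_own_instruments=np.ones(n_med, dtype=bool),
        mediator_names=names,
    )


def simulate_panel(
    config: SimulationConfig,
    seed: int | None = None,
    n_mediators: int = 168,
    n_true: int = 95,
    n_reverse_instances: int = 0,
    n_pleiotropic: int = 1,
    a_true_range: tuple = (0.15, 0.35),
):
    """A screening panel of mediators, only a subset truly downstream.

    The mediators named in ``config.a_vec`` (the mediators of interest, with
    nonzero outcome effects ``b_vec``) occupy the first slots and get their
    own instruments; a further ``n_true - len(a_vec) - n_pleiotropic``
    mediators receive nonzero exposure effects drawn from ``a_true_range``
    (random sign) but no outcome effect; the remainder are null.
    ``n_reverse_instances`` (mediator, exposure-SNV) pairs are planted with
    reverse-causal effects for the Steiger filter to remove, avoiding the
    mediators of interest.  ``n_pleiotropic`` truly-associated mediators get
    a directional per-SNV offset for the Egger-intercept exclusion to catch.
    Returns ``(exposure, mediators: dict, outcome, truth)``.
    """
    if n_true > n_mediators:
        raise ValueError("n_true cannot exceed n_mediators")
    n_interest = len(config.a_vec)
    if n_interest + n_pleiotropic > n_true:
        raise ValueError("n_true too small for mediators of interest + pleiotropic")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    names = [f"metabolite_{i + 1:03d}" for i in range(n_mediators)]
    a = np.zeros(n_mediators)
    b = np.zeros(n_mediators)
    a[:n_interest] = np.asarray(config.a_vec, float)
    b[:n_interest] = np.asarray(config.b_vec, float)
    n_other_true = n_true - n_interest
    mag = rng.uniform(*a_true_range, size=n_other_true)
    sgn = rng.choice([-1.0, 1.0], size=n_other_true)
    a[n_interest : n_interest + n_other_true] = mag * sgn
    pleio = list(range(n_interest, n_interest + n_pleiotropic))
    # a positive exposure effect keeps the pleiotropic mediator's apparent
    # association clear of the directional offset, as screening expects
    a[pleio] = np.abs(a[pleio])

    own = np.zeros(n_mediators, dtype=bool)
    own[:n_true] = True  # every truly-associated mediator can enter MVMR

    reverse: list[tuple[int, int]] = []
    if n_reverse_instances:
        eligible = [
            (mi, sj)
            for mi in range(n_interest, n_mediators)
            for sj in range(config.n_snv)
            if mi not in pleio
        ]
        take = rng.choice(len(eligible), size=min(n_reverse_instances, len(eligible)), replace=False)
        reverse = [eligible[t] for t in sorted(take)]

    return _mediation_universe(
        config,
        rng,
        n_mediators=n_mediators,
        a_by_mediator=a,
        b_by_mediator=b,
        with_own_instruments=own,
        mediator_names=names,
        reverse_instances=reverse,
        pleiotropic=pleio,
    )
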