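"""Instrument selection: the QC cascade that turns genome-wide summary
statistics into a set of valid instrumental variants.

The cascade, in order: genome-wide significance (p < 5e-8) -> LD clumping
(r^2 < 0.001 within 10,000 kb, greedy by p-value) -> minor-allele-frequency
filter (MAF > 1%) -> harmonization to the outcome (palindrome exclusion) ->
proxy substitution for variants absent from the outcome (r^2 > 0.8) ->
instrument-strength filter (F >= 10) -> Steiger directionality filter.
Each stage's attrition is tallied so the final report can show exactly where
candidate variants were lost.

LD is an input contract: clumping and proxy search consume externally
supplied tables (a reference panel is not shipped); pairs absent from the
LD table are treated as independent by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import (
    HarmonizedSet,
    SummaryDataset,
    harmonize,
    FLAG_ABSENT_DROPPED,
    FLAG_PROXY_USED,
)

__all__ = [
    "InstrumentConfig",
    "InstrumentSet",
    "LDTable",
    "ProxyTable",
    "filter_pvalue",
    "clump",
    "filter_maf",
    "f_statistic",
    "steiger_report",
    "steiger_filter",
    "substitute_proxies",
    "select_instruments",
    "EmptyInstrumentSetError",
]


class EmptyInstrumentSetError(RuntimeError):
    """No instruments survived; names the stage that exhausted the set."""

    def __init__(self, stage: str):
        super().__init__(f"no instruments survive the '{stage}' stage")
        self.stage = stage


@dataclass
class InstrumentConfig:
    """All tunables of the QC cascade with their conventional defaults."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    maf_min: float = 0.01
    missing_maf: str = "drop"  # keep|drop variants without eaf
    f_min: float = 10.0
    f_mode: str = "z2"  # z2: (beta/se)^2 ; r2: (n-2) r2 / (1 - r2)
    steiger_alpha: float = 0.05
    steiger_mode: str = "confirm"  # confirm | exclude_significant_wrong
    proxy_r2_min: float = 0.8
    palindrome_eaf_window: tuple = (0.42, 0.58)
    missing_ld: str = "zero"  # zero | error


class LDTable:
    """Sparse symmetric table of pairwise LD (r^2 in [0, 1])."""

    def __init__(self, pairs: pd.DataFrame | None = None):
        self._r2: dict[frozenset, float] = {}
        if pairs is not None and len(pairs):
            bad = ~pairs["r2"].between(0.0, 1.0)
            if bad.any():
                raise ValueError("LD r2 values must lie in [0, 1]")
            for a, b, r2 in pairs[["variant_id_a", "variant_id_b", "r2"]].itertuples(
                index=False
            ):
                self._r2[frozenset((a, b))] = float(r2)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LDTable":
        tab = pd.read_csv(path, sep=sep)
        tab.columns = ["variant_id_a", "variant_id_b", "r2"][: len(tab.columns)]
        return cls(tab)

    def __len__(self) -> int:
        return len(self._r2)

    def r2(self, a: str, b: str, missing: str = "zero") -> float:
        key = frozenset((a, b))
        if key in self._r2:
            return self._r2[key]
        if missing == "zero":
            return 0.0
        raise KeyError(f"no LD entry for pair ({a}, {b})")


class ProxyTable:
    """Rows of (original, proxy, r2, ea_map, oa_map) with r2 above threshold.

    ``ea_map``/``oa_map`` name the proxy's alleles that correspond to the
    original variant's effect and other allele respectively.
    """

    COLUMNS = ["original_id", "proxy_id", "r2", "ea_map", "oa_map"]

    def __init__(self, rows: pd.DataFrame | None = None, r2_min: float = 0.8):
        self.r2_min = r2_min
        if rows is None or not len(rows):
            self.table = pd.DataFrame(columns=self.COLUMNS)
            return
        rows = rows[self.COLUMNS].copy()
        if (rows["r2"] <= r2_min).any():
            raise ValueError(f"proxy rows must have r2 > {r2_min}")
        self.table = rows.reset_index(drop=True)

    @classmethod
    def read(cls, path, r2_min: float = 0.8, sep: str = "\t") -> "ProxyTable":
        tab = pd.read_csv(path, sep=sep)
        tab.columns = cls.COLUMNS[: len(tab.columns)]
        return cls(tab, r2_min=r2_min)

    def candidates(self, original_id: str) -> pd.DataFrame:
        sub = self.table[self.table["original_id"] == original_id]
        return sub.sort_values("r2", ascending=False)


def filter_pvalue(dataset: SummaryDataset, threshold: float = 5e-8) -> list:
    """Variant ids with p strictly below ``threshold``, in input order."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    mask = dataset.table["pvalue"] < threshold
    return dataset.table.loc[mask, "variant_id"].tolist()


def clump(
    dataset: SummaryDataset,
    candidates: list,
    ld: LDTable | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
    missing_ld: str = "zero",
) -> list:
    """Greedy p-value clumping of candidate variants.

    Candidates are ranked by ascending p-value (ties broken by chromosome,
    position, then id, for determinism); the best remaining variant is
    accepted and every remaining candidate on the same chromosome within
    ``window_kb`` AND in LD (r^2 > ``r2_max``) with any accepted variant is
    removed.  The result is the accepted set in acceptance order.
    """
    if not candidates:
        raise ValueError("clump requires a non-empty candidate list")
    if missing_ld == "error" and (ld is None or len(ld) == 0):
        raise ValueError("LD table is empty and missing_ld policy is 'error'")
    ld = ld or LDTable()
    info = dataset.loc(candidates)
    order = info.sort_values(
        ["pvalue", "chrom", "pos", "variant_id"], kind="mergesort"
    )
    accepted: list[dict] = []
    window_bp = window_kb * 1000.0
    for row in order.itertuples(index=False):
        conflict = False
        for acc in accepted:
            if row.chrom != acc["chrom"]:
                continue
            if abs(row.pos - acc["pos"]) > window_bp:
                continue
            if ld.r2(row.variant_id, acc["variant_id"], missing=missing_ld) > r2_max:
                conflict = True
                break
        if not conflict:
            accepted.append(
                dict(variant_id=row.variant_id, chrom=row.chrom, pos=row.pos)
            )
    return [a["variant_id"] for a in accepted]


def filter_maf(
    dataset: SummaryDataset,
    ids: list,
    maf_min: float = 0.01,
    missing: str = "drop",
) -> list:
    """Keep ids whose minor-allele frequency ``min(eaf, 1-eaf)`` exceeds ``maf_min``."""
    sub = dataset.loc(ids)
    eaf = sub["eaf"]
    maf = np.minimum(eaf, 1.0 - eaf)
    keep = maf > maf_min
    if missing == "keep":
        keep = keep | eaf.isna()
    return sub.loc[keep.to_numpy(), "variant_id"].tolist()


def f_statistic(beta, se, mode: str = "z2", n=None, eaf=None):
    """Per-variant instrument-strength F statistic.

    ``z2`` (default): ``(beta/se)**2`` — the squared z-score, needing no
    allele frequency.  ``r2``: ``(n-2) r2 / (1-r2)`` with variance explained
    ``r2 = z^2 / (z^2 + n - 2)``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    z2 = (beta / se) ** 2
    if mode == "z2":
        return z2
    if mode == "r2":
        if n is None:
            raise ValueError("mode='r2' requires sample sizes")
        n = np.asarray(n, dtype=float)
        r2 = z2 / (z2 + n - 2.0)
        return (n - 2.0) * r2 / (1.0 - r2)
    raise ValueError(f"unknown f_mode {mode!r}")


def _variance_explained(beta, se, n):
    z2 = (np.asarray(beta, float) / np.asarray(se, float)) ** 2
    return z2 / (z2 + np.asarray(n, float) - 2.0)


def steiger_report(
    h: HarmonizedSet,
    n_x=None,
    n_y=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variant directionality report.

    Variance explained in exposure and outcome via ``r^2 = z^2/(z^2+n-2)``;
    the direction is correct iff ``r2_x > r2_y`` strictly.  The Steiger test
    compares Fisher-transformed correlations with variances ``1/(n-3)``.
    For multi-exposure sets the first (primary) exposure is used.
    """
    n_x = h.n_x[:, 0] if n_x is None else np.broadcast_to(float(n_x), (h.k,))
    n_y = h.n_y if n_y is None else np.broadcast_to(float(n_y), (h.k,))
    if np.any(np.asarray(n_x) <= 3) or np.any(np.asarray(n_y) <= 3):
        raise ValueError("Steiger filtering requires sample sizes > 3")
    r2_x = _variance_explained(h.beta_x[:, 0], h.se_x[:, 0], n_x)
    r2_y = _variance_explained(h.beta_y, h.se_y, n_y)
    r_x, r_y = np.sqrt(r2_x), np.sqrt(r2_y)
    z = (np.arctanh(r_x) - np.arctanh(r_y)) / np.sqrt(
        1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0)
    )
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "variant_id": h.variant_ids,
            "r2_exposure": r2_x,
            "r2_outcome": r2_y,
            "direction_ok": r2_x > r2_y,
            "steiger_z": z,
            "steiger_p": p,
        }
    )


def steiger_filter(
    h: HarmonizedSet,
    n_x=None,
    n_y=None,
    alpha: float = 0.05,
    mode: str = "confirm",
) -> tuple[list, pd.DataFrame]:
    """Apply the directionality filter; returns (kept ids, report).

    ``confirm`` keeps only variants whose direction is correct AND whose
    Steiger test confirms it (p < alpha) — retaining confidently-oriented
    instruments.  ``exclude_significant_wrong`` keeps correct-direction
    variants and drops wrong-direction ones only when the test is
    significant against them.
    """
    rep = steiger_report(h, n_x=n_x, n_y=n_y, alpha=alpha)
    if mode == "confirm":
        keep = rep["direction_ok"] & (rep["steiger_p"] < alpha)
    elif mode == "exclude_significant_wrong":
        keep = rep["direction_ok"] | (rep["steiger_p"] >= alpha)
    else:
        raise ValueError(f"unknown steiger_mode {mode!r}")
    rep = rep.assign(kept=keep)
    return rep.loc[keep, "variant_id"].tolist(), rep


def substitute_proxies(
    missing_ids: list,
    proxies: ProxyTable | None,
    outcome: SummaryDataset,
) -> pd.DataFrame:
    """Plan proxy substitutions for instruments absent from the outcome.

    For each missing id the available proxy with the highest r^2 that is
    present in the outcome wins; ``ea_map``/``oa_map`` orient the proxy's
    effect onto the original variant's effect allele.  Unresolvable ids are
    reported with ``resolved = False`` (the pipeline continues without
    them).
    """
    columns = ["original_id", "proxy_id", "r2", "sign", "beta", "se", "n", "eaf",
               "resolved"]
    if not missing_ids:
        return pd.DataFrame(columns=columns)
    rows = []
    for vid in missing_ids:
        chosen = None
        if proxies is not None:
            for cand in proxies.candidates(vid).itertuples(index=False):
                if cand.proxy_id not in outcome:
                    continue
                rec = outcome.record(cand.proxy_id)
                alleles = {rec["effect_allele"], rec["other_allele"]}
                if {cand.ea_map, cand.oa_map} != alleles:
                    import warnings

                    warnings.warn(
                        f"proxy {cand.proxy_id} allele mapping inconsistent with "
                        f"outcome record; skipping",
                        stacklevel=2,
                    )
                    continue
                sign = 1.0 if rec["effect_allele"] == cand.ea_map else -1.0
                chosen = dict(
                    original_id=vid,
                    proxy_id=cand.proxy_id,
                    r2=cand.r2,
                    sign=sign,
                    beta=sign * float(rec["beta"]),
                    se=float(rec["se"]),
                    n=float(rec["n"]),
                    eaf=(
                        float(rec["eaf"])
                        if sign == 1.0
                        else 1.0 - float(rec["eaf"])
                    )
                    if pd.notna(rec["eaf"])
                    else np.nan,
                    resolved=True,
                )
                break
        rows.append(
            chosen
            or dict(
                original_id=vid, proxy_id=None, r2=np.nan, sign=np.nan,
                beta=np.nan, se=np.nan, n=np.nan, eaf=np.nan, resolved=False,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class InstrumentSet:
    """Selected instruments with per-variant strength and provenance."""

    variant_ids: list
    f_stats: pd.Series
    provenance: pd.DataFrame
    attrition: pd.DataFrame

    @property
    def mean_f(self) -> float:
        return float(self.f_stats.mean())


def _apply_proxy_rows(h: HarmonizedSet, plan: pd.DataFrame, exposure: SummaryDataset):
    """Fold resolved proxy rows into a harmonized set, flagging proxy_used."""
    resolved = plan[plan["resolved"]]
    if not len(resolved):
        return h
    exp = exposure.table.set_index("variant_id")
    add_ids, add = [], []
    for row in resolved.itertuples(index=False):
        e = exp.loc[row.original_id]
        add_ids.append(row.original_id)
        add.append(
            dict(
                beta_x=float(e["beta"]), se_x=float(e["se"]), n_x=float(e["n"]),
                beta_y=row.beta, se_y=row.se, n_y=row.n,
                eaf=float(e["eaf"]) if pd.notna(e["eaf"]) else np.nan,
            )
        )
    flags = dict(h.flags)
    for vid in add_ids:
        flags[vid] = FLAG_PROXY_USED
    return HarmonizedSet(
        variant_ids=list(h.variant_ids) + add_ids,
        beta_x=np.concatenate([h.beta_x[:, 0], [a["beta_x"] for a in add]]),
        se_x=np.concatenate([h.se_x[:, 0], [a["se_x"] for a in add]]),
        beta_y=np.concatenate([h.beta_y, [a["beta_y"] for a in add]]),
        se_y=np.concatenate([h.se_y, [a["se_y"] for a in add]]),
        eaf=np.concatenate([h.eaf, [a["eaf"] for a in add]]),
        n_x=np.concatenate([h.n_x[:, 0], [a["n_x"] for a in add]]),
        n_y=np.concatenate([h.n_y, [a["n_y"] for a in add]]),
        flags=flags,
        exposure_names=h.exposure_names,
        outcome_name=h.outcome_name,
    )


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDTable | None = None,
    proxies: ProxyTable | None = None,
    config: InstrumentConfig | None = None,
) -> tuple[InstrumentSet, HarmonizedSet]:
    """Run the full QC cascade and return instruments + harmonized effects.

    Raises :class:`EmptyInstrumentSetError` naming the first stage that
    leaves zero candidates.  The attrition table records, per stage, how
    many candidates entered, were dropped, and survived.
    """
    cfg = config or InstrumentConfig()
    attrition: list[dict] = []

    def stage(name: str, before: int, after: int) -> None:
        attrition.append(dict(stage=name, n_in=before, n_dropped=before - after, n_out=after))
        if after == 0:
            raise EmptyInstrumentSetError(name)

    ids = filter_pvalue(exposure, cfg.p_threshold)
    stage("pvalue", len(exposure), len(ids))

    clumped = clump(
        exposure, ids, ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb,
        missing_ld=cfg.missing_ld,
    )
    stage("clump", len(ids), len(clumped))

    maf_ids = filter_maf(exposure, clumped, cfg.maf_min, missing=cfg.missing_maf)
    stage("maf", len(clumped), len(maf_ids))

    h = harmonize(
        exposure, outcome, maf_ids, palindrome_eaf_window=cfg.palindrome_eaf_window
    )
    absent = [v for v in maf_ids if h.flags.get(v) == FLAG_ABSENT_DROPPED]
    plan = substitute_proxies(absent, proxies, outcome)
    h = _apply_proxy_rows(h, plan, exposure)
    stage("harmonize", len(maf_ids), h.k)

    f = f_statistic(h.beta_x[:, 0], h.se_x[:, 0], mode=cfg.f_mode, n=h.n_x[:, 0])
    strong = np.asarray(f) >= cfg.f_min
    h_f = h.subset(list(np.flatnonzero(strong)))
    stage("f_statistic", h.k, h_f.k)

    kept, steiger = steiger_filter(
        h_f, alpha=cfg.steiger_alpha, mode=cfg.steiger_mode
    )
    h_final = h_f.subset(kept)
    stage("steiger", h_f.k, h_final.k)

    f_final = pd.Series(
        f_statistic(h_final.beta_x[:, 0], h_final.se_x[:, 0], mode=cfg.f_mode,
                    n=h_final.n_x[:, 0]),
        index=h_final.variant_ids,
        name="f",
    )
    provenance = pd.DataFrame(
        {
            "variant_id": h_final.variant_ids,
            "flag": [h_final.flags[v] for v in h_final.variant_ids],
            "proxy_used": [h_final.flags[v] == FLAG_PROXY_USED for v in h_final.variant_ids],
        }
    )
    instruments = InstrumentSet(
        variant_ids=list(h_final.variant_ids),
        f_stats=f_final,
        provenance=provenance,
        attrition=pd.DataFrame(attrition),
    )
    return instruments, h_final
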