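"""Reading, validation, writing and harmonization of GWAS summary statistics.

Every downstream stage of the package consumes the two containers defined
here: :class:`SummaryDataset` (per-variant association records for one trait)
and :class:`HarmonizedSet` (variants aligned across one or more exposures and
an outcome, with effect alleles reconciled).

Summary statistics are exchanged as tab-separated text with a header.  The
default column names are ``variant_id, chrom, pos, effect_allele,
other_allele, eaf, beta, se, pvalue, n``; a ``column_map`` argument lets
callers rename arbitrary headers onto this scheme (covering GWAS-SSF-style
exports).  Missing values are serialized as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SUMMARY_COLUMNS",
    "SummaryDataset",
    "HarmonizedSet",
    "read_summary",
    "write_summary",
    "harmonize",
]

#: Canonical column order of a summary-statistics table.
SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Allele pairs whose strand cannot be resolved from the labels alone.
_PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: Harmonization flags. Every input variant receives exactly one.
FLAG_ALIGNED = "aligned"
FLAG_FLIPPED = "flipped"
FLAG_PALINDROMIC_DROPPED = "palindromic_dropped"
FLAG_ABSENT_DROPPED = "absent_dropped"
FLAG_INCOMPATIBLE_DROPPED = "incompatible_dropped"
FLAG_PROXY_USED = "proxy_used"

RETAINED_FLAGS = frozenset({FLAG_ALIGNED, FLAG_FLIPPED, FLAG_PROXY_USED})


class InputError(ValueError):
    """Raised for unusable input files (empty, missing mandatory columns)."""


@dataclass
class SummaryDataset:
    """Per-variant GWAS association records for a single trait.

    Parameters
    ----------
    trait_name : str
        Human-readable trait label.
    trait_type : {"binary", "continuous"}
        Scale of ``beta``: log-odds for binary traits, SD units otherwise.
    table : pandas.DataFrame
        Validated records in :data:`SUMMARY_COLUMNS` order, one row per
        variant, ``variant_id`` unique.
    qc : dict
        Tally of rows dropped during validation, keyed by reason.
    """

    trait_name: str
    trait_type: str
    table: pd.DataFrame
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary|continuous, got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @property
    def _index(self) -> pd.Index:
        return pd.Index(self.table["variant_id"])

    def loc(self, variant_ids) -> pd.DataFrame:
        """Rows for the given variant ids, in the given order."""
        sub = self.table.set_index("variant_id").loc[list(variant_ids)]
        return sub.reset_index()

    def record(self, variant_id: str) -> pd.Series:
        pos = self._index.get_loc(variant_id)
        return self.table.iloc[pos]

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def median_n(self) -> float:
        return float(self.table["n"].median())

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        trait_name: str,
        trait_type: str,
        validate: bool = True,
    ) -> "SummaryDataset":
        """Build a dataset from an in-memory frame, applying row-level QC."""
        frame = frame.copy()
        missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
        if missing:
            raise InputError(f"missing mandatory column(s): {missing}")
        frame = frame[SUMMARY_COLUMNS]
        if not validate:
            return cls(trait_name, trait_type, frame.reset_index(drop=True), {})
        table, qc = _validate_rows(frame)
        return cls(trait_name, trait_type, table, qc)


def _validate_rows(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Vectorized row validation. Returns (clean table, drop tally)."""
    qc: dict[str, int] = {}
    f = frame.copy()
    f["variant_id"] = f["variant_id"].astype("string")
    f["chrom"] = f["chrom"].astype("string")
    for col in ("effect_allele", "other_allele"):
        f[col] = f[col].astype("string").str.upper()
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        f[col] = pd.to_numeric(f[col], errors="coerce")

    checks = [
        ("dropped_missing_id", lambda t: t["variant_id"].isna() | (t["variant_id"].str.len() == 0)),
        (
            "dropped_alleles",
            lambda t: ~t["effect_allele"].isin(_VALID_ALLELES)
            | ~t["other_allele"].isin(_VALID_ALLELES)
            | (t["effect_allele"] == t["other_allele"]),
        ),
        ("dropped_beta", lambda t: t["beta"].isna()),
        ("dropped_se", lambda t: ~(t["se"] > 0)),
        ("dropped_pvalue", lambda t: ~((t["pvalue"] > 0) & (t["pvalue"] <= 1))),
        ("dropped_n", lambda t: ~(t["n"] > 0)),
        ("dropped_pos", lambda t: ~(t["pos"] >= 1)),
        # eaf may be missing; when present it must lie strictly inside (0, 1)
        ("dropped_eaf", lambda t: t["eaf"].notna() & ~((t["eaf"] > 0) & (t["eaf"] < 1))),
        ("dropped_duplicate_id", lambda t: t["variant_id"].duplicated(keep="first")),
    ]
    for reason, rule in checks:
        mask = rule(f).fillna(True) if reason != "dropped_eaf" else rule(f)
        n = int(mask.sum())
        if n:
            qc[reason] = n
            f = f.loc[~mask]

    out = f.reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    return out, qc


def read_summary(
    path,
    trait_type: str,
    trait_name: str | None = None,
    column_map: dict | None = None,
    sep: str = "\t",
) -> SummaryDataset:
    """Read a delimited summary-statistics file into a validated dataset.

    ``column_map`` maps file header names onto canonical names, e.g.
    ``{"rsid": "variant_id", "p": "pvalue"}``.  Rows violating record
    invariants are dropped and tallied in the returned dataset's ``qc``.
    """
    try:
        raw = pd.read_csv(path, sep=sep, dtype={"chrom": str}, na_values=["NA"])
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty summary-statistics file: {path}") from exc
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in SUMMARY_COLUMNS if c not in raw.columns]
    if missing:
        raise InputError(
            f"missing mandatory column(s) {missing} in {path}; have {list(raw.columns)}"
        )
    name = trait_name if trait_name is not None else str(path)
    return SummaryDataset.from_frame(raw, name, trait_type)


def write_summary(dataset: SummaryDataset, path, sep: str = "\t") -> None:
    """Write a dataset as tab-separated text; missing values become ``NA``.

    Round-trip contract: ``read_summary(write_summary(d))`` reproduces the
    records exactly (trait metadata travels out of band).
    """
    out = dataset.table.copy()
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizedSet:
    """Variants aligned across exposure(s) and outcome.

    ``beta_x``/``se_x``/``n_x`` have one column per exposure; harmonization
    orients every dataset's effect to the first exposure's effect allele.
    ``flags`` records the outcome of harmonization for *every* input variant,
    retained or dropped, in input order.
    """

    variant_ids: list
    beta_x: np.ndarray  # (k, m)
    se_x: np.ndarray  # (k, m)
    beta_y: np.ndarray  # (k,)
    se_y: np.ndarray  # (k,)
    eaf: np.ndarray  # (k,) aligned to the first exposure's effect allele
    n_x: np.ndarray  # (k, m)
    n_y: np.ndarray  # (k,)
    flags: dict  # variant_id -> flag, covering all input ids
    exposure_names: list = field(default_factory=list)
    outcome_name: str = ""

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        if self.beta_x.shape[0] == 1 and len(self.variant_ids) != 1:
            self.beta_x = self.beta_x.T
        self.se_x = np.asarray(self.se_x, dtype=float).reshape(self.beta_x.shape)
        self.n_x = np.asarray(self.n_x, dtype=float).reshape(self.beta_x.shape)
        for name in ("beta_y", "se_y", "eaf", "n_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        k = len(self.variant_ids)
        if not (
            self.beta_x.shape[0] == k == self.beta_y.size == self.se_y.size == self.eaf.size
        ):
            raise ValueError("harmonized vectors must share one length and order")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_x.shape[1]

    def subset(self, keep) -> "HarmonizedSet":
        """New set restricted to positions/ids in ``keep`` (order preserved)."""
        if len(keep) and isinstance(next(iter(keep)), str):
            wanted = set(keep)
            idx = [i for i, v in enumerate(self.variant_ids) if v in wanted]
        else:
            idx = list(keep)
        return HarmonizedSet(
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_x=self.beta_x[idx],
            se_x=self.se_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            eaf=self.eaf[idx],
            n_x=self.n_x[idx],
            n_y=self.n_y[idx],
            flags=dict(self.flags),
            exposure_names=list(self.exposure_names),
            outcome_name=self.outcome_name,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-variant table (one exposure column pair per exposure)."""
        data = {"variant_id": self.variant_ids}
        names = self.exposure_names or [f"x{i + 1}" for i in range(self.n_exposures)]
        for j, nm in enumerate(names):
            data[f"beta_{nm}"] = self.beta_x[:, j]
            data[f"se_{nm}"] = self.se_x[:, j]
        data["beta_y"] = self.beta_y
        data["se_y"] = self.se_y
        data["eaf"] = self.eaf
        return pd.DataFrame(data)


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in _PALINDROMIC_PAIRS


def _orientation(
    ref_ea: str,
    ref_oa: str,
    ea: str,
    oa: str,
    allow_complement: bool = True,
) -> int | None:
    """Sign relating another dataset's effect to the reference orientation.

    +1: same effect allele (directly or via strand complement); -1: alleles
    swapped; None: no orientation reconciles the pairs.
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return 1
    if (ea, oa) == (ref_oa, ref_ea):
        return -1
    if allow_complement:
        cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if (cea, coa) == (ref_ea, ref_oa):
            return 1
        if (cea, coa) == (ref_oa, ref_ea):
            return -1
    return None


def harmonize(
    exposures,
    outcome: SummaryDataset,
    variant_ids,
    palindrome_eaf_window: tuple = (0.42, 0.58),
    allow_complement: bool = True,
) -> HarmonizedSet:
    """Align effect estimates across exposure(s) and outcome.

    For each variant the first exposure defines the reference effect allele.
    Other datasets are oriented by allele-label match, swap, or strand
    complement; a swap negates the beta and complements the frequency.
    Palindromic variants (A/T or C/G) are oriented by which side of 0.5 the
    allele frequencies fall on, and are dropped whenever any dataset's
    frequency lies inside ``palindrome_eaf_window`` or is missing (strand
    unresolvable).  Variants absent from the outcome are dropped with flag
    ``absent_dropped`` (proxy substitution is a separate operation).
    """
    if isinstance(exposures, SummaryDataset):
        exposures = [exposures]
    lo, hi = palindrome_eaf_window
    ref = exposures[0]
    others = list(exposures[1:])

    flags: dict[str, str] = {}
    rows: list[dict] = []

    ref_tab = ref.table.set_index("variant_id")
    other_tabs = [d.table.set_index("variant_id") for d in others]
    out_tab = outcome.table.set_index("variant_id")

    for vid in variant_ids:
        if vid not in ref_tab.index:
            raise KeyError(f"variant {vid!r} absent from the first exposure")
        r = ref_tab.loc[vid]
        ea0, oa0 = r["effect_allele"], r["other_allele"]
        eaf0 = r["eaf"]
        palindromic = _is_palindromic(ea0, oa0)

        partner_rows = []
        absent = False
        for tab in other_tabs + [out_tab]:
            if vid not in tab.index:
                absent = True
                break
            partner_rows.append(tab.loc[vid])
        if absent:
            flags[vid] = FLAG_ABSENT_DROPPED
            continue

        if palindromic:
            eafs = [eaf0] + [p["eaf"] for p in partner_rows]
            intermediate = any(
                pd.isna(e) or (lo < float(e) < hi) for e in eafs
            )
            if intermediate:
                flags[vid] = FLAG_PALINDROMIC_DROPPED
                continue

        signs = []
        ok = True
        for p in partner_rows:
            s = _orientation(ea0, oa0, p["effect_allele"], p["other_allele"], allow_complement)
            if s is None:
                ok = False
                break
            if palindromic:
                # labels cannot distinguish strands; resolve by frequency side
                eaf_eff = p["eaf"] if s == 1 else 1.0 - float(p["eaf"])
                if (float(eaf0) - 0.5) * (float(eaf_eff) - 0.5) < 0:
                    s = -s
            signs.append(s)
        if not ok:
            flags[vid] = FLAG_INCOMPATIBLE_DROPPED
            continue

        flags[vid] = FLAG_ALIGNED if all(s == 1 for s in signs) else FLAG_FLIPPED
        x_betas = [float(r["beta"])]
        x_ses = [float(r["se"])]
        x_ns = [float(r["n"])]
        for p, s in zip(partner_rows[:-1], signs[:-1]):
            x_betas.append(s * float(p["beta"]))
            x_ses.append(float(p["se"]))
            x_ns.append(float(p["n"]))
        yrow, ysign = partner_rows[-1], signs[-1]
        rows.append(
            dict(
                variant_id=vid,
                beta_x=x_betas,
                se_x=x_ses,
                n_x=x_ns,
                beta_y=ysign * float(yrow["beta"]),
                se_y=float(yrow["se"]),
                n_y=float(yrow["n"]),
                eaf=float(eaf0) if pd.notna(eaf0) else np.nan,
            )
        )

    k = len(rows)
    m = 1 + len(others)
    return HarmonizedSet(
        variant_ids=[row["variant_id"] for row in rows],
        beta_x=np.array([row["beta_x"] for row in rows], dtype=float).reshape(k, m),
        se_x=np.array([row["se_x"] for row in rows], dtype=float).reshape(k, m),
        beta_y=np.array([row["beta_y"] for row in rows], dtype=float),
        se_y=np.array([row["se_y"] for row in rows], dtype=float),
        eaf=np.array([row["eaf"] for row in rows], dtype=float),
        n_x=np.array([row["n_x"] for row in rows], dtype=float).reshape(k, m),
        n_y=np.array([row["n_y"] for row in rows], dtype=float),
        flags=flags,
        exposure_names=[d.trait_name for d in exposures],
        outcome_name=outcome.trait_name,
    )
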