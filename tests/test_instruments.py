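"""Instrument QC cascade: p-filter, clumping, MAF, F, Steiger, proxies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrpath import SimulationConfig, simulate_pair
from mrpath.gwas_io import HarmonizedSet
from mrpath.instruments import (
    EmptyInstrumentSetError,
    InstrumentConfig,
    LDTable,
    ProxyTable,
    clump,
    f_statistic,
    filter_maf,
    filter_pvalue,
    select_instruments,
    steiger_filter,
    substitute_proxies,
)

from conftest import make_dataset


class TestPvalueFilter:
    def test_strict_inequality(self):
        ds = make_dataset([{"pvalue": 1e-9}, {"pvalue": 1e-7}, {"pvalue": 1e-8}])
        assert filter_pvalue(ds, 5e-8) == ["rs1", "rs3"]

    def test_all_null_gives_empty(self):
        ds = make_dataset([{"pvalue": 0.5}] * 4)
        assert filter_pvalue(ds, 5e-8) == []

    def test_null_genome_retains_almost_nothing(self):
        """Under uniform p, 10,000 null variants yield ~0.0005 expected hits."""
        rng = np.random.default_rng(0)
        ds = make_dataset([{"pvalue": p} for p in rng.uniform(size=10_000)])
        assert len(filter_pvalue(ds, 5e-8)) == 0


def _brute_force_clump_check(dataset, accepted, candidates, ld, r2_max, window_kb):
    """Check the greedy-clump definition exhaustively."""
    info = dataset.loc(candidates).set_index("variant_id")

    def conflicts(a, b):
        if info.loc[a, "chrom"] != info.loc[b, "chrom"]:
            return False
        if abs(info.loc[a, "pos"] - info.loc[b, "pos"]) > window_kb * 1000:
            return False
        return ld.r2(a, b) > r2_max

    acc = set(accepted)
    for a in accepted:
        for b in accepted:
            if a != b:
                assert not conflicts(a, b), "retained pair violates the rule"
    order = info.sort_values(["pvalue", "chrom", "pos"]).index
    for v in order:
        if v not in acc:
            better = [a for a in accepted if info.loc[a, "pvalue"] <= info.loc[v, "pvalue"]]
            assert any(conflicts(v, a) for a in better), "dropped variant conflicts with nobody"


class TestClump:
    def test_dominant_pair_keeps_smaller_pvalue(self):
        ds = make_dataset(
            [
                {"pvalue": 1e-10, "pos": 1000},
                {"pvalue": 1e-9, "pos": 6000},
            ]
        )
        ld = LDTable(pd.DataFrame(
            [("rs1", "rs2", 0.9)], columns=["variant_id_a", "variant_id_b", "r2"]
        ))
        assert clump(ds, ["rs1", "rs2"], ld) == ["rs1"]

    def test_different_chromosomes_both_survive(self):
        ds = make_dataset(
            [{"chrom": "1", "pos": 1000}, {"chrom": "2", "pos": 1000}]
        )
        assert clump(ds, ["rs1", "rs2"], None) == ["rs1", "rs2"]

    def test_matches_brute_force_oracle_on_20_variants(self):
        rng = np.random.default_rng(42)
        rows = [
            {
                "pvalue": float(rng.uniform(1e-12, 1e-6)),
                "chrom": str(rng.integers(1, 4)),
                "pos": int(rng.integers(1, 30_000_000)),
            }
            for _ in range(20)
        ]
        ds = make_dataset(rows)
        ids = ds.variant_ids
        pair_rows = []
        for i in range(20):
            for j in range(i + 1, 20):
                if rng.random() < 0.3:
                    pair_rows.append((ids[i], ids[j], float(rng.uniform(0, 1))))
        ld = LDTable(pd.DataFrame(pair_rows, columns=["variant_id_a", "variant_id_b", "r2"]))
        accepted = clump(ds, ids, ld, r2_max=0.001, window_kb=10_000)
        _brute_force_clump_check(ds, accepted, ids, ld, 0.001, 10_000)

    def test_invariant_to_candidate_ordering(self):
        rng = np.random.default_rng(3)
        rows = [
            {"pvalue": float(rng.uniform(1e-12, 1e-6)), "pos": int(rng.integers(1, 5_000_000))}
            for _ in range(10)
        ]
        ds = make_dataset(rows)
        ids = ds.variant_ids
        pair_rows = [(ids[i], ids[j], 0.5) for i in range(10) for j in range(i + 1, 10)
                     if rng.random() < 0.5]
        ld = LDTable(pd.DataFrame(pair_rows, columns=["variant_id_a", "variant_id_b", "r2"]))
        base = clump(ds, ids, ld)
        shuffled = list(ids)
        rng.shuffle(shuffled)
        assert clump(ds, shuffled, ld) == base

    def test_empty_ld_with_error_policy_fails(self):
        ds = make_dataset([{}])
        with pytest.raises(ValueError, match="missing_ld"):
            clump(ds, ["rs1"], None, missing_ld="error")


class TestMafFilter:
    @pytest.mark.parametrize(
        "eaf,kept",
        [(0.995, False), (0.0100, False), (0.30, True), (0.011, True)],
    )
    def test_complement_and_boundary(self, eaf, kept):
        ds = make_dataset([{"eaf": eaf}])
        result = filter_maf(ds, ["rs1"], 0.01)
        assert (result == ["rs1"]) is kept

    def test_missing_eaf_policy(self):
        ds = make_dataset([{"eaf": np.nan}])
        assert filter_maf(ds, ["rs1"], 0.01, missing="drop") == []
        assert filter_maf(ds, ["rs1"], 0.01, missing="keep") == ["rs1"]


class TestFStatistic:
    def test_closed_form(self):
        assert f_statistic(0.032, 0.010) == pytest.approx(10.24)
        assert f_statistic(0.030, 0.010) == pytest.approx(9.0)

    def test_se_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        beta=st.floats(-5, 5, allow_nan=False),
        se=st.floats(1e-6, 10, allow_nan=False),
    )
    def test_equals_squared_z_score(self, beta, se):
        assert f_statistic(beta, se) == pytest.approx((beta / se) ** 2, rel=1e-12)


def _steiger_set(z_x, z_y, n=100_000):
    k = len(z_x)
    se = 0.01
    return HarmonizedSet(
        variant_ids=[f"rs{i}" for i in range(k)],
        beta_x=np.asarray(z_x) * se,
        se_x=np.full(k, se),
        beta_y=np.asarray(z_y) * se,
        se_y=np.full(k, se),
        eaf=np.full(k, 0.3),
        n_x=np.full(k, float(n)),
        n_y=np.full(k, float(n)),
        flags={},
    )


class TestSteiger:
    def test_dominant_exposure_signal_retained(self):
        h = _steiger_set([6.0], [2.0])
        kept, rep = steiger_filter(h)
        assert kept == ["rs0"]
        assert bool(rep["direction_ok"].iloc[0])

    def test_mirror_case_dropped(self):
        h = _steiger_set([2.0], [6.0])
        kept, rep = steiger_filter(h)
        assert kept == []
        assert not bool(rep["direction_ok"].iloc[0])

    def test_exact_tie_dropped_with_p_one(self):
        h = _steiger_set([4.0], [4.0])
        kept, rep = steiger_filter(h)
        assert kept == []
        assert rep["steiger_p"].iloc[0] == pytest.approx(1.0)

    def test_exclude_significant_wrong_mode_keeps_ambiguous(self):
        h = _steiger_set([2.0, 4.0], [2.5, 40.0])
        kept, _ = steiger_filter(h, mode="exclude_significant_wrong")
        # rs0: wrong direction but not significantly so -> kept;
        # rs1: significantly wrong -> dropped
        assert kept == ["rs0"]

    def test_small_sample_sizes_rejected(self):
        h = _steiger_set([4.0], [1.0], n=3)
        with pytest.raises(ValueError):
            steiger_filter(h)

    def test_commutes_with_variant_relabeling(self):
        h = _steiger_set([6.0, 5.0, 2.0], [1.0, 1.5, 6.0])
        relabeled = _steiger_set([6.0, 5.0, 2.0], [1.0, 1.5, 6.0])
        relabeled.variant_ids = ["a", "b", "c"]
        kept1, _ = steiger_filter(h)
        kept2, _ = steiger_filter(relabeled)
        mapping = dict(zip(h.variant_ids, relabeled.variant_ids))
        assert [mapping[v] for v in kept1] == kept2


class TestProxies:
    def _proxy_table(self):
        return ProxyTable(
            pd.DataFrame(
                [
                    ("rs1", "rs_p95", 0.95, "A", "G"),
                    ("rs1", "rs_p85", 0.85, "A", "G"),
                ],
                columns=ProxyTable.COLUMNS,
            )
        )

    def test_highest_r2_proxy_wins(self):
        outcome = make_dataset([{}, {}], name="out")
        outcome.table.loc[0, "variant_id"] = "rs_p95"
        outcome.table.loc[1, "variant_id"] = "rs_p85"
        plan = substitute_proxies(["rs1"], self._proxy_table(), outcome)
        assert plan.loc[0, "proxy_id"] == "rs_p95"
        assert bool(plan.loc[0, "resolved"])

    def test_low_r2_rows_rejected_at_load(self):
        with pytest.raises(ValueError, match="r2"):
            ProxyTable(
                pd.DataFrame([("rs1", "rs2", 0.7, "A", "G")], columns=ProxyTable.COLUMNS)
            )

    def test_unresolvable_id_reported_not_fatal(self):
        outcome = make_dataset([{}], name="out")
        plan = substitute_proxies(["rs_missing"], self._proxy_table(), outcome)
        assert not bool(plan.loc[0, "resolved"])

    def test_swapped_proxy_alleles_flip_effect(self):
        outcome = make_dataset(
            [{"effect_allele": "G", "other_allele": "A", "beta": 0.2}], name="out"
        )
        outcome.table.loc[0, "variant_id"] = "rs_p95"
        plan = substitute_proxies(["rs1"], self._proxy_table(), outcome)
        assert plan.loc[0, "beta"] == pytest.approx(-0.2)


class TestSelectInstruments:
    def test_planted_instruments_all_survive(self, sim_pair):
        """A scenario built to plant 36 strong independent instruments."""
        ex, out, truth = sim_pair
        instruments, h = select_instruments(ex, out)
        assert len(instruments.variant_ids) == 36
        assert set(instruments.variant_ids) == set(truth.instrument_ids)
        assert instruments.mean_f >= 10
        assert (instruments.f_stats >= 10).all()
        att = instruments.attrition
        assert (att["n_in"] - att["n_dropped"] == att["n_out"]).all()

    def test_pass_through_config_retains_everything(self, sim_pair):
        ex, out, _ = sim_pair
        cfg = InstrumentConfig(
            p_threshold=1.0, maf_min=0.0, f_min=0.0,
            steiger_mode="exclude_significant_wrong", steiger_alpha=0.0,
            palindrome_eaf_window=(0.5, 0.5),
        )
        instruments, _ = select_instruments(ex, out, config=cfg)
        att = instruments.attrition.set_index("stage")
        assert len(instruments.variant_ids) == len(ex)
        assert (att["n_dropped"] == 0).all()

    def test_weak_instrument_dropped_exactly_at_f_stage(self):
        rows = [{"beta": 0.06, "se": 0.005, "pvalue": 1e-3} for _ in range(5)]
        rows.append({"beta": 0.01, "se": 0.005, "pvalue": 1e-3})  # F = 4
        ex = make_dataset(rows, name="exp")
        out = make_dataset([{"beta": 0.0, "se": 0.005, "pvalue": 0.5}] * 6, name="out")
        cfg = InstrumentConfig(p_threshold=0.05,
                               steiger_mode="exclude_significant_wrong",
                               steiger_alpha=0.0)
        instruments, _ = select_instruments(ex, out, config=cfg)
        att = instruments.attrition.set_index("stage")
        assert att.loc["f_statistic", "n_dropped"] == 1
        assert len(instruments.variant_ids) == 5

    def test_exhausted_stage_named_in_error(self, sim_pair):
        ex, out, _ = sim_pair
        cfg = InstrumentConfig(f_min=1e6)
        with pytest.raises(EmptyInstrumentSetError, match="f_statistic"):
            select_instruments(ex, out, config=cfg)
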