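"""Univariable MR estimators: Wald ratio, IVW, Egger, median, modes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrpath import SimulationConfig, simulate_pair
from mrpath.estimators import (
    DegenerateDesignError,
    EggerEstimator,
    IVWEstimator,
    ModeEstimator,
    WeightedMedianEstimator,
    weighted_median,
)
from mrpath.gwas_io import HarmonizedSet
from mrpath.simulate import harmonized_from_truth
from mrpath.univariable import (
    beta_to_or,
    ivw,
    mode_estimate,
    mr_egger,
    run_all,
    wald_ratio,
    weighted_median_mr,
)


def hset(beta_x, beta_y, se_y, se_x=None, n=200_000):
    beta_x = np.asarray(beta_x, float)
    k = beta_x.size
    return HarmonizedSet(
        variant_ids=[f"rs{i}" for i in range(k)],
        beta_x=beta_x,
        se_x=np.full(k, 0.01) if se_x is None else np.asarray(se_x, float),
        beta_y=np.asarray(beta_y, float),
        se_y=np.asarray(se_y, float),
        eaf=np.full(k, 0.3),
        n_x=np.full(k, float(n)),
        n_y=np.full(k, float(n)),
        flags={},
    )


class TestWaldRatio:
    def test_closed_form(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.ci_low == pytest.approx(0.5 - 1.96 * 0.2, abs=1e-3)

    def test_null_numerator(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert est.beta == 0.0
        assert est.pvalue == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    @settings(max_examples=50, deadline=None)
    @given(
        bx=st.floats(0.01, 1), bys=st.floats(-1, 1),
        sx=st.floats(1e-4, 0.5), sy=st.floats(1e-4, 0.5),
    )
    def test_second_order_se_never_smaller(self, bx, bys, sx, sy):
        first = wald_ratio(bx, sx, bys, sy).se
        second = wald_ratio(bx, sx, bys, sy, second_order=True).se
        assert second >= first


class TestIVW:
    def test_single_snv_reduces_to_wald_ratio(self):
        h = hset([0.1], [0.05], [0.02])
        est = ivw(h)
        ref = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_two_equal_snvs_average_the_ratios(self):
        h = hset([0.1, 0.1], [0.05, 0.07], [0.02, 0.02])
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(np.mean([0.5, 0.7]))

    def test_regression_equals_weighted_mean_of_ratios(self, sim_harmonized):
        """Two independent algebraic routes must agree to 1e-10."""
        h = sim_harmonized
        est = ivw(h, model="fixed")
        w = h.beta_x[:, 0] ** 2 / h.se_y**2
        r = h.beta_y / h.beta_x[:, 0]
        oracle = np.sum(w * r) / np.sum(w)
        assert est.beta == pytest.approx(oracle, abs=1e-10)
        assert est.se == pytest.approx(1 / np.sqrt(np.sum(w)), abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, sim_harmonized):
        fixed = ivw(sim_harmonized, model="fixed")
        random = ivw(sim_harmonized, model="random")
        assert random.se >= fixed.se
        assert random.beta == pytest.approx(fixed.beta)

    def test_recovers_planted_effect_across_reps(self):
        """50 instruments, no pleiotropy: mean IVW within 3 MC SEs of truth."""
        cfg = SimulationConfig(n_snv=50, n_null_snv=0)
        theta = cfg.theta_total
        est = []
        for s in range(150):
            ex, out, tr = simulate_pair(cfg, seed=3000 + s)
            est.append(ivw(harmonized_from_truth(ex, out, tr.instrument_ids)).beta)
        est = np.array(est)
        assert abs(est.mean() - theta) < 3 * est.std() / np.sqrt(est.size)

    def test_all_zero_exposure_effects_rejected(self):
        h = hset([0.0, 0.0], [0.05, 0.02], [0.02, 0.02])
        with pytest.raises(DegenerateDesignError):
            IVWEstimator().fit(h.beta_x, h.beta_y, se_y=h.se_y)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 10.0])
    def test_exposure_rescaling_equivariance(self, sim_harmonized, scale):
        h = sim_harmonized
        base = ivw(h).beta
        scaled = IVWEstimator().fit(h.beta_x * scale, h.beta_y, se_y=h.se_y)
        assert scaled.coef_[0] == pytest.approx(base / scale)


class TestEgger:
    def test_nested_in_ivw_when_intercept_is_zero(self):
        """Zero-pleiotropy data: Egger slope ~ IVW slope within sim error."""
        cfg = SimulationConfig(n_snv=50, n_null_snv=0)
        diffs = []
        for s in range(60):
            ex, out, tr = simulate_pair(cfg, seed=5000 + s)
            h = harmonized_from_truth(ex, out, tr.instrument_ids)
            diffs.append(mr_egger(h).beta - ivw(h).beta)
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 1e-3

    def test_constant_exposure_effects_degenerate(self):
        h = hset([0.1, 0.1, 0.1], [0.04, 0.05, 0.06], [0.02] * 3)
        with pytest.raises(DegenerateDesignError):
            mr_egger(h)

    def test_recovers_planted_directional_pleiotropy(self):
        cfg = SimulationConfig(n_snv=50, n_null_snv=0, pleiotropy=(1.0, 0.02, 0.005))
        intercepts = []
        for s in range(100):
            ex, out, tr = simulate_pair(cfg, seed=7000 + s)
            h = harmonized_from_truth(ex, out, tr.instrument_ids)
            intercepts.append(mr_egger(h).extras["intercept"])
        assert np.mean(intercepts) == pytest.approx(0.02, abs=0.002)

    def test_orientation_rederived_internally(self, sim_harmonized):
        h = sim_harmonized
        base = mr_egger(h)
        flipped = EggerEstimator().fit(-h.beta_x, -h.beta_y, se_y=h.se_y)
        assert flipped.coef_[0] == pytest.approx(base.beta)
        assert flipped.intercept_ == pytest.approx(base.extras["intercept"])


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        assert weighted_median([0.2, 0.5, 0.9], [1, 1, 1]) == pytest.approx(0.5)

    def test_interpolation_matches_direct_formula(self):
        ratios = np.array([0.2, 0.5, 0.9])
        weights = np.array([0.6, 0.2, 0.2])
        # brute-force evaluation of the cumulative-weight definition
        order = np.argsort(ratios)
        v, w = ratios[order], weights[order] / weights.sum()
        s = np.cumsum(w) - w / 2
        expected = np.interp(0.5, s, v)
        assert weighted_median(ratios, weights) == pytest.approx(expected)
        # with 60% of weight on the smallest ratio the estimate leans low
        assert weighted_median(ratios, weights) < 0.5

    def test_all_equal_weights_odd_k_is_sample_median(self):
        rng = np.random.default_rng(1)
        ratios = rng.normal(size=9)
        assert weighted_median(ratios, np.ones(9)) == pytest.approx(np.median(ratios))

    def test_robust_to_forty_percent_invalid(self):
        """Directional pleiotropy on 40% of instruments: median beats IVW."""
        cfg = SimulationConfig(n_snv=50, n_null_snv=0, pleiotropy=(0.4, 0.02, 0.005))
        theta = cfg.theta_total
        b_ivw, b_med = [], []
        for s in range(100):
            ex, out, tr = simulate_pair(cfg, seed=9000 + s)
            h = harmonized_from_truth(ex, out, tr.instrument_ids)
            b_ivw.append(ivw(h).beta)
            b_med.append(
                WeightedMedianEstimator._point(h.beta_x[:, 0], h.beta_y, h.se_y)
            )
        assert abs(np.mean(b_med) - theta) < abs(np.mean(b_ivw) - theta)

    def test_bootstrap_se_deterministic_under_seed(self, sim_harmonized):
        a = weighted_median_mr(sim_harmonized, n_boot=200, seed=5)
        b = weighted_median_mr(sim_harmonized, n_boot=200, seed=5)
        assert a.se == b.se


class TestModes:
    def test_majority_cluster_ignores_outlier(self):
        h = hset([0.1] * 4, [0.05, 0.05, 0.05, 0.5], [0.02] * 4)
        est = mode_estimate(h, kind="simple", n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_symmetric_bimodal_breaks_tie_low_with_warning(self):
        h = hset([0.1] * 4, [0.02, 0.02, 0.08, 0.08], [0.02] * 4)
        with pytest.warns(UserWarning, match="tie"):
            est = mode_estimate(h, kind="simple", n_boot=10, seed=0)
        assert est.beta < 0.5  # lower mode chosen

    def test_grid_argmax_matches_fine_scan(self, sim_harmonized):
        h = sim_harmonized
        m = ModeEstimator(kind="weighted")
        est = m._point(h.beta_x[:, 0], h.beta_y, h.se_y)
        ratios = h.beta_y / h.beta_x[:, 0]
        w = h.beta_x[:, 0] ** 2 / h.se_y**2
        w = w / w.sum()
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        bw = 0.9 * min(sd, iqr / 1.349) * ratios.size ** -0.2
        fine = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 20_001)
        dens = np.sum(
            w[:, None] * np.exp(-0.5 * ((fine[None] - ratios[:, None]) / bw) ** 2), axis=0
        )
        grid_step = (ratios.max() - ratios.min() + 6 * bw) / 511
        assert abs(est - fine[np.argmax(dens)]) <= grid_step

    def test_zero_bandwidth_factor_rejected(self, sim_harmonized):
        with pytest.raises(ValueError, match="phi"):
            mode_estimate(sim_harmonized, phi=0.0, n_boot=10, seed=0)


class TestRunAll:
    def test_single_instrument_only_wald(self):
        h = hset([0.1], [0.05], [0.02])
        res = run_all(h)
        assert list(res.estimates) == ["wald_ratio"]

    def test_five_methods_reported_with_diagnostics(self, sim_harmonized):
        res = run_all(sim_harmonized, n_boot=50, seed=2)
        assert set(res.estimates) == {
            "ivw", "mr_egger", "weighted_median", "weighted_mode", "simple_mode"
        }
        assert res.diagnostics is not None
        assert res.diagnostics.loo_table.shape[0] == sim_harmonized.k

    def test_protective_effect_sign_consistent_across_methods(self):
        """All five point estimates negative in >= 95% of replicates."""
        cfg = SimulationConfig(n_snv=36, n_null_snv=0, f_true_range=(600.0, 6000.0))
        wmode, smode = ModeEstimator(kind="weighted"), ModeEstimator(kind="simple")
        all_negative = 0
        n_reps = 200
        for s in range(n_reps):
            ex, out, tr = simulate_pair(cfg, seed=90_000 + s)
            h = harmonized_from_truth(ex, out, tr.instrument_ids)
            bx, by, sy = h.beta_x[:, 0], h.beta_y, h.se_y
            points = [
                ivw(h).beta,
                EggerEstimator().fit(bx, by, se_y=sy).coef_[0],
                WeightedMedianEstimator._point(bx, by, sy),
                wmode._point(bx, by, sy),
                smode._point(bx, by, sy),
            ]
            all_negative += all(p < 0 for p in points)
        assert all_negative / n_reps >= 0.95

    def test_reproducible_bootstrap_with_seed(self, sim_harmonized):
        r1 = run_all(sim_harmonized, n_boot=100, seed=42)
        r2 = run_all(sim_harmonized, n_boot=100, seed=42)
        for m in r1.estimates:
            assert r1.estimates[m].se == r2.estimates[m].se


class TestBetaToOr:
    @pytest.mark.parametrize(
        "beta,expected",
        [(-0.075, 0.928), (-0.073, 0.930), (0.145, 1.156), (0.115, 1.122),
         (0.183, 1.201), (0.0, 1.0)],
    )
    def test_reference_conversions(self, beta, expected):
        or_, _, _ = beta_to_or(beta, 0.01)
        assert round(or_, 3) == expected

    def test_interval_is_exponentiated_wald(self):
        or_, lo, hi = beta_to_or(0.1, 0.05)
        assert lo == pytest.approx(np.exp(0.1 - 1.959964 * 0.05))
        assert hi == pytest.approx(np.exp(0.1 + 1.959964 * 0.05))
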