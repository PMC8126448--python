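"""Moderated paired differential expression: formula oracles and properties."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metabodnm import diffexpr
from metabodnm.diffexpr import (
    ModerationPrior,
    bh_adjust,
    classify_and_summarize,
    estimate_prior,
    moderated_paired_test,
    paired_differences,
    run_diffexpr,
    volcano_table,
)
from metabodnm.exceptions import DegenerateDataError
from metabodnm.synth import SynthConfig, generate_paired_metabolome, truth_recovery_summary
from tests.conftest import make_tensor


class TestPairedDifferences:
    def test_hand_arithmetic(self, toy_tensor):
        d = paired_differences(toy_tensor)
        np.testing.assert_allclose(d.loc["M1"], [1.0, 2.0])
        assert d.loc["M1"].mean() == pytest.approx(1.5)
        np.testing.assert_allclose(d.loc["M2"], [1.0, 1.0])  # fasted = 2 x post

    def test_identity_gives_zero(self):
        vals = np.ones((3, 4, 2)) * 7.0
        d = paired_differences(make_tensor(vals))
        assert (d.to_numpy() == 0).all()

    def test_zero_intensity_names_offender(self):
        vals = np.ones((2, 2, 2))
        vals[1, 0, 1] = 0.0
        with pytest.raises(ValueError, match="M2"):
            paired_differences(make_tensor(vals))


class TestPrior:
    def test_recovers_scaled_inv_chi2_parameters(self):
        rng = np.random.default_rng(42)
        d0, s0_sq, dg = 4.0, 0.5, 7
        n = 10_000
        true_var = d0 * s0_sq / rng.chisquare(d0, size=n)
        s2 = true_var * rng.chisquare(dg, size=n) / dg
        prior = estimate_prior(s2, dg)
        assert prior.d0 == pytest.approx(d0, rel=0.10)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.05)

    def test_common_scale_recovers_mean(self):
        rng = np.random.default_rng(7)
        scale = 0.8
        s2 = scale * rng.chisquare(7, size=20_000) / 7
        prior = estimate_prior(s2, 7)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(scale, rel=0.05)

    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(100, 0.3), 7)
        assert math.isinf(prior.d0)
        assert prior.s0_sq > 0

    def test_all_zero_variances_degenerate(self):
        with pytest.raises(DegenerateDataError):
            estimate_prior(np.zeros(50), 7)


class TestModeratedTest:
    def test_d0_zero_reduces_to_classical_paired_t(self, rng):
        d = pd.DataFrame(rng.normal(0.3, 1.0, size=(40, 8)))
        res = moderated_paired_test(d, ModerationPrior(d0=1e-12, s0_sq=1.0))
        classical = stats.ttest_rel(
            d.to_numpy(), np.zeros_like(d.to_numpy()), axis=1
        )
        np.testing.assert_allclose(res["t_mod"], classical.statistic, rtol=1e-5)
        np.testing.assert_allclose(res["p"], classical.pvalue, rtol=1e-4)

    def test_posterior_variance_formula_scalar_oracle(self):
        # n = 2, d = (1, 2): lfc = 1.5, s2 = 0.5, dg = 1
        d = pd.DataFrame([[1.0, 2.0]])
        prior = ModerationPrior(d0=2.0, s0_sq=0.25)
        res = moderated_paired_test(d, prior)
        s2_post = (2.0 * 0.25 + 1.0 * 0.5) / (2.0 + 1.0)
        t_expected = 1.5 / math.sqrt(s2_post / 2)
        p_expected = 2 * stats.t.sf(abs(t_expected), 3.0)
        assert res["t_mod"].iloc[0] == pytest.approx(t_expected)
        assert res["p"].iloc[0] == pytest.approx(p_expected)

    def test_zero_lfc_gives_t_zero_p_one(self):
        d = pd.DataFrame([[-1.0, 1.0], [0.0, 0.0]])
        res = moderated_paired_test(d, ModerationPrior(d0=4.0, s0_sq=0.5))
        np.testing.assert_allclose(res["t_mod"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_infinite_d0_pools_variance(self, rng):
        d = pd.DataFrame(rng.normal(size=(20, 6)))
        prior = ModerationPrior(d0=math.inf, s0_sq=0.7)
        res = moderated_paired_test(d, prior)
        expected_t = d.mean(axis=1) / math.sqrt(0.7 / 6)
        np.testing.assert_allclose(res["t_mod"], expected_t)

    def test_moderation_shrinks_between_s2_and_s0(self, rng):
        # heterogeneous true variances so the fitted prior df is finite
        scales = np.sqrt(4 * 0.5 / rng.chisquare(4, size=200))
        d = pd.DataFrame(rng.normal(size=(200, 8)) * scales[:, None])
        s2 = d.var(axis=1, ddof=1).to_numpy()
        prior = estimate_prior(s2, 7)
        assert math.isfinite(prior.d0)
        res = moderated_paired_test(d, prior)
        dg = 7.0
        s2_post = (prior.d0 * prior.s0_sq + dg * s2) / (prior.d0 + dg)
        lo = np.minimum(s2, prior.s0_sq) - 1e-12
        hi = np.maximum(s2, prior.s0_sq) + 1e-12
        assert np.all((s2_post >= lo) & (s2_post <= hi))

    def test_t_monotone_in_lfc_at_fixed_variance(self):
        # rows with identical spread but growing mean shift
        base = np.array([-1.0, 1.0, -1.0, 1.0])
        d = pd.DataFrame([base + shift for shift in (0.0, 0.5, 1.0, 2.0)])
        res = moderated_paired_test(d, ModerationPrior(d0=3.0, s0_sq=1.0))
        t = np.abs(res["t_mod"].to_numpy())
        assert np.all(np.diff(t) > 0)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_step_up_by_hand(self, p, expected):
        np.testing.assert_allclose(bh_adjust(np.array(p)), expected)

    def test_invariants(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in the ranking
        # invariant under relabelling
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_step_up_properties_hold_for_arbitrary_p(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestClassification:
    def make_table(self, p_adj, lfc):
        return pd.DataFrame({"p_adj": p_adj, "lfc": lfc},
                            index=[f"M{i}" for i in range(len(p_adj))])

    def test_definition_and_boundary(self):
        tab = self.make_table([0.04, 0.05, 0.04], [0.3, 2.0, -0.3])
        cls = diffexpr.classify(tab)
        assert list(cls) == ["increase", "no_change", "decrease"]

    def test_counts_sum_to_total(self, default_dataset):
        tensor, _ = default_dataset
        table = run_diffexpr(tensor)
        summary = classify_and_summarize(table, tensor.annotations)
        assert summary.loc["all"].sum() == tensor.n_metabolites
        assert summary.drop("all").sum().sum() == tensor.n_metabolites

    def test_sensitivity_on_low_noise_synthetic(self):
        cfg = SynthConfig(seed=21, residual_sd=0.15, subject_effect_sd=0.5,
                          plant_dnm=False, base_within_module_correlation=0.0)
        tensor, truth = generate_paired_metabolome(cfg)
        table = run_diffexpr(tensor)
        rec = truth_recovery_summary(truth, diffexpr_table=table)
        assert rec["de_sensitivity"] >= 0.95
        assert rec["de_fdr"] <= 0.10


class TestVolcano:
    def test_count_outside_quantiles(self, rng):
        lfc = rng.normal(size=100)
        tab = pd.DataFrame({"lfc": lfc, "p_adj": rng.uniform(size=100)})
        out = volcano_table(tab)
        lo, hi = out.attrs["lfc_quantiles"]
        assert out["extreme_lfc"].sum() == ((lfc < lo) | (lfc > hi)).sum()
        assert 3 <= out["extreme_lfc"].sum() <= 6  # ~5 of 100 outside 2.5/97.5%

    def test_all_equal_lfc_labels_none(self):
        tab = pd.DataFrame({"lfc": np.ones(50), "p_adj": np.full(50, 0.5)})
        assert volcano_table(tab)["extreme_lfc"].sum() == 0

    def test_permutation_invariance(self, rng):
        lfc = rng.normal(size=60)
        tab = pd.DataFrame({"lfc": lfc, "p_adj": rng.uniform(size=60)},
                           index=[f"M{i}" for i in range(60)])
        out1 = volcano_table(tab)
        perm = rng.permutation(60)
        out2 = volcano_table(tab.iloc[perm])
        assert set(out1.index[out1.extreme_lfc]) == set(out2.index[out2.extreme_lfc])
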