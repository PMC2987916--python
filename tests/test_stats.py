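import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import covnet
from covnet import ContractError
from covnet.network import CorrelationMatrix


class TestFisherZ:
    def test_closed_form_values(self):
        assert covnet.fisher_z(0.0) == 0.0
        assert covnet.fisher_z(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-0.999, max_value=0.999))
    def test_odd_symmetry(self, r):
        assert covnet.fisher_z(-r) == pytest.approx(-covnet.fisher_z(r), abs=1e-15)

    def test_domain_error(self):
        for r in (1.0, -1.0, 1.5):
            with pytest.raises(ContractError):
                covnet.fisher_z(r)


class TestCompareEdge:
    def test_equal_correlations_give_null(self):
        z, p = covnet.compare_edge(0.3, 50, 0.3, 80)
        assert z == 0.0 and p == 1.0

    def test_closed_form_example(self):
        # z(0.5)/sqrt(1/100 + 1/100), evaluated independently
        z, p = covnet.compare_edge(0.5, 103, 0.0, 103)
        expected = (0.5 * math.log(3)) / math.sqrt(2.0 / 100.0)
        assert z == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(3.884, abs=5e-4)
        assert p == pytest.approx(2 * (1 - sps.norm.cdf(expected)), abs=1e-12)

    def test_antisymmetric_in_group_order(self):
        z1, p1 = covnet.compare_edge(0.6, 40, 0.2, 60)
        z2, p2 = covnet.compare_edge(0.2, 60, 0.6, 40)
        assert z1 == pytest.approx(-z2, abs=1e-15)
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_small_groups_rejected(self):
        with pytest.raises(ContractError):
            covnet.compare_edge(0.5, 3, 0.1, 50)

    def test_null_p_values_uniform(self):
        # bivariate-normal simulation with equal population correlation:
        # p-values must pass a KS uniformity check
        rng = np.random.default_rng(2024)
        n, rho, m = 50, 0.3, 10_000
        ps = np.empty(m)
        for arm in range(2):
            x = rng.standard_normal((m, n))
            e = rng.standard_normal((m, n))
            y = rho * x + math.sqrt(1 - rho ** 2) * e
            xc = x - x.mean(1, keepdims=True)
            yc = y - y.mean(1, keepdims=True)
            r = (xc * yc).sum(1) / np.sqrt((xc ** 2).sum(1) * (yc ** 2).sum(1))
            if arm == 0:
                r1 = r
            else:
                r2 = r
        z = (np.arctanh(r1) - np.arctanh(r2)) / math.sqrt(2.0 / (n - 3))
        ps = 2 * sps.norm.sf(np.abs(z))
        d = sps.kstest(ps, "uniform").statistic
        assert d < 1.628 / math.sqrt(m)  # 1% critical value


class TestFdrMask:
    def test_no_rejections_when_all_half(self):
        assert not covnet.fdr_mask([0.5] * 100, q=0.01).any()

    def test_single_small_p_rejected(self):
        assert covnet.fdr_mask([0.005], q=0.01).tolist() == [True]

    def test_step_up_rule_by_hand(self):
        # p sorted: thresholds k*q/m = .0125, .025, .0375, .05; p(4)=0.03<=0.05
        # so the step-up rule rejects all four
        mask = covnet.fdr_mask([0.001, 0.004, 0.019, 0.03], q=0.05)
        assert mask.tolist() == [True, True, True, True]
        # and with the last p raised, only the first two survive
        mask = covnet.fdr_mask([0.001, 0.004, 0.19, 0.3], q=0.05)
        assert mask.tolist() == [True, True, False, False]

    def test_by_variant_more_conservative(self):
        p = np.linspace(0.001, 0.04, 20)
        assert covnet.fdr_mask(p, 0.05, method="by").sum() <= covnet.fdr_mask(p, 0.05).sum()


def _corr_from_latent(latent, n, rng, atlas, label):
    w, v = np.linalg.eigh(latent)
    x = rng.standard_normal((n, latent.shape[0])) @ (v * np.sqrt(np.clip(w, 0, None))).T
    r = np.corrcoef(x, rowvar=False)
    return CorrelationMatrix(r=r, n_subjects=n, group_label=label, atlas=atlas)


class TestEdgeDifferenceMap:
    def test_self_comparison_never_significant(self, small_spec_factory):
        c = covnet.generate_cohort(small_spec_factory(seed=1), "A")
        corr = covnet.cohort_correlation(c)
        for q in (0.01, 0.05, 0.5):
            res = covnet.edge_difference_map(corr, corr, q=q)
            assert res.n_significant == 0

    def test_planted_block_recovery(self, small_atlas):
        # groups differ by +0.4 correlation inside one 4-region block only;
        # rejections should concentrate (>=80%) on the planted pairs
        rng = np.random.default_rng(33)
        base = np.eye(10) * 0.7 + 0.3  # exchangeable r=0.3
        planted = base.copy()
        blk = np.ix_(range(4), range(4))
        planted[blk] = 0.7
        np.fill_diagonal(planted, 1.0)
        planted_pairs = {(i, j) for i in range(4) for j in range(i + 1, 4)}
        hits = total = 0
        for _ in range(5):
            ca = _corr_from_latent(base, 100, rng, small_atlas, "A")
            cb = _corr_from_latent(planted, 100, rng, small_atlas, "B")
            res = covnet.edge_difference_map(ca, cb, q=0.05)
            sig = res.significant_edges()
            total += len(sig)
            hits += sum((i, j) in planted_pairs for i, j in zip(sig["i"], sig["j"]))
            assert (sig["direction"] == "increase").all()
        assert total > 0 and hits / total >= 0.8

    def test_direction_flips_with_group_order(self, small_atlas):
        rng = np.random.default_rng(44)
        base = np.eye(10) * 0.9 + 0.1
        strong = np.eye(10) * 0.3 + 0.7
        ca = _corr_from_latent(base, 150, rng, small_atlas, "A")
        cb = _corr_from_latent(strong, 150, rng, small_atlas, "B")
        fwd = covnet.edge_difference_map(ca, cb, q=0.05)
        rev = covnet.edge_difference_map(cb, ca, q=0.05)
        assert fwd.n_significant == rev.n_significant > 0
        np.testing.assert_allclose(fwd.table["p_value"], rev.table["p_value"], atol=1e-12)
        sig_f = fwd.significant_edges()
        sig_r = rev.significant_edges()
        assert (sig_f["direction"] == "increase").all()
        assert (sig_r["direction"] == "decrease").all()

    def test_mismatched_atlases_rejected(self, small_atlas):
        rng = np.random.default_rng(5)
        ca = _corr_from_latent(np.eye(10), 30, rng, small_atlas, "A")
        cb = _corr_from_latent(np.eye(6), 30, rng, covnet.reduced_atlas(3), "B")
        with pytest.raises(ContractError, match="atlas"):
            covnet.edge_difference_map(ca, cb)


class TestPermutationTest:
    def test_split_halves_of_one_cohort_not_significant(self, small_spec_factory):
        spec = small_spec_factory(seed=6, n_per_group=80)
        c = covnet.generate_cohort(spec, "A")
        rows = np.random.default_rng(7).permutation(80)
        a, b = c.subset(rows[:40], "A1"), c.subset(rows[40:], "A2")
        res = covnet.permutation_test_metrics(a, b, sparsity=0.45, n_perm=200, seed=8)
        assert not res.significant["Cp"] and not res.significant["Lp"]
        assert abs(res.observed_dCp) < 0.15
        assert res.ci_lower["Cp"] <= res.observed_dCp <= res.ci_upper["Cp"]

    def test_nc_vs_ad_preset_difference_detected_and_symmetric(self):
        # at study scale the local-up/long-range-down covariance shift of the
        # AD-like preset produces a clustering difference far outside the
        # permutation null; swapping the group order flips signs only
        spec = covnet.default_three_group_spec(seed=3)
        nc = covnet.generate_cohort(spec, "NC")
        ad = covnet.generate_cohort(spec, "AD")
        fwd = covnet.permutation_test_metrics(nc, ad, sparsity=0.15, n_perm=150, seed=10)
        rev = covnet.permutation_test_metrics(ad, nc, sparsity=0.15, n_perm=150, seed=10)
        assert fwd.significant["Cp"]
        assert fwd.observed_dCp < 0  # Cp(NC) < Cp(AD)
        assert rev.significant["Cp"] == fwd.significant["Cp"]
        assert fwd.observed_dCp == pytest.approx(-rev.observed_dCp, abs=1e-12)

    def test_small_n_perm_warns(self, small_spec_factory, caplog):
        import logging
        spec = small_spec_factory(seed=12, n_per_group=30)
        a = covnet.generate_cohort(spec, "A")
        b = covnet.generate_cohort(spec, "B")
        with caplog.at_level(logging.WARNING, logger="covnet.stats"):
            covnet.permutation_test_metrics(a, b, sparsity=0.45, n_perm=50, seed=13)
        assert any("unstable" in rec.message for rec in caplog.records)

    def test_nodal_table_shape(self, small_spec_factory):
        spec = small_spec_factory(seed=14, n_per_group=40)
        a = covnet.generate_cohort(spec, "A")
        b = covnet.generate_cohort(spec, "B")
        df = covnet.permutation_test_nodal(a, b, sparsity=0.45, n_perm=50, seed=15)
        assert len(df) == 10
        assert set(["observed_diff", "p_uncorrected", "significant_fdr"]) <= set(df.columns)
        assert df["p_uncorrected"].between(0, 1).all()
        assert df["significant_fdr"].sum() <= df["significant_uncorrected"].sum()


class TestBootstrap:
    def test_single_resample_degenerate(self, small_spec_factory):
        c = covnet.generate_cohort(small_spec_factory(seed=16, n_per_group=40), "A")
        df = covnet.bootstrap_metric_ci(c, sparsity=0.45, n_boot=1, seed=17, n_random=2)
        assert (df["ci_lower"] == df["ci_upper"]).all()
        assert (df["se"] == 0).all()

    def test_deterministic_under_seed(self, small_spec_factory):
        c = covnet.generate_cohort(small_spec_factory(seed=18, n_per_group=40), "A")
        d1 = covnet.bootstrap_metric_ci(c, sparsity=0.45, n_boot=8, seed=19, n_random=2)
        d2 = covnet.bootstrap_metric_ci(c, sparsity=0.45, n_boot=8, seed=19, n_random=2)
        assert d1.equals(d2)

    def test_se_shrinks_with_sample_size(self, small_atlas):
        ses = {}
        for label, n in (("small", 50), ("large", 200)):
            spec = covnet.SyntheticSpec(
                n_subjects_per_group={"A": n}, homotopic_corr=0.6,
                within_block_corr=0.35, between_block_corr=0.15,
                seed=20, atlas=small_atlas,
            )
            c = covnet.generate_cohort(spec, "A")
            df = covnet.bootstrap_metric_ci(c, sparsity=0.45, n_boot=50, seed=21, n_random=1)
            ses[label] = df.loc["Cp", "se"]
        assert ses["large"] < ses["small"]
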