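import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allosrna.diffexpr import (NonAdditivityModel, bh_fdr, binomial_z_test,
                               classify, t_test)
from allosrna.simulate import SimConfig, plan_features, simulate_feature_counts
from oracles import bh_step_up, two_sided_normal_p


class TestBinomialZTest:
    def test_equal_proportions_give_p_one(self):
        assert binomial_z_test(30, 1000, 60, 2000) == pytest.approx(1.0)

    def test_both_zero_gives_p_one(self):
        assert binomial_z_test(0, 10**6, 0, 10**6) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_z_test(11, 10, 0, 10)
        with pytest.raises(ValueError):
            binomial_z_test(1, 0, 0, 10)

    def test_matches_independent_normal_cdf(self):
        k1, n1, k2, n2 = 50, 10**6, 5, 10**6
        pooled = (k1 + k2) / (n1 + n2)
        z = (k1 / n1 - k2 / n2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        assert binomial_z_test(k1, n1, k2, n2) == pytest.approx(
            two_sided_normal_p(z), rel=1e-12)

    def test_within_factor_two_of_fisher_exact(self, rng):
        """Normal-approximation p agrees with Fisher's exact test within 2x on
        random moderate-count tables."""
        checked = 0
        while checked < 200:
            n1 = int(rng.integers(500, 3000))
            n2 = int(rng.integers(500, 3000))
            p = rng.uniform(0.02, 0.2)
            k1 = int(rng.binomial(n1, p * rng.uniform(0.8, 1.25)))
            k2 = int(rng.binomial(n2, p))
            if min(k1, k2) < 8:
                continue
            p_z = binomial_z_test(k1, n1, k2, n2)
            _, p_fisher = stats.fisher_exact(
                [[k1, n1 - k1], [k2, n2 - k2]])
            if p_fisher < 1e-6:
                continue
            assert p_z / 2 <= p_fisher <= p_z * 2 or abs(p_z - p_fisher) < 0.05
            checked += 1


class TestTTest:
    def test_identical_replicates_p_one(self):
        assert t_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0]) == pytest.approx(1.0)

    def test_zero_variance_unequal_means_p_zero(self):
        assert t_test([0.0, 0.0, 0.0], [5.0, 5.0, 5.0]) == 0.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            t_test([1.0], [2.0, 3.0])

    def test_matches_scipy_on_gaussian_fixtures(self, rng):
        for _ in range(50):
            a = rng.normal(10, 2, size=int(rng.integers(2, 6)))
            b = rng.normal(11, 2, size=int(rng.integers(2, 6)))
            expected = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert t_test(a, b) == pytest.approx(expected, abs=1e-9)


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        out = bh_fdr([0.2] * 5)
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert np.allclose(bh_fdr(p), bh_step_up(list(p)))

    def test_preserves_input_order(self):
        p = [0.9, 0.001, 0.5]
        out = bh_fdr(p)
        assert out[1] == min(out)


class TestClassify:
    def test_activated_high_parent(self):
        cat, dom, log2fc = classify(40, 10, 10, pvalue=0.001, fdr=0.01)
        assert (cat, dom) == ("activated", "high-parent")
        assert log2fc == pytest.approx(np.log2(40.25 / 10.25))

    def test_additive_intermediate(self):
        cat, dom, _ = classify(10, 10, 10, pvalue=0.5, fdr=0.9)
        assert (cat, dom) == ("additive", "intermediate")

    def test_repressed_low_parent(self):
        cat, dom, _ = classify(1, 10, 30, pvalue=0.001, fdr=0.01)
        assert (cat, dom) == ("repressed", "low-parent")

    def test_significance_requires_both_thresholds(self):
        cat, _, _ = classify(40, 10, 10, pvalue=0.01, fdr=0.2)
        assert cat == "additive"

    def test_dominance_computed_without_significance(self):
        _, dom, _ = classify(40, 10, 10, pvalue=0.9, fdr=0.9)
        assert dom == "high-parent"


def _null_fit(method: str, n_features: int = 800, depth: int = 200_000,
              seed: int = 13):
    cfg = SimConfig(seed=seed, n_mirna_loci=n_features // 2,
                    n_sirna_loci=n_features // 4, read_depth=depth,
                    frac_nonadditive=0.0, chrom_len=10_000)
    feats = plan_features(cfg)
    cols, sizes, rows = {}, {}, []
    for g in ("P1", "P2", "F2"):
        for rep in (1, 2, 3):
            c, _ = simulate_feature_counts(cfg, feats, g, rep)
            sid = f"{g}_rep{rep}"
            cols[sid], sizes[sid] = c, depth
            rows.append((sid, g, g, rep))
    counts = pd.DataFrame(cols, index=feats["feature_id"])
    info = pd.DataFrame(rows, columns=["sample", "genotype", "group",
                                       "replicate"]).set_index("sample")
    model = NonAdditivityModel(counts, info, pd.Series(sizes), method=method)
    return model, model.fit()


class TestModel:
    def test_category_partition(self):
        _, res = _null_fit("ztest", n_features=200)
        tested = res.calls[res.calls["tested"]]
        assert set(tested["category"]) <= {"additive", "activated", "repressed"}
        counts = res.category_counts()
        assert counts.sum(axis=1).iloc[0] == len(tested)

    def test_null_median_log2fc_near_zero(self):
        _, res = _null_fit("ztest")
        tested = res.calls[res.calls["tested"]]
        assert -0.2 <= tested["log2fc"].median() <= 0.2

    def test_parent_swap_invariance(self):
        model, res = _null_fit("ztest", n_features=100)
        info_swapped = model.info.copy()
        info_swapped["genotype"] = info_swapped["genotype"].map(
            {"P1": "P2", "P2": "P1", "F2": "F2"})
        info_swapped["group"] = info_swapped["genotype"]
        swapped = NonAdditivityModel(model.counts, info_swapped, model.lib,
                                     method="ztest").fit()
        a = res.calls.set_index("feature")
        b = swapped.calls.set_index("feature")
        assert np.allclose(a["pvalue"].fillna(-1), b["pvalue"].fillna(-1), atol=1e-12)
        assert (a["category"] == b["category"]).all()
        assert np.allclose(a["p1_rpm"], b["p2_rpm"])

    def test_all_zero_feature_untestable(self):
        model, res = _null_fit("ztest", n_features=60)
        counts = model.counts.copy()
        counts.iloc[0] = 0
        res2 = NonAdditivityModel(counts, model.info, model.lib, "ztest").fit()
        row = res2.calls.iloc[0]
        assert not row["tested"] and row["category"] == "untestable"
        assert np.isnan(row["pvalue"])

    def test_ttest_path_runs_and_partitions(self):
        _, res = _null_fit("ttest", n_features=200)
        tested = res.calls[res.calls["tested"]]
        assert len(tested) > 0
        assert ((tested["pvalue"] >= 0) & (tested["pvalue"] <= 1)).all()

    def test_summary_mentions_method_and_counts(self):
        _, res = _null_fit("ztest", n_features=60)
        text = res.summary()
        assert "binomial z-test" in text and "category counts" in text

    def test_design_validation(self):
        model, _ = _null_fit("ztest", n_features=60)
        info = model.info[model.info["genotype"] != "P2"]
        with pytest.raises(ValueError, match="P2"):
            NonAdditivityModel(model.counts[info.index], info,
                               model.lib[info.index])
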