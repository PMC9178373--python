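"""Age categories, nonparametric tests, ratios, PCA and the full study."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trabmorph import assign_age_category, compute_ratios, kruskal_wallis, \
    make_cohort_table, nemenyi_posthoc, run_pca, run_study, shapiro_gate
from trabmorph.stats import ratio_table
from trabmorph.synthetic import default_trajectory


class TestAgeCategories:
    @pytest.mark.parametrize("age,expected", [
        (0, "Neonate"), (4, "Neonate"), (6.9, "Neonate"),
        (7, "Infant1"), (24, "Infant1"), (35.9, "Infant1"),
        (36, "Infant2"), (71.9, "Infant2"),
        (72, "Juvenile"), (96, "Juvenile"), (143.9, "Juvenile"),
        (144, "Adult"), (400, "Adult"),
    ])
    def test_bins(self, age, expected):
        assert assign_age_category(age) == expected

    def test_negative_age_raises(self):
        with pytest.raises(ValueError):
            assign_age_category(-1)


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        # all-identical *values* is the degenerate case
        h2, p2 = kruskal_wallis([[5, 5, 5], [5, 5], [5]])
        assert (h2, p2) == (0.0, 1.0)

    def test_matches_hand_computed_rank_formula(self):
        groups = [[1, 2, 3], [10, 11, 12], [20, 21, 22]]
        h, p = kruskal_wallis(groups)
        # no ties: H = 12/(N(N+1)) * sum n_i Rbar_i^2 - 3(N+1)
        n = 9
        rbar = [2.0, 5.0, 8.0]
        h_hand = 12.0 / (n * (n + 1)) * sum(3 * r * r for r in rbar) \
            - 3 * (n + 1)
        assert h == pytest.approx(h_hand)
        assert p == pytest.approx(sps.chi2.sf(h_hand, 2))

    def test_detects_age_trend_in_cohort(self):
        hits = 0
        for seed in range(20):
            t = make_cohort_table(n_per_category=10, seed=3000 + seed)
            groups = {c: t.loc[t.age_category == c, "bvtv_base"].values
                      for c in t.age_category.unique()}
            _, p = kruskal_wallis(groups)
            hits += p < 0.05
        assert hits >= 18

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestNemenyi:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        g = {k: rng.normal(i, 1, 7) for i, k in enumerate("ABC")}
        m = nemenyi_posthoc(g)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_identical_groups_near_one(self):
        g = {"A": [1, 2, 3, 4], "B": [1, 2, 3, 4], "C": [1, 2, 3, 4]}
        m = nemenyi_posthoc(g)
        off = m.values[~np.eye(3, dtype=bool)]
        assert (off > 0.95).all()

    def test_separated_pair_is_minimum(self):
        rng = np.random.default_rng(1)
        g = {"A": rng.normal(0, 1, 8), "B": rng.normal(0.5, 1, 8),
             "C": rng.normal(8, 1, 8)}
        m = nemenyi_posthoc(g)
        off = m.where(~np.eye(3, dtype=bool).astype(bool))
        assert m.loc["A", "C"] == np.nanmin(off.values)

    def test_two_groups_match_asymptotic_mannwhitney(self):
        """Independent oracle: for k=2 the Nemenyi studentized-range p
        equals the tie-corrected asymptotic two-sided Mann-Whitney p."""
        rng = np.random.default_rng(3)
        for _ in range(3):
            a = rng.normal(0, 1, 9)
            b = rng.normal(0.8, 1, 12)
            p_nem = nemenyi_posthoc({"a": a, "b": b}).loc["a", "b"]
            p_mwu = sps.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=False).pvalue
            assert p_nem == pytest.approx(p_mwu, abs=1e-12)
        # and with ties
        a = np.array([1.0, 2, 2, 3, 3, 3])
        b = np.array([2.0, 3, 4, 4, 5])
        p_nem = nemenyi_posthoc({"a": a, "b": b}).loc["a", "b"]
        p_mwu = sps.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic",
                                 use_continuity=False).pvalue
        assert p_nem == pytest.approx(p_mwu, abs=1e-12)

    def test_family_wise_error_controlled(self):
        """Monte-Carlo: under the null the minimum pairwise p rejects at
        most ~alpha of the time (Nemenyi is conservative)."""
        rng = np.random.default_rng(11)
        hits = 0
        M = 400
        for _ in range(M):
            g = {k: rng.normal(0, 1, 8) for k in "ABCD"}
            m = nemenyi_posthoc(g).values
            hits += np.nanmin(m[~np.eye(4, dtype=bool)]) < 0.05
        assert hits / M < 0.08

    def test_small_group_flagged(self):
        g = {"A": [1.0, 2, 3, 4], "B": [2.0, 3, 4, 5], "C": [1.0]}
        m = nemenyi_posthoc(g)
        assert np.isnan(m.loc["C", "A"])
        assert np.isfinite(m.loc["A", "B"])


class TestShapiroGate:
    def test_normal_passes_mostly(self):
        rng = np.random.default_rng(0)
        passes = sum(shapiro_gate(rng.standard_normal(500))[2]
                     for _ in range(40))
        assert passes >= 36

    def test_exponential_fails_mostly(self):
        rng = np.random.default_rng(0)
        fails = sum(not shapiro_gate(rng.exponential(1.0, 500))[2]
                    for _ in range(40))
        assert fails >= 36

    def test_degenerate_inputs(self):
        w, p, normal, flag = shapiro_gate(np.array([1.0, 2.0]))
        assert not normal and "n < 3" in flag
        w, p, normal, flag = shapiro_gate(np.full(10, 3.0))
        assert not normal and "constant" in flag


class TestRatios:
    def _record(self, **over):
        rec = {}
        for p in ("bvtv", "da", "tb_th", "tb_sp", "tb_n"):
            for r in ("base", "metaphysis", "epiphysis"):
                rec[f"{p}_{r}"] = 0.4
        rec.update(over)
        return rec

    def test_all_equal_gives_unity(self):
        rr = compute_ratios(self._record())
        for p, pairs in rr.ratios.items():
            for v in pairs.values():
                assert v == pytest.approx(1.0)

    def test_arithmetic(self):
        rr = compute_ratios(self._record(bvtv_base=0.3, bvtv_metaphysis=0.2))
        assert rr.ratios["bvtv"]["base_metaphysis"] == pytest.approx(1.5)

    def test_missing_epiphysis(self):
        rec = self._record()
        for p in ("bvtv", "da", "tb_th", "tb_sp", "tb_n"):
            rec[f"{p}_epiphysis"] = math.nan
        rr = compute_ratios(rec)
        assert math.isnan(rr.ratios["bvtv"]["base_epiphysis"])
        assert np.isfinite(rr.ratios["bvtv"]["base_metaphysis"])

    def test_zero_denominator_flagged_not_infinite(self):
        rr = compute_ratios(self._record(bvtv_metaphysis=0.0))
        assert math.isnan(rr.ratios["bvtv"]["base_metaphysis"])

    def test_antisymmetry(self):
        rec = self._record(bvtv_base=0.31, bvtv_metaphysis=0.22)
        rr = compute_ratios(rec)
        fwd = rr.ratios["bvtv"]["base_metaphysis"]
        assert fwd * (rec["bvtv_metaphysis"] / rec["bvtv_base"]) \
            == pytest.approx(1.0)

    def test_cohort_ratio_table(self):
        t = make_cohort_table(seed=2)
        rt = ratio_table(t)
        neo = rt[t.age_category == "Neonate"]
        assert neo["bvtv_base_epiphysis"].isna().all()
        assert rt["bvtv_base_metaphysis"].notna().all()


class TestPCA:
    def test_reconstruction_identity(self):
        t = make_cohort_table(seed=5)
        rep = run_pca(t, "base_metaphysis")
        X = t[rep.loadings.index].dropna().to_numpy(dtype=float)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = rep.scores.to_numpy() @ rep.loadings.to_numpy().T
        assert np.allclose(recon, Xs, atol=1e-10)

    def test_proportions_non_increasing_sum_to_one(self):
        t = make_cohort_table(seed=6)
        rep = run_pca(t, "epiphysis")
        assert (np.diff(rep.proportion) <= 1e-12).all()
        assert rep.proportion.sum() == pytest.approx(1.0)

    def test_sign_convention(self):
        t = make_cohort_table(seed=7)
        rep = run_pca(t, "base_metaphysis")
        for col in rep.loadings.columns:
            v = rep.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_constant_column_dropped_with_warning(self):
        t = make_cohort_table(seed=8)
        t["da_epiphysis"] = 0.3
        with pytest.warns(UserWarning, match="constant"):
            rep = run_pca(t, "epiphysis")
        assert "da_epiphysis" in rep.dropped
        assert rep.proportion.sum() == pytest.approx(1.0)

    def test_correlated_pair_equal_loadings(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        t = pd.DataFrame({f"{p}_epiphysis": x * (i + 1)
                          for i, p in enumerate(
                              ("bvtv", "da", "tb_th", "tb_sp", "tb_n"))})
        rep = run_pca(t, "epiphysis")
        l1 = np.abs(rep.loadings["PC1"].to_numpy())
        assert np.allclose(l1, l1[0])
        assert rep.proportion[0] == pytest.approx(1.0)


class TestRunStudy:
    def test_age_trend_detected_everywhere(self):
        t = make_cohort_table(n_per_category=10, seed=9)
        rep = run_study(t)
        pooled = rep.pooled_tests.set_index(["parameter", "region"])
        for p in ("bvtv", "tb_th", "tb_n"):
            for r in ("base", "metaphysis"):
                assert pooled.loc[(p, r), "significant"]

    def test_posthoc_matrices_symmetric(self):
        t = make_cohort_table(seed=10)
        rep = run_study(t)
        for m in rep.pooled_posthoc.values():
            assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_no_epiphyses_reported_with_reason(self):
        t = make_cohort_table(seed=11)
        for p in ("bvtv", "da", "tb_th", "tb_sp", "tb_n"):
            t[f"{p}_epiphysis"] = math.nan
        rep = run_study(t, pca=False)
        epi = rep.pooled_tests.query("region == 'epiphysis'")
        assert epi["p"].isna().all()
        assert (epi["note"] != "").all()

    def test_neonate_merged_for_interspecific(self):
        t = make_cohort_table(seed=12)  # 4 neonates over 2 species
        rep = run_study(t, posthoc=False, pca=False)
        assert rep.config["merged_neonate"]
        assert "Neonate" not in set(rep.interspecific["category"])

    def test_interspecific_null_calibrated(self):
        """No generated species effect: the interspecific significance
        rate stays near alpha."""
        flags, total = 0, 0
        for seed in range(60):
            t = make_cohort_table(n_per_category=8, seed=40000 + seed)
            rep = run_study(t, posthoc=False, pca=False)
            ok = rep.interspecific["p"].notna()
            flags += (rep.interspecific.loc[ok, "p"] < 0.05).sum()
            total += ok.sum()
        assert 0.01 <= flags / total <= 0.10

    def test_write_csv(self, tmp_path):
        t = make_cohort_table(seed=13)
        rep = run_study(t)
        rep.write_csv(str(tmp_path))
        assert (tmp_path / "pooled_tests.csv").exists()
        assert (tmp_path / "posthoc_bvtv_base.csv").exists()
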