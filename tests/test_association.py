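"""Fixed-effect association: design building, LS fitting, LS means,
F-tests, letter displays and the additive/dominance partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from indelpop import (
    GenotypeTraitModel,
    SimConfig,
    ValidationError,
    simulate_cross,
    simulate_phenos,
    trait_scan,
)
from indelpop.association import (
    build_design,
    compact_letter_display,
    fit_ls,
)


def normal_equations_oracle(X, y):
    """Independent least-squares solve via the pseudo-inverse."""
    return np.linalg.pinv(X.T @ X) @ X.T @ y


def make_frame(n=120, seed=0, with_effects=True):
    """A hand-rolled factorial dataset independent of the simulator."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(n)],
        "genotype": rng.choice(["DD", "ID", "II"], n, p=[0.2, 0.5, 0.3]),
        "sex": rng.choice(["male", "female"], n),
        "hatch": rng.choice(["1", "2"], n),
        "family": rng.choice([f"fam{j}" for j in range(1, 8)], n),
        "slaughter_weight": rng.normal(1200, 150, n),
    })
    effect = df["genotype"].map({"II": 30.0, "ID": 0.0, "DD": -30.0})
    df["y"] = 500 + (effect if with_effects else 0.0) + rng.normal(0, 20, n)
    return df


class TestBuildDesign:
    def test_column_count_models_one_and_two(self):
        df = make_frame(n=400, seed=1)
        d1 = build_design(df, "y", model="I")
        # 1 intercept + 2 genotype + 1 sex + 1 hatch + 6 family
        assert d1.X.shape[1] == 11
        d2 = build_design(df, "y", model="II")
        assert d2.X.shape[1] == 12
        assert d2.columns[-1] == "slaughter_weight_centered"
        # covariate centered at the analyzed subset mean
        assert d2.X[:, -1].mean() == pytest.approx(0.0, abs=1e-9)

    def test_single_level_factor_dropped_with_warning(self):
        df = make_frame(n=200, seed=2)
        df["family"] = "fam1"
        with pytest.warns(UserWarning, match="family"):
            d = build_design(df, "y", model="I")
        assert not any("family" in c for c in d.columns)

    def test_single_genotype_class_is_an_error(self):
        df = make_frame(n=50, seed=3)
        df["genotype"] = "II"
        with pytest.raises(ValidationError, match="genotype"):
            build_design(df, "y")

    def test_rank_deficiency_names_confounded_factors(self):
        df = make_frame(n=100, seed=4)
        # make hatch a copy of sex -> their columns are collinear
        df["hatch"] = np.where(df["sex"] == "male", "1", "2")
        with pytest.raises(ValidationError, match="confounded"):
            build_design(df, "y")

    def test_column_space_invariant_to_level_relabeling(self):
        df = make_frame(n=150, seed=5)
        d1 = build_design(df, "y")
        relabeled = df.assign(
            family=df["family"].map(lambda f: f.replace("fam", "zz"))
        )
        d2 = build_design(relabeled, "y")
        # identical projection matrices <=> identical column spaces
        p1 = d1.X @ np.linalg.pinv(d1.X)
        p2 = d2.X @ np.linalg.pinv(d2.X)
        assert np.allclose(p1, p2, atol=1e-8)

    def test_missing_trait_rows_dropped_listwise(self):
        df = make_frame(n=80, seed=6)
        df.loc[df.index[:10], "y"] = np.nan
        d = build_design(df, "y")
        assert d.X.shape[0] == 70


class TestFitLs:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            df = make_frame(n=int(rng.integers(60, 300)),
                            seed=int(rng.integers(1 << 30)))
            d = build_design(df, "y", model=rng.choice(["I", "II"]))
            fit = fit_ls(d.X, d.y)
            expected = normal_equations_oracle(d.X, d.y)
            np.testing.assert_allclose(fit.params, expected, rtol=1e-8)
            # residuals orthogonal to the column space
            assert np.abs(d.X.T @ fit.resid).max() < 1e-6

    def test_constant_response_has_zero_effects(self):
        df = make_frame(n=100, seed=10)
        df["y"] = 42.0
        d = build_design(df, "y")
        fit = fit_ls(d.X, d.y)
        assert fit.params[0] == pytest.approx(42.0)
        np.testing.assert_allclose(fit.params[1:], 0.0, atol=1e-10)

    def test_underdetermined_fit_rejected(self):
        X = np.ones((3, 4))
        with pytest.raises(ValidationError):
            fit_ls(X, np.zeros(3))


class TestLsMeans:
    def balanced_frame(self):
        """Fully crossed genotype x sex x hatch design, 2 families dropped."""
        rows = []
        k = 0
        for g in ("DD", "ID", "II"):
            for s in ("male", "female"):
                for h in ("1", "2"):
                    for r in range(5):
                        rows.append((f"i{k}", g, s, h, "fam1", 1000.0))
                        k += 1
        df = pd.DataFrame(rows, columns=["individual_id", "genotype", "sex",
                                         "hatch", "family", "slaughter_weight"])
        rng = np.random.default_rng(3)
        df["y"] = (df["genotype"].map({"DD": 10.0, "ID": 30.0, "II": 20.0})
                   + rng.normal(0, 1, len(df)))
        return df

    def test_balanced_ls_means_equal_group_means(self):
        df = self.balanced_frame()
        with pytest.warns(UserWarning):  # single-level family factor
            res = GenotypeTraitModel(df, "y", model="I").fit()
        raw = df.groupby("genotype")["y"].mean()
        for g in ("DD", "ID", "II"):
            assert res.ls_means.loc[g, "ls_mean"] == pytest.approx(raw[g])

    def test_shift_equivariance(self):
        df = make_frame(n=250, seed=11)
        res1 = GenotypeTraitModel(df, "y").fit()
        df2 = df.assign(y=df["y"] + 100.0)
        res2 = GenotypeTraitModel(df2, "y").fit()
        np.testing.assert_allclose(
            res2.ls_means["ls_mean"], res1.ls_means["ls_mean"] + 100.0
        )
        np.testing.assert_allclose(res2.ls_means["sem"], res1.ls_means["sem"])

    def test_simulation_recovers_known_genotype_means(self, small_cross):
        config, cross = small_cross
        phenos = simulate_phenos(cross, config, ["BW2"])
        res = GenotypeTraitModel.from_tables(phenos, cross.genotypes, "BW2",
                                             model="I").fit()
        # truth: LS mean difference II - DD = 2a = 30 g
        diff = (res.ls_means.loc["II", "ls_mean"]
                - res.ls_means.loc["DD", "ls_mean"])
        se = np.hypot(res.ls_means.loc["II", "sem"],
                      res.ls_means.loc["DD", "sem"])
        assert abs(diff - 2 * config.a) < 2.5 * se


class TestGenotypeTest:
    def test_f_statistic_matches_explicit_formula(self):
        df = make_frame(n=200, seed=12)
        model = GenotypeTraitModel(df, "y")
        res = model.fit()
        d = model.design
        full = fit_ls(d.X, d.y)
        reduced = fit_ls(np.delete(d.X, d.genotype_cols, axis=1), d.y)
        q = len(d.genotype_cols)
        f_manual = ((reduced.ssr - full.ssr) / q) / (full.ssr / full.df_resid)
        assert res.f_stat == pytest.approx(f_manual, rel=1e-10)
        assert res.p_overall == pytest.approx(
            stats.f.sf(f_manual, q, full.df_resid), rel=1e-10)

    def test_deterministic_genotype_effect_gives_p_near_zero(self):
        df = make_frame(n=150, seed=13)
        df["y"] = df["genotype"].map({"DD": 1.0, "ID": 2.0, "II": 3.0})
        res = GenotypeTraitModel(df, "y").fit()
        assert res.p_overall < 1e-12


class TestLetters:
    def test_published_table_pattern(self):
        """ID lowest and II highest are distinguishable; DD (small class)
        is distinguishable from neither -> a / b / ab."""
        means = {"DD": 31.54, "ID": 30.368, "II": 31.012}
        significant = {frozenset(("ID", "II"))}
        letters = compact_letter_display(means, significant)
        assert letters["DD"] == "ab"
        assert {letters["ID"], letters["II"]} == {"a", "b"}
        assert letters["DD"] != letters["ID"] != letters["II"]

    def test_no_significant_pairs_share_one_letter(self):
        letters = compact_letter_display({"DD": 1.0, "ID": 2.0, "II": 3.0}, set())
        assert set(letters.values()) == {"a"}

    def test_all_pairs_distinct(self):
        sig = {frozenset(p) for p in (("DD", "ID"), ("DD", "II"), ("ID", "II"))}
        letters = compact_letter_display({"DD": 3.0, "ID": 2.0, "II": 1.0}, sig)
        assert sorted(letters.values()) == ["a", "b", "c"]
        assert letters["DD"] == "a"  # largest mean gets 'a'

    def test_invariant_to_input_order(self):
        sig = {frozenset(("ID", "II"))}
        m1 = {"DD": 5.0, "ID": 1.0, "II": 3.0}
        m2 = dict(reversed(list(m1.items())))
        assert compact_letter_display(m1, sig) == compact_letter_display(m2, sig)


class TestAdditiveDominance:
    @pytest.mark.parametrize("means,expected", [
        ({"II": 10.0, "ID": 5.0, "DD": 0.0}, (5.0, 0.0)),    # pure additive
        ({"II": 10.0, "ID": 10.0, "DD": 0.0}, (5.0, 5.0)),   # complete dominance
    ])
    def test_closed_form_cases(self, means, expected):
        rows = []
        for k in range(300):
            g = ("DD", "ID", "II")[k % 3]
            rows.append((f"i{k}", g, ("male", "female")[k % 2],
                         ("1", "2")[(k // 2) % 2], f"fam{(k // 4) % 7 + 1}",
                         1000.0, means[g]))
        df = pd.DataFrame(rows, columns=["individual_id", "genotype", "sex",
                                         "hatch", "family",
                                         "slaughter_weight", "y"])
        res = GenotypeTraitModel(df, "y").fit()
        assert res.additive_a == pytest.approx(expected[0], abs=1e-8)
        assert res.dominance_d == pytest.approx(expected[1], abs=1e-8)

    def test_recovery_within_two_se(self):
        config = SimConfig(seed=21, a=15.0, d=-5.0, resid_sd=60.0)
        cross = simulate_cross(config)
        phenos = simulate_phenos(cross, config, ["CW_carcass"])
        res = GenotypeTraitModel.from_tables(
            phenos, cross.genotypes, "CW_carcass", model="I").fit()
        assert abs(res.additive_a - config.a) < 2 * res.additive_se
        assert abs(res.dominance_d - config.d) < 2 * res.dominance_se

    def test_missing_homozygote_flags_undefined(self):
        df = make_frame(n=120, seed=14)
        df = df[df["genotype"] != "DD"]
        with pytest.warns(UserWarning, match="DD"):
            res = GenotypeTraitModel(df, "y").fit()
        assert res.additive_a is None and res.dominance_d is None


class TestModelTwo:
    def test_zero_covariate_truth_matches_model_one(self):
        config = SimConfig(seed=31, b=0.0)
        cross = simulate_cross(config)
        phenos = simulate_phenos(cross, config, ["BSL4"])
        res1 = GenotypeTraitModel.from_tables(phenos, cross.genotypes,
                                              "BSL4", model="I").fit()
        res2 = GenotypeTraitModel.from_tables(phenos, cross.genotypes,
                                              "BSL4", model="II").fit()
        b_hat = res2.fit.params[-1]
        b_se = np.sqrt(res2.fit.cov_params[-1, -1])
        assert abs(b_hat) < 3 * b_se
        np.testing.assert_allclose(res2.ls_means["ls_mean"],
                                   res1.ls_means["ls_mean"], atol=1.0)


class TestTraitScan:
    def test_scan_structure_and_policy(self, small_dataset):
        phenos, genos = small_dataset
        results = trait_scan(phenos, genos, ["BW2", "CW_carcass", "BSL4"])
        assert [r.trait_code for r in results] == ["BW2", "CW_carcass", "BSL4"]
        assert [r.model for r in results] == ["I", "I", "II"]
        for r in results:
            for cell in r.cells.values():
                assert cell.sem > 0
                assert cell.n > 0

    def test_unknown_trait_skipped_with_warning(self, small_dataset):
        phenos, genos = small_dataset
        with pytest.warns(UserWarning, match="nope"):
            results = trait_scan(phenos, genos, ["BW2", "nope"])
        assert len(results) == 1

    def test_empty_trait_list(self, small_dataset):
        phenos, genos = small_dataset
        assert trait_scan(phenos, genos, []) == []
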