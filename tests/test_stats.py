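import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bloompheno.stats import (
    PowerSpec,
    anova_factorial,
    anova_oneway_letters,
    anova_power,
    cohens_f,
    error_analysis,
    regress_origin,
    required_replicates,
)


class TestRegressionThroughOrigin:
    def test_perfect_fit(self):
        r = regress_origin([1, 2, 3], [2, 4, 6])
        assert r.slope == pytest.approx(2.0)
        assert r.r2 == pytest.approx(1.0)
        assert r.rmse == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # b = (1*2 + 2*2)/(1+4) = 6/5; residuals 0.8, -0.4
        r = regress_origin([1, 2], [2, 2])
        assert r.slope == pytest.approx(1.2)
        assert r.rmse == pytest.approx(np.sqrt((0.8**2 + 0.4**2) / 2))
        assert r.r2 == pytest.approx(1 - (0.8**2 + 0.4**2) / (4 + 4))

    def test_permutation_invariance_and_orthogonality(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 10, 50).astype(float)
        x[0] = 1.0
        y = 0.9 * x + rng.normal(0, 0.5, 50)
        r1 = regress_origin(x, y)
        perm = rng.permutation(50)
        r2 = regress_origin(x[perm], y[perm])
        assert r1.slope == pytest.approx(r2.slope)
        assert np.isclose(np.sum(x * (y - r1.slope * x)), 0.0, atol=1e-9)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            regress_origin([0, 0, 0], [1, 2, 3])


class TestErrorAnalysis:
    @staticmethod
    def tables(img_counts, man_counts, daps=None):
        daps = daps or list(range(70, 70 + len(img_counts)))
        img = pd.DataFrame({"plant_id": "p", "dap": daps, "count": img_counts})
        man = pd.DataFrame({"plant_id": "p", "dap": daps, "manual_count": man_counts})
        return img, man

    def test_identical_counts_all_mass_at_zero(self):
        img, man = self.tables([1, 2, 3, 0], [1, 2, 3, 0])
        ea = error_analysis(img, man)
        assert ea.error_hist == {0: 4}
        assert ea.relative_hist["0%"] == len(ea.relative_errors) == 3  # manual>0 rows
        assert ea.zero_manual_nonzero_imaging == 0

    def test_zero_manual_nonzero_imaging_is_separate_bin(self):
        img, man = self.tables([1, 2], [0, 2])
        ea = error_analysis(img, man)
        assert ea.zero_manual_nonzero_imaging == 1
        assert len(ea.relative_errors) == 1  # the manual=0 sample is excluded

    def test_load_groups_clip_at_twelve(self):
        img, man = self.tables([14, 3], [15, 3])
        ea = error_analysis(img, man)
        assert ea.per_load_n[12] == 1 and ea.per_load_mean_error[12] == -1.0

    def test_disjoint_join_rejected(self):
        img = pd.DataFrame({"plant_id": "a", "dap": [70], "count": [1]})
        man = pd.DataFrame({"plant_id": "b", "dap": [70], "manual_count": [1]})
        with pytest.raises(ValueError):
            error_analysis(img, man)

    def test_known_miss_rate_underestimation(self):
        # binomial thinning at p=0.8: expected error at manual load m is -0.2*m
        rng = np.random.default_rng(9)
        man_counts = np.repeat(np.arange(0, 11), 400)
        img_counts = rng.binomial(man_counts, 0.8)
        img, man = self.tables(img_counts.tolist(), man_counts.tolist(),
                               daps=list(range(len(man_counts))))
        ea = error_analysis(img, man)
        for load in (2, 5, 10):
            se = np.sqrt(load * 0.8 * 0.2 / 400)
            assert ea.per_load_mean_error[load] == pytest.approx(-0.2 * load, abs=4 * se)


class TestAnova:
    @staticmethod
    def two_factor_data(interaction=0.0, seed=0, reps=6):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(4):
            for b in (1, 2):
                mu = 70 + 2 * g + 3 * (b - 1) + interaction * g * (b - 1)
                for _ in range(reps):
                    rows.append({"genotype": f"g{g}", "transplant_batch": b,
                                 "y": mu + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_factorial_detects_injected_interaction(self):
        tab = anova_factorial(self.two_factor_data(interaction=4.0, seed=3), "y")
        inter = tab.loc["C(genotype):C(transplant_batch)"]
        assert inter["PR(>F)"] < 0.05

    def test_factorial_no_interaction_usually_ns(self):
        tab = anova_factorial(self.two_factor_data(interaction=0.0, seed=3), "y")
        assert tab.loc["C(genotype):C(transplant_batch)", "PR(>F)"] > 0.05
        assert tab.loc["C(genotype)", "PR(>F)"] < 0.05

    def test_factorial_permutation_invariant(self):
        df = self.two_factor_data(interaction=2.0, seed=5)
        tab1 = anova_factorial(df, "y")
        tab2 = anova_factorial(df.sample(frac=1, random_state=1), "y")
        assert np.allclose(tab1["F"].to_numpy()[:3], tab2["F"].to_numpy()[:3])

    def test_constant_response_flagged_zero_f(self):
        df = self.two_factor_data(seed=0)
        df["y"] = 5.0
        tab = anova_factorial(df, "y")
        assert (tab["F"] == 0).all() and (tab["flag"] == "constant_response").all()


class TestLetters:
    @staticmethod
    def groups_df(means, sd=1.0, n=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = [
            {"g": name, "y": rng.normal(mu, sd)}
            for name, mu in means.items()
            for _ in range(n)
        ]
        return pd.DataFrame(rows)

    def test_separated_groups_get_different_letters(self):
        res = anova_oneway_letters(self.groups_df({"lo": 0.0, "hi": 100.0}), "y", "g")
        assert res.letters["lo"] != res.letters["hi"]
        assert res.marks["lo"] == "-" and res.marks["hi"] == "+"

    def test_identical_groups_share_letter(self):
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "y": [5.0] * 8})
        res = anova_oneway_letters(df, "y", "g")
        assert res.letters["a"] == res.letters["b"]
        assert res.marks["a"] == res.marks["b"] == ""

    def test_letters_invariant_to_relabeling(self):
        means = {"a": 0.0, "b": 0.5, "c": 50.0}
        res1 = anova_oneway_letters(self.groups_df(means, seed=2), "y", "g")
        renamed = self.groups_df(means, seed=2)
        renamed["g"] = renamed["g"].map({"a": "x", "b": "y_", "c": "z"})
        res2 = anova_oneway_letters(renamed, "y", "g")
        for old, new in [("a", "x"), ("b", "y_"), ("c", "z")]:
            assert res1.letters[old] == res2.letters[new]

    def test_shared_letter_implies_nonsignificant_tukey_pair(self):
        means = {"a": 0.0, "b": 1.0, "c": 3.0, "d": 8.0}
        res = anova_oneway_letters(self.groups_df(means, sd=1.5, n=6, seed=4), "y", "g")
        padj = {
            frozenset((r["group1"], r["group2"])): r["p-adj"]
            for _, r in res.tukey.iterrows()
        }
        names = list(res.letters)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if set(res.letters[a]) & set(res.letters[b]):
                    assert padj[frozenset((a, b))] >= 0.05

    def test_holm_posthoc_variant_runs(self):
        res = anova_oneway_letters(
            self.groups_df({"lo": 0.0, "hi": 100.0}), "y", "g", posthoc="holm-t"
        )
        assert res.letters["lo"] != res.letters["hi"]

    def test_singleton_only_groups_rejected(self):
        df = pd.DataFrame({"g": ["a", "b"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_oneway_letters(df, "y", "g")


class TestEffectSizeAndPower:
    def test_cohens_f_closed_forms(self):
        assert cohens_f(1.0, 2.0) == pytest.approx(1.0)  # SSb == SSw -> eta2 0.5
        assert cohens_f(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            cohens_f(2.0, 2.0)

    def test_effect_size_recovered_from_simulated_groups(self):
        rng = np.random.default_rng(12)
        k, n, sd = 5, 200, 1.0
        mus = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        # population f = sd_between/sd_within with sd_between over group means
        f_true = np.sqrt(np.mean((mus - mus.mean()) ** 2)) / sd
        df = pd.DataFrame(
            {"g": np.repeat([f"g{i}" for i in range(k)], n),
             "y": np.concatenate([rng.normal(m, sd, n) for m in mus])}
        )
        res = anova_oneway_letters(df, "y", "g")
        assert res.cohens_f == pytest.approx(f_true, rel=0.1)

    def test_power_matches_direct_simulation(self):
        # oracle: Monte-Carlo power of the one-way F test at f=0.5, k=3, n=10
        from scipy import stats as sps
        rng = np.random.default_rng(77)
        k, n, f = 3, 10, 0.5
        delta = f * np.sqrt(3.0 / 2.0)  # means (-d, 0, d) give exactly this f
        rej = 0
        trials = 4000
        for _ in range(trials):
            groups = [rng.normal(m, 1.0, n) for m in (-delta, 0.0, delta)]
            rej += sps.f_oneway(*groups).pvalue < 0.05
        mc = rej / trials
        analytic = anova_power(f, k, n, alpha=0.05)
        assert analytic == pytest.approx(mc, abs=0.03)

    def test_minimality_of_returned_n(self):
        spec = PowerSpec(0.88, 22)
        n = required_replicates(spec)
        assert anova_power(spec.effect_size_f, spec.k, n) >= spec.power
        assert n == 2 or anova_power(spec.effect_size_f, spec.k, n - 1) < spec.power

    @given(st.floats(0.3, 2.0), st.floats(0.3, 2.0), st.integers(2, 50))
    @settings(derandomize=True, max_examples=30)
    def test_monotone_in_effect_size(self, f1, f2, k):
        lo, hi = sorted([f1, f2])
        assert required_replicates(PowerSpec(hi, k)) <= required_replicates(PowerSpec(lo, k))

    def test_monotone_in_alpha_and_power(self):
        base = required_replicates(PowerSpec(0.5, 10, alpha=0.05, power=0.9))
        assert required_replicates(PowerSpec(0.5, 10, alpha=0.01, power=0.9)) >= base
        assert required_replicates(PowerSpec(0.5, 10, alpha=0.05, power=0.99)) >= base

    def test_unreachable_power_raises(self):
        with pytest.raises(ValueError):
            required_replicates(PowerSpec(0.01, 3, power=0.99), n_max=5)
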