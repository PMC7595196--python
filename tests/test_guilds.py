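"""Guild assignment, log transform and the parameter screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dmta import (DietaryComposition, GuildRules, assign_guild, bh_adjust,
                  log_transform_parameters, ranked_profile_test,
                  screen_parameters)
from dmta.simulate import GuildEffectProfile, default_guild_profiles, simulate_framework


class TestAssignGuild:
    def test_fish_dominated_is_piscivore(self):
        d = DietaryComposition("gharial", fish=0.9, tetrapods=0.1)
        assert assign_guild(d) == "piscivore"

    def test_plant_animal_mix_is_omnivore(self):
        d = DietaryComposition("monitor", plants=0.5, harder_invertebrates=0.5)
        assert assign_guild(d) == "omnivore"

    def test_tie_raises_listing_guilds(self):
        d = DietaryComposition("x", harder_invertebrates=0.5,
                               softer_invertebrates=0.5)
        with pytest.raises(ValueError, match="harder_invertebrate.*softer_invertebrate"):
            assign_guild(d)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            assign_guild(DietaryComposition("empty"))

    def test_composition_invariants(self):
        d = DietaryComposition("croc", tetrapods=0.3, fish=0.2,
                               harder_invertebrates=0.25,
                               softer_invertebrates=0.15,
                               softest_invertebrates=0.1)
        assert d.total_vertebrates == pytest.approx(0.5, abs=1e-12)
        assert d.total_invertebrates == pytest.approx(0.5, abs=1e-12)
        with pytest.raises(ValueError, match="outside"):
            DietaryComposition("bad", fish=1.2)
        with pytest.raises(ValueError, match="> 1"):
            DietaryComposition("bad", fish=0.8, plants=0.4)


class TestLogTransform:
    def test_ssk_dropped_and_log10_identities(self):
        t = pd.DataFrame({"Sa": [1.0, 100.0], "Ssk": [-0.2, 0.3],
                          "Sq": [10.0, 1000.0]}, index=["s1", "s2"])
        out = log_transform_parameters(t)
        assert "Ssk" not in out.columns
        assert list(out.columns) == ["Sa", "Sq"]
        assert out.loc["s1", "Sa"] == 0.0
        assert out.loc["s2", "Sa"] == 2.0

    def test_nonpositive_value_names_specimen(self):
        t = pd.DataFrame({"Sa": [1.0, 0.0]}, index=["good", "degenerate"])
        with pytest.raises(ValueError, match="'Sa'.*'degenerate'"):
            log_transform_parameters(t)


class TestBenjaminiHochberg:
    @staticmethod
    def _brute_force(p, fdr):
        """Literal step-up definition: largest i with p_(i) <= i*fdr/m and
        everything ranked at or below it is flagged."""
        m = len(p)
        order = np.argsort(p, kind="stable")
        k = 0
        for i in range(1, m + 1):
            if p[order[i - 1]] <= i * fdr / m:
                k = i
        flags = np.zeros(m, dtype=bool)
        flags[order[:k]] = True
        return flags

    def test_matches_brute_force_on_all_short_lists(self):
        rng = np.random.default_rng(5)
        grid = rng.random(400)
        for length in range(1, 9):
            for _ in range(60):
                p = rng.choice(grid, size=length)
                flags, _ = bh_adjust(p, 0.05)
                np.testing.assert_array_equal(flags, self._brute_force(p, 0.05))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.random(40)
        flags, adj = bh_adjust(p, 0.05)
        ref_flags, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(flags, ref_flags)
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)

    def test_edge_cases(self):
        flags, _ = bh_adjust([0.01, 0.02, 0.03, 0.04], 0.05)
        assert flags.all()
        flags, _ = bh_adjust([1.0, 1.0, 1.0], 0.05)
        assert not flags.any()
        flags, _ = bh_adjust([0.04], 0.05)
        assert flags.all()
        flags, adj = bh_adjust([], 0.05)
        assert len(flags) == 0 and len(adj) == 0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_property_matches_brute_force(self, pvals):
        flags, adj = bh_adjust(pvals, 0.05)
        np.testing.assert_array_equal(flags, self._brute_force(np.array(pvals), 0.05))
        # adjusted values monotone in raw rank
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestScreen:
    def _table(self, rng, n=8, shift=0.0):
        g = ["a"] * n + ["b"] * n
        t = pd.DataFrame({
            "P1": np.r_[rng.normal(0, 1, n), rng.normal(shift, 1, n)],
            "P2": rng.normal(0, 1, 2 * n),
        }, index=[f"s{i}" for i in range(2 * n)])
        return t, g

    def test_levene_rule_selects_anova_or_welch(self):
        rng = np.random.default_rng(8)
        t, g = self._table(rng)
        res = screen_parameters(t, g)
        assert set(res.table["test"]).issubset({"anova", "welch_anova"})
        # equal variances -> anova
        assert res.table.set_index("parameter").loc["P1", "test"] == "anova"
        # variance ratio 100 -> welch
        t2 = t.copy()
        t2.loc[[f"s{i}" for i in range(8)], "P2"] = rng.normal(0, 10, 8)
        res2 = screen_parameters(t2, g)
        assert res2.table.set_index("parameter").loc["P2", "test"] == "welch_anova"

    def test_strong_effect_always_detected(self):
        # guild means 3 within-guild SD apart, n = 10/guild
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t, g = self._table(rng, n=10, shift=3.0)
            res = screen_parameters(t, g, pairwise=False)
            hits += "P1" in res.significant
        assert hits >= 99

    def test_constant_parameter_untestable(self):
        rng = np.random.default_rng(9)
        t, g = self._table(rng)
        t["Pconst"] = 1.0
        res = screen_parameters(t, g)
        assert "Pconst" in res.untestable
        assert "Pconst" not in list(res.table["parameter"])

    def test_invariant_to_row_order_and_label_renaming(self):
        rng = np.random.default_rng(10)
        t, g = self._table(rng, n=6, shift=1.0)
        res = screen_parameters(t, g)
        perm = rng.permutation(len(t))
        res2 = screen_parameters(t.iloc[perm], list(np.array(g)[perm]))
        pd.testing.assert_frame_equal(
            res.table.sort_values("parameter").reset_index(drop=True),
            res2.table.sort_values("parameter").reset_index(drop=True))
        renamed = ["guild_" + x for x in g]
        res3 = screen_parameters(t, renamed)
        np.testing.assert_allclose(res.table["p_raw"], res3.table["p_raw"])

    def test_tukey_reported_for_significant_parameters(self):
        rng = np.random.default_rng(12)
        t, g = self._table(rng, n=10, shift=3.0)
        res = screen_parameters(t, g)
        assert "P1" in res.tukey
        m = res.tukey["P1"]
        assert m.shape == (2, 2) and m.loc["a", "b"] < 0.05


class TestRankedProfileTest:
    def test_identical_profiles(self):
        t, df, p = ranked_profile_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == 1.0 and df == 3

    def test_antisymmetry(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=10)
        b = a + 0.5 + rng.normal(0, 0.2, 10)
        t1, df1, p1 = ranked_profile_test(a, b)
        t2, df2, p2 = ranked_profile_test(b, a)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_textbook_formula(self):
        # independently coded paired-t oracle
        rng = np.random.default_rng(15)
        a = rng.normal(size=12)
        b = a + 0.3 + rng.normal(0, 0.4, 12)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist
        p_ref = 2 * tdist.sf(abs(t_ref), len(d) - 1)
        t, df, p = ranked_profile_test(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_constant_difference_degenerate(self):
        t, df, p = ranked_profile_test([1, 2, 3], [0, 1, 2])
        assert np.isnan(t) and np.isnan(p)

    def test_too_short_profiles(self):
        with pytest.raises(ValueError, match="at least 3"):
            ranked_profile_test([1, 2], [3, 4])


class TestNullCalibration:
    def test_screen_type_one_error_under_null(self):
        # all guilds drawn from one distribution: flagged fraction bounded
        # by the FDR plus two binomial SEs (Monte-Carlo, seeded)
        null = [GuildEffectProfile(g.guild, 1.0, 1.0, 1.0, g.diet)
                for g in default_guild_profiles()]
        total = flagged = 0
        for seed in range(100):
            sim = simulate_framework(null, n_per_guild=5, seed=70_000 + seed)
            logp = log_transform_parameters(sim["params"])
            res = screen_parameters(logp, sim["specimens"]["guild"], pairwise=False)
            total += len(res.table)
            flagged += res.n_significant
        rate = flagged / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 2 * se
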