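import warnings

import numpy as np
import pandas as pd
import pytest

from _oracles import greedy_match_oracle
from paguard.matching import (
    COMPARISONS,
    MatchedSet,
    PropensityScoreMatch,
    att,
    fit_propensity,
    nn_match,
    run_comparisons,
    smd,
)


def toy_table(n, seed=0, confounded=False):
    """Random pixel table with all four protection categories."""
    rng = np.random.default_rng(seed)
    elev = rng.standard_normal(n)
    if confounded:
        p_treat = 1 / (1 + np.exp(-(elev - 0.5)))
        treated = rng.random(n) < p_treat
    else:
        treated = rng.random(n) < 0.3
    protection = np.where(treated, "P70", "NEVER").astype(object)
    # sprinkle the other categories so run_comparisons has all four
    other = rng.choice(n, size=max(4, n // 10), replace=False)
    protection[other[: len(other) // 2]] = "P15"
    protection[other[len(other) // 2 :]] = "BUFFER"
    df = pd.DataFrame(
        {
            "protection": protection,
            "outcome_pct_lost": rng.uniform(0, 100, n),
            "elevation": elev,
            "slope": rng.standard_normal(n),
            "pop_density": rng.standard_normal(n),
            "travel_time": rng.standard_normal(n),
            "bioanthrome_id": rng.integers(0, 3, n),
        }
    )
    for cov in ("elevation", "slope", "pop_density", "travel_time"):
        df[f"{cov}_bin"] = pd.qcut(df[cov], 4, labels=False) + 1
    return df


class TestFitPropensity:
    def test_saturated_single_covariate_closed_form(self):
        # counts: level 1 -> (30 treated, 10 control); level 0 -> (10, 30)
        x = np.array([1] * 40 + [0] * 40)
        treatment = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        df = pd.DataFrame({"x_bin": x})
        fit = fit_propensity(df, treatment, bin_cols=("x_bin",), bioanthrome_col=None)
        np.testing.assert_allclose(fit.scores[x == 1], 0.75, atol=1e-6)
        np.testing.assert_allclose(fit.scores[x == 0], 0.25, atol=1e-6)

    def test_independent_covariate_gives_marginal_rate(self):
        rng = np.random.default_rng(1)
        n = 4000
        df = pd.DataFrame({"x_bin": rng.integers(1, 5, n)})
        treatment = (rng.random(n) < 0.3).astype(int)
        fit = fit_propensity(df, treatment, bin_cols=("x_bin",), bioanthrome_col=None)
        assert np.allclose(fit.scores, treatment.mean(), atol=0.05)

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x_bin": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            fit_propensity(df, np.ones(4, int), bin_cols=("x_bin",), bioanthrome_col=None)

    def test_separation_falls_back_to_ridge(self):
        # covariate perfectly predicts treatment
        x = np.array([1] * 20 + [2] * 20)
        df = pd.DataFrame({"x_bin": x})
        treatment = (x == 2).astype(int)
        with pytest.warns(UserWarning, match="ridge"):
            fit = fit_propensity(df, treatment, bin_cols=("x_bin",), bioanthrome_col=None)
        assert fit.penalized
        assert np.isfinite(fit.scores).all()

    def test_scores_increase_with_confounder(self, standard_world, standard_table):
        table = standard_table
        prot = table["protection"].astype(str).to_numpy()
        keep = np.isin(prot, ["P70", "P15", "NEVER"])
        sub = table[keep].reset_index(drop=True)
        treatment = np.isin(sub["protection"].astype(str), ["P70", "P15"]).astype(int)
        fit = fit_propensity(sub, treatment)
        by_bin = pd.Series(fit.scores).groupby(sub["elevation_bin"].to_numpy()).mean()
        assert by_bin.loc[4] > by_bin.loc[1]


class TestNNMatch:
    def test_single_pair(self):
        scores = np.array([0.4, 0.6])
        ms = nn_match(scores, np.array([0]), np.array([1]))
        assert ms.pairs == [(0, 1)]

    def test_greedy_order_matters(self):
        scores = np.array([0.9, 0.8, 0.85, 0.1])
        ms = nn_match(scores, np.array([0, 1]), np.array([2, 3]))
        assert ms.pairs == [(0, 2), (1, 3)]

    def test_equals_bruteforce_on_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 11))
            n_treated = int(rng.integers(1, n))
            ids = rng.permutation(n)
            treated, controls = ids[:n_treated], ids[n_treated:]
            # mix continuous and heavily tied scores
            if rng.random() < 0.5:
                scores = rng.random(n)
            else:
                scores = rng.integers(0, 3, n) / 2.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = nn_match(scores, treated, controls).pairs
            assert got == greedy_match_oracle(scores, treated, controls)

    def test_excess_treated_stay_unmatched_with_warning(self):
        scores = np.array([0.1, 0.2, 0.3, 0.5])
        with pytest.warns(UserWarning, match="unmatched"):
            ms = nn_match(scores, np.array([0, 1, 2]), np.array([3]))
        assert ms.n_pairs == 1
        assert len(ms.unmatched_treated) == 2

    def test_without_replacement_enforced(self):
        with pytest.raises(ValueError):
            MatchedSet(pairs=[(0, 2), (1, 2)], unmatched_treated=[], unmatched_controls=[])

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError):
            nn_match(np.array([0.5]), np.array([0]), np.array([], dtype=int))


class TestSMD:
    def test_identical_groups_zero(self):
        v = np.array([1.0, 2, 3, 1, 2, 3])
        assert smd(v, np.array([0, 1, 2]), np.array([3, 4, 5])) == 0.0

    def test_arithmetic_with_fixed_denominator(self):
        v = np.array([1.0, 1.0, 0.0, 0.0])
        assert smd(v, np.array([0, 1]), np.array([2, 3]), denominator_sd=2.0) == 0.5

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(50)
        t, c = np.arange(20), np.arange(20, 50)
        expected = abs(v[t].mean() - v[c].mean()) / np.sqrt(
            (v[t].std(ddof=1) ** 2 + v[c].std(ddof=1) ** 2) / 2
        )
        assert smd(v, t, c) == pytest.approx(expected)

    def test_zero_variance_unequal_means_rejected(self):
        v = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            smd(v, np.array([0, 1]), np.array([2, 3]), denominator_sd=0.0)


class TestATT:
    def test_identical_outcomes_within_pairs(self):
        df = pd.DataFrame({"outcome_pct_lost": [10.0, 10, 20, 20, 30, 30]})
        ms = MatchedSet([(0, 1), (2, 3), (4, 5)], [], [])
        e = att(df, ms)
        assert e.estimate == 0.0
        assert e.ci_low <= 0 <= e.ci_high

    def test_constant_difference_zero_width_ci(self):
        df = pd.DataFrame({"outcome_pct_lost": [0.0, 10, 5, 15, 20, 30, 40, 50]})
        ms = MatchedSet([(0, 1), (2, 3), (4, 5), (6, 7)], [], [])
        e = att(df, ms)
        assert e.estimate == -10.0
        assert e.se == 0.0
        assert (e.ci_low, e.ci_high) == (-10.0, -10.0)

    def test_single_pair_rejected(self):
        df = pd.DataFrame({"outcome_pct_lost": [1.0, 2.0]})
        with pytest.raises(ValueError):
            att(df, MatchedSet([(0, 1)], [], []))

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"outcome_pct_lost": rng.uniform(0, 100, 40)})
        ms = MatchedSet([(i, i + 20) for i in range(20)], [], [])
        e = att(df, ms)
        assert e.ci_low <= e.estimate <= e.ci_high


class TestModelFrontEnd:
    def test_randomized_world_is_balanced_before_and_after(self):
        table = toy_table(3000, seed=5, confounded=False)
        res = PropensityScoreMatch(table, ("P70",), ("NEVER",)).fit()
        # covariates start balanced (the fitted distance itself always shows
        # some in-sample separation, so it is excluded from the before check)
        covs = res.balance["covariate"] != "distance"
        assert (res.balance.loc[covs, "smd_before"] < 0.1).all()
        assert (res.balance["smd_after"] < 0.12).all()
        # ATT tracks the naive difference when there is no confounding
        prot = table["protection"].astype(str)
        naive = (
            table.loc[prot == "P70", "outcome_pct_lost"].mean()
            - table.loc[prot == "NEVER", "outcome_pct_lost"].mean()
        )
        assert res.effect.estimate == pytest.approx(naive, abs=3.0)

    def test_matching_reduces_smd_of_confounder(self):
        table = toy_table(4000, seed=6, confounded=True)
        res = PropensityScoreMatch(table, ("P70",), ("NEVER",)).fit()
        bal = res.balance.set_index("covariate")
        assert bal.loc["elevation", "smd_after"] < bal.loc["elevation", "smd_before"]

    def test_balance_report_row_structure(self):
        table = toy_table(1000, seed=7)
        res = PropensityScoreMatch(table, ("P70",), ("NEVER",)).fit()
        assert res.balance["covariate"].tolist() == [
            "distance",
            "elevation",
            "slope",
            "population density",
            "travel time",
            "bioanthromes (average)",
        ]

    def test_summary_mentions_groups_and_att(self):
        table = toy_table(800, seed=8)
        res = PropensityScoreMatch(table, ("P70",), ("NEVER",)).fit()
        text = res.summary()
        assert "treatment: P70" in text
        assert "ATT" in text


class TestRunComparisons:
    def test_all_four_comparisons_present(self):
        table = toy_table(1500, seed=9)
        results = run_comparisons(table)
        assert set(results) == {"a", "b", "c", "d"}

    def test_missing_buffer_skips_c_and_d(self, caplog):
        table = toy_table(1500, seed=10)
        table = table[table["protection"] != "BUFFER"].reset_index(drop=True)
        results = run_comparisons(table)
        assert set(results) == {"a", "b"}

    def test_buffer_is_treatment_against_never(self):
        treat, ctrl = COMPARISONS["d"]
        assert treat == ("BUFFER",)
        assert ctrl == ("NEVER",)

    def test_higher_protection_is_treatment_everywhere(self):
        order = {"NEVER": 0, "BUFFER": 1, "P15": 2, "P70": 3}
        for treat, ctrl in COMPARISONS.values():
            assert min(order[t] for t in treat) > max(order[c] for c in ctrl)
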