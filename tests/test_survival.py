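import numpy as np
import pandas as pd
import pytest

import oracles
from hubnet.simulate import simulate_survival
from hubnet.survival import (
    dichotomize,
    hazard_ratio,
    km_estimate,
    logrank_test,
    screen_genes,
)


def make_table(times, events, expr=None):
    n = len(times)
    d = {
        "subject_id": [f"s{i}" for i in range(n)],
        "time_months": times,
        "event": events,
    }
    if expr is not None:
        d["g"] = expr
    return pd.DataFrame(d)


class TestDichotomize:
    def test_median_split(self):
        t = make_table([1] * 4, [1] * 4, expr=[1.0, 2.0, 3.0, 4.0])
        groups = dichotomize(t, "g")
        assert list(groups) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        t = make_table([1] * 4, [1] * 4, expr=[1.0, 2.0, 2.0, 4.0])
        groups = dichotomize(t, "g")
        assert list(groups) == ["low", "low", "low", "high"]

    def test_constant_expression_rejected(self):
        t = make_table([1, 2], [1, 1], expr=[3.0, 3.0])
        with pytest.raises(ValueError, match="identical"):
            dichotomize(t, "g")

    def test_simulated_groups_match_truth(self):
        table, _ = simulate_survival(n_subjects=40, gene_list=["g1"], seed=3)
        groups = dichotomize(table, "g1")
        expected = np.where(
            table["g1"] > table["g1"].median(), "high", "low"
        )
        assert list(groups) == list(expected)


class TestKaplanMeier:
    def test_two_events_closed_form(self):
        t = make_table([1.0, 2.0], [1, 1], expr=[0.0, 1.0])
        curves = km_estimate(t, pd.Series(["a", "a"]))
        sf = curves["a"].set_index("time")["survival"]
        assert sf.loc[1.0] == pytest.approx(0.5)
        assert sf.loc[2.0] == pytest.approx(0.0)

    def test_single_censored_subject_flat_curve(self):
        t = make_table([5.0], [0], expr=[0.0])
        curves = km_estimate(t, pd.Series(["a"]))
        assert (curves["a"]["survival"] == 1.0).all()

    def test_matches_hand_product_limit(self, small_survival):
        groups = pd.Series(["a"] * 10)
        curves = km_estimate(small_survival, groups)
        ref = oracles.km_by_hand(
            small_survival["time_months"], small_survival["event"]
        )
        sf = curves["a"].set_index("time")["survival"]
        for t, s in ref:
            assert sf.loc[t] == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        t = make_table(times, [1] * 5)
        curves = km_estimate(t, pd.Series(["a"] * 5))
        sf = curves["a"].set_index("time")["survival"]
        for i, ti in enumerate(times, start=1):
            assert sf.loc[ti] == pytest.approx(1 - i / 5)


class TestLogrank:
    def test_identical_groups_null(self):
        t = make_table([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        chi2, p = logrank_test(t, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        t = make_table([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        groups = pd.Series(["a", "a", "b", "b"])
        chi2, _ = logrank_test(t, groups)
        ref = oracles.logrank_by_hand(
            np.array([1.0, 2.0]), np.array([1, 1]), np.array([3.0, 4.0]), np.array([1, 1])
        )
        assert chi2 == pytest.approx(ref, rel=1e-9)

    def test_hand_oracle_on_mixed_censoring(self, small_survival):
        groups = dichotomize(small_survival, "gX")
        chi2, _ = logrank_test(small_survival, groups)
        a = groups == "high"
        ref = oracles.logrank_by_hand(
            small_survival.loc[a, "time_months"].to_numpy(),
            small_survival.loc[a, "event"].to_numpy(),
            small_survival.loc[~a, "time_months"].to_numpy(),
            small_survival.loc[~a, "event"].to_numpy(),
        )
        assert chi2 == pytest.approx(ref, rel=1e-9)

    def test_no_events_rejected(self):
        t = make_table([1, 2], [0, 0])
        with pytest.raises(ValueError):
            logrank_test(t, pd.Series(["a", "b"]))


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        t = make_table(times * 2, [1] * 12)
        groups = pd.Series(["high"] * 6 + ["low"] * 6)
        hr, (lo, hi), p = hazard_ratio(t, groups)
        assert hr == pytest.approx(1.0, abs=1e-6)
        assert lo <= hr <= hi

    def test_three_subject_closed_form(self):
        # deaths at t=1 (high, risk set all three), t=2 (low, risk set
        # {low, high}), t=3 (high, risk set {high}); no ties, so the partial
        # likelihood is L(b) = [e^b/(2e^b+1)] * [1/(e^b+1)] * 1 and the
        # score equation 1 - 2e^b/(2e^b+1) - e^b/(e^b+1) = 0 has a finite
        # root solved here independently.
        t = make_table([1.0, 2.0, 3.0], [1, 1, 1])
        groups = pd.Series(["high", "low", "high"])
        hr, _, _ = hazard_ratio(t, groups)
        from scipy.optimize import brentq

        def score(b):
            eb = np.exp(b)
            return 1 - 2 * eb / (2 * eb + 1) - eb / (eb + 1)

        beta = brentq(score, -5, 5)
        assert np.log(hr) == pytest.approx(beta, abs=1e-3)

    def test_ci_brackets_estimate(self, small_survival):
        groups = dichotomize(small_survival, "gX")
        hr, (lo, hi), p = hazard_ratio(small_survival, groups)
        assert lo <= hr <= hi
        assert 0 <= p <= 1


class TestScreen:
    def test_planted_prognostic_gene_flagged(self):
        table, _ = simulate_survival(
            n_subjects=300, gene_list=["gP", "gN"], prognostic_genes=["gP"],
            hazard_ratio=3.0, censor_rate=0.005, seed=11,
        )
        screen = screen_genes(table, ["gP", "gN"])
        assert bool(screen.set_index("gene").loc["gP", "significant"])

    def test_empty_gene_list(self):
        table, _ = simulate_survival(n_subjects=20, gene_list=["g1"], seed=1)
        assert screen_genes(table, []).empty

    def test_missing_gene_flagged_and_continues(self):
        table, _ = simulate_survival(n_subjects=30, gene_list=["g1"], seed=2)
        screen = screen_genes(table, ["nope", "g1"])
        assert list(screen["gene"]) == ["nope", "g1"]
        assert bool(screen.loc[0, "missing"])
        assert not bool(screen.loc[1, "missing"])

    def test_boundary_p_is_significant(self):
        # significance is inclusive at 0.05 on either criterion
        row = pd.DataFrame(
            {"logrank_p": [0.05], "hr_p": [0.4]}
        )
        assert bool((row["logrank_p"] <= 0.05).iloc[0])
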