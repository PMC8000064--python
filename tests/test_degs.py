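import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hubnet.datasets import (
    common_deg_records,
    load_deg_class_sets,
    load_common_deg_table,
)
from hubnet.degs import call_degs, classify_by_annotation, partition_common
from hubnet.degs import test_differential as differential_stats


def welch_by_hand(x, y):
    """Textbook Welch t statistic and two-sided p (independent of the package)."""
    from scipy.stats import t as tdist  # only for the CDF of the t distribution

    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, 2 * tdist.sf(abs(t), df)


class TestDifferential:
    def test_matches_hand_welch(self, tiny_expression):
        stats = differential_stats(tiny_expression, 1).set_index("gene")
        m = tiny_expression.values
        treated = m.loc["gA", ["gen1_1", "gen1_2", "gen1_3"]].tolist()
        control = m.loc["gA", ["ctrl_1", "ctrl_2", "ctrl_3"]].tolist()
        t_ref, p_ref = welch_by_hand(treated, control)
        assert stats.loc["gA", "t_stat"] == pytest.approx(t_ref, rel=1e-10)
        assert stats.loc["gA", "p_value"] == pytest.approx(p_ref, rel=1e-10)
        assert stats.loc["gA", "logfc"] == pytest.approx(
            np.mean(treated) - np.mean(control), rel=1e-12
        )

    def test_worked_six_number_example(self):
        # control (5.1, 4.9, 5.0) vs treated (7.0, 7.2, 6.8)
        from hubnet.io import ExpressionMatrix

        values = pd.DataFrame(
            [[5.1, 4.9, 5.0, 7.0, 7.2, 6.8]],
            index=["g"],
            columns=["c1", "c2", "c3", "t1", "t2", "t3"],
        )
        groups = pd.DataFrame(
            {"condition": ["control"] * 3 + ["treated"] * 3,
             "generation": [0, 0, 0, 1, 1, 1]},
            index=pd.Index(values.columns, name="sample_id"),
        )
        stats = differential_stats(ExpressionMatrix(values, groups), 1)
        t_ref, p_ref = welch_by_hand([7.0, 7.2, 6.8], [5.1, 4.9, 5.0])
        assert stats.loc[0, "t_stat"] == pytest.approx(t_ref, rel=1e-10)
        assert stats.loc[0, "p_value"] == pytest.approx(p_ref, rel=1e-10)

    def test_identical_groups_zero_logfc(self):
        from hubnet.io import ExpressionMatrix

        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]],
            index=["g"],
            columns=["c1", "c2", "c3", "t1", "t2", "t3"],
        )
        groups = pd.DataFrame(
            {"condition": ["control"] * 3 + ["treated"] * 3,
             "generation": [0, 0, 0, 1, 1, 1]},
            index=pd.Index(values.columns, name="sample_id"),
        )
        stats = differential_stats(ExpressionMatrix(values, groups), 1)
        assert stats.loc[0, "logfc"] == pytest.approx(0.0)

    def test_zero_variance_equal_means_p_one(self):
        from hubnet.io import ExpressionMatrix

        values = pd.DataFrame(
            [[5.0] * 6], index=["g"], columns=["c1", "c2", "c3", "t1", "t2", "t3"]
        )
        groups = pd.DataFrame(
            {"condition": ["control"] * 3 + ["treated"] * 3,
             "generation": [0, 0, 0, 1, 1, 1]},
            index=pd.Index(values.columns, name="sample_id"),
        )
        stats = differential_stats(ExpressionMatrix(values, groups), 1)
        assert stats.loc[0, "p_value"] == 1.0

    def test_too_few_replicates_rejected(self, tiny_expression):
        m = tiny_expression
        m.groups.loc["gen1_2", "generation"] = 99
        m.groups.loc["gen1_3", "generation"] = 99
        with pytest.raises(ValueError, match="replicates"):
            differential_stats(m, 1)


class TestCallDegs:
    @pytest.mark.parametrize(
        "logfc,p,expected",
        [
            (1.5, 0.01, "up"),
            (-1.2, 0.04, "down"),
            (1.0, 0.001, "none"),   # boundary logfc excluded (strict >)
            (-1.0, 0.001, "none"),
            (2.0, 0.05, "none"),    # boundary p excluded (strict <)
            (0.5, 0.001, "none"),
        ],
    )
    def test_threshold_rules(self, logfc, p, expected):
        table = pd.DataFrame({"gene": ["g"], "logfc": [logfc], "t_stat": [1.0],
                              "p_value": [p]})
        assert call_degs(table).loc[0, "direction"] == expected

    @given(
        logfc=st.floats(-4, 4, allow_nan=False),
        p=st.floats(0, 1, allow_nan=False),
        thr=st.floats(0.5, 3.0),
    )
    def test_raising_logfc_threshold_never_adds_degs(self, logfc, p, thr):
        table = pd.DataFrame(
            {"gene": ["g"], "logfc": [logfc], "t_stat": [0.0], "p_value": [p]}
        )
        lo = call_degs(table, logfc_threshold=thr).loc[0, "direction"]
        hi = call_degs(table, logfc_threshold=thr + 0.5).loc[0, "direction"]
        assert not (lo == "none" and hi != "none")


def _records(**directions):
    """gene -> list of per-generation directions."""
    out = {}
    genes = sorted(directions)
    n_gens = len(next(iter(directions.values())))
    for i in range(n_gens):
        out[i + 1] = pd.DataFrame(
            {
                "gene": genes,
                "logfc": [2.0 if directions[g][i] == "up" else -2.0 for g in genes],
                "t_stat": 0.0,
                "p_value": 0.01,
                "direction": [directions[g][i] for g in genes],
            }
        )
    return out


class TestPartition:
    def test_concordant_and_discordant_assignment(self):
        part = partition_common(
            _records(
                gU=["up", "up", "up"],
                gD=["down", "down", "down"],
                gB=["up", "up", "down"],
                gN=["up", "none", "up"],
            )
        )
        assert part.up == {"gU"}
        assert part.down == {"gD"}
        assert part.both == {"gB"}
        assert "gN" not in part.common

    def test_generation_order_invariant(self):
        recs = _records(gU=["up", "up", "up"], gB=["down", "up", "up"])
        p1 = partition_common(recs)
        p2 = partition_common(dict(reversed(list(recs.items()))))
        assert (p1.up, p1.down, p1.both) == (p2.up, p2.down, p2.both)

    def test_identical_generations_yield_no_both(self):
        rec = _records(gU=["up"], gD=["down"])[1]
        part = partition_common({1: rec, 4: rec, 9: rec})
        assert part.up == {"gU"} and part.down == {"gD"} and part.both == frozenset()

    def test_single_generation_rejected(self):
        with pytest.raises(ValueError):
            partition_common({1: _records(g=["up"])[1]})


class TestClassification:
    def test_published_growth_factor_count(self):
        classes = load_deg_class_sets()
        gf = classes.sets["growth_factors"]
        tallies = classify_by_annotation(sorted(gf), classes)
        assert len(tallies["growth_factors"].members) == 16

    def test_direction_tallies(self):
        classes = {"c": frozenset({"A", "B", "C"})}
        degs = pd.DataFrame(
            {"gene": ["A", "B", "C"], "direction": ["up", "up", "down"]}
        )
        t = classify_by_annotation(["A", "B", "C", "D"], classes, degs)["c"]
        assert (t.n_up, t.n_down) == (2, 1)

    def test_empty_class_and_identity_class(self):
        classes = {"empty": frozenset({"zzz"}), "all": frozenset({"A", "B"})}
        t = classify_by_annotation(["A", "B"], classes)
        assert t["empty"].members == frozenset()
        assert t["all"].members == {"A", "B"}


class TestPublishedTables:
    def test_partition_of_published_common_degs(self):
        part = partition_common(common_deg_records())
        assert part.counts() == {"common": 199, "up": 62, "down": 122, "both": 15}

    def test_published_table_is_label_partition(self):
        table = load_common_deg_table()
        assert not table["gene"].duplicated().any()
        assert set(table["category"]) == {"up", "down", "both"}
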