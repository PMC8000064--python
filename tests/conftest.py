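import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_expression():
    """3 control + 3 treated x 2 generations, 4 genes, fixed values."""
    from hubnet.io import ExpressionMatrix

    genes = ["gA", "gB", "gC", "gD"]
    samples = ["ctrl_1", "ctrl_2", "ctrl_3", "gen1_1", "gen1_2", "gen1_3",
               "gen4_1", "gen4_2", "gen4_3"]
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        8.0 + 0.05 * rng.standard_normal((4, 9)), index=genes, columns=samples
    )
    # gA strongly up in both generations, gB down in gen 1 only
    values.loc["gA", ["gen1_1", "gen1_2", "gen1_3", "gen4_1", "gen4_2", "gen4_3"]] += 2.0
    values.loc["gB", ["gen1_1", "gen1_2", "gen1_3"]] -= 2.0
    groups = pd.DataFrame(
        {
            "condition": ["control"] * 3 + ["treated"] * 6,
            "generation": [0, 0, 0, 1, 1, 1, 4, 4, 4],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def star_graph():
    import networkx as nx

    g = nx.star_graph(4)
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


@pytest.fixture
def small_survival():
    """10-subject cohort with a mix of events and censorings."""
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(10)],
            "time_months": [2.0, 3.0, 3.0, 5.0, 7.0, 8.0, 10.0, 12.0, 14.0, 20.0],
            "event": [1, 1, 0, 1, 1, 0, 1, 1, 0, 1],
            "gX": [0.1, 1.2, -0.4, 2.0, 0.5, -1.1, 0.9, -0.2, 1.5, -0.8],
        }
    )
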