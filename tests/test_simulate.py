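import numpy as np
import pandas as pd
import pytest

from hubnet.simulate import (
    simulate_annotation,
    simulate_bundle,
    simulate_expression,
    simulate_network,
    simulate_survival,
)


class TestSimulateExpression:
    def test_zero_noise_logfc_exact(self):
        matrix, truth = simulate_expression(
            n_genes=200, noise_sd=0.0, effect_logfc=2.0, discordant_frac=0.0, seed=1
        )
        treated = matrix.samples_for("treated", 1)
        control = matrix.samples_for("control")
        logfc = matrix.values[treated].mean(axis=1) - matrix.values[control].mean(axis=1)
        for gene, label in truth.true_deg_labels[1].items():
            expected = 2.0 if label == "up" else -2.0
            assert logfc[gene] == pytest.approx(expected, abs=1e-12)

    def test_same_seed_identical(self):
        m1, _ = simulate_expression(n_genes=100, seed=5)
        m2, _ = simulate_expression(n_genes=100, seed=5)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_planted_label_counts(self):
        _, truth = simulate_expression(
            n_genes=1000, frac_up=0.1, frac_down=0.0, discordant_frac=0.0, seed=2
        )
        for gen in (1, 4, 9):
            labels = truth.true_deg_labels[gen]
            assert sum(v == "up" for v in labels.values()) == 100

    def test_discordant_genes_flip_in_one_generation(self):
        _, truth = simulate_expression(
            n_genes=1000, frac_up=0.05, frac_down=0.05, discordant_frac=0.2, seed=3
        )
        per_gene = {}
        for gen, labels in truth.true_deg_labels.items():
            for g, d in labels.items():
                per_gene.setdefault(g, set()).add(d)
        n_discordant = sum(len(dirs) > 1 for dirs in per_gene.values())
        assert n_discordant == round(0.2 * 100)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(n_genes=10, n_replicates=1)


class TestSimulateNetwork:
    def test_planted_clique_is_complete(self):
        import networkx as nx

        edges, truth = simulate_network(
            n_background_nodes=50, planted_clique_sizes=(6,), planted_hub_spokes=5, seed=1
        )
        g = nx.from_pandas_edgelist(edges, "node_a", "node_b")
        clique = truth.planted_modules[0]
        sub = g.subgraph(clique)
        assert sub.number_of_edges() == 6 * 5 // 2

    def test_empty_background_gives_clique_plus_bridge(self):
        edges, truth = simulate_network(
            n_background_nodes=20,
            background_model=("erdos_renyi", 0.0),
            planted_clique_sizes=(5,),
            planted_hub_spokes=1,
            seed=2,
        )
        # 10 clique edges + 1 bridge + 1 hub spoke
        assert len(edges) == 12

    def test_planted_hub_has_max_degree(self):
        import networkx as nx

        for seed in range(5):
            edges, truth = simulate_network(
                n_background_nodes=200,
                background_model=("erdos_renyi", 0.02),
                planted_clique_sizes=(3,),
                planted_hub_spokes=50,
                seed=seed,
            )
            g = nx.from_pandas_edgelist(edges, "node_a", "node_b")
            degrees = dict(g.degree())
            hub = truth.planted_hub_ids[0]
            assert degrees[hub] == max(degrees.values())

    def test_all_scores_above_filter_by_default(self):
        edges, _ = simulate_network(n_background_nodes=50, seed=4)
        assert (edges["confidence"] >= 0.5).all()

    def test_node_budget_enforced(self):
        with pytest.raises(ValueError, match="budget"):
            simulate_network(
                n_background_nodes=10,
                planted_clique_sizes=(6,),
                node_names=[f"g{i}" for i in range(12)],
            )


class TestSimulateSurvival:
    def test_no_censoring_all_events(self):
        table, _ = simulate_survival(
            n_subjects=50, gene_list=["g1"], censor_rate=0.0, seed=1
        )
        assert (table["event"] == 1).all()

    def test_same_seed_identical(self):
        t1, _ = simulate_survival(n_subjects=30, gene_list=["g1", "g2"], seed=9)
        t2, _ = simulate_survival(n_subjects=30, gene_list=["g1", "g2"], seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_hr_unbiased(self):
        # Monte-Carlo null: mean log-HR across simulations stays near 0
        from hubnet.survival import dichotomize, hazard_ratio

        logs = []
        for seed in range(40):
            table, _ = simulate_survival(
                n_subjects=120, gene_list=["g1"], prognostic_genes=(),
                censor_rate=0.002, seed=seed,
            )
            hr, _, _ = hazard_ratio(table, dichotomize(table, "g1"))
            logs.append(np.log(hr))
        assert abs(np.mean(logs)) < 0.1

    def test_truth_records_hazard_ratios(self):
        _, truth = simulate_survival(
            n_subjects=40, gene_list=["g1", "g2"], prognostic_genes=["g2"],
            hazard_ratio=3.0, seed=2,
        )
        assert truth.true_hazard_ratio == {"g1": 1.0, "g2": 3.0}


class TestSimulateAnnotation:
    def test_planted_overlap_exact(self):
        universe = [f"g{i}" for i in range(500)]
        query = universe[:40]
        coll, truth = simulate_annotation(
            universe, n_sets=10, set_size_range=(20, 30),
            enriched_sets=[(query, 15)], seed=1,
        )
        sid = truth.enriched_set_ids[0]
        assert len(coll.sets[sid] & set(query)) == 15

    def test_deterministic(self):
        universe = [f"g{i}" for i in range(100)]
        c1, _ = simulate_annotation(universe, n_sets=5, set_size_range=(5, 10), seed=3)
        c2, _ = simulate_annotation(universe, n_sets=5, set_size_range=(5, 10), seed=3)
        assert c1.sets == c2.sets

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate_annotation(["a", "b"], n_sets=1, set_size_range=(3, 5))


class TestBundle:
    def test_bundle_files_written_and_namespaces_shared(self, tmp_path):
        bundle = simulate_bundle(
            seed=0, out_dir=tmp_path, n_genes=2000, n_background_nodes=60,
            clique_size=6, hub_spokes=20, n_subjects=80,
        )
        for name in ("expression.tsv", "samples.tsv", "edges.tsv",
                     "genesets.gmt", "survival.tsv", "truth.json"):
            assert (tmp_path / name).exists()
        genes = set(bundle["expression"].gene_ids)
        net_nodes = set(bundle["edges"]["node_a"]) | set(bundle["edges"]["node_b"])
        assert net_nodes <= genes
        assert bundle["truth"].planted_hub_ids[0] in net_nodes
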