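"""Synthetic bundle generator: topology, expression, dependency, round-trip."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kerndep as kd
from kerndep.errors import ParameterError
from kerndep.io import mutation_records
from kerndep.synthetic import simulate_network, simulate_expression, simulate_dependency


class TestNetworkTopology:
    def test_planted_genes_at_shell_one(self, small_bundle, small_network):
        for gene in small_bundle.ground_truth["planted_genes"]:
            assert small_network.shell[gene] == 1

    def test_same_seed_byte_identical(self, small_config):
        e1, a1, _ = simulate_network(small_config)
        e2, a2, _ = simulate_network(small_config)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(a1, a2)

    def test_raw_graph_connected(self, small_bundle):
        import networkx as nx

        g = nx.Graph()
        for r in small_bundle.edges.itertuples(index=False):
            g.add_edge(r.protein1, r.protein2)
        assert nx.is_connected(g)

    def test_preferential_attachment_heavy_tail(self):
        import networkx as nx

        maxima, medians = [], []
        for seed in range(10):
            cfg = kd.SimulationConfig(n_genes=200, n_cells=30,
                                      topology="preferential_attachment",
                                      effect_weights=(-1.0,), n_planted=1, seed=seed)
            edges, _, _ = simulate_network(cfg)
            g = nx.Graph(list(zip(edges["protein1"], edges["protein2"])))
            assert nx.is_connected(g)
            degrees = np.array([d for _, d in g.degree()])
            maxima.append(degrees.max())
            medians.append(np.median(degrees))
        assert np.mean(maxima) >= 3 * np.mean(medians)

    def test_infeasible_planting_rejected(self):
        with pytest.raises(ParameterError):
            kd.SimulationConfig(n_genes=30, n_planted=10, n_shell1=5,
                                effect_weights=tuple([-1.0] * 10))


class TestExpression:
    def test_adjacent_genes_more_correlated_than_random_pairs(self):
        adj, non = [], []
        for seed in range(3):
            cfg = kd.SimulationConfig(n_genes=80, n_cells=500, n_shell1=15, seed=seed)
            _, _, truth = simulate_network(cfg)
            expr = simulate_expression(truth, cfg)
            corr = expr.corr()
            rng = np.random.default_rng(seed)
            pairs = [(g, p) for g, p in truth["parent"].items()]
            adj.extend(corr.loc[g, p] for g, p in pairs[:40])
            genes = truth["genes"]
            for _ in range(40):
                a, b = rng.choice(genes, 2, replace=False)
                if b != truth["parent"].get(a) and a != truth["parent"].get(b):
                    non.append(corr.loc[a, b])
        assert np.mean(adj) > np.mean(non) + 0.1

    def test_values_nonnegative_log_scale(self, small_bundle):
        assert (small_bundle.expression.min() >= 0).all()

    def test_missing_fraction_near_target(self):
        cfg = kd.SimulationConfig(n_genes=100, n_cells=300, n_shell1=15,
                                  missing_fraction=0.01, seed=1)
        _, _, truth = simulate_network(cfg)
        expr = simulate_expression(truth, cfg)
        frac = float(expr.isna().to_numpy().mean())
        assert frac == pytest.approx(0.01, abs=0.005)


class TestDependency:
    def test_noiseless_single_gene_rank_correlation(self):
        cfg = kd.SimulationConfig(n_genes=40, n_cells=120, n_shell1=8, n_planted=1,
                                  effect_weights=(-1.0,), noise_sd=0.0,
                                  mutation_rate=0.0, seed=3)
        _, _, truth = simulate_network(cfg)
        expr = simulate_expression(truth, cfg)
        effect, prob, truth = simulate_dependency(expr, truth, cfg)
        g = truth["planted_genes"][0]
        rho = stats.spearmanr(effect["KRAS"], expr[g]).statistic
        assert abs(rho) == pytest.approx(1.0)
        assert rho < 0  # high expression of a negative-weight gene => dependent

    def test_probabilities_in_unit_interval(self, small_bundle):
        p = small_bundle.dependency_prob.to_numpy()
        assert p.min() >= 0 and p.max() <= 1

    def test_designed_r2_matches_signal_noise_split(self, small_bundle):
        truth = small_bundle.ground_truth
        signal = np.array([truth["signal"][c] for c in small_bundle.expression.index])
        noise_sd = truth["noise_sd"]
        implied_r2 = signal.var() / (signal.var() + noise_sd**2)
        assert implied_r2 == pytest.approx(small_bundle.config.target_r2, abs=1e-9)


class TestMutationsAndCopyNumber:
    def test_zero_mutation_rate_all_wild_type(self):
        cfg = kd.SimulationConfig(n_genes=40, n_cells=60, n_shell1=8,
                                  mutation_rate=0.0, seed=0)
        bundle = kd.make_bundle(cfg)
        status = kd.classify_mutation_status(
            mutation_records(bundle.mutations), "KRAS", list(bundle.expression.index)
        )
        assert (status == "wt").all()

    def test_amplified_lines_flagged_exactly(self, small_bundle):
        flagged = [
            cl for cl in small_bundle.copy_number.index
            if kd.classify_amplified(
                kd.relative_copy_number(small_bundle.copy_number.loc[cl], "KRAS")
            )
        ]
        assert sorted(flagged) == sorted(small_bundle.ground_truth["amplified_cells"])

    def test_decoys_stay_wild_type_but_encode(self, small_bundle):
        records = mutation_records(small_bundle.mutations)
        cells = list(small_bundle.expression.index)
        status = kd.classify_mutation_status(records, "KRAS", cells)
        enc = kd.encode_mutation_predictors(records, "KRAS", cells)
        for cl in small_bundle.ground_truth["decoy_cells"]:
            assert status[cl] == "wt"
            assert enc.loc[cl, "hotspot"] == 0 and enc.loc[cl, "other"] == 0
        for cl in small_bundle.ground_truth["mutant_cells"]:
            assert status[cl] == "mut"


class TestBundleRoundTrip:
    def test_write_load_reproduces_tables(self, small_bundle, small_bundle_dir):
        loaded = kd.load_bundle(small_bundle_dir)
        for attr in ("expression", "gene_effect", "dependency_prob", "copy_number"):
            pd.testing.assert_frame_equal(
                getattr(loaded, attr), getattr(small_bundle, attr),
                atol=1e-9, rtol=0, check_names=False,
            )
        assert loaded.ground_truth["planted_genes"] == small_bundle.ground_truth["planted_genes"]

    def test_ground_truth_lists_planted_genes(self, small_bundle_dir):
        truth = json.loads((small_bundle_dir / "ground_truth.json").read_text())
        assert len(truth["planted_genes"]) == 5
        assert set(truth["planted_genes"]) <= set(truth["genes"])

    def test_loaders_accept_dialects_cleanly(self, small_bundle_dir):
        from kerndep.io import load_expression, load_mutation_table

        table = kd.read_interactions(small_bundle_dir / "protein_links.txt")
        assert table.n_rejected == 0
        assert table.scale == "0-1000"
        aliases = kd.read_aliases(small_bundle_dir / "protein_aliases.txt")
        assert "KRAS" in aliases.values()
        expr = load_expression(small_bundle_dir / "expression.csv")
        assert "KRAS" in expr.columns  # entrez suffix stripped
        muts = load_mutation_table(small_bundle_dir / "mutations.csv")
        assert set(muts.columns) >= {"cell_line", "gene", "is_hotspot"}
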