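"""Synthetic-data generator: sampling statistics, closed forms, invariants."""

import numpy as np
import pytest
from scipy import stats as sps

import gennet as g
from gennet.simulate import solve_grn_profile, solve_ppin_profile

from oracles import resample_truth_edges


class TestTruthNetwork:
    def test_zero_density_gives_empty_edge_sets(self):
        truth = g.generate_truth_network(
            n_genes=2, n_mirnas=0, mean_tfs_per_gene=0,
            mean_partners_per_protein=0, mean_mirnas_per_gene=0, seed=7,
        )
        assert truth.true_ppi == {} and truth.true_tf == {} and truth.true_mirna == {}
        assert len(truth.genes) == 2

    def test_mean_tf_in_degree_matches_request(self):
        """Across many seeds the mean candidate-TF in-degree hits 7.3."""
        means = []
        for seed in range(1, 1001):
            truth = g.generate_truth_network(
                n_genes=50, n_mirnas=0, mean_tfs_per_gene=7.3,
                mean_partners_per_protein=0, mean_mirnas_per_gene=0, seed=seed,
            )
            means.append(len(truth.true_tf) / 50)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 7.3) < 3 * se

    def test_edge_sampler_matches_independent_reimplementation(self):
        truth = g.generate_truth_network(
            n_genes=20, n_mirnas=4, mean_tfs_per_gene=2.0,
            mean_partners_per_protein=4.0, mean_mirnas_per_gene=1.0, seed=3,
        )
        tf, ppi, mir = resample_truth_edges(20, 4, 2.0, 4.0, 1.0, seed=3)
        assert len(truth.true_ppi) == len(ppi)
        assert {(truth.genes.index(a), truth.genes.index(b)) for a, b in truth.true_ppi} == ppi
        assert len(truth.true_tf) == len(tf)
        assert len(truth.true_mirna) == len(mir)

    def test_excessive_mean_degree_rejected(self):
        with pytest.raises(ValueError, match="mean degree"):
            g.generate_truth_network(n_genes=5, mean_tfs_per_gene=10, seed=0)

    def test_sinks_have_incoming_edges_and_source_regulators(self):
        truth = g.generate_truth_network(
            n_genes=40, n_mirnas=8, mean_tfs_per_gene=3,
            mean_partners_per_protein=4, mean_mirnas_per_gene=2, seed=11,
        )
        assert truth.sink_nodes
        for gene, mech in truth.sink_nodes.items():
            regulators = truth.regulators_of(gene)
            assert regulators, f"sink {gene} has no incoming true edge"
            for r in regulators:
                assert r not in truth.sink_nodes


class TestDecoys:
    @pytest.fixture(scope="class")
    @staticmethod
    def truth():
        return g.generate_truth_network(
            n_genes=20, n_mirnas=4, mean_tfs_per_gene=2,
            mean_partners_per_protein=3, mean_mirnas_per_gene=1, seed=1,
        )

    def test_zero_ratio_reproduces_truth(self, truth):
        cand = g.add_decoys(truth, 0.0, seed=0)
        assert cand.ppi == set(truth.true_ppi)
        assert cand.tf == set(truth.true_tf)
        assert cand.mirna == set(truth.true_mirna)
        assert not any(cand.decoys.values())

    def test_unit_ratio_doubles_each_edge_class(self, truth):
        cand = g.add_decoys(truth, 1.0, seed=0)
        for cls, true_set in (
            ("ppi", truth.true_ppi), ("tf", truth.true_tf), ("mirna", truth.true_mirna)
        ):
            assert len(getattr(cand, cls)) == 2 * len(true_set)
            assert len(cand.decoys[cls]) == len(true_set)

    def test_decoys_disjoint_from_truth(self, truth):
        cand = g.add_decoys(truth, 2.5, seed=4)
        assert not cand.decoys["ppi"] & set(truth.true_ppi)
        assert not cand.decoys["tf"] & set(truth.true_tf)
        assert not cand.decoys["mirna"] & set(truth.true_mirna)


class TestMethylation:
    def test_uniform_beta_mean_is_half(self):
        truth = g.generate_truth_network(n_genes=5, n_mirnas=0, seed=0,
                                         mean_tfs_per_gene=0,
                                         mean_partners_per_protein=0,
                                         mean_mirnas_per_gene=0)
        meth = g.simulate_methylation(truth, L=1000, beta_params=(1, 1), seed=2)
        for gene in truth.genes:
            row = meth.profile(gene)
            se = row.std(ddof=1) / np.sqrt(row.size)
            assert abs(row.mean() - 0.5) < 3 * se

    def test_hyper_shift_matches_clipped_moment(self):
        """Shifted-gene mean equals the analytic moment of the clipped
        shifted beta distribution."""
        truth = g.generate_truth_network(n_genes=3, n_mirnas=0, seed=0,
                                         mean_tfs_per_gene=0,
                                         mean_partners_per_protein=0,
                                         mean_mirnas_per_gene=0)
        a, b, shift = 2.0, 8.0, 0.3  # base mean 0.2
        gene = truth.genes[0]
        meth = g.simulate_methylation(
            truth, L=4000, beta_params=(a, b),
            shifted_genes={gene: "hyper"}, shift=shift, seed=9,
        )
        expected = sps.beta(a, b).expect(lambda x: min(x + shift, 1.0))
        row = meth.profile(gene)
        se = row.std(ddof=1) / np.sqrt(row.size)
        assert abs(row.mean() - expected) < 3 * se

    def test_values_stay_in_unit_interval(self):
        truth = g.generate_truth_network(n_genes=4, n_mirnas=0, seed=0,
                                         mean_tfs_per_gene=0,
                                         mean_partners_per_protein=0,
                                         mean_mirnas_per_gene=0)
        meth = g.simulate_methylation(
            truth, L=200, beta_params=(0.5, 0.5),
            shifted_genes={truth.genes[0]: "hyper", truth.genes[1]: "hypo"},
            shift=0.9, seed=1,
        )
        values = meth.beta.to_numpy()
        assert values.min() >= 0 and values.max() <= 1


class TestClosedForms:
    def test_gene_with_single_tf_no_mirna(self):
        x = solve_grn_profile(b=[2.0], y_tfs=[[3.0]], c=[], x_mirs=[],
                              m=[0.0], kappa=1.0, omega=[0.0])
        assert x == pytest.approx([7.0])

    def test_gene_with_mirna_and_full_methylation(self):
        x = solve_grn_profile(b=[2.0], y_tfs=[[3.0]], c=[1.0], x_mirs=[[2.0]],
                              m=[1.0], kappa=1.0, omega=[0.0])
        assert x == pytest.approx([1.0])

    def test_protein_with_single_partner(self):
        y = solve_ppin_profile(a=[0.1], y_partners=[[4.0]], h=2.0, v=[0.0])
        assert y == pytest.approx([10.0 / 3.0])

    def test_denominator_guard_raises(self):
        with pytest.raises(ValueError, match="guard"):
            solve_ppin_profile(a=[0.5], y_partners=[[1.9]], h=1.0, v=[0.0])


class TestExpression:
    def test_noiseless_profiles_satisfy_models_exactly(self, small_system):
        truth, candidate, meth, expr = small_system
        for node, mech in truth.sink_nodes.items():
            if mech == "ppin":
                problem = g.build_ppin_problem(node, expr, candidate)
                theta = [
                    truth.true_ppi[tuple(sorted((node, c.source)))]
                    if c.kind == "partner" else truth.basal_protein[node]
                    for c in problem.columns
                ]
            else:
                problem = g.build_grn_problem(node, expr, meth, candidate)
                theta = []
                for c in problem.columns:
                    if c.kind == "tf":
                        theta.append(truth.true_tf[(c.source, node)])
                    elif c.kind == "mirna":
                        theta.append(-truth.true_mirna[(c.source, node)])
                    else:
                        theta.append(truth.basal_gene[node])
            residual = problem.response - problem.design @ np.array(theta)
            assert np.abs(residual).max() < 1e-9

    def test_regeneration_is_bit_identical(self, small_system):
        truth, _, meth, expr = small_system
        again = g.simulate_expression(truth, meth, noise_sd=0.0, seed=7)
        assert again.mrna.equals(expr.mrna)
        assert again.mirna.equals(expr.mirna)

    def test_residual_variance_matches_noise_level(self):
        truth = g.generate_truth_network(
            n_genes=20, n_mirnas=4, mean_tfs_per_gene=2,
            mean_partners_per_protein=3, mean_mirnas_per_gene=1, seed=13,
        )
        noise_sd, L = 0.1, 10_000
        meth = g.simulate_methylation(truth, L=L, seed=14)
        expr = g.simulate_expression(truth, meth, noise_sd=noise_sd, seed=15)
        candidate = g.truth_candidate(truth)
        gene = next(n for n, m in truth.sink_nodes.items() if m == "grn")
        problem = g.build_grn_problem(gene, expr, meth, candidate)
        theta = []
        for c in problem.columns:
            if c.kind == "tf":
                theta.append(truth.true_tf[(c.source, gene)])
            elif c.kind == "mirna":
                theta.append(-truth.true_mirna[(c.source, gene)])
            else:
                theta.append(truth.basal_gene[gene])
        residual = problem.response - problem.design @ np.array(theta)
        var = residual.var(ddof=0)
        se = noise_sd**2 * np.sqrt(2.0 / (L - 1))
        assert abs(var - noise_sd**2) < 3 * se

    def test_ill_posed_truth_raises_generation_error(self):
        genes = ["G0000", "G0001"]
        truth = g.SyntheticTruth(
            genes=genes, mirnas=[],
            true_ppi={("G0000", "G0001"): 0.95},
            true_tf={}, true_mirna={},
            basal_protein={gg: 1.0 for gg in genes},
            basal_gene={gg: 1.0 for gg in genes},
            sink_nodes={"G0001": "ppin"},
        )
        meth = g.simulate_methylation(truth, L=100, seed=0)
        # a = 0.95 puts the partner profile's bulk right at the denominator
        # singularity (~30% of columns rejected); a 20% redraw budget trips
        with pytest.raises(RuntimeError, match="smaller"):
            g.simulate_expression(truth, meth, noise_sd=0.0, seed=0,
                                  max_redraw_rate=0.2)
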