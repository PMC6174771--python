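"""Constrained least squares, AIC stepwise order detection, permutation
significance and whole-network identification."""

import numpy as np
import pytest

import gennet as g
from gennet.models import ColumnLink, RegressionProblem

from oracles import exhaustive_best_subset_aic, grid_search_lsq


def make_problem(design, response, mirna_cols=(), node="n", kind="grn"):
    """Assemble a RegressionProblem from raw arrays (last column basal)."""
    design = np.asarray(design, float)
    L, p = design.shape
    columns = [ColumnLink("tf", f"c{k}") for k in range(p - 1)] + [ColumnLink("basal")]
    for k in mirna_cols:
        columns[k] = ColumnLink("mirna", f"m{k}")
    lower = np.full(p, -np.inf)
    upper = np.full(p, np.inf)
    lower[-1] = 0.0
    for k in mirna_cols:
        upper[k] = 0.0
    return RegressionProblem(node, kind, design, np.asarray(response, float),
                             columns, lower, upper)


class TestConstrainedLsq:
    def test_reduces_to_ols_when_bounds_inactive(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(50, 4))
        A[:, -1] = 1.0
        y = rng.normal(size=50) + 2.0  # positive intercept keeps basal bound slack
        problem = make_problem(A, y)
        theta, _ = g.constrained_lsq(problem)
        ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(theta, ols, atol=1e-10)

    def test_noiseless_feasible_truth_recovered_exactly(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(30, 3))
        A[:, -1] = 1.0
        truth = np.array([1.5, -0.7, 0.3])
        problem = make_problem(A, A @ truth)
        theta, sigma2 = g.constrained_lsq(problem)
        np.testing.assert_allclose(theta, truth, atol=1e-10)
        assert sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_active_bound_matches_grid_search(self):
        """Bounded optimum with an active miRNA sign constraint agrees
        with a dense feasible-region grid search."""
        rng = np.random.default_rng(2)
        A = np.column_stack([rng.normal(size=40), np.ones(40)])
        # true coefficient positive, but the miRNA bound forces <= 0
        y = A @ np.array([0.8, 1.0]) + 0.05 * rng.normal(size=40)
        problem = make_problem(A, y, mirna_cols=(0,))
        theta, _ = g.constrained_lsq(problem)
        ref = grid_search_lsq(A, y, problem.lower, problem.upper)
        assert theta[0] == pytest.approx(0.0, abs=1e-10)  # bound active
        np.testing.assert_allclose(theta, ref, atol=1e-4)

    def test_rank_deficient_design_is_reported(self):
        A = np.ones((10, 3))
        problem = make_problem(A, np.ones(10))
        with pytest.raises(g.RankDeficientError):
            g.constrained_lsq(problem)


class TestAic:
    @pytest.mark.parametrize(
        "sigma2,delta,L,expected",
        [(1.0, 0, 10, 0.0), (np.e, 10, 10, 3.0), (1.0, 5, 10, 1.0)],
    )
    def test_formula(self, sigma2, delta, L, expected):
        assert g.aic(sigma2, delta, L) == pytest.approx(expected)

    def test_floor_keeps_noiseless_fits_finite(self):
        assert np.isfinite(g.aic(0.0, 1, 10))


class TestStepwise:
    def test_strong_signal_matches_exhaustive_four_subsets(self):
        rng = np.random.default_rng(3)
        L = 200
        true_col = rng.normal(size=L)
        decoy = rng.normal(size=L)
        y = 3.0 * true_col + 0.1 * rng.normal(size=L) + 1.0
        problem = make_problem(
            np.column_stack([true_col, decoy, np.ones(L)]), y
        )
        model = g.stepwise_select(problem)
        best_aic, best_subset = exhaustive_best_subset_aic(problem)
        assert model.aic == pytest.approx(best_aic, abs=1e-9)
        assert {c for c in best_subset} == {
            i for i, c in enumerate(problem.columns) if c in model.theta
        }

    def test_matches_exhaustive_on_most_random_instances(self):
        """Stepwise is a local search: it can never beat the exhaustive
        best subset, and on small problems it should almost always tie."""
        wins = ties = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            L, p = 60, 6
            A = np.column_stack([rng.normal(size=(L, p - 1)), np.ones(L)])
            beta = np.where(rng.random(p - 1) < 0.4, rng.normal(size=p - 1), 0.0)
            y = A[:, :-1] @ beta + 1.0 + 0.5 * rng.normal(size=L)
            problem = make_problem(A, y)
            model = g.stepwise_select(problem)
            best_aic, _ = exhaustive_best_subset_aic(problem)
            assert model.aic >= best_aic - 1e-9
            if model.aic <= best_aic + 1e-9:
                ties += 1
            wins += 1
        assert ties / wins >= 0.9

    def test_null_inclusion_rate_follows_aic_law(self):
        """On pure-noise responses each independent decoy enters when its
        deviance gain exceeds the AIC penalty (chi2(1) > 2, ~15.7%)."""
        picked = 0
        total = 0
        for seed in range(100):
            rng = np.random.default_rng(200 + seed)
            L = 200
            A = np.column_stack([rng.normal(size=(L, 5)), np.ones(L)])
            y = 1.0 + rng.normal(size=L)
            model = g.stepwise_select(make_problem(A, y))
            picked += len(model.links)
            total += 5
        rate = picked / total
        expected = 0.157
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(rate - expected) < 4 * se

    def test_empty_candidate_set_returns_basal_only(self):
        problem = make_problem(np.ones((10, 1)), np.full(10, 2.0))
        model = g.stepwise_select(problem)
        assert model.links == [] and model.delta_star == 1
        assert model.basal == pytest.approx(2.0)


class TestPermutation:
    def _signal_model(self, L=100, seed=1):
        rng = np.random.default_rng(seed)
        col = rng.normal(size=L)
        noise_sd = 0.1
        y = 1.0 * col + 1.0 + noise_sd * rng.normal(size=L)  # effect 10x noise SD
        problem = make_problem(np.column_stack([col, np.ones(L)]), y)
        return g.stepwise_select(problem), problem

    def test_strong_signal_hits_the_floor(self):
        model, problem = self._signal_model()
        link = model.links[0]
        p = g.permutation_pvalue(model, problem, link, B=1000, seed=1)
        assert p == pytest.approx(1e-3)
        assert p <= 1e-3

    def test_all_zero_column_gives_p_one(self):
        L = 20
        design = np.column_stack([np.zeros(L), np.ones(L)])
        problem = make_problem(design, np.ones(L))
        link = problem.columns[0]
        model = g.NodeModel(
            node="n", kind="grn", links=[link], theta={link: 0.0},
            basal=1.0, sigma2=0.0, aic=g.aic(0.0, 2, L),
        )
        assert g.permutation_pvalue(model, problem, link, B=50, seed=0) == 1.0

    def test_invalid_permutation_count_rejected(self):
        model, problem = self._signal_model()
        with pytest.raises(ValueError, match="at least 1"):
            g.permutation_pvalues(model, problem, B=0)

    def test_unselected_link_rejected(self):
        model, problem = self._signal_model()
        with pytest.raises(ValueError, match="not in the selected set"):
            g.permutation_pvalue(model, problem, ColumnLink("tf", "nope"), B=10)


class TestIdentifyGen:
    def test_empty_candidate_network_yields_empty_gen(self, small_system):
        _, _, meth, expr = small_system
        empty = g.CandidateGEN(genes=set(expr.genes))
        gen = g.identify_gen(expr, meth, empty, B=0, seed=0)
        assert gen.n_ppi == 0 and gen.n_tf == 0 and gen.n_mirna == 0

    def test_noiseless_truth_candidate_recovered_exactly(self, small_identified):
        truth, _, _, _, gen = small_identified
        active = truth.active_edges()
        assert gen.retained_ppi == active["ppi"]
        assert gen.retained_tf == active["tf"]
        assert gen.retained_mirna == active["mirna"]

    def test_sign_constraints_hold_everywhere(self, pruning_benchmark):
        _, gen = pruning_benchmark
        for store in (gen.ppin, gen.grn):
            for model in store.values():
                assert model.basal >= -1e-9
                for link, value in model.theta.items():
                    if link.kind == "mirna":
                        assert value <= 1e-9  # c_iv = -value >= 0

    def test_retained_edges_subset_of_candidates(self, pruning_benchmark):
        scenario, gen = pruning_benchmark
        assert gen.retained_ppi <= scenario.candidate.ppi
        assert gen.retained_tf <= scenario.candidate.tf
        assert gen.retained_mirna <= scenario.candidate.mirna

    def test_estimator_rmse_shrinks_with_sample_size(self):
        truth = g.generate_truth_network(
            n_genes=20, n_mirnas=4, mean_tfs_per_gene=2,
            mean_partners_per_protein=3, mean_mirnas_per_gene=1, seed=31,
        )
        candidate = g.truth_candidate(truth)
        gene = next(n for n, m in truth.sink_nodes.items() if m == "grn")

        def rmse_at(L):
            errors = []
            for rep in range(3):
                meth = g.simulate_methylation(truth, L=L, seed=40 + rep)
                expr = g.simulate_expression(truth, meth, noise_sd=0.2, seed=50 + rep)
                problem = g.build_grn_problem(gene, expr, meth, candidate)
                theta, _ = g.constrained_lsq(problem)
                ref = []
                for c in problem.columns:
                    if c.kind == "tf":
                        ref.append(truth.true_tf[(c.source, gene)])
                    elif c.kind == "mirna":
                        ref.append(-truth.true_mirna[(c.source, gene)])
                    else:
                        ref.append(truth.basal_gene[gene])
                errors.append(np.sqrt(np.mean((theta - np.array(ref)) ** 2)))
            return float(np.mean(errors))

        rmse = [rmse_at(L) for L in (25, 50, 100, 200)]
        assert rmse[-1] < rmse[0]
        for prev, nxt in zip(rmse, rmse[1:]):
            assert nxt < prev * 1.15  # monotone within simulation error

    def test_serialization_round_trip(self, small_identified, tmp_path):
        *_, gen = small_identified
        e, n = tmp_path / "edges.tsv", tmp_path / "nodes.tsv"
        g.write_identified(gen, e, n)
        back = g.read_identified(e, n)
        assert back.retained_ppi == gen.retained_ppi
        assert back.retained_tf == gen.retained_tf
        assert back.retained_mirna == gen.retained_mirna
        for node, model in gen.grn.items():
            for link, value in model.theta.items():
                assert back.grn[node].theta[link] == pytest.approx(value, rel=1e-10)
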