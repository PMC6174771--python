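import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gennet as g

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_system():
    """Small noiseless system with candidate = (active) truth."""
    truth = g.generate_truth_network(
        n_genes=30, n_mirnas=6, mean_tfs_per_gene=2.0,
        mean_partners_per_protein=3.0, mean_mirnas_per_gene=1.5, seed=5,
    )
    candidate = g.truth_candidate(truth)
    meth = g.simulate_methylation(truth, L=40, seed=6)
    expr = g.simulate_expression(truth, meth, noise_sd=0.0, seed=7)
    return truth, candidate, meth, expr


@pytest.fixture(scope="session")
def small_identified(small_system):
    truth, candidate, meth, expr = small_system
    gen = g.identify_gen(expr, meth, candidate, B=0, seed=0)
    return truth, candidate, meth, expr, gen


@pytest.fixture(scope="session")
def pruning_benchmark():
    """The standard decoy-pruning benchmark (200 genes, decoy ratio 1,
    L = 100, noise at 10% of the expression spread, seed 1)."""
    scenario = g.benchmark_scenario(seed=1)
    gen = g.identify_gen(
        scenario.expression, scenario.methylation, scenario.candidate, B=0, seed=1
    )
    return scenario, gen


def tiny_expression(mrna: dict, mirna: dict | None = None, samples=None):
    """Build an ExpressionData from per-feature value lists."""
    any_row = next(iter(mrna.values()))
    samples = samples or [f"S{i}" for i in range(len(any_row))]
    mrna_df = pd.DataFrame({k: np.asarray(v, float) for k, v in mrna.items()}).T
    mrna_df.columns = samples
    mir_df = pd.DataFrame(
        {k: np.asarray(v, float) for k, v in (mirna or {}).items()}
    ).T
    if mirna:
        mir_df.columns = samples
    else:
        mir_df = pd.DataFrame(np.empty((0, len(samples))), columns=samples)
    return g.ExpressionData(mrna_df, mir_df)
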