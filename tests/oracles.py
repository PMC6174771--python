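"""Independent oracles used by the tests.

These deliberately re-derive quantities through routes different from
the package implementation (brute force, enumeration, dense grids),
so that agreement is an actual cross-check.
"""

from itertools import combinations

import numpy as np

import gennet as g


def exhaustive_best_subset_aic(problem):
    """Global AIC minimum over all link subsets (bounded fits).

    Feasible for small candidate counts only.  Returns (best_aic,
    best_subset) where the subset is a tuple of link column indices.
    """
    L = problem.n_samples
    links = problem.link_indices
    best = (np.inf, ())
    for size in range(len(links) + 1):
        for subset in combinations(links, size):
            try:
                _, s2 = g.constrained_lsq(problem, list(subset) + [problem.basal_index])
            except g.RankDeficientError:
                continue
            value = g.aic(s2, size + 1, L)
            if value < best[0] - 1e-12:
                best = (value, subset)
    return best


def grid_search_lsq(A, y, lower, upper, span=3.0, steps=241, refinements=3):
    """Dense feasible-region grid search for a 2-column bounded LS problem.

    Coarse-to-fine: each refinement shrinks the grid around the best
    point by 10x, reaching ~1e-4 resolution on the last pass.
    """
    lo = np.where(np.isfinite(lower), lower, -span)
    hi = np.where(np.isfinite(upper), upper, span)
    center = (lo + hi) / 2
    width = hi - lo
    best = None
    for _ in range(refinements):
        g0 = np.linspace(center[0] - width[0] / 2, center[0] + width[0] / 2, steps)
        g1 = np.linspace(center[1] - width[1] / 2, center[1] + width[1] / 2, steps)
        g0 = np.clip(g0, lower[0], upper[0])
        g1 = np.clip(g1, lower[1], upper[1])
        t0, t1 = np.meshgrid(g0, g1, indexing="ij")
        pred = A[:, 0][:, None, None] * t0[None] + A[:, 1][:, None, None] * t1[None]
        rss = ((pred - y[:, None, None]) ** 2).sum(axis=0)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        best = np.array([t0[i, j], t1[i, j]])
        center = best
        width = width / 10
    return best


def resample_truth_edges(n_genes, n_mirnas, mean_tfs, mean_partners, mean_mirnas, seed):
    """Independent re-implementation of the edge sampler's documented
    draw order (TF uniform matrix, then PPI, then miRNA)."""
    rng = np.random.default_rng(seed)
    tf_u = rng.random((n_genes, n_genes))
    p_tf = mean_tfs / (n_genes - 1)
    tf = {(j, i) for j in range(n_genes) for i in range(n_genes) if j != i and tf_u[j, i] < p_tf}
    ppi_u = rng.random((n_genes, n_genes))
    p_ppi = mean_partners / (n_genes - 1)
    ppi = {(i, j) for i, j in combinations(range(n_genes), 2) if ppi_u[i, j] < p_ppi}
    mir = set()
    if n_mirnas:
        mir_u = rng.random((n_mirnas, n_genes))
        p_mir = mean_mirnas / n_mirnas
        mir = {(v, i) for v in range(n_mirnas) for i in range(n_genes) if mir_u[v, i] < p_mir}
    return tf, ppi, mir
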