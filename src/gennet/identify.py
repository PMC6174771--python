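"""Identification of the real GEN from the candidate GEN.

For each node the candidate links define a constrained least-squares
regression (see :mod:`gennet.models`).  The true system order -- the
set of real links -- is detected by minimizing

    AIC(Delta) = log(sigma_hat^2) + 2 * Delta / L

over link subsets via stepwise selection (forward addition alternating
with backward elimination until no single move improves the criterion),
where sigma_hat^2 = ||residual||^2 / L and Delta counts the selected
links plus the always-present basal term.  Candidate links not in the
selected set are pruned as false positives.  Each retained link then
receives a permutation p-value: the response vector is permuted B times
across samples, the selected model refit, and the fraction of permuted
|estimates| at least as large as the observed one reported (floored at
1/B; ties count as exceedances).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .candidates import CandidateGEN, _ppi_key
from .data import ExpressionData, MethylationData
from .models import ColumnLink, RegressionProblem, build_grn_problem, build_ppin_problem

__all__ = [
    "RankDeficientError",
    "NodeModel",
    "IdentifiedGEN",
    "constrained_lsq",
    "aic",
    "stepwise_select",
    "permutation_pvalue",
    "permutation_pvalues",
    "identify_gen",
    "write_identified",
    "read_identified",
]

log = logging.getLogger(__name__)

#: floor inside the log of the AIC so that noiseless fits stay finite
SIGMA2_FLOOR = 1e-12

_BOUND_TOL = 1e-9


class RankDeficientError(ValueError):
    """Raised when the selected design columns are rank deficient."""

    def __init__(self, columns: Sequence[int]):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design over columns {self.columns}")


def _solve_bounded(A: np.ndarray, y: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                   check_rank: bool = True) -> np.ndarray:
    """Bounded least squares: fast unconstrained path, solver fallback.

    The ordinary (min-norm) solution is accepted whenever it is
    feasible, since it is then also the bounded optimum; otherwise a
    bounded-variable solver is used to the requested tolerance.
    """
    theta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if check_rank and rank < A.shape[1]:
        raise RankDeficientError(range(A.shape[1]))
    if np.all(theta >= lower - _BOUND_TOL) and np.all(theta <= upper + _BOUND_TOL):
        return np.clip(theta, lower, upper)
    method = "bvls" if rank == A.shape[1] and A.shape[0] >= A.shape[1] else "trf"
    res = lsq_linear(A, y, bounds=(lower, upper), method=method, tol=1e-12)
    return np.clip(res.x, lower, upper)


def constrained_lsq(
    problem: RegressionProblem, subset: Optional[Sequence[int]] = None
) -> tuple[np.ndarray, float]:
    """Solve min 1/2 ||Phi theta - Y||^2 subject to the per-column bounds.

    ``subset`` restricts the fit to the given column indices (defaults
    to all columns).  Returns the estimate over those columns and
    sigma_hat^2 = RSS / L.  A rank-deficient selected design raises
    :class:`RankDeficientError`; no regularization is applied.
    """
    cols = sorted(subset) if subset is not None else list(range(problem.design.shape[1]))
    A = problem.design[:, cols]
    theta = _solve_bounded(A, problem.response, problem.lower[cols], problem.upper[cols])
    resid = problem.response - A @ theta
    sigma2 = float(resid @ resid) / problem.n_samples
    return theta, sigma2


def aic(sigma2: float, delta: int, L: int) -> float:
    """Akaike information criterion log(sigma^2) + 2*Delta/L (natural log)."""
    if L < 1:
        raise ValueError("L must be at least 1")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    return float(np.log(max(sigma2, SIGMA2_FLOOR)) + 2.0 * delta / L)


@dataclass
class NodeModel:
    """Identified model of one node (protein or gene).

    ``theta`` maps each selected link descriptor to its raw regression
    coefficient (for miRNA links this is -c_iv <= 0); ``basal`` is h_i
    (PPIN) or kappa_i (GRN).  ``delta_star`` counts selected links plus
    the basal term.  ``tstats`` carries auxiliary analytic t-statistics
    from the unconstrained fit; pruning and reporting use the
    permutation p-values only.
    """

    node: str
    kind: str
    links: list[ColumnLink]
    theta: dict[ColumnLink, float]
    basal: float
    sigma2: float
    aic: float
    pvalues: dict[ColumnLink, float] = field(default_factory=dict)
    tstats: dict[ColumnLink, float] = field(default_factory=dict)

    @property
    def delta_star(self) -> int:
        return len(self.links) + 1

    def __post_init__(self):
        if self.basal < -_BOUND_TOL:
            raise ValueError("basal level must be non-negative")
        for link, value in self.theta.items():
            if link.kind == "mirna" and value > _BOUND_TOL:
                raise ValueError("miRNA coefficient must be non-positive (-c_iv <= 0)")


def _fit_subset(problem: RegressionProblem, links: list[int]) -> tuple[np.ndarray, float, list[int]]:
    cols = sorted(links) + [problem.basal_index]
    cols = sorted(cols)
    theta, sigma2 = constrained_lsq(problem, cols)
    return theta, sigma2, cols


def _analytic_tstats(
    problem: RegressionProblem, cols: list[int], theta: np.ndarray
) -> dict[ColumnLink, float]:
    """t = theta_hat / SE from the unconstrained normal equations (auxiliary)."""
    A = problem.design[:, cols]
    L, p = A.shape
    out: dict[ColumnLink, float] = {}
    if L <= p:
        return out
    try:
        cov = np.linalg.inv(A.T @ A)
    except np.linalg.LinAlgError:
        return out
    resid = problem.response - A @ theta
    s2 = float(resid @ resid) / (L - p)
    for pos, col in enumerate(cols):
        link = problem.columns[col]
        if link.kind == "basal":
            continue
        se = np.sqrt(max(s2 * cov[pos, pos], 0.0))
        out[link] = float(theta[pos] / se) if se > 0 else np.inf
    return out


def stepwise_select(problem: RegressionProblem) -> NodeModel:
    """Detect the node's true system order by stepwise AIC minimization.

    Starting from the basal-only model, alternate (i) adding the single
    candidate link whose inclusion most decreases the AIC with (ii) a
    backward sweep removing any selected link whose removal decreases
    it, until no single move improves the criterion.  The basal term is
    never removable; AIC ties break on the smallest column index, so
    the procedure is deterministic.  Candidate moves that would make
    the selected design rank deficient are not taken.
    """
    L = problem.n_samples
    selected: list[int] = []
    theta, sigma2, cols = _fit_subset(problem, selected)
    current_aic = aic(sigma2, 1, L)
    candidates = problem.link_indices

    def try_fit(links: list[int]) -> Optional[tuple[np.ndarray, float, list[int], float]]:
        try:
            th, s2, cs = _fit_subset(problem, links)
        except RankDeficientError:
            return None
        return th, s2, cs, aic(s2, len(links) + 1, L)

    improved = True
    while improved:
        improved = False
        # forward: best single addition (ties -> smallest column index)
        best = None
        for k in candidates:
            if k in selected:
                continue
            fit = try_fit(selected + [k])
            if fit is not None and (best is None or fit[3] < best[1][3]):
                best = (k, fit)
        if best is not None and best[1][3] < current_aic - 1e-12:
            selected.append(best[0])
            theta, sigma2, cols, current_aic = best[1]
            improved = True
        # backward sweep: drop links while any single removal decreases AIC
        changed = True
        while changed and selected:
            changed = False
            best_rm = None
            for k in sorted(selected):
                fit = try_fit([j for j in selected if j != k])
                if fit is not None and (best_rm is None or fit[3] < best_rm[1][3]):
                    best_rm = (k, fit)
            if best_rm is not None and best_rm[1][3] < current_aic - 1e-12:
                selected.remove(best_rm[0])
                theta, sigma2, cols, current_aic = best_rm[1]
                changed = True
                improved = True

    links = [problem.columns[c] for c in cols if problem.columns[c].kind != "basal"]
    theta_map = {
        problem.columns[c]: float(theta[pos])
        for pos, c in enumerate(cols)
        if problem.columns[c].kind != "basal"
    }
    basal = float(theta[cols.index(problem.basal_index)])
    return NodeModel(
        node=problem.node,
        kind=problem.kind,
        links=links,
        theta=theta_map,
        basal=basal,
        sigma2=sigma2,
        aic=current_aic,
        tstats=_analytic_tstats(problem, cols, theta),
    )


def _permute_and_refit(
    model: NodeModel, problem: RegressionProblem, B: int, rng: np.random.Generator
) -> dict[ColumnLink, np.ndarray]:
    """Permutation null: refit the selected model on permuted responses."""
    link_cols = [
        i for i, c in enumerate(problem.columns) if c in model.theta
    ]
    cols = sorted(link_cols + [problem.basal_index])
    A = problem.design[:, cols]
    lower, upper = problem.lower[cols], problem.upper[cols]
    stats: dict[ColumnLink, list[float]] = {problem.columns[c]: [] for c in cols
                                            if problem.columns[c].kind != "basal"}
    for _ in range(B):
        y = problem.response[rng.permutation(problem.n_samples)]
        th = _solve_bounded(A, y, lower, upper, check_rank=False)
        for pos, c in enumerate(cols):
            link = problem.columns[c]
            if link.kind != "basal":
                stats[link].append(abs(th[pos]))
    return {k: np.asarray(v) for k, v in stats.items()}


def permutation_pvalues(
    model: NodeModel,
    problem: RegressionProblem,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[ColumnLink, float]:
    """Permutation p-value for every selected link of a node model.

    p = #{permuted |estimate| >= observed |estimate|} / B, floored at
    1/B (zero exceedances report the floor); ties count as exceedances,
    which is conservative.
    """
    if B < 1:
        raise ValueError("permutation count B must be at least 1")
    if not model.links:
        return {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = _permute_and_refit(model, problem, B, rng)
    out = {}
    for link, value in model.theta.items():
        exceed = int(np.sum(null[link] >= abs(value)))
        out[link] = max(exceed, 1) / B
    return out


def permutation_pvalue(
    model: NodeModel,
    problem: RegressionProblem,
    link: ColumnLink,
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value of a single selected link (see above)."""
    if link not in model.theta:
        raise ValueError(f"link {link} is not in the selected set of {model.node}")
    return permutation_pvalues(model, problem, B=B, seed=seed)[link]


@dataclass
class IdentifiedGEN:
    """Per-node identified models plus aggregate retained-edge counts."""

    ppin: dict[str, NodeModel]
    grn: dict[str, NodeModel]
    genes: list[str]
    mirnas: list[str]

    @property
    def retained_ppi(self) -> set[tuple[str, str]]:
        """Unordered protein pairs retained in at least one endpoint's model."""
        pairs = set()
        for node, model in self.ppin.items():
            for link in model.links:
                pairs.add(_ppi_key(node, link.source))
        return pairs

    @property
    def retained_tf(self) -> set[tuple[str, str]]:
        return {
            (link.source, node)
            for node, model in self.grn.items()
            for link in model.links
            if link.kind == "tf"
        }

    @property
    def retained_mirna(self) -> set[tuple[str, str]]:
        return {
            (link.source, node)
            for node, model in self.grn.items()
            for link in model.links
            if link.kind == "mirna"
        }

    @property
    def n_ppi(self) -> int:
        return len(self.retained_ppi)

    @property
    def n_tf(self) -> int:
        return len(self.retained_tf)

    @property
    def n_mirna(self) -> int:
        return len(self.retained_mirna)


def identify_gen(
    expr: ExpressionData,
    meth: MethylationData,
    candidate: CandidateGEN,
    B: int = 1000,
    seed: int = 0,
    nodes: Optional[Iterable[str]] = None,
) -> IdentifiedGEN:
    """Prune the candidate GEN to the real GEN, node by node.

    For every modeled gene the PPIN and GRN problems are built,
    stepwise-selected and (for B >= 1) annotated with permutation
    p-values.  ``B = 0`` skips the permutation stage.  Fully
    deterministic given ``seed``: each node model draws from a
    seed derived from (seed, node position, model kind).
    """
    all_nodes = sorted(candidate.genes & set(expr.mrna.index))
    skipped = sorted(candidate.genes - set(expr.mrna.index))
    if skipped:
        log.warning("%d candidate genes missing from expression data", len(skipped))
    wanted = set(nodes) if nodes is not None else None
    ppin_models: dict[str, NodeModel] = {}
    grn_models: dict[str, NodeModel] = {}
    for idx, node in enumerate(all_nodes):
        if wanted is not None and node not in wanted:
            continue
        for kind_code, builder, store in (
            (0, lambda n: build_ppin_problem(n, expr, candidate), ppin_models),
            (1, lambda n: build_grn_problem(n, expr, meth, candidate), grn_models),
        ):
            try:
                problem = builder(node)
            except KeyError as exc:
                raise KeyError(f"node {node!r}: {exc}") from exc
            model = stepwise_select(problem)
            if B >= 1 and model.links:
                rng = np.random.default_rng(np.random.SeedSequence([seed, idx, kind_code]))
                model.pvalues = permutation_pvalues(model, problem, B=B, seed=rng)
            store[node] = model
    gen = IdentifiedGEN(
        ppin=ppin_models,
        grn=grn_models,
        genes=all_nodes if wanted is None else sorted(wanted & set(all_nodes)),
        mirnas=sorted(candidate.mirnas),
    )
    log.info(
        "identified GEN: %d PPIs, %d gene regulations, %d miRNA inhibitions",
        gen.n_ppi, gen.n_tf, gen.n_mirna,
    )
    return gen


# ---------------------------------------------------------------------------
# serialization: edge-list + per-node TSVs with round-trip readers
# ---------------------------------------------------------------------------

def write_identified(gen: IdentifiedGEN, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Write (source, target, edge_type, ability, p_value) edge rows and a
    per-node table (node, kind, basal, sigma2, delta_star, aic).

    PPI rows are written per node model (source = partner, target =
    modeled node), so both endpoints' abilities survive a round trip.
    """
    edge_rows = []
    node_rows = []
    for kind, store in (("ppin", gen.ppin), ("grn", gen.grn)):
        for node in sorted(store):
            model = store[node]
            node_rows.append((node, kind, model.basal, model.sigma2, model.delta_star, model.aic))
            for link in model.links:
                etype = {"partner": "ppi", "tf": "tf", "mirna": "mirna"}[link.kind]
                edge_rows.append(
                    (
                        link.source,
                        node,
                        etype,
                        model.theta[link],
                        model.pvalues.get(link, np.nan),
                    )
                )
    pd.DataFrame(
        edge_rows, columns=["source", "target", "edge_type", "ability", "p_value"]
    ).to_csv(edges_path, sep="\t", index=False, float_format="%.12g")
    pd.DataFrame(
        node_rows, columns=["node", "kind", "basal", "sigma2", "delta_star", "aic"]
    ).to_csv(nodes_path, sep="\t", index=False, float_format="%.12g")


def read_identified(edges_path: str | Path, nodes_path: str | Path) -> IdentifiedGEN:
    edges = pd.read_csv(edges_path, sep="\t", dtype={"source": str, "target": str})
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"node": str})
    ppin: dict[str, NodeModel] = {}
    grn: dict[str, NodeModel] = {}
    for row in nodes.itertuples(index=False):
        store = ppin if row.kind == "ppin" else grn
        store[row.node] = NodeModel(
            node=row.node,
            kind=row.kind,
            links=[],
            theta={},
            basal=float(row.basal),
            sigma2=float(row.sigma2),
            aic=float(row.aic),
        )
    mirnas = set()
    for row in edges.itertuples(index=False):
        kind = {"ppi": "partner", "tf": "tf", "mirna": "mirna"}[row.edge_type]
        link = ColumnLink(kind, row.source)
        store = ppin if row.edge_type == "ppi" else grn
        model = store[row.target]
        model.links.append(link)
        model.theta[link] = float(row.ability)
        if np.isfinite(row.p_value):
            model.pvalues[link] = float(row.p_value)
        if kind == "mirna":
            mirnas.add(row.source)
    genes = sorted(set(ppin) | set(grn))
    return IdentifiedGEN(ppin=ppin, grn=grn, genes=genes, mirnas=sorted(mirnas))
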