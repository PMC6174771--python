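"""Methylation-modulated regression models for the GEN.

Two per-node stochastic models are encoded as linear regression problems:

Protein interactive model (PPIN), for protein i over samples n = 1..L::

    y_i[n] = sum_{j in N_i} a_ij * y_i[n] * y_j[n] + h_i + v_i[n],   h_i >= 0

The product y_i*y_j stands for the collision probability of the two
interacting proteins; a_ij is the interaction ability and h_i the basal
level.  mRNA abundance is used as the proxy for protein abundance.

Gene regulatory model (GRN), for gene i::

    x_i[n] = sum_{j in K_i} b_ij * y_j[n] * M_i[n]
           - sum_{v in V_i} c_iv * x_i[n] * x_v^miR[n] * M_i[n]
           + M_i[n] * kappa_i + w_i[n],        kappa_i >= 0, c_iv >= 0

where M_i[n] = 1 / (1 + (m_i[n]/0.5)^2) is the methylation regulation:
it attenuates TF binding, miRNA binding and basal transcription as the
beta value m rises, from 1 (unmethylated) down to 0.2 (fully
methylated) -- never to zero, so binding is weakened but not shut off.

Each model is expressed as a :class:`RegressionProblem`: a design matrix
whose columns are elementwise products of the stated profiles, one
column per candidate link plus exactly one basal column, with per-column
sign bounds (miRNA parameters are fitted as -c_iv <= 0; basal levels are
fitted with a lower bound of 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .candidates import CandidateGEN
from .data import ExpressionData, MethylationData

__all__ = [
    "methylation_regulation",
    "RegressionProblem",
    "ColumnLink",
    "build_ppin_problem",
    "build_grn_problem",
]

#: link kinds a design column can represent
LINK_KINDS = ("partner", "tf", "mirna", "basal")


def methylation_regulation(m):
    """Attenuation factor M(m) = 1 / (1 + (m/0.5)^2) for beta values m.

    Maps [0,1] onto [0.2, 1], strictly decreasing; values outside [0,1]
    are clipped with a warning.  Accepts scalars or arrays.
    """
    arr = np.asarray(m, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("methylation beta values must be finite")
    if (arr < 0).any() or (arr > 1).any():
        warnings.warn("methylation beta values outside [0,1] were clipped")
        arr = np.clip(arr, 0.0, 1.0)
    out = 1.0 / (1.0 + (arr / 0.5) ** 2)
    return float(out) if np.isscalar(m) else out


@dataclass(frozen=True)
class ColumnLink:
    """Descriptor tying a design-matrix column to a network link.

    ``kind`` is one of ``partner`` (PPI partner protein), ``tf``,
    ``mirna`` or ``basal``; ``source`` is the partner/TF/miRNA id (None
    for the basal column).
    """

    kind: str
    source: Optional[str] = None

    def __post_init__(self):
        if self.kind not in LINK_KINDS:
            raise ValueError(f"unknown link kind {self.kind!r}")


@dataclass
class RegressionProblem:
    """A per-node constrained least-squares problem.

    ``design`` is L x (n_links + 1); ``columns[k]`` describes column k;
    ``lower``/``upper`` are the per-parameter sign bounds.
    """

    node: str
    kind: str  # "ppin" | "grn"
    design: np.ndarray
    response: np.ndarray
    columns: list[ColumnLink]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        L, p = self.design.shape
        if len(self.columns) != p or len(self.lower) != p or len(self.upper) != p:
            raise ValueError("column metadata does not match the design matrix")
        if sum(c.kind == "basal" for c in self.columns) != 1:
            raise ValueError("exactly one basal column is required")
        if self.response.shape != (L,):
            raise ValueError("response length does not match the design matrix")

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def basal_index(self) -> int:
        return next(i for i, c in enumerate(self.columns) if c.kind == "basal")

    @property
    def link_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.kind != "basal"]


def _expression_row(expr: ExpressionData, node: str) -> np.ndarray:
    if node not in expr.mrna.index:
        raise KeyError(f"feature {node!r} is missing from the expression matrix")
    return expr.mrna.loc[node].to_numpy(dtype=float)


def build_ppin_problem(
    node: str, expr: ExpressionData, candidate: CandidateGEN
) -> RegressionProblem:
    """Regression form of the protein interactive model for one protein.

    One column y_i*y_j per candidate partner j (sorted for determinism),
    plus a constant basal column with lower bound 0; the response is y_i.
    Partners absent from the expression matrix raise a KeyError.
    """
    y_i = _expression_row(expr, node)
    partners = candidate.partners(node)
    cols, links = [], []
    for j in partners:
        cols.append(y_i * _expression_row(expr, j))
        links.append(ColumnLink("partner", j))
    cols.append(np.ones_like(y_i))
    links.append(ColumnLink("basal"))
    design = np.column_stack(cols)
    lower = np.full(design.shape[1], -np.inf)
    upper = np.full(design.shape[1], np.inf)
    lower[-1] = 0.0  # h_i >= 0
    return RegressionProblem(node, "ppin", design, y_i, links, lower, upper)


def build_grn_problem(
    node: str,
    expr: ExpressionData,
    meth: MethylationData,
    candidate: CandidateGEN,
) -> RegressionProblem:
    """Regression form of the gene regulatory model for one gene.

    TF columns hold y_j*M_i, miRNA columns hold x_i*x_v^miR*M_i with the
    fitted parameter bounded above by 0 (it estimates -c_iv), and the
    basal column holds M_i with lower bound 0.  Genes without
    methylation coverage get M_i = 1 (no attenuation).
    """
    x_i = _expression_row(expr, node)
    if meth.covers(node):
        m_i = methylation_regulation(meth.profile(node))
    else:
        m_i = np.ones_like(x_i)
    cols, links = [], []
    for j in candidate.tfs_of(node):
        cols.append(_expression_row(expr, j) * m_i)
        links.append(ColumnLink("tf", j))
    mirna_cols = []
    for v in candidate.mirnas_of(node):
        if v not in expr.mirna.index:
            raise KeyError(f"miRNA {v!r} is missing from the expression matrix")
        cols.append(x_i * expr.mirna.loc[v].to_numpy(dtype=float) * m_i)
        links.append(ColumnLink("mirna", v))
        mirna_cols.append(len(cols) - 1)
    cols.append(m_i.copy())
    links.append(ColumnLink("basal"))
    design = np.column_stack(cols)
    lower = np.full(design.shape[1], -np.inf)
    upper = np.full(design.shape[1], np.inf)
    for k in mirna_cols:
        upper[k] = 0.0  # fitted parameter is -c_iv <= 0
    lower[-1] = 0.0  # kappa_i >= 0
    return RegressionProblem(node, "grn", design, x_i, links, lower, upper)
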