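"""Principal network projection (PNP): core-GEN extraction by SVD.

The identified GEN is flattened into a network structure matrix H of
shape (2N + V) x N: column i collects everything pointing at target
node i -- protein rows hold the retained interaction abilities a_ik,
TF rows the regulatory abilities b_ij and miRNA rows the (negative)
repression abilities -c_iv; absent links are exactly zero.  The
singular spectrum of H defines eigenexpression fractions
E_m = s_m^2 / sum s^2; the smallest M with cumulative fraction >= 0.85
fixes the principal network structure, and each row's alignment with it
is its dependent score D(k) = || h_k projected on the top-M right
singular subspace ||_2.  The core GEN is the top 5% of proteins by
D(k) plus their 1-hop neighbours through retained edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional

import numpy as np

from .identify import IdentifiedGEN

__all__ = [
    "ProjectionResult",
    "CoreGEN",
    "assemble_structure_matrix",
    "eigenexpression_fractions",
    "select_components",
    "dependent_scores",
    "extract_core",
    "project",
]


@dataclass
class CoreGEN:
    """Core network: selected proteins, their neighbours and induced edges."""

    selected_proteins: set[str]
    genes: set[str]          # all core gene-space nodes (includes the proteins)
    mirnas: set[str]
    edges: set[tuple[str, str, str]]  # (source, target, edge_type)

    @property
    def nodes(self) -> set[str]:
        return self.genes | self.mirnas


@dataclass
class ProjectionResult:
    structure_matrix: np.ndarray
    gene_index: list[str]
    mirna_index: list[str]
    singular_values: np.ndarray
    fractions: np.ndarray
    n_components: int
    dependent: np.ndarray           # D(k), k over proteins, genes, miRNAs
    core: Optional[CoreGEN] = None

    def row_label(self, k: int) -> tuple[str, str]:
        """(node id, class) of structure-matrix row k."""
        N = len(self.gene_index)
        if k < N:
            return self.gene_index[k], "protein"
        if k < 2 * N:
            return self.gene_index[k - N], "gene"
        return self.mirna_index[k - 2 * N], "mirna"


def assemble_structure_matrix(gen: IdentifiedGEN) -> np.ndarray:
    """Build the (2N + V) x N structure matrix of retained abilities.

    Row/column ordering follows ``gen.genes`` and ``gen.mirnas``
    (sorted).  For target column i: H[k, i] = a_ik (protein row k),
    H[N + j, i] = b_ij (TF row j), H[2N + v, i] = -c_iv (miRNA row v).
    """
    genes, mirnas = gen.genes, gen.mirnas
    N, V = len(genes), len(mirnas)
    gidx = {g: i for i, g in enumerate(genes)}
    midx = {m: v for v, m in enumerate(mirnas)}
    H = np.zeros((2 * N + V, N))
    for node, model in gen.ppin.items():
        for link in model.links:
            H[gidx[link.source], gidx[node]] = model.theta[link]
    for node, model in gen.grn.items():
        for link in model.links:
            if link.kind == "tf":
                H[N + gidx[link.source], gidx[node]] = model.theta[link]
            else:  # mirna: stored coefficient is already -c_iv
                H[2 * N + midx[link.source], gidx[node]] = model.theta[link]
    return H


def eigenexpression_fractions(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Singular values of H (descending) and fractions E_m = s_m^2 / sum s^2."""
    s = np.linalg.svd(H, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("structure matrix is all zero; spectrum undefined")
    return s, s**2 / total


def select_components(E: np.ndarray, threshold: float = 0.85) -> int:
    """Minimal M with cumulative eigenexpression fraction >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(E)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def dependent_scores(H: np.ndarray, M: int) -> np.ndarray:
    """D(k) = 2-norm of row k of H projected on the top-M right singular subspace.

    Invariant to the sign ambiguity of the singular vectors; with M
    equal to the full rank dimension it reduces to the row norms.
    """
    if not 1 <= M <= H.shape[1]:
        raise ValueError("M must lie in 1..N")
    _, _, vt = np.linalg.svd(H, full_matrices=False)
    P = H @ vt[:M].T  # p_{k,m} = h_k . r_m
    return np.sqrt(np.sum(P**2, axis=1))


def extract_core(
    gen: IdentifiedGEN, D: np.ndarray, top_fraction: float = 0.05
) -> CoreGEN:
    """Top-fraction proteins by dependent score plus connected neighbours.

    Selects the ceil(top_fraction * N) highest-scoring proteins (rows
    k <= N of D), including every protein tied with the cutoff value,
    then adds all genes and miRNAs adjacent to a selected protein
    through a retained edge.  Core edges are the retained edges with
    both endpoints in the core node set.
    """
    genes = gen.genes
    N = len(genes)
    scores = np.asarray(D[:N])
    n_top = max(1, ceil(top_fraction * N))
    cutoff = np.sort(scores)[::-1][n_top - 1]
    selected = {genes[i] for i in range(N) if scores[i] >= cutoff}

    core_genes = set(selected)
    core_mirnas: set[str] = set()
    ppi = gen.retained_ppi
    tf = gen.retained_tf
    mirna = gen.retained_mirna
    for p in selected:
        for a, b in ppi:
            if p in (a, b):
                core_genes.add(b if a == p else a)
        for t, g in tf:
            if p == g:
                core_genes.add(t)
            if p == t:
                core_genes.add(g)
        for m, g in mirna:
            if p == g:
                core_mirnas.add(m)

    edges = set()
    for a, b in ppi:
        if a in core_genes and b in core_genes:
            edges.add((a, b, "ppi"))
    for t, g in tf:
        if t in core_genes and g in core_genes:
            edges.add((t, g, "tf"))
    for m, g in mirna:
        if m in core_mirnas and g in core_genes:
            edges.add((m, g, "mirna"))
    return CoreGEN(
        selected_proteins=selected, genes=core_genes, mirnas=core_mirnas, edges=edges
    )


def project(
    gen: IdentifiedGEN, threshold: float = 0.85, top_fraction: float = 0.05
) -> ProjectionResult:
    """Full PNP pipeline: structure matrix -> spectrum -> scores -> core."""
    H = assemble_structure_matrix(gen)
    s, E = eigenexpression_fractions(H)
    M = select_components(E, threshold)
    D = dependent_scores(H, M)
    core = extract_core(gen, D, top_fraction)
    return ProjectionResult(
        structure_matrix=H,
        gene_index=gen.genes,
        mirna_index=gen.mirnas,
        singular_values=s,
        fractions=E,
        n_components=M,
        dependent=D,
        core=core,
    )
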