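"""Synthetic ground-truth GENs and matched expression/methylation data.

The generator produces data with exactly the statistical structure the
identification stage assumes, so that every downstream stage can be
exercised and benchmarked without any external download:

1. A ground-truth network is sampled with configurable mean candidate
   in-degrees (defaults follow the genome-wide candidate network the
   method targets: ~7.3 candidate TFs per gene and ~15.9 candidate PPI
   partners per protein).
2. Decoy (false-positive) edges are added to form a candidate GEN.
3. Beta-distributed methylation profiles are drawn, with optional
   per-gene hyper-/hypomethylation shifts between conditions.
4. Expression is generated from the protein interactive and gene
   regulatory models themselves plus Gaussian noise.

Both models are implicit in the response (the node's own profile
appears on both sides), so the generator solves the exact linear
rearrangement in closed form rather than iterating a fixed point:

* gene (GRN) sink:    x_i = (M_i * sum_j b_ij y_j + M_i kappa_i + w_i)
                          / (1 + M_i * sum_v c_iv x_v^miR)
* protein (PPIN) sink: y_i = (h_i + v_i) / (1 - sum_j a_ij y_j)

The network is layered: *source* nodes carry exogenous (lognormal)
profiles and *sink* nodes are computed from the model, each sink
through exactly one of the two mechanisms, with all of its regulators
drawn from the source layer.  Identification quality is therefore
evaluated on sink nodes, where the generating mechanism is known.
Sample columns whose PPIN denominator |1 - sum_j a_ij y_j| falls below
a guard of 0.2 are rejected and redrawn, which keeps the computed
profiles finite and well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .candidates import CandidateGEN, _ppi_key
from .data import ExpressionData, MethylationData
from .models import methylation_regulation

__all__ = [
    "SyntheticTruth",
    "generate_truth_network",
    "add_decoys",
    "simulate_methylation",
    "simulate_expression",
    "solve_grn_profile",
    "solve_ppin_profile",
    "truth_candidate",
]

#: guard on the PPIN denominator; samples closer to singularity are redrawn
DENOMINATOR_GUARD = 0.2

#: sigma of the lognormal exogenous expression profiles (positive,
#: right-skewed, expression-like; the marginal law of real preprocessed
#: expression is not prescribed anywhere, so this is an explicit stand-in)
EXOGENOUS_SIGMA = 0.5

# ability distributions for the ground truth
_PPI_ABILITY = (0.1, 0.4)     # |a_ij| before degree scaling, random sign
_TF_ABILITY = (0.5, 1.5)      # |b_ij|, random sign
_MIRNA_ABILITY = (0.3, 0.9)   # c_iv before degree scaling, >= 0
_BASAL = (0.5, 1.5)           # h_i, kappa_i >= 0


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _mirna_names(n: int) -> list[str]:
    return [f"MIR{v:03d}" for v in range(n)]


@dataclass
class SyntheticTruth:
    """Ground-truth GEN with generating abilities and sink bookkeeping.

    ``sink_nodes`` maps each modeled (computed) gene to the mechanism
    that generates its profile (``"ppin"`` or ``"grn"``); every other
    gene is an exogenous source.  True edges whose target is a sink of
    the matching mechanism actively shape the data; the remaining true
    edges are inactive and excluded from recovery benchmarks.
    """

    genes: list[str]
    mirnas: list[str]
    true_ppi: dict[tuple[str, str], float]      # unordered pair -> a_ij
    true_tf: dict[tuple[str, str], float]       # (TF, gene) -> b_ij
    true_mirna: dict[tuple[str, str], float]    # (miRNA, gene) -> c_iv >= 0
    basal_protein: dict[str, float]             # h_i >= 0
    basal_gene: dict[str, float]                # kappa_i >= 0
    sink_nodes: dict[str, str]                  # gene -> "ppin" | "grn"
    generation_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b) in self.true_ppi:
            if a == b:
                raise ValueError("self-pair in true PPI set")
        if any(c < 0 for c in self.true_mirna.values()):
            raise ValueError("miRNA inhibition abilities must be non-negative")
        if any(h < 0 for h in self.basal_protein.values()):
            raise ValueError("basal protein levels must be non-negative")
        if any(k < 0 for k in self.basal_gene.values()):
            raise ValueError("basal gene levels must be non-negative")

    # mechanism-relevant regulators of a sink (all guaranteed to be sources)
    def regulators_of(self, gene: str) -> list[str]:
        mech = self.sink_nodes.get(gene)
        if mech == "ppin":
            return sorted(b if a == gene else a for a, b in self.true_ppi if gene in (a, b))
        if mech == "grn":
            tfs = [t for t, g in self.true_tf if g == gene]
            mirs = [m for m, g in self.true_mirna if g == gene]
            return sorted(tfs) + sorted(mirs)
        return []

    def active_edges(self) -> dict[str, set[tuple[str, str]]]:
        """True edges that shaped the generated data, per edge class."""
        ppin_sinks = {g for g, m in self.sink_nodes.items() if m == "ppin"}
        grn_sinks = {g for g, m in self.sink_nodes.items() if m == "grn"}
        return {
            "ppi": {e for e in self.true_ppi if e[0] in ppin_sinks or e[1] in ppin_sinks},
            "tf": {e for e in self.true_tf if e[1] in grn_sinks},
            "mirna": {e for e in self.true_mirna if e[1] in grn_sinks},
        }


def generate_truth_network(
    n_genes: int = 200,
    n_mirnas: int = 30,
    mean_tfs_per_gene: float = 7.3,
    mean_partners_per_protein: float = 15.9,
    mean_mirnas_per_gene: float = 11.8,
    seed: int = 0,
) -> SyntheticTruth:
    """Sample a ground-truth GEN with the requested mean in-degrees.

    Edges are drawn by Poisson-thinned uniform (Bernoulli) sampling:
    each ordered TF pair j->i enters with probability
    ``mean_tfs_per_gene/(n_genes-1)``, each unordered protein pair with
    ``mean_partners_per_protein/(n_genes-1)`` and each miRNA->gene pair
    with ``mean_mirnas_per_gene/n_mirnas``, so the expected per-gene
    in-degrees equal the requested means.  The random draws are
    consumed in a documented order (TF uniform matrix, then PPI, then
    miRNA) so the sampler can be reproduced independently.

    After edge sampling, a single layer of sink nodes is chosen
    greedily (in seeded random order): a gene becomes a sink for one
    mechanism if it has at least one incoming true edge of that class
    and none of its regulators is itself a sink or already frozen as
    another sink's regulator.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be at least 2")
    for name, mean in (
        ("mean_tfs_per_gene", mean_tfs_per_gene),
        ("mean_partners_per_protein", mean_partners_per_protein),
        ("mean_mirnas_per_gene", mean_mirnas_per_gene),
    ):
        if mean < 0:
            raise ValueError(f"{name} must be non-negative")
    if mean_tfs_per_gene > n_genes - 1 or mean_partners_per_protein > n_genes - 1:
        raise ValueError("requested mean degree exceeds n_genes - 1")
    if n_mirnas and mean_mirnas_per_gene > n_mirnas:
        raise ValueError("requested mean miRNA in-degree exceeds n_mirnas")
    if n_mirnas == 0 and mean_mirnas_per_gene > 0:
        raise ValueError("mean_mirnas_per_gene > 0 requires n_mirnas > 0")

    genes = _gene_names(n_genes)
    mirnas = _mirna_names(n_mirnas)
    rng = np.random.default_rng(seed)

    # -- edge sampling (fixed draw order; see docstring) -----------------------
    p_tf = mean_tfs_per_gene / (n_genes - 1)
    tf_u = rng.random((n_genes, n_genes))
    tf_edges = [
        (genes[j], genes[i])
        for j in range(n_genes)
        for i in range(n_genes)
        if j != i and tf_u[j, i] < p_tf
    ]
    p_ppi = mean_partners_per_protein / (n_genes - 1)
    ppi_u = rng.random((n_genes, n_genes))
    ppi_edges = [
        (genes[i], genes[j])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if ppi_u[i, j] < p_ppi
    ]
    p_mir = mean_mirnas_per_gene / n_mirnas if n_mirnas else 0.0
    mir_u = rng.random((n_mirnas, n_genes))
    mir_edges = [
        (mirnas[v], genes[i])
        for v in range(n_mirnas)
        for i in range(n_genes)
        if mir_u[v, i] < p_mir
    ]

    tf_in: dict[str, set[str]] = {g: set() for g in genes}
    for t, g in tf_edges:
        tf_in[g].add(t)
    mir_in: dict[str, set[str]] = {g: set() for g in genes}
    for m, g in mir_edges:
        mir_in[g].add(m)
    ppi_nb: dict[str, set[str]] = {g: set() for g in genes}
    for a, b in ppi_edges:
        ppi_nb[a].add(b)
        ppi_nb[b].add(a)

    # -- greedy single-layer sink selection ------------------------------------
    sinks: dict[str, str] = {}
    frozen: set[str] = set()  # regulators of chosen sinks stay sources
    for idx in rng.permutation(n_genes):
        g = genes[idx]
        if g in frozen:
            continue
        sink_set = sinks.keys()
        options = []
        if (tf_in[g] or mir_in[g]) and not (tf_in[g] & sink_set):
            options.append("grn")
        if ppi_nb[g] and not (ppi_nb[g] & sink_set):
            options.append("ppin")
        if not options:
            continue
        mech = options[0] if len(options) == 1 else options[rng.integers(len(options))]
        sinks[g] = mech
        frozen |= tf_in[g] if mech == "grn" else ppi_nb[g]

    # -- generating abilities ---------------------------------------------------
    def _signed(lo: float, hi: float) -> float:
        return float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))

    # PPI abilities are scaled by sqrt(partner count) of the sink endpoint:
    # with random signs the interactive feedback sum_j a_ij y_j then has a
    # degree-independent spread well below 1 (keeping the closed-form solve
    # away from the denominator guard) while each individual edge keeps an
    # identifiable effect size
    def _ppi_scale(a: str, b: str) -> float:
        if sinks.get(a) == "ppin":
            d = len(ppi_nb[a])
        elif sinks.get(b) == "ppin":
            d = len(ppi_nb[b])
        else:
            d = max(len(ppi_nb[a]), len(ppi_nb[b]))
        return float(np.sqrt(max(1, d)))

    true_ppi = {
        _ppi_key(a, b): _signed(*_PPI_ABILITY) / _ppi_scale(a, b)
        for a, b in sorted(ppi_edges)
    }
    true_tf = {e: _signed(*_TF_ABILITY) for e in sorted(tf_edges)}
    # miRNA abilities get the same sqrt(in-degree) scaling: the aggregate
    # repression M * sum_v c_iv x_v then stays O(1) (no saturation of the
    # 1/(1 + ...) response) while each repression stays identifiable
    true_mirna = {
        (m, gg): float(rng.uniform(*_MIRNA_ABILITY)) / np.sqrt(max(1, len(mir_in[gg])))
        for m, gg in sorted(mir_edges)
    }
    basal_protein = {g: float(rng.uniform(*_BASAL)) for g in genes}
    basal_gene = {g: float(rng.uniform(*_BASAL)) for g in genes}

    config = dict(
        n_genes=n_genes,
        n_mirnas=n_mirnas,
        mean_tfs_per_gene=mean_tfs_per_gene,
        mean_partners_per_protein=mean_partners_per_protein,
        mean_mirnas_per_gene=mean_mirnas_per_gene,
        seed=seed,
    )
    return SyntheticTruth(
        genes=genes,
        mirnas=mirnas,
        true_ppi=true_ppi,
        true_tf=true_tf,
        true_mirna=true_mirna,
        basal_protein=basal_protein,
        basal_gene=basal_gene,
        sink_nodes=sinks,
        generation_config=config,
    )


def truth_candidate(truth: SyntheticTruth, active_only: bool = True) -> CandidateGEN:
    """The candidate GEN equal to the ground truth (no decoys).

    By default only the *active* true edges are included -- those whose
    target is a sink of the matching mechanism and which therefore
    shaped the generated data.  Inactive true edges point at exogenous
    (source) profiles, carry no signal, and are not identifiable even
    in principle.
    """
    edges = truth.active_edges() if active_only else {
        "ppi": set(truth.true_ppi),
        "tf": set(truth.true_tf),
        "mirna": set(truth.true_mirna),
    }
    return CandidateGEN(
        ppi=set(edges["ppi"]),
        tf=set(edges["tf"]),
        mirna=set(edges["mirna"]),
        genes=set(truth.genes),
        mirnas=set(truth.mirnas),
    )


def add_decoys(truth: SyntheticTruth, decoy_ratio: float, seed: int = 0) -> CandidateGEN:
    """Candidate GEN = true edges plus uniformly sampled decoy non-edges.

    Per edge class, ``round(decoy_ratio * n_true)`` decoys are drawn
    without replacement from the non-edges of that class (capped by
    availability).  Decoys are flagged on the returned candidate for
    evaluation purposes only.
    """
    if decoy_ratio < 0:
        raise ValueError("decoy_ratio must be non-negative")
    rng = np.random.default_rng(seed)
    genes, mirnas = truth.genes, truth.mirnas

    def sample_decoys(pool: list[tuple[str, str]], n_true: int) -> set[tuple[str, str]]:
        want = int(round(decoy_ratio * n_true))
        take = min(want, len(pool))
        if take == 0:
            return set()
        idx = rng.choice(len(pool), size=take, replace=False)
        return {pool[i] for i in idx}

    ppi_pool = sorted(
        _ppi_key(a, b)
        for i, a in enumerate(genes)
        for b in genes[i + 1 :]
        if _ppi_key(a, b) not in truth.true_ppi
    )
    tf_pool = sorted(
        (t, g) for t in genes for g in genes if t != g and (t, g) not in truth.true_tf
    )
    mir_pool = sorted(
        (m, g) for m in mirnas for g in genes if (m, g) not in truth.true_mirna
    )
    decoy_ppi = sample_decoys(ppi_pool, len(truth.true_ppi))
    decoy_tf = sample_decoys(tf_pool, len(truth.true_tf))
    decoy_mirna = sample_decoys(mir_pool, len(truth.true_mirna))

    return CandidateGEN(
        ppi=set(truth.true_ppi) | decoy_ppi,
        tf=set(truth.true_tf) | decoy_tf,
        mirna=set(truth.true_mirna) | decoy_mirna,
        genes=set(genes),
        mirnas=set(mirnas),
        decoys={"ppi": decoy_ppi, "tf": decoy_tf, "mirna": decoy_mirna},
    )


def simulate_methylation(
    truth: SyntheticTruth,
    L: int,
    beta_params: tuple[float, float] | Mapping[str, tuple[float, float]] = (2.0, 5.0),
    shifted_genes: Optional[Mapping[str, str]] = None,
    shift: float = 0.3,
    seed: int = 0,
) -> MethylationData:
    """Beta-distributed methylation profiles, optionally shifted per gene.

    ``beta_params`` is either one (a, b) shape pair for all genes or a
    per-gene mapping.  Genes in ``shifted_genes`` ("hyper" / "hypo")
    have their draws moved up/down by ``shift`` and clipped to [0, 1],
    emulating condition-specific hyper-/hypomethylation.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    shifted_genes = dict(shifted_genes or {})
    rng = np.random.default_rng(seed)
    rows = np.empty((len(truth.genes), L))
    for i, g in enumerate(truth.genes):
        a, b = beta_params[g] if isinstance(beta_params, Mapping) else beta_params
        if a <= 0 or b <= 0:
            raise ValueError("beta shape parameters must be positive")
        draw = rng.beta(a, b, size=L)
        direction = shifted_genes.get(g)
        if direction == "hyper":
            draw = draw + shift
        elif direction == "hypo":
            draw = draw - shift
        elif direction is not None:
            raise ValueError(f"unknown shift direction {direction!r} for gene {g}")
        rows[i] = np.clip(draw, 0.0, 1.0)
    samples = [f"S{n:04d}" for n in range(L)]
    return MethylationData(pd.DataFrame(rows, index=truth.genes, columns=samples))


def solve_grn_profile(b, y_tfs, c, x_mirs, m, kappa, omega):
    """Closed-form gene profile under the gene regulatory model.

    Parameters are the TF abilities ``b`` (K,), TF profiles ``y_tfs``
    (K, L), miRNA abilities ``c`` (V,) with profiles ``x_mirs`` (V, L),
    methylation betas ``m`` (L,), basal level ``kappa`` and noise
    ``omega`` (L,).  Solves
    x * (1 + M * sum_v c_v x_v) = M * sum_j b_j y_j + M * kappa + omega.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    y_tfs = np.atleast_2d(np.asarray(y_tfs, dtype=float))
    x_mirs = np.atleast_2d(np.asarray(x_mirs, dtype=float)) if c.size else np.zeros((0, len(m)))
    M = methylation_regulation(np.asarray(m, dtype=float))
    numer = M * (b @ y_tfs) + M * kappa + np.asarray(omega, dtype=float)
    denom = 1.0 + M * (c @ x_mirs if c.size else 0.0)
    return numer / denom


def solve_ppin_profile(a, y_partners, h, v):
    """Closed-form protein profile under the protein interactive model.

    Solves y * (1 - sum_j a_j y_j) = h + v given partner abilities
    ``a`` (J,) and partner profiles ``y_partners`` (J, L).  Raises if
    any sample denominator violates the guard |1 - sum| >= 0.2.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    y_partners = np.atleast_2d(np.asarray(y_partners, dtype=float))
    denom = 1.0 - a @ y_partners
    if np.any(np.abs(denom) < DENOMINATOR_GUARD):
        raise ValueError("PPIN denominator guard violated; use smaller |a_ij|")
    return (h + np.asarray(v, dtype=float)) / denom


def simulate_expression(
    truth: SyntheticTruth,
    methylation: MethylationData,
    L: Optional[int] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_redraw_rate: float = 0.5,
) -> ExpressionData:
    """Generate expression from the GEN models given methylation.

    Source genes and miRNAs get exogenous lognormal(0, 0.5^2) profiles;
    sink genes are solved in closed form from their generating model
    with Normal(0, noise_sd^2) noise.  Sample columns for which any
    PPIN sink's denominator |1 - sum_j a_ij y_j| < 0.2 are rejected and
    the whole column of exogenous draws is redrawn.  If more than
    ``max_redraw_rate`` of all drawn columns are rejected, generation
    aborts and advises smaller |a_ij| (the truth network is ill posed).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if L is None:
        L = len(methylation.samples)
    if L != len(methylation.samples):
        raise ValueError("L does not match the methylation sample count")
    missing = [g for g in truth.genes if not methylation.covers(g)]
    if missing:
        raise ValueError(f"methylation does not cover genes: {missing[:5]} ...")

    rng = np.random.default_rng(seed)
    genes = truth.genes
    sources = [g for g in genes if g not in truth.sink_nodes]
    ppin_sinks = sorted(g for g, m in truth.sink_nodes.items() if m == "ppin")
    grn_sinks = sorted(g for g, m in truth.sink_nodes.items() if m == "grn")

    src_idx = {g: i for i, g in enumerate(sources)}
    src = rng.lognormal(0.0, EXOGENOUS_SIGMA, size=(len(sources), L))
    mir = rng.lognormal(0.0, EXOGENOUS_SIGMA, size=(len(truth.mirnas), L))
    mir_idx = {m: i for i, m in enumerate(truth.mirnas)}

    # precompute PPIN sink partner structure
    partner_lists = {
        g: sorted(b if a == g else a for a, b in truth.true_ppi if g in (a, b))
        for g in ppin_sinks
    }

    def ppin_denominators() -> np.ndarray:
        d = np.empty((len(ppin_sinks), L))
        for r, g in enumerate(ppin_sinks):
            partners = partner_lists[g]
            a = np.array([truth.true_ppi[_ppi_key(g, j)] for j in partners])
            y = src[[src_idx[j] for j in partners], :]
            d[r] = 1.0 - a @ y
        return d

    # rejection loop: redraw whole columns violating the denominator guard
    total_drawn = L
    total_redrawn = 0
    while True:
        if ppin_sinks:
            denom = ppin_denominators()
            bad = np.flatnonzero((np.abs(denom) < DENOMINATOR_GUARD).any(axis=0))
        else:
            bad = np.array([], dtype=int)
        if bad.size == 0:
            break
        total_redrawn += bad.size
        total_drawn += bad.size
        if total_redrawn / total_drawn > max_redraw_rate:
            raise RuntimeError(
                "expression generation rejected more than "
                f"{max_redraw_rate:.0%} of sample draws; the truth network is "
                "ill posed -- use smaller |a_ij| interaction abilities"
            )
        src[:, bad] = rng.lognormal(0.0, EXOGENOUS_SIGMA, size=(len(sources), bad.size))
        mir[:, bad] = rng.lognormal(0.0, EXOGENOUS_SIGMA, size=(len(truth.mirnas), bad.size))

    samples = list(methylation.samples)
    expr = pd.DataFrame(0.0, index=genes, columns=samples)
    for g in sources:
        expr.loc[g] = src[src_idx[g]]

    # noise draws in sorted sink order (deterministic given seed)
    noise = {
        g: (rng.normal(0.0, noise_sd, size=L) if noise_sd > 0 else np.zeros(L))
        for g in sorted(truth.sink_nodes)
    }

    for g in ppin_sinks:
        partners = partner_lists[g]
        a = np.array([truth.true_ppi[_ppi_key(g, j)] for j in partners])
        y = src[[src_idx[j] for j in partners], :]
        expr.loc[g] = solve_ppin_profile(a, y, truth.basal_protein[g], noise[g])

    for g in grn_sinks:
        tfs = sorted(t for t, gg in truth.true_tf if gg == g)
        mirs = sorted(m for m, gg in truth.true_mirna if gg == g)
        b = np.array([truth.true_tf[(t, g)] for t in tfs])
        c = np.array([truth.true_mirna[(m, g)] for m in mirs])
        y = src[[src_idx[t] for t in tfs], :] if tfs else np.zeros((0, L))
        xm = mir[[mir_idx[m] for m in mirs], :] if mirs else np.zeros((0, L))
        expr.loc[g] = solve_grn_profile(
            b, y, c, xm, methylation.beta.loc[g].to_numpy(), truth.basal_gene[g], noise[g]
        )

    mirna_frame = pd.DataFrame(mir, index=truth.mirnas, columns=samples)
    return ExpressionData(expr, mirna_frame)
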