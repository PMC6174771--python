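"""Recovery benchmarks of the identification stage on synthetic truth.

A benchmark scenario draws a ground-truth network, a decoy-diluted
candidate GEN and expression/methylation matrices, with the noise
standard deviation set as a fraction of the noiseless expression
signal's spread.  Recovery is scored on the *evaluable* candidate
edges: those whose target node is a sink generated by the matching
mechanism (PPI edges at protein-model sinks; TF and miRNA edges at
gene-model sinks), since only there does the ground truth define which
links shaped the data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidates import CandidateGEN
from .data import ExpressionData, MethylationData
from .identify import IdentifiedGEN
from .simulate import (
    SyntheticTruth,
    add_decoys,
    generate_truth_network,
    simulate_expression,
    simulate_methylation,
)

__all__ = ["Scenario", "benchmark_scenario", "edge_recovery"]


@dataclass
class Scenario:
    truth: SyntheticTruth
    candidate: CandidateGEN
    expression: ExpressionData
    methylation: MethylationData
    noise_sd: float


def benchmark_scenario(
    n_genes: int = 200,
    n_mirnas: int = 30,
    L: int = 100,
    decoy_ratio: float = 1.0,
    noise_frac: float = 0.1,
    seed: int = 1,
    mean_tfs_per_gene: float = 7.3,
    mean_partners_per_protein: float = 15.9,
    mean_mirnas_per_gene: float = 11.8,
) -> Scenario:
    """Standard recovery benchmark: decoy-diluted candidates, noisy data.

    ``noise_frac`` scales the noise: the scenario is first generated
    noiselessly, the pooled standard deviation of the expression matrix
    measured, and the data regenerated (same seeds) with
    noise_sd = noise_frac * that spread.
    """
    truth = generate_truth_network(
        n_genes=n_genes,
        n_mirnas=n_mirnas,
        mean_tfs_per_gene=mean_tfs_per_gene,
        mean_partners_per_protein=mean_partners_per_protein,
        mean_mirnas_per_gene=mean_mirnas_per_gene,
        seed=seed,
    )
    candidate = add_decoys(truth, decoy_ratio, seed=seed + 1)
    meth = simulate_methylation(truth, L=L, seed=seed + 2)
    clean = simulate_expression(truth, meth, noise_sd=0.0, seed=seed + 3)
    noise_sd = float(noise_frac * clean.mrna.to_numpy().std())
    expr = (
        clean
        if noise_sd == 0.0
        else simulate_expression(truth, meth, noise_sd=noise_sd, seed=seed + 3)
    )
    return Scenario(truth, candidate, expr, meth, noise_sd)


def edge_recovery(
    identified: IdentifiedGEN, truth: SyntheticTruth, candidate: CandidateGEN
) -> dict:
    """Precision/recall/F1 of retained vs true edges on evaluable targets.

    Positives are the active true edges (see
    :meth:`SyntheticTruth.active_edges`); predictions are the links the
    matching sink-node models retained among the evaluable candidates.
    """
    ppin_sinks = {g for g, m in truth.sink_nodes.items() if m == "ppin"}
    grn_sinks = {g for g, m in truth.sink_nodes.items() if m == "grn"}
    active = truth.active_edges()

    # PPI pairs are undirected: a pair counts as retained when either
    # endpoint's model keeps it (that is what the GEN-level count N_P uses)
    predicted: dict[str, set] = {"ppi": set(identified.retained_ppi), "tf": set(), "mirna": set()}
    for node in grn_sinks:
        model = identified.grn.get(node)
        if model:
            for l in model.links:
                predicted["tf" if l.kind == "tf" else "mirna"].add((l.source, node))

    evaluable = {
        "ppi": {e for e in candidate.ppi if e[0] in ppin_sinks or e[1] in ppin_sinks},
        "tf": {e for e in candidate.tf if e[1] in grn_sinks},
        "mirna": {e for e in candidate.mirna if e[1] in grn_sinks},
    }

    out: dict = {}
    tp_all = fp_all = fn_all = 0
    for cls in ("ppi", "tf", "mirna"):
        pos = active[cls] & evaluable[cls]
        pred = predicted[cls] & evaluable[cls]
        tp = len(pred & pos)
        fp = len(pred - pos)
        fn = len(pos - pred)
        tp_all, fp_all, fn_all = tp_all + tp, fp_all + fp, fn_all + fn
        out[cls] = _prf(tp, fp, fn)
    out["overall"] = _prf(tp_all, fp_all, fn_all)
    out["n_evaluable_sinks"] = len(ppin_sinks) + len(grn_sinks)
    return out


def _prf(tp: int, fp: int, fn: int) -> dict:
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}
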