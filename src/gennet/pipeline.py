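"""End-to-end orchestration: simulate -> identify -> project -> compare.

A :class:`RunConfig` fully determines a run: the whole artifact bundle
is a pure function of the configuration (every stochastic stage draws
from a seed derived deterministically from the master seed), and a
rerun with the same configuration reproduces the output files
bit-identically (verified through the checksums in the manifest).

Also provides the k-fold consistency analysis: samples are split into
k near-equal folds, identification is repeated on the complement of
each fold, and the fraction of edges selected in all k repetitions
(out of those selected in at least one) is reported per edge class.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import yaml

from .candidates import CandidateGEN, write_gen_tsv
from .compare import (
    ConditionComparison,
    basal_shift,
    compare_core_gens,
    differential_table,
)
from .data import ExpressionData, MethylationData
from .identify import IdentifiedGEN, identify_gen, write_identified
from .projection import CoreGEN, ProjectionResult, project
from .simulate import (
    SyntheticTruth,
    add_decoys,
    generate_truth_network,
    simulate_expression,
    simulate_methylation,
)

__all__ = [
    "RunConfig",
    "RunBundle",
    "run_pipeline",
    "kfold_consistency",
    "fold_sizes",
    "export_network",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a two-condition synthetic study.

    Defaults follow the scaled-down study shape (200 genes, 30 miRNAs,
    60 samples per condition) with candidate in-degrees matching the
    genome-wide candidate network (7.3 TFs and 15.9 PPI partners on
    average; 11.8 candidate miRNAs per gene, the ratio of candidate
    miRNA repressions to regulated genes).
    """

    n_genes: int = 200
    n_mirnas: int = 30
    mean_tfs_per_gene: float = 7.3
    mean_partners_per_protein: float = 15.9
    mean_mirnas_per_gene: float = 11.8
    samples_per_condition: int = 60
    decoy_ratio: float = 1.0
    noise_sd: float = 0.05
    beta_params: tuple[float, float] = (2.0, 5.0)
    methylation_shift: float = 0.3
    n_hyper: int = 5
    n_hypo: int = 5
    shifted_genes: Optional[dict[str, str]] = None  # overrides n_hyper/n_hypo
    b_permutations: int = 0
    compare_b_perm: int = 1000
    pnp_threshold: float = 0.85
    top_fraction: float = 0.05
    kfold: int = 0  # 0 disables the consistency analysis
    kfold_train_on_complement: bool = True
    seed: int = 1
    outdir: Optional[str] = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("beta_params") is not None:
            raw["beta_params"] = tuple(raw["beta_params"])
        return cls(**raw)


@dataclass
class RunBundle:
    config: RunConfig
    truth: SyntheticTruth
    candidate: CandidateGEN
    expression: dict[str, ExpressionData]
    methylation: dict[str, MethylationData]
    identified: dict[str, IdentifiedGEN]
    projections: dict[str, ProjectionResult]
    comparison: ConditionComparison
    consistency: Optional[dict] = None
    manifest: Optional[dict] = None


def _stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunBundle:
    """Execute the full stage graph on two synthetic conditions A and B.

    Both conditions share one ground-truth network and candidate GEN;
    condition B applies the configured hyper/hypomethylation shifts.
    When ``config.outdir`` is set, all intermediate artifacts are
    written as TSV/YAML with SHA-256 checksums in ``manifest.json``.
    """
    seed = config.seed
    truth = generate_truth_network(
        n_genes=config.n_genes,
        n_mirnas=config.n_mirnas,
        mean_tfs_per_gene=config.mean_tfs_per_gene,
        mean_partners_per_protein=config.mean_partners_per_protein,
        mean_mirnas_per_gene=config.mean_mirnas_per_gene,
        seed=_stage_seed(seed, "truth"),
    )
    candidate = add_decoys(truth, config.decoy_ratio, seed=_stage_seed(seed, "decoys"))

    shifted = config.shifted_genes
    if shifted is None:
        # shift methylation of GRN-modeled sinks so the shift is identifiable
        grn_sinks = sorted(g for g, m in truth.sink_nodes.items() if m == "grn")
        rng = np.random.default_rng(_stage_seed(seed, "shift-pick"))
        picked = list(rng.permutation(grn_sinks))
        shifted = {g: "hyper" for g in picked[: config.n_hyper]}
        shifted.update({g: "hypo" for g in picked[config.n_hyper : config.n_hyper + config.n_hypo]})

    expression, methylation, identified, projections = {}, {}, {}, {}
    for cond, cond_shift in (("A", {}), ("B", shifted)):
        meth = simulate_methylation(
            truth,
            L=config.samples_per_condition,
            beta_params=config.beta_params,
            shifted_genes=cond_shift,
            shift=config.methylation_shift,
            seed=_stage_seed(seed, f"meth-{cond}"),
        )
        expr = simulate_expression(
            truth, meth, noise_sd=config.noise_sd, seed=_stage_seed(seed, f"expr-{cond}")
        )
        gen = identify_gen(
            expr, meth, candidate,
            B=config.b_permutations,
            seed=_stage_seed(seed, f"identify-{cond}"),
        )
        log.info(
            "condition %s: retained %d PPIs, %d regulations, %d miRNA inhibitions",
            cond, gen.n_ppi, gen.n_tf, gen.n_mirna,
        )
        methylation[cond], expression[cond], identified[cond] = meth, expr, gen
        projections[cond] = project(gen, config.pnp_threshold, config.top_fraction)

    comparison = compare_core_gens(projections["A"].core, projections["B"].core)
    compare_genes = sorted(shifted)
    comparison.expression = differential_table(
        expression["A"].mrna, expression["B"].mrna, features=compare_genes,
        B_perm=config.compare_b_perm, seed=_stage_seed(seed, "diff-expr"),
    )
    comparison.methylation = differential_table(
        methylation["A"].beta, methylation["B"].beta, features=compare_genes,
        B_perm=config.compare_b_perm, seed=_stage_seed(seed, "diff-meth"),
    )
    if len(comparison.methylation):
        direction = np.where(
            comparison.methylation.mean_b > comparison.methylation.mean_a, "hyper", "hypo"
        )
        comparison.methylation["direction"] = np.where(
            np.isclose(comparison.methylation.mean_b, comparison.methylation.mean_a,
                       rtol=0, atol=1e-12),
            "none", direction,
        )
    comparison.basal = basal_shift(identified["A"], identified["B"])

    consistency = None
    if config.kfold:
        consistency = kfold_consistency(
            expression["A"], methylation["A"], candidate,
            k=config.kfold,
            seed=_stage_seed(seed, "kfold"),
            train_on_complement=config.kfold_train_on_complement,
        )

    bundle = RunBundle(
        config=config, truth=truth, candidate=candidate,
        expression=expression, methylation=methylation,
        identified=identified, projections=projections,
        comparison=comparison, consistency=consistency,
    )
    if config.outdir is not None:
        bundle.manifest = _write_bundle(bundle, Path(config.outdir))
    return bundle


def _write_bundle(bundle: RunBundle, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    config = bundle.config
    # the output location is not a scientific parameter: leaving it out keeps
    # reruns into different directories bit-identical
    dataclasses.replace(config, outdir=None).to_yaml(outdir / "config.yaml")
    write_gen_tsv(bundle.candidate, outdir / "candidate_gen.tsv")
    for cond in bundle.identified:
        bundle.expression[cond].write(
            outdir / f"expression_{cond}.tsv", outdir / f"mirna_{cond}.tsv"
        )
        bundle.methylation[cond].write(outdir / f"methylation_{cond}.tsv")
        write_identified(
            bundle.identified[cond],
            outdir / f"identified_edges_{cond}.tsv",
            outdir / f"identified_nodes_{cond}.tsv",
        )
        proj = bundle.projections[cond]
        _write_dependent_scores(proj, outdir / f"dependent_scores_{cond}.tsv")
        export_network(proj.core, outdir / f"core_{cond}.sif", "sif")
    for name, frame in (
        ("diff_expression.tsv", bundle.comparison.expression),
        ("diff_methylation.tsv", bundle.comparison.methylation),
        ("basal_shift.tsv", bundle.comparison.basal),
    ):
        if frame is not None:
            frame.to_csv(outdir / name, sep="\t", float_format="%.10g")
    if bundle.consistency is not None:
        (outdir / "kfold_consistency.json").write_text(
            json.dumps(bundle.consistency, indent=2, sort_keys=True) + "\n"
        )
    manifest = {
        "seed": config.seed,
        "edge_counts": {
            cond: {
                "ppi": gen.n_ppi, "tf": gen.n_tf, "mirna": gen.n_mirna,
                "pruned_ppi": len(bundle.candidate.ppi) - gen.n_ppi,
                "pruned_tf": len(bundle.candidate.tf) - gen.n_tf,
                "pruned_mirna": len(bundle.candidate.mirna) - gen.n_mirna,
            }
            for cond, gen in bundle.identified.items()
        },
        "checksums": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_dependent_scores(proj: ProjectionResult, path: Path) -> None:
    rows = []
    for k in range(len(proj.dependent)):
        node, cls = proj.row_label(k)
        selected = cls == "protein" and node in proj.core.selected_proteins
        rows.append(f"{node}\t{cls}\t{proj.dependent[k]:.10g}\t{int(selected)}")
    path.write_text("node\tclass\tscore\tselected\n" + "\n".join(rows) + "\n")


def fold_sizes(L: int, k: int) -> list[int]:
    """Near-equal fold sizes (differing by at most one, larger folds last)."""
    base, rem = divmod(L, k)
    return [base] * (k - rem) + [base + 1] * rem


def kfold_consistency(
    expr: ExpressionData,
    meth: MethylationData,
    candidate: CandidateGEN,
    k: int = 10,
    seed: int = 0,
    train_on_complement: bool = True,
    B: int = 0,
) -> dict:
    """Selection consistency of identification across k resampled runs.

    Samples are shuffled and split into k near-equal folds; repetition
    r identifies the GEN on the complement of fold r (set
    ``train_on_complement=False`` to fit on the fold itself).
    Consistency per edge class = |edges selected in all k runs| /
    |edges selected in >= 1 run|, reported for the PPIN and for the GRN
    (TF and miRNA regulations pooled).
    """
    L = expr.n_samples
    if L < 2 * k:
        raise ValueError(f"k-fold consistency needs L >= 2k (got L={L}, k={k})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(L)
    sizes = fold_sizes(L, k)
    folds, start = [], 0
    for size in sizes:
        folds.append(order[start : start + size])
        start += size

    samples = np.asarray(expr.samples)
    ppi_runs, grn_runs = [], []
    for r in range(k):
        if train_on_complement:
            keep = np.concatenate([folds[j] for j in range(k) if j != r])
        else:
            keep = folds[r]
        sub_expr = expr.subset_samples(samples[np.sort(keep)])
        sub_meth = meth.subset_samples(samples[np.sort(keep)])
        gen = identify_gen(sub_expr, sub_meth, candidate, B=B, seed=seed)
        ppi_runs.append(gen.retained_ppi)
        grn_runs.append(gen.retained_tf | gen.retained_mirna)

    def ratio(runs):
        union = set().union(*runs)
        inter = set.intersection(*runs)
        return {
            "consistency": len(inter) / len(union) if union else 1.0,
            "always_selected": len(inter),
            "ever_selected": len(union),
        }

    return {"ppin": ratio(ppi_runs), "grn": ratio(grn_runs), "k": k,
            "fold_sizes": sizes}


def export_network(network, path: str | Path, fmt: str = "tsv") -> None:
    """Export an identified GEN or a core GEN as tsv, graphml or sif.

    TSV export of an identified GEN is lossless (an adjacent
    ``*.nodes.tsv`` carries the per-node models); GraphML and SIF carry
    ability, p-value and edge-type attributes where available.
    """
    path = Path(path)
    if network is None:
        raise ValueError("cannot export a null network")
    if fmt not in ("tsv", "graphml", "sif"):
        raise ValueError(f"unknown export format {fmt!r}")

    if isinstance(network, IdentifiedGEN):
        rows = []
        for node, model in sorted(network.ppin.items()):
            for link in sorted(model.links, key=lambda l: l.source):
                rows.append((link.source, node, "ppi", model.theta[link],
                             model.pvalues.get(link, float("nan"))))
        for node, model in sorted(network.grn.items()):
            for link in sorted(model.links, key=lambda l: (l.kind, l.source)):
                etype = "tf" if link.kind == "tf" else "mirna"
                rows.append((link.source, node, etype, model.theta[link],
                             model.pvalues.get(link, float("nan"))))
    elif isinstance(network, CoreGEN):
        rows = [(s, t, e, float("nan"), float("nan")) for s, t, e in sorted(network.edges)]
    else:
        raise TypeError(f"cannot export {type(network).__name__}")

    if fmt == "tsv":
        if isinstance(network, IdentifiedGEN):
            write_identified(network, path, path.with_suffix(".nodes.tsv"))
        else:
            lines = ["source\ttarget\tedge_type"]
            lines += [f"{s}\t{t}\t{e}" for s, t, e, *_ in rows]
            path.write_text("\n".join(lines) + "\n")
    elif fmt == "sif":
        path.write_text("".join(f"{s}\t{e}\t{t}\n" for s, t, e, *_ in rows))
    else:  # graphml
        g = nx.DiGraph()
        for s, t, e, ability, p in rows:
            attrs = {"edge_type": e}
            if np.isfinite(ability):
                attrs["ability"] = float(ability)
            if np.isfinite(p):
                attrs["p_value"] = float(p)
            g.add_edge(s, t, **attrs)
        nx.write_graphml(g, path)
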