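#!/usr/bin/env python
"""Compare the two conditions: expression, methylation, basal levels, cores.

For the genes whose methylation was shifted in condition B, runs the
differential expression and methylation permutation tests, calls the
hyper/hypo direction from the mean beta change, tabulates the
basal-level (kappa) shifts of the identified gene models, and
partitions the two core GENs into common and condition-specific parts.
"""

import sys
from pathlib import Path

import pandas as pd

import gennet as g
from gennet.projection import CoreGEN

STUDY = Path("results/study")
DATA = Path("scratch/study")  # matrices written by 01_simulate_cohorts.py


def read_core(path: Path) -> CoreGEN:
    edges = set()
    for line in path.read_text().splitlines():
        source, etype, target = line.split("\t")
        edges.add((source, target, etype))
    mirnas = {s for s, _, e in edges if e == "mirna"}
    genes = {n for s, t, e in edges for n in ((t,) if e == "mirna" else (s, t))}
    return CoreGEN(selected_proteins=set(), genes=genes, mirnas=mirnas, edges=edges)


def main() -> int:
    config = g.RunConfig.from_yaml(STUDY / "study_config.yaml")
    shifted = pd.read_csv(STUDY / "shifted_genes.tsv", sep="\t")
    genes = sorted(shifted.gene)

    data = {}
    for cond in ("A", "B"):
        data[cond] = (
            g.ExpressionData.read(DATA / f"expression_{cond}.tsv", DATA / f"mirna_{cond}.tsv"),
            g.MethylationData.read(DATA / f"methylation_{cond}.tsv"),
            g.read_identified(STUDY / f"identified_edges_{cond}.tsv",
                              STUDY / f"identified_nodes_{cond}.tsv"),
        )

    diff_expr = g.differential_table(
        data["A"][0].mrna, data["B"][0].mrna, features=genes,
        B_perm=config.compare_b_perm, seed=config.seed,
    )
    diff_meth = g.differential_table(
        data["A"][1].beta, data["B"][1].beta, features=genes,
        B_perm=config.compare_b_perm, seed=config.seed,
    )
    calls = {
        gene: g.call_methylation_direction(
            data["A"][1], data["B"][1], gene,
            B_perm=config.compare_b_perm, seed=config.seed,
        )[0]
        for gene in genes
    }
    diff_meth["direction"] = [calls[gene] for gene in diff_meth.index]
    diff_expr.to_csv(STUDY / "diff_expression.tsv", sep="\t", float_format="%.6g")
    diff_meth.to_csv(STUDY / "diff_methylation.tsv", sep="\t", float_format="%.6g")

    basal = g.basal_shift(data["A"][2], data["B"][2])
    basal.to_csv(STUDY / "basal_shift.tsv", sep="\t", float_format="%.6g")

    core_a = read_core(STUDY / "core_A.sif")
    core_b = read_core(STUDY / "core_B.sif")
    cmp = g.compare_core_gens(core_a, core_b)

    print("shifted genes (direction call, methylation p, expression p, delta kappa):")
    for gene in genes:
        dk = basal.delta_kappa.get(gene, float("nan"))
        print(f"  {gene}: {calls[gene]:5s}  p_meth={diff_meth.p_value[gene]:.3g}  "
              f"p_expr={diff_expr.p_value[gene]:.3g}  dkappa={dk:+.3f}")
    print(f"core-GEN edge partition: {len(cmp.edges_a_only)} A-specific, "
          f"{len(cmp.edges_common)} common, {len(cmp.edges_b_only)} B-specific")
    print(f"core-GEN node partition: {len(cmp.nodes_a_only)} A-specific, "
          f"{len(cmp.nodes_common)} common, {len(cmp.nodes_b_only)} B-specific")
    print(f"comparison tables written to {STUDY}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
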