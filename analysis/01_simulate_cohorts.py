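#!/usr/bin/env python
"""Generate and write the synthetic two-condition study data.

Draws one ground-truth genetic-and-epigenetic network, dilutes it with
an equal number of decoy edges to form the candidate network, and
simulates methylation + expression for two conditions: A (baseline)
and B, in which a set of gene-model sinks undergoes hyper- or
hypomethylation.  All matrices and edge tables land in results/study/
as TSV; later scripts read them from there.
"""

import sys
from pathlib import Path

import numpy as np

import gennet as g

OUT = Path("results/study")
DATA = Path("scratch/study")  # bulky regenerable matrices
SEED = 1

# desk-scale study shape: 80 genes / 12 miRNAs keeps every later stage
# (identification, projection, 10-fold consistency) re-runnable in minutes
CONFIG = g.RunConfig(
    n_genes=80, n_mirnas=12,
    mean_tfs_per_gene=4.0, mean_partners_per_protein=6.0, mean_mirnas_per_gene=3.0,
    samples_per_condition=60, decoy_ratio=1.0, noise_sd=0.05,
    n_hyper=4, n_hypo=4, b_permutations=100, compare_b_perm=1000,
    kfold=10, seed=SEED, outdir=None,
)


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    DATA.mkdir(parents=True, exist_ok=True)
    CONFIG.to_yaml(OUT / "study_config.yaml")

    truth = g.generate_truth_network(
        n_genes=CONFIG.n_genes, n_mirnas=CONFIG.n_mirnas,
        mean_tfs_per_gene=CONFIG.mean_tfs_per_gene,
        mean_partners_per_protein=CONFIG.mean_partners_per_protein,
        mean_mirnas_per_gene=CONFIG.mean_mirnas_per_gene, seed=SEED,
    )
    candidate = g.add_decoys(truth, CONFIG.decoy_ratio, seed=SEED + 1)
    g.write_gen_tsv(candidate, OUT / "candidate_gen.tsv")
    g.write_gen_tsv(g.truth_candidate(truth), OUT / "truth_active_gen.tsv")
    (OUT / "sink_nodes.tsv").write_text(
        "gene\tmechanism\n"
        + "".join(f"{n}\t{m}\n" for n, m in sorted(truth.sink_nodes.items()))
    )

    grn_sinks = sorted(n for n, m in truth.sink_nodes.items() if m == "grn")
    rng = np.random.default_rng(SEED + 2)
    picked = [str(gene) for gene in rng.permutation(grn_sinks)]
    shifted = {gene: "hyper" for gene in picked[: CONFIG.n_hyper]}
    shifted |= {gene: "hypo" for gene in picked[CONFIG.n_hyper : CONFIG.n_hyper + CONFIG.n_hypo]}
    (OUT / "shifted_genes.tsv").write_text(
        "gene\tdirection\n" + "".join(f"{k}\t{v}\n" for k, v in sorted(shifted.items()))
    )

    for cond, shifts in (("A", {}), ("B", shifted)):
        meth = g.simulate_methylation(
            truth, L=CONFIG.samples_per_condition, beta_params=CONFIG.beta_params,
            shifted_genes=shifts, shift=CONFIG.methylation_shift,
            seed=SEED + (10 if cond == "A" else 20),
        )
        expr = g.simulate_expression(
            truth, meth, noise_sd=CONFIG.noise_sd,
            seed=SEED + (11 if cond == "A" else 21),
        )
        meth.write(DATA / f"methylation_{cond}.tsv")
        expr.write(DATA / f"expression_{cond}.tsv", DATA / f"mirna_{cond}.tsv")

    stats = g.network_stats(candidate)
    print(f"truth: {len(truth.true_ppi)} PPIs, {len(truth.true_tf)} TF regulations, "
          f"{len(truth.true_mirna)} miRNA repressions; "
          f"{len(truth.sink_nodes)} modeled sink genes "
          f"({len(grn_sinks)} gene-model, "
          f"{len(truth.sink_nodes) - len(grn_sinks)} protein-model)")
    print(f"candidate network (decoy ratio {CONFIG.decoy_ratio}): "
          f"{stats.n_ppi} PPI / {stats.n_tf} TF / {stats.n_mirna} miRNA edges; "
          f"TFs per gene {stats.mean_tfs_per_gene:.2f} ± {stats.sd_tfs_per_gene:.2f}, "
          f"partners per protein {stats.mean_partners_per_protein:.2f} "
          f"± {stats.sd_partners_per_protein:.2f}")
    print(f"condition B shifts: {sorted(shifted.items())}")
    print(f"wrote edge tables to {OUT}/ and matrices to {DATA}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
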