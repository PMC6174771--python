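#!/usr/bin/env python
"""Ten-fold consistency of the identified network selection.

Splits condition A's samples into ten near-equal folds, re-runs the
identification on the complement of each fold, and reports the
fraction of edges selected in all ten repetitions (out of those
selected in at least one), separately for the protein-interaction and
gene-regulation models.
"""

import json
import sys
from pathlib import Path

import gennet as g

STUDY = Path("results/study")
DATA = Path("scratch/study")  # matrices written by 01_simulate_cohorts.py


def main() -> int:
    config = g.RunConfig.from_yaml(STUDY / "study_config.yaml")
    candidate = g.read_gen_tsv(STUDY / "candidate_gen.tsv")
    expr = g.ExpressionData.read(DATA / "expression_A.tsv", DATA / "mirna_A.tsv")
    meth = g.MethylationData.read(DATA / "methylation_A.tsv")

    result = g.kfold_consistency(
        expr, meth, candidate, k=config.kfold or 10, seed=config.seed
    )
    (STUDY / "kfold_consistency.json").write_text(
        json.dumps(result, indent=2, sort_keys=True) + "\n"
    )
    print(f"fold sizes: {result['fold_sizes']}")
    for cls, label in (("ppin", "PPIN"), ("grn", "GRN")):
        r = result[cls]
        print(f"{label}: {r['consistency']:.2%} of edges selected in all "
              f"{result['k']} repetitions ({r['always_selected']}/{r['ever_selected']})")
    print(f"consistency table written to {STUDY}/kfold_consistency.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
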