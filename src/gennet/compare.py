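"""Two-condition comparison: differential expression/methylation, basal
shifts and core-GEN overlap.

Differential tests use the pooled-variance two-sample t-statistic with
a label-permutation p-value (two-sided, floored at 1/B).  Methylation
direction calls (hyper/hypo) are made on the sign of the mean beta
difference alone -- the p-value is carried as annotation, not used as a
gate.  Basal-level (kappa) shifts between the two identified GENs proxy
the effect of DNA methylation on transcription.  Core networks are
partitioned into condition-specific and common edges and nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import MethylationData
from .identify import IdentifiedGEN
from .projection import CoreGEN

__all__ = [
    "ConditionComparison",
    "differential_feature_test",
    "call_methylation_direction",
    "basal_shift",
    "compare_core_gens",
    "differential_table",
]


def differential_feature_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    B_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pooled-variance two-sample t-statistic with permutation p-value.

    p = #{ |t_perm| >= |t_obs| } / B_perm over label shuffles, floored
    at 1/B_perm (ties count, so identical groups give p = 1).  Zero
    variance in both groups yields t = 0, p = 1 with a warning.
    """
    if B_perm < 1:
        raise ValueError("B_perm must be at least 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn("zero variance in both groups; p = 1 by convention")
        return 0.0, 1.0

    na, nb = a.size, b.size
    scale = np.sqrt(1.0 / na + 1.0 / nb)
    dof = na + nb - 2

    def tstat(x, y):
        sp2 = ((na - 1) * np.var(x, ddof=1) + (nb - 1) * np.var(y, ddof=1)) / dof
        if sp2 == 0:
            return 0.0
        return float((np.mean(x) - np.mean(y)) / (np.sqrt(sp2) * scale))

    t_obs = tstat(a, b)
    # sorting the pooled sample makes the realized permutation null
    # independent of the order the two groups were passed in
    pooled = np.sort(np.concatenate([a, b]))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B_perm):
        perm = rng.permutation(pooled.size)
        if abs(tstat(pooled[perm[:na]], pooled[perm[na:]])) >= abs(t_obs):
            exceed += 1
    return t_obs, max(exceed, 1) / B_perm


def call_methylation_direction(
    meth_a: MethylationData,
    meth_b: MethylationData,
    gene: str,
    B_perm: int = 1000,
    seed: int = 0,
) -> tuple[str, float]:
    """Direction of the methylation change of one gene from A to B.

    "hyper" if the mean beta rises in condition B, "hypo" if it falls,
    "none" if the means agree to within 1e-12.  The permutation p-value
    is attached as annotation only (calls are not thresholded on it).
    Genes uncovered in either condition raise KeyError.
    """
    for meth, label in ((meth_a, "A"), (meth_b, "B")):
        if not meth.covers(gene):
            raise KeyError(f"gene {gene!r} has no methylation coverage in condition {label}")
    a = meth_a.profile(gene)
    b = meth_b.profile(gene)
    diff = float(np.mean(b) - np.mean(a))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = differential_feature_test(a, b, B_perm=B_perm, seed=seed)
    if abs(diff) <= 1e-12:
        return "none", p
    return ("hyper" if diff > 0 else "hypo"), p


def basal_shift(gen_a: IdentifiedGEN, gen_b: IdentifiedGEN) -> pd.DataFrame:
    """Per-gene basal-level change Delta kappa = kappa_hat(B) - kappa_hat(A).

    Rows are genes modeled in both conditions' GRNs; genes modeled in
    only one are returned with a flag and no Delta kappa.
    """
    rows = []
    for gene in sorted(set(gen_a.grn) | set(gen_b.grn)):
        in_a, in_b = gene in gen_a.grn, gene in gen_b.grn
        if in_a and in_b:
            ka = gen_a.grn[gene].basal
            kb = gen_b.grn[gene].basal
            rows.append((gene, ka, kb, kb - ka, "both"))
        else:
            rows.append((gene, np.nan, np.nan, np.nan, "A_only" if in_a else "B_only"))
    return pd.DataFrame(
        rows, columns=["gene", "kappa_a", "kappa_b", "delta_kappa", "modeled_in"]
    ).set_index("gene")


@dataclass
class ConditionComparison:
    """Differential tables plus core-GEN edge/node partitions."""

    expression: Optional[pd.DataFrame] = None
    methylation: Optional[pd.DataFrame] = None
    basal: Optional[pd.DataFrame] = None
    edges_common: set = field(default_factory=set)
    edges_a_only: set = field(default_factory=set)
    edges_b_only: set = field(default_factory=set)
    nodes_common: set = field(default_factory=set)
    nodes_a_only: set = field(default_factory=set)
    nodes_b_only: set = field(default_factory=set)


def compare_core_gens(core_a: CoreGEN, core_b: CoreGEN) -> ConditionComparison:
    """Partition two core GENs into common / A-specific / B-specific parts.

    Edge comparison is type-aware; the three edge parts are a disjoint
    cover of the union of both edge sets (same for nodes).
    """
    ea, eb = core_a.edges, core_b.edges
    na, nb = core_a.nodes, core_b.nodes
    return ConditionComparison(
        edges_common=ea & eb,
        edges_a_only=ea - eb,
        edges_b_only=eb - ea,
        nodes_common=na & nb,
        nodes_a_only=na - nb,
        nodes_b_only=nb - na,
    )


def differential_table(
    frame_a: pd.DataFrame,
    frame_b: pd.DataFrame,
    features: Optional[list[str]] = None,
    B_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Row-wise differential test between two feature-by-sample matrices."""
    if features is None:
        features = sorted(set(frame_a.index) & set(frame_b.index))
    rows = []
    for i, f in enumerate(features):
        a = frame_a.loc[f].to_numpy(dtype=float)
        b = frame_b.loc[f].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = differential_feature_test(a, b, B_perm=B_perm, seed=seed + i)
        rows.append((f, float(np.mean(a)), float(np.mean(b)), t, p))
    return pd.DataFrame(
        rows, columns=["feature", "mean_a", "mean_b", "t_statistic", "p_value"]
    ).set_index("feature")
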