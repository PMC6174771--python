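"""Candidate genetic-and-epigenetic network (GEN) edge tables.

The candidate GEN is the union of putative links reported by interaction
databases (protein-protein interactions, TF->gene regulations and
miRNA->gene repressions) or produced by the synthetic-data generator.
It deliberately contains false positives; identification prunes it down
to the real GEN.  Genes and proteins share a single identifier space
(mRNA abundance proxies protein abundance), miRNAs live in their own.

PPI pairs are stored orientation-free as sorted tuples; regulations are
directed (source, target) pairs.  Each edge optionally carries a decoy
flag, used only when evaluating identification against a synthetic
ground truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CandidateGEN",
    "NetworkStats",
    "read_edge_tables",
    "read_alias_table",
    "unify_symbols",
    "network_stats",
    "write_gen_tsv",
    "read_gen_tsv",
]

log = logging.getLogger(__name__)

EDGE_TYPES = ("ppi", "tf", "mirna")


def _ppi_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CandidateGEN:
    """Candidate PPI / TF->gene / miRNA->gene edge sets with node registries."""

    ppi: set[tuple[str, str]] = field(default_factory=set)
    tf: set[tuple[str, str]] = field(default_factory=set)
    mirna: set[tuple[str, str]] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    mirnas: set[str] = field(default_factory=set)
    #: edges flagged as decoys (evaluation bookkeeping only)
    decoys: dict[str, set[tuple[str, str]]] = field(
        default_factory=lambda: {t: set() for t in EDGE_TYPES}
    )

    def __post_init__(self) -> None:
        self.ppi = {_ppi_key(a, b) for a, b in self.ppi}
        for a, b in self.ppi:
            if a == b:
                raise ValueError(f"self-interaction {a!r} is not allowed in the PPI set")
        # every edge endpoint is registered
        self.genes |= {n for e in self.ppi for n in e}
        self.genes |= {n for e in self.tf for n in e}
        self.genes |= {g for _, g in self.mirna}
        self.mirnas |= {m for m, _ in self.mirna}
        for t in EDGE_TYPES:
            self.decoys.setdefault(t, set())

    # -- per-node candidate sets -------------------------------------------------
    def partners(self, node: str) -> list[str]:
        """Candidate interaction partners N_i of a protein, sorted."""
        out = {b if a == node else a for a, b in self.ppi if node in (a, b)}
        return sorted(out)

    def tfs_of(self, gene: str) -> list[str]:
        """Candidate TFs K_i of a gene, sorted."""
        return sorted({t for t, g in self.tf if g == gene})

    def mirnas_of(self, gene: str) -> list[str]:
        """Candidate repressing miRNAs V_i of a gene, sorted."""
        return sorted({m for m, g in self.mirna if g == gene})

    def is_decoy(self, edge_type: str, source: str, target: str) -> bool:
        e = _ppi_key(source, target) if edge_type == "ppi" else (source, target)
        return e in self.decoys[edge_type]

    @property
    def n_edges(self) -> dict[str, int]:
        return {"ppi": len(self.ppi), "tf": len(self.tf), "mirna": len(self.mirna)}


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
            pairs.append((fields[0], fields[1]))
    return pairs


def read_edge_tables(
    ppi_path: str | Path, tf_path: str | Path, mirna_path: str | Path
) -> CandidateGEN:
    """Load a candidate GEN from three 2+ column TSV edge lists.

    Duplicate rows (and, for PPIs, reversed duplicates) collapse to one
    edge; self-PPI rows are dropped with a warning since a protein's
    interactive model only sums over partners j != i.
    """
    ppi: set[tuple[str, str]] = set()
    for a, b in _read_pairs(ppi_path):
        if a == b:
            warnings.warn(f"dropping self-interaction PPI row ({a},{b})")
            continue
        ppi.add(_ppi_key(a, b))
    tf = set(_read_pairs(tf_path))
    mirna = set(_read_pairs(mirna_path))
    gen = CandidateGEN(ppi=ppi, tf=tf, mirna=mirna)
    log.info("read candidate GEN: %s", gen.n_edges)
    return gen


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read an alias -> canonical gene-symbol table (2-column TSV)."""
    table: dict[str, str] = {}
    for alias, canonical in _read_pairs(path):
        if alias in table and table[alias] != canonical:
            raise ValueError(
                f"alias {alias!r} maps to both {table[alias]!r} and {canonical!r}"
            )
        table[alias] = canonical
    return table


def unify_symbols(candidate: CandidateGEN, alias_table: Mapping[str, str]) -> CandidateGEN:
    """Replace node identifiers by canonical symbols and collapse duplicates.

    Identifiers without an alias entry are kept verbatim (their count is
    logged).  Idempotent as long as canonical symbols do not themselves
    appear as aliases of something else.
    """
    # reject one-alias-to-many tables supplied as e.g. multidicts flattened upstream
    if len(set(alias_table.keys())) != len(alias_table):
        raise ValueError("alias table has duplicate alias entries")

    def canon(name: str) -> str:
        return alias_table.get(name, name)

    all_nodes = candidate.genes | candidate.mirnas
    unmapped = sum(1 for n in all_nodes if n not in alias_table)
    log.info("unify_symbols: %d of %d identifiers had no alias entry", unmapped, len(all_nodes))

    return CandidateGEN(
        ppi={_ppi_key(canon(a), canon(b)) for a, b in candidate.ppi if canon(a) != canon(b)},
        tf={(canon(t), canon(g)) for t, g in candidate.tf},
        mirna={(canon(m), canon(g)) for m, g in candidate.mirna},
        genes={canon(g) for g in candidate.genes},
        mirnas={canon(m) for m in candidate.mirnas},
        decoys={
            "ppi": {_ppi_key(canon(a), canon(b)) for a, b in candidate.decoys["ppi"]},
            "tf": {(canon(t), canon(g)) for t, g in candidate.decoys["tf"]},
            "mirna": {(canon(m), canon(g)) for m, g in candidate.decoys["mirna"]},
        },
    )


@dataclass
class NetworkStats:
    """Candidate in-degree summary: mean +/- population SD per edge class."""

    mean_tfs_per_gene: float
    sd_tfs_per_gene: float
    mean_partners_per_protein: float
    sd_partners_per_protein: float
    mean_mirnas_per_gene: float
    sd_mirnas_per_gene: float
    n_ppi: int
    n_tf: int
    n_mirna: int


def _mean_sd(values: list[int]) -> tuple[float, float]:
    if not values:
        return 0.0, 0.0
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std())  # population SD


def network_stats(candidate: CandidateGEN) -> NetworkStats:
    """Degree statistics over all registered genes (zero-candidate genes count)."""
    genes = sorted(candidate.genes)
    k = {g: 0 for g in genes}
    for _, g in candidate.tf:
        k[g] += 1
    v = {g: 0 for g in genes}
    for _, g in candidate.mirna:
        v[g] += 1
    n = {g: 0 for g in genes}
    for a, b in candidate.ppi:
        n[a] += 1
        n[b] += 1
    mk, sk = _mean_sd(list(k.values()))
    mv, sv = _mean_sd(list(v.values()))
    mn, sn = _mean_sd(list(n.values()))
    return NetworkStats(
        mean_tfs_per_gene=mk,
        sd_tfs_per_gene=sk,
        mean_partners_per_protein=mn,
        sd_partners_per_protein=sn,
        mean_mirnas_per_gene=mv,
        sd_mirnas_per_gene=sv,
        n_ppi=len(candidate.ppi),
        n_tf=len(candidate.tf),
        n_mirna=len(candidate.mirna),
    )


def write_gen_tsv(candidate: CandidateGEN, path: str | Path) -> None:
    """Write the 4-column edge-list TSV (source, target, edge_type, is_decoy).

    Rows are canonically sorted so that writing the same network twice
    produces byte-identical files.
    """
    rows = []
    for a, b in sorted(candidate.ppi):
        rows.append((a, b, "ppi", int((a, b) in candidate.decoys["ppi"])))
    for t, g in sorted(candidate.tf):
        rows.append((t, g, "tf", int((t, g) in candidate.decoys["tf"])))
    for m, g in sorted(candidate.mirna):
        rows.append((m, g, "mirna", int((m, g) in candidate.decoys["mirna"])))
    frame = pd.DataFrame(rows, columns=["source", "target", "edge_type", "is_decoy"])
    frame.to_csv(path, sep="\t", index=False)


def read_gen_tsv(path: str | Path) -> CandidateGEN:
    frame = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    gen = CandidateGEN()
    for row in frame.itertuples(index=False):
        etype = row.edge_type
        edge = (
            _ppi_key(row.source, row.target) if etype == "ppi" else (row.source, row.target)
        )
        getattr(gen, etype).add(edge)
        if bool(row.is_decoy):
            gen.decoys[etype].add(edge)
    return CandidateGEN(
        ppi=gen.ppi, tf=gen.tf, mirna=gen.mirna, decoys=gen.decoys
    )
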