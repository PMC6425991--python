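"""TCR repertoire composition and clonotype overlap between primed lines.

A clonotype is identified by (chain, CDR3 amino-acid sequence); the V gene is
carried along for usage summaries but is not part of clonotype identity.
Overlap between two peptide-primed lines counts shared CDR3s per chain and
reports per-chain Jaccard indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple, TextIO

import pandas as pd

from .landscape import STANDARD_AA

__all__ = [
    "ClonotypeRecord",
    "Repertoire",
    "UniqueCounts",
    "OverlapSummary",
    "read_repertoire",
    "unique_clonotypes",
    "overlap",
    "v_gene_usage",
]

Chain = Literal["alpha", "beta"]


@dataclass(frozen=True)
class ClonotypeRecord:
    chain: Chain
    cdr3_aa: str
    v_gene: str
    count: int

    def __post_init__(self) -> None:
        if self.chain not in ("alpha", "beta"):
            raise ValueError(f"chain must be 'alpha' or 'beta', got {self.chain!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        bad = set(self.cdr3_aa) - set(STANDARD_AA)
        if bad or not self.cdr3_aa:
            raise ValueError(f"CDR3 {self.cdr3_aa!r} not over the 20-letter alphabet")


@dataclass(frozen=True)
class Repertoire:
    """A line's clonotype table: unique (chain, CDR3, V gene) records with counts."""

    line_id: str
    records: tuple[ClonotypeRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        keys = [(r.chain, r.cdr3_aa, r.v_gene) for r in records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, cdr3_aa, v_gene) records")
        object.__setattr__(self, "records", records)

    def clonotype_set(self, chain: Chain) -> set[str]:
        return {r.cdr3_aa for r in self.records if r.chain == chain}


class UniqueCounts(NamedTuple):
    alpha: int
    beta: int
    total: int


@dataclass(frozen=True)
class OverlapSummary:
    shared_alpha: int
    shared_beta: int
    total_unique_union: int
    jaccard_alpha: float
    jaccard_beta: float


def read_repertoire(source: str | Path | TextIO, line_id: str = "") -> Repertoire:
    """Read an AIRR-style TSV: chain, cdr3_aa (or junction_aa), v_call, duplicate_count."""
    df = pd.read_csv(source, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    chain_col = cols.get("chain")
    cdr3_col = cols.get("cdr3_aa") or cols.get("junction_aa")
    v_col = cols.get("v_call") or cols.get("v_gene")
    count_col = cols.get("duplicate_count") or cols.get("count")
    if not (chain_col and cdr3_col and v_col):
        raise ValueError("repertoire TSV needs chain, cdr3_aa/junction_aa, v_call")
    tidy = pd.DataFrame(
        {
            "chain": df[chain_col].astype(str),
            "cdr3": df[cdr3_col].astype(str),
            "v": df[v_col].astype(str),
            "count": df[count_col].astype(int) if count_col else 1,
        }
    )
    # duplicated rows collapse to one record with summed counts
    grouped = tidy.groupby(["chain", "cdr3", "v"], as_index=False)["count"].sum()
    records = tuple(
        ClonotypeRecord(
            chain=row.chain, cdr3_aa=row.cdr3, v_gene=row.v, count=int(row.count)
        )
        for row in grouped.itertuples(index=False)
    )
    return Repertoire(line_id=line_id, records=records)


def unique_clonotypes(rep: Repertoire) -> UniqueCounts:
    """Unique (chain, CDR3) clonotypes per chain and in total."""
    if not rep.records:
        raise ValueError("empty repertoire")
    alpha = len(rep.clonotype_set("alpha"))
    beta = len(rep.clonotype_set("beta"))
    return UniqueCounts(alpha=alpha, beta=beta, total=alpha + beta)


def overlap(rep_a: Repertoire, rep_b: Repertoire) -> OverlapSummary:
    """Shared clonotypes and per-chain Jaccard indices between two lines."""
    if not rep_a.records or not rep_b.records:
        raise ValueError("both repertoires must be non-empty")
    summary = {}
    union_total = 0
    for chain in ("alpha", "beta"):
        sa, sb = rep_a.clonotype_set(chain), rep_b.clonotype_set(chain)
        shared = len(sa & sb)
        union = len(sa | sb)
        union_total += union
        summary[chain] = (shared, shared / union if union else 0.0)
    return OverlapSummary(
        shared_alpha=summary["alpha"][0],
        shared_beta=summary["beta"][0],
        total_unique_union=union_total,
        jaccard_alpha=summary["alpha"][1],
        jaccard_beta=summary["beta"][1],
    )


def v_gene_usage(
    rep: Repertoire,
    gene: str,
    weighting: Literal["clonotype", "read"] = "clonotype",
) -> float:
    """Fraction of a chain's repertoire using a V gene.

    The chain is inferred from the gene name (TRAV* -> alpha, TRBV* -> beta).
    Clonotype weighting counts unique clonotypes; read weighting weights each
    clonotype by its duplicate count.
    """
    if weighting not in ("clonotype", "read"):
        raise ValueError("weighting must be 'clonotype' or 'read'")
    upper = gene.upper()
    if upper.startswith("TRAV"):
        chain: Chain = "alpha"
    elif upper.startswith("TRBV"):
        chain = "beta"
    else:
        raise ValueError(f"cannot infer chain from gene {gene!r}")
    chain_records = [r for r in rep.records if r.chain == chain]
    if not chain_records:
        raise ValueError(f"no {chain}-chain records in repertoire")
    if weighting == "clonotype":
        hits = sum(r.v_gene == gene for r in chain_records)
        return hits / len(chain_records)
    total = sum(r.count for r in chain_records)
    hits = sum(r.count for r in chain_records if r.v_gene == gene)
    return hits / total
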