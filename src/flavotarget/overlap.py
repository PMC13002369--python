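"""Candidate-panel construction and over-representation statistics.

The candidate panel is the intersection of differentially expressed genes
with the union of compound-predicted target lists, keeping per-gene
provenance (which compounds predicted it). Enrichment of user-supplied gene
sets is an upper-tail hypergeometric over-representation test with BH
correction across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


class OverlapError(ValueError):
    pass


@dataclass
class CandidatePanel:
    genes: list[str]                       # lexicographic order
    provenance: dict[str, set[str]]        # gene -> compound ids
    sizes: tuple[int, int, int]            # (n_deg, n_target, n_intersection)


def intersect_targets(deg_genes, target_table: pd.DataFrame) -> CandidatePanel:
    """Intersect DEGs with compound target predictions.

    ``target_table`` is the long-format compound_id/gene_symbol table; gene
    symbols are assumed pre-normalized to uppercase.
    """
    if target_table is None or len(target_table) == 0:
        raise OverlapError("target table is empty")
    degs = {str(g).upper() for g in deg_genes}
    provenance: dict[str, set[str]] = {}
    target_genes: set[str] = set()
    for cid, g in zip(target_table["compound_id"], target_table["gene_symbol"]):
        g = str(g).upper()
        target_genes.add(g)
        if g in degs:
            provenance.setdefault(g, set()).add(str(cid))
    genes = sorted(provenance)
    return CandidatePanel(
        genes=genes,
        provenance=provenance,
        sizes=(len(degs), len(target_genes), len(genes)),
    )


@dataclass
class EnrichmentRow:
    name: str
    k: int          # overlap
    K: int          # set size (within universe)
    n: int          # panel size (within universe)
    N: int          # universe size
    p: float
    q: float
    overlap_genes: list[str]


def enrich(panel_genes, collection, universe) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each collection set in the panel.

    p = P(X >= k) with X ~ Hypergeom(N, K, n); every set and the panel are
    intersected with the declared universe first. Rows sorted by (q, p, name).
    """
    universe = {str(g).upper() for g in universe}
    panel = {str(g).upper() for g in panel_genes}
    if not panel <= universe:
        raise OverlapError("panel must be a subset of the universe")
    if len(universe) < len(panel):
        raise OverlapError("universe smaller than panel")
    N, n = len(universe), len(panel)
    rows: list[EnrichmentRow] = []
    for name in sorted(collection):
        members = {str(g).upper() for g in collection[name]} & universe
        K = len(members)
        hits = sorted(members & panel)
        k = len(hits)
        # upper-tail: P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(max(p, 0.0), 1.0)
        rows.append(EnrichmentRow(name, k, K, n, N, p, q=1.0, overlap_genes=hits))
    qvals = bh_adjust([r.p for r in rows]) if rows else []
    for r, q in zip(rows, qvals):
        r.q = float(q)
    rows.sort(key=lambda r: (r.q, r.p, r.name))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.name for r in rows],
            "overlap": [r.k for r in rows],
            "set_size": [r.K for r in rows],
            "panel_size": [r.n for r in rows],
            "universe_size": [r.N for r in rows],
            "p": [r.p for r in rows],
            "q": [r.q for r in rows],
            "genes": ["|".join(r.overlap_genes) for r in rows],
        }
    )
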