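"""Hypergeometric overrepresentation analysis against GMT gene sets.

The query is the top-150 genes increased with endoscopic activity (best
probe per gene); the background universe defaults to every gene represented
on the array, conditioning enrichment on measurability.  Per set the
one-sided tail P(X >= k) of Hypergeometric(N, K, n) is computed and
Benjamini-Hochberg adjusted within the collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .de import benjamini_hochberg, rank_transcripts

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def restricted(self, universe) -> "GeneSetCollection":
        """Intersect every set with a new universe, dropping emptied sets."""
        universe = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = members & universe
            if inter:
                kept[name] = inter
            else:
                logger.warning("gene set %s empty after universe intersection; dropped", name)
        return GeneSetCollection(sets=kept, universe=universe)


def read_gene_sets(path, universe=None) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated member symbols).

    With no explicit universe the union of set members is used; callers
    normally re-restrict to the array universe via :meth:`restricted`.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected name, description, members")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r} at GMT line {lineno}")
        members = {g for g in parts[2:] if g}
        sets[name] = members
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    collection = GeneSetCollection(sets=sets, universe=set(universe))
    if universe is not None:
        collection = collection.restricted(collection.universe)
    return collection


def array_universe(annotation: pd.DataFrame) -> set[str]:
    """All nonempty gene symbols represented on the array."""
    return set(annotation["gene_symbol"]) - {""}


def select_enrichment_input(de_table: pd.DataFrame, annotation: pd.DataFrame,
                            n: int = 150) -> list[str]:
    """Top-n increased genes by p, one (best) probe per gene.

    Warns if any selected transcript misses FDR < 0.05 (the expected regime
    is that all of the top 150 clear it) or if fewer than n increased
    transcripts exist.
    """
    table = de_table.copy()
    if "gene_symbol" not in table.columns:
        table["gene_symbol"] = annotation["gene_symbol"].reindex(table.index).fillna("")
    increased = int((table["log2_fold_change"] > 0).sum())
    k = min(n, increased)
    if increased < n:
        logger.warning("only %d increased transcripts available (requested %d)", increased, n)
    top = rank_transcripts(table, "increased", k, collapse_to_genes=True)
    if (top["p_fdr"] >= 0.05).any():
        logger.warning("%d of the selected transcripts have FDR >= 0.05",
                       int((top["p_fdr"] >= 0.05).sum()))
    genes = [g for g in top["gene_symbol"].tolist() if g]
    return genes


def ora_test(genes, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation test per gene set.

    p = P(X >= k) with X ~ Hypergeometric(N=len(universe), K=set size,
    n=query size); BH adjustment across the collection's sets; sorted by p.
    """
    query = set(genes) & collection.universe
    if not query:
        raise ValueError("empty query after intersecting with the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K, "query_size": n,
                     "universe_size": N, "p": min(p, 1.0), "genes": ";".join(overlap)})
    table = pd.DataFrame(rows)
    table["p_fdr"] = benjamini_hochberg(table["p"].to_numpy())
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)
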