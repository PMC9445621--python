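"""Hypergeometric over-representation analysis of functional terms.

Given a gene -> functional-term annotation map and a gene set of interest
(e.g. the core, accessory, singleton or MAG-unique genes of a pangenome),
each term carried by at least one set member is tested with the one-sided
hypergeometric tail P(X >= k) against the annotated universe, p-values are
Benjamini-Hochberg adjusted across the tested terms, and a term is flagged
enriched when both p < 0.05 and q < 0.05.

The universe is the set of genes carrying at least one annotation — genes
without any functional assignment are outside the test.  The map is used as
given; no ontology-graph propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AnnotationMap",
    "read_annotation",
    "write_annotation",
    "bh_adjust",
    "hypergeometric_enrichment",
]

P_THRESHOLD = 0.05
Q_THRESHOLD = 0.05


@dataclass
class AnnotationMap:
    """Gene -> set-of-term-ids map with optional term descriptions."""

    gene_terms: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # drop genes with no terms: the universe is the annotated genes
        self.gene_terms = {g: set(t) for g, t in self.gene_terms.items() if t}

    @property
    def universe(self) -> set[str]:
        return set(self.gene_terms)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.gene_terms.values():
            out |= t
        return out

    def term_genes(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                inv.setdefault(t, set()).add(gene)
        return inv


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read a two-column gene<TAB>term file (one term per line; repeated
    gene rows accumulate)."""
    gene_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            gene_terms.setdefault(gene, set()).add(term)
    return AnnotationMap(gene_terms)


def write_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotation.gene_terms):
            for term in sorted(annotation.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j on the sorted p-values, mapped
    back to the input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeometric_enrichment(
    gene_set: Iterable[str],
    annotation: AnnotationMap,
    p_threshold: float = P_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """One-sided over-representation test for every term hit by the set.

    For a term annotating K of the N universe genes, with n set members
    drawn and k of them carrying the term, p = P(X >= k) with
    X ~ Hypergeometric(N, K, n).  Genes outside the universe are dropped
    from the set before testing.  Returns a table sorted by p-value with
    columns: term, set_hits, set_size, universe_hits, universe_size,
    p_value, q_value, enriched.
    """
    universe = annotation.universe
    genes = set(gene_set) & universe
    if not genes:
        raise ValueError("gene set has no overlap with the annotated universe")
    n_univ = len(universe)
    n_set = len(genes)
    term_genes = annotation.term_genes()
    rows = []
    for term, carriers in sorted(term_genes.items()):
        k = len(carriers & genes)
        if k == 0:
            continue
        big_k = len(carriers)
        p = float(hypergeom.sf(k - 1, n_univ, big_k, n_set))
        rows.append((term, k, n_set, big_k, n_univ, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=["term", "set_hits", "set_size", "universe_hits", "universe_size", "p_value"],
    )
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["enriched"] = (table["p_value"] < p_threshold) & (table["q_value"] < q_threshold)
    if annotation.descriptions:
        table["description"] = table["term"].map(annotation.descriptions)
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
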