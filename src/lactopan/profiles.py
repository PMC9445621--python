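"""Community-composition statistics on sample x species abundance tables.

Works on MetaPhlAn-style relative-abundance tables (percent scale) with a
per-sample niche label (e.g. ``food`` vs ``human``).  Implements presence
calling at a strict abundance threshold (default 0.01%), per-niche prevalence
and mean abundance, abundance variance on the fraction scale, niche
species-overlap counts, Bray-Curtis dissimilarity matrices, and a
complete-linkage distance tree written as Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "AbundanceTable",
    "PresenceMatrix",
    "DissimilarityMatrix",
    "read_abundance",
    "apply_presence_threshold",
    "species_prevalence",
    "mean_relative_abundance",
    "abundance_variance",
    "niche_overlap",
    "bray_curtis_matrix",
    "complete_linkage_tree",
]

SUM_TOLERANCE = 1e-6  # slack on the per-sample 100% total


@dataclass
class AbundanceTable:
    """Sample x species relative abundances on the percent scale.

    ``values``: DataFrame with sample ids as the index and species names as
    columns; entries are relative abundances in percent (rows sum to <=100
    plus tolerance — MetaPhlAn rows sum to 100 at each rank, but subset
    tables may sum lower).  ``niche``: per-sample label aligned to the index.
    """

    values: pd.DataFrame
    niche: pd.Series

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("abundances must be non-negative")
        sums = arr.sum(axis=1)
        if (sums > 100 + SUM_TOLERANCE).any():
            bad = self.values.index[sums > 100 + SUM_TOLERANCE][:3].tolist()
            raise ValueError(f"per-sample abundance sums exceed 100%: {bad}")
        self.niche = self.niche.reindex(self.values.index)
        if self.niche.isna().any():
            missing = self.values.index[self.niche.isna()][:5].tolist()
            raise ValueError(f"samples without a niche label: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    def niche_samples(self, niche: str) -> list[str]:
        sel = self.niche[self.niche == niche]
        if sel.empty:
            raise KeyError(f"unknown niche: {niche!r}")
        return list(sel.index)

    def subset(self, samples: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[list(samples)], self.niche)


@dataclass
class PresenceMatrix:
    """Boolean presence per (sample, species) at a recorded threshold."""

    values: pd.DataFrame  # boolean, samples x species
    threshold: float  # percent
    niche: pd.Series

    def niche_species(self, niche: str) -> set[str]:
        """Species present in at least one sample of the niche."""
        samples = self.niche[self.niche == niche]
        if samples.empty:
            raise KeyError(f"unknown niche: {niche!r}")
        present = self.values.loc[list(samples.index)].any(axis=0)
        return set(self.values.columns[present])


@dataclass
class DissimilarityMatrix:
    """Symmetric Bray-Curtis matrix with zero diagonal, values in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.allclose(arr, arr.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0):
            raise ValueError("diagonal must be zero")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis values must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)


def read_abundance(table_path: str | Path, niche_path: str | Path) -> AbundanceTable:
    """Read a MetaPhlAn-style TSV (rows = species, columns = samples) plus a
    two-column sample -> niche TSV sidecar."""
    values = pd.read_csv(table_path, sep="\t", index_col=0).T
    values.index.name = None
    values.columns.name = None
    niche_df = pd.read_csv(niche_path, sep="\t", index_col=0)
    niche = niche_df.iloc[:, 0]
    niche.index.name = None
    return AbundanceTable(values, niche)


def write_abundance(table: AbundanceTable, table_path: str | Path, niche_path: str | Path) -> None:
    table.values.T.to_csv(table_path, sep="\t", index_label="species")
    table.niche.rename("niche").to_csv(niche_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# presence, prevalence, abundance statistics
# ---------------------------------------------------------------------------

def apply_presence_threshold(table: AbundanceTable, threshold: float = 0.01) -> PresenceMatrix:
    """Call a species present in a sample iff its relative abundance strictly
    exceeds ``threshold`` (percent); an abundance exactly at the threshold is
    absent."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return PresenceMatrix(table.values > threshold, threshold, table.niche)


def species_prevalence(
    presence: PresenceMatrix, species: str, niche: str
) -> tuple[int, int, float]:
    """(positive sample count, total samples in niche, fraction positive)."""
    if species not in presence.values.columns:
        raise KeyError(f"unknown species: {species!r}")
    samples = presence.niche[presence.niche == niche]
    if samples.empty:
        raise KeyError(f"unknown niche: {niche!r}")
    col = presence.values.loc[list(samples.index), species]
    positive = int(col.sum())
    total = len(col)
    return positive, total, positive / total


def mean_relative_abundance(
    table: AbundanceTable,
    species: str,
    niche: str,
    positives_only: bool = False,
    threshold: float = 0.01,
) -> float:
    """Arithmetic mean relative abundance (percent) of a species over the
    niche's samples, optionally restricted to presence-positive samples."""
    if species not in table.values.columns:
        raise KeyError(f"unknown species: {species!r}")
    samples = table.niche_samples(niche)
    col = table.values.loc[samples, species]
    if positives_only:
        col = col[col > threshold]
        if col.empty:
            raise ValueError(
                f"no positive samples for {species!r} in niche {niche!r}"
            )
    return float(col.mean())


def abundance_variance(table: AbundanceTable, species: str, niche: str) -> float:
    """Sample variance (divisor n-1) of the species' abundance on the
    fraction scale (percent / 100), over all samples of the niche including
    zeros."""
    if species not in table.values.columns:
        raise KeyError(f"unknown species: {species!r}")
    samples = table.niche_samples(niche)
    if len(samples) < 2:
        raise ValueError(f"need >=2 samples in niche {niche!r} for a variance")
    fractions = table.values.loc[samples, species] / 100.0
    return float(fractions.var(ddof=1))


def niche_overlap(
    presence: PresenceMatrix, niche_a: str, niche_b: str
) -> tuple[int, int, int]:
    """Counts of species common to both niches and unique to each.

    A species belongs to a niche iff it is present in at least one of that
    niche's samples.
    """
    set_a = presence.niche_species(niche_a)
    set_b = presence.niche_species(niche_b)
    return len(set_a & set_b), len(set_a - set_b), len(set_b - set_a)


# ---------------------------------------------------------------------------
# dissimilarity and clustering
# ---------------------------------------------------------------------------

def bray_curtis_matrix(
    table: AbundanceTable, sample_subset: Sequence[str] | None = None
) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity over the selected samples.

    BC(i, j) = 1 - 2 * sum_k min(x_ik, x_jk) / sum_k (x_ik + x_jk), computed
    on the abundances as given (the index is invariant under a common row
    scale).  A pair of all-zero samples is degenerate; it is defined as
    distance 0 with a warning.
    """
    samples = list(sample_subset) if sample_subset is not None else table.samples
    if not samples:
        raise ValueError("sample subset is empty")
    x = table.values.loc[samples].to_numpy(dtype=float)
    n = len(samples)
    mins = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
    totals = x.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = 1.0 - 2.0 * mins / denom
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            "all-zero sample pair(s) encountered; Bray-Curtis defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        bc[degenerate] = 0.0
    np.fill_diagonal(bc, 0.0)
    bc = np.clip((bc + bc.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(pd.DataFrame(bc, index=samples, columns=samples))


def complete_linkage_tree(dist: DissimilarityMatrix) -> str:
    """Complete-linkage hierarchical clustering of the samples, as Newick.

    Leaves sit at height 0 and each internal node at its complete-linkage
    merge height; a child's branch length is (parent height - child height).
    A two-leaf tree at distance d therefore joins with two branches of
    length d (the merge height), not d/2.
    """
    samples = dist.samples
    if len(samples) < 2:
        raise ValueError("need >=2 samples for a tree")
    z = linkage(dist.condensed(), method="complete")
    return _linkage_to_newick(z, samples)


def _linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return labels[node]
        left, right, height = int(z[node - n, 0]), int(z[node - n, 1]), z[node - n, 2]
        parts = []
        for child in (left, right):
            sub = build(child)
            parts.append(f"{sub}:{height - heights[child]:.10g}")
        heights[node] = height
        return "(" + ",".join(parts) + ")"

    return build(n + len(z) - 1) + ";"
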