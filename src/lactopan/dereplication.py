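"""Two-step ANI dereplication of a genome catalog with scored representatives.

Mirrors the dRep-style workflow: genomes are first split into primary
clusters at 95% ANI, each primary cluster is then subdivided into secondary
clusters at 99.8% ANI with a minimum 50% alignment coverage of the shorter
genome, and one representative per secondary cluster is chosen by the score

    Score = A*Completeness - B*Contamination
            + C*(Contamination * strain_heterogeneity/100)
            + D*log10(N50) + E*log10(size) + F*(centrality - S_ani)

with default weights (A..F) = (1, 5, 1, 0.5, 0, 1).  Completeness,
contamination and strain heterogeneity are CheckM-style percentages;
centrality is the genome's mean ANI to the other members of its secondary
cluster (1 for singletons) and S_ani the secondary threshold.

Both clustering steps use average linkage on distance 1 - ANI (the reference
tool's default; single and complete linkage are available).  Pairs failing
the coverage filter contribute ANI 0 to the matrix view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "GenomeMetadata",
    "ANITable",
    "DereplicationResult",
    "ScoreWeights",
    "read_fastani",
    "write_fastani",
    "symmetrize_ani",
    "primary_clusters",
    "secondary_clusters",
    "drep_score",
    "select_representatives",
    "dereplicate",
    "ani_summary",
]

Linkage = Literal["average", "single", "complete"]

PRIMARY_ANI = 0.95
SECONDARY_ANI = 0.998
MIN_COVERAGE = 0.5


@dataclass
class GenomeMetadata:
    """CheckM-style quality fields for one genome."""

    genome: str
    completeness: float  # percent
    contamination: float  # percent
    strain_heterogeneity: float  # percent
    n50: int  # bp
    size: int  # bp
    source: str | None = None
    subspecies: str | None = None

    def __post_init__(self) -> None:
        for name in ("completeness", "contamination", "strain_heterogeneity"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.size <= 0:
            raise ValueError(f"size must be positive, got {self.size}")
        if self.n50 <= 0:
            raise ValueError(f"N50 must be positive, got {self.n50}")
        if self.n50 > self.size:
            raise ValueError(f"N50 ({self.n50}) cannot exceed genome size ({self.size})")


@dataclass
class ANITable:
    """Directed (query, reference) ANI pairs plus a symmetric matrix view.

    ``pairs`` columns: query, reference, ani (fraction), coverage (aligned
    fraction of the shorter genome).  ``matrix`` is built lazily by
    :func:`symmetrize_ani`: symmetric, unit diagonal, low-coverage or
    missing pairs set to ANI 0.
    """

    pairs: pd.DataFrame
    matrix: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"query", "reference", "ani", "coverage"}
        if not required <= set(self.pairs.columns):
            raise ValueError(f"pairs must have columns {sorted(required)}")
        ani = self.pairs["ani"].to_numpy(dtype=float)
        cov = self.pairs["coverage"].to_numpy(dtype=float)
        if ((ani < 0) | (ani > 1)).any():
            raise ValueError("ANI values must lie in [0, 1] (fractions)")
        if ((cov < 0) | (cov > 1)).any():
            raise ValueError("coverage values must lie in [0, 1]")

    @property
    def genomes(self) -> list[str]:
        if self.matrix is not None:
            return list(self.matrix.index)
        return sorted(set(self.pairs["query"]) | set(self.pairs["reference"]))


@dataclass
class DereplicationResult:
    """Cluster labels, scores and the representative per secondary cluster."""

    primary: pd.Series  # genome -> primary cluster id (int)
    secondary: pd.Series  # genome -> secondary cluster id (str "p.s")
    representatives: dict[str, str]  # secondary cluster -> genome
    scores: pd.Series  # genome -> dRep score
    centrality: pd.Series  # genome -> mean within-cluster ANI

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "primary_cluster": self.primary,
                "secondary_cluster": self.secondary,
                "score": self.scores,
                "centrality": self.centrality,
            }
        )
        df["representative"] = [
            self.representatives[c] == g for g, c in self.secondary.items()
        ]
        return df


@dataclass(frozen=True)
class ScoreWeights:
    """Weights A..F of the representative-selection score."""

    a: float = 1.0
    b: float = 5.0
    c: float = 1.0
    d: float = 0.5
    e: float = 0.0
    f: float = 1.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fastani(path: str | Path) -> ANITable:
    """Read fastANI 5-column tabular output: query, reference, ANI (percent),
    mapped fragments, total fragments.  Coverage = mapped / total."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["query", "reference", "ani", "mapped", "total"],
    )
    df["ani"] = df["ani"].astype(float) / 100.0
    df["coverage"] = df["mapped"] / df["total"]
    return ANITable(df[["query", "reference", "ani", "coverage"]])


def write_fastani(table: ANITable, path: str | Path, n_fragments: int = 1000) -> None:
    """Write ANI pairs in the fastANI 5-column dialect (ANI on the percent
    scale, coverage encoded as mapped/total fragment counts)."""
    out = table.pairs.copy()
    out["ani_pct"] = out["ani"] * 100.0
    out["mapped"] = (out["coverage"] * n_fragments).round().astype(int)
    out["total"] = n_fragments
    out[["query", "reference", "ani_pct", "mapped", "total"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# matrix construction and clustering
# ---------------------------------------------------------------------------

def symmetrize_ani(table: ANITable, min_cov: float = MIN_COVERAGE) -> ANITable:
    """Build the symmetric matrix view from directed pairs.

    Pairs with coverage below ``min_cov`` are treated as ANI 0 (no valid
    alignment).  Asymmetric reciprocal values are averaged; a pair reported
    in only one direction keeps its single value.  The diagonal is 1.
    """
    pairs = table.pairs
    genomes = sorted(set(pairs["query"]) | set(pairs["reference"]))
    idx = {g: i for i, g in enumerate(genomes)}
    n = len(genomes)
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)
    for q, r, ani, cov in pairs[["query", "reference", "ani", "coverage"]].itertuples(index=False):
        if q == r:
            continue
        val = ani if cov >= min_cov else 0.0
        i, j = idx[q], idx[r]
        acc[i, j] += val
        cnt[i, j] += 1
    sym = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = cnt[i, j] + cnt[j, i]
            if c:
                sym[i, j] = sym[j, i] = (acc[i, j] + acc[j, i]) / c
    np.fill_diagonal(sym, 1.0)
    matrix = pd.DataFrame(sym, index=genomes, columns=genomes)
    return ANITable(pairs=pairs, matrix=matrix)


def _require_matrix(table: ANITable) -> pd.DataFrame:
    if table.matrix is None:
        raise ValueError("ANITable has no matrix view; call symmetrize_ani first")
    return table.matrix


def _cut_clusters(
    matrix: pd.DataFrame, threshold: float, method: Linkage
) -> pd.Series:
    """Hierarchical clustering on distance 1 - ANI, cut at 1 - threshold."""
    genomes = list(matrix.index)
    if len(genomes) == 1:
        return pd.Series([1], index=genomes)
    dist = 1.0 - matrix.to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    return pd.Series(labels, index=genomes)


def primary_clusters(
    table: ANITable, threshold: float = PRIMARY_ANI, method: Linkage = "average"
) -> pd.Series:
    """Primary (species-level) clusters at the 95% ANI default."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return _cut_clusters(_require_matrix(table), threshold, method)


def secondary_clusters(
    table: ANITable,
    primary: pd.Series,
    threshold: float = SECONDARY_ANI,
    method: Linkage = "average",
) -> pd.Series:
    """Secondary (strain-level) clusters within each primary cluster.

    Labels are ``"<primary>.<k>"`` so secondary clusters nest within
    primary clusters by construction.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    matrix = _require_matrix(table)
    labels: dict[str, str] = {}
    for p in sorted(primary.unique()):
        members = sorted(primary.index[primary == p])
        sub = matrix.loc[members, members]
        sec = _cut_clusters(sub, threshold, method)
        for g in members:
            labels[g] = f"{p}.{sec[g]}"
    return pd.Series(labels).reindex(matrix.index)


# ---------------------------------------------------------------------------
# scoring and representative selection
# ---------------------------------------------------------------------------

def drep_score(
    meta: GenomeMetadata,
    centrality: float,
    s_ani: float = SECONDARY_ANI,
    weights: ScoreWeights = ScoreWeights(),
) -> float:
    """Representative-selection score (base-10 logarithms).

    With the default weights the genome-size term drops out (E = 0) and the
    contamination penalty dominates its strain-heterogeneity rebate, so the
    score is strictly decreasing in contamination.
    """
    w = weights
    return (
        w.a * meta.completeness
        - w.b * meta.contamination
        + w.c * (meta.contamination * meta.strain_heterogeneity / 100.0)
        + w.d * math.log10(meta.n50)
        + w.e * math.log10(meta.size)
        + w.f * (centrality - s_ani)
    )


def select_representatives(
    table: ANITable,
    secondary: pd.Series,
    metadata: Mapping[str, GenomeMetadata] | Sequence[GenomeMetadata],
    primary: pd.Series | None = None,
    s_ani: float = SECONDARY_ANI,
    weights: ScoreWeights = ScoreWeights(),
) -> DereplicationResult:
    """Pick the highest-scoring genome of each secondary cluster.

    Centrality (mean ANI to the other cluster members; 1 for singletons) is
    computed before scoring.  Ties break on lexicographic genome id.
    """
    matrix = _require_matrix(table)
    if not isinstance(metadata, Mapping):
        metadata = {m.genome: m for m in metadata}
    missing = [g for g in matrix.index if g not in metadata]
    if missing:
        raise KeyError(f"metadata missing for genome(s): {missing[:5]}")
    centrality: dict[str, float] = {}
    scores: dict[str, float] = {}
    for cluster in sorted(secondary.unique()):
        members = sorted(secondary.index[secondary == cluster])
        for g in members:
            others = [m for m in members if m != g]
            centrality[g] = (
                float(matrix.loc[g, others].mean()) if others else 1.0
            )
            scores[g] = drep_score(metadata[g], centrality[g], s_ani, weights)
    representatives = {
        cluster: min(
            secondary.index[secondary == cluster], key=lambda g: (-scores[g], g)
        )
        for cluster in sorted(secondary.unique())
    }
    if primary is None:
        primary = pd.Series(
            [int(str(c).split(".")[0]) if "." in str(c) else 0 for c in secondary],
            index=secondary.index,
        )
    return DereplicationResult(
        primary=primary,
        secondary=secondary,
        representatives=representatives,
        scores=pd.Series(scores).reindex(matrix.index),
        centrality=pd.Series(centrality).reindex(matrix.index),
    )


def dereplicate(
    table: ANITable,
    metadata: Mapping[str, GenomeMetadata] | Sequence[GenomeMetadata],
    primary_threshold: float = PRIMARY_ANI,
    secondary_threshold: float = SECONDARY_ANI,
    min_cov: float = MIN_COVERAGE,
    method: Linkage = "average",
    weights: ScoreWeights = ScoreWeights(),
) -> DereplicationResult:
    """Full two-step dereplication from raw ANI pairs to representatives."""
    sym = symmetrize_ani(table, min_cov=min_cov) if table.matrix is None else table
    prim = primary_clusters(sym, primary_threshold, method)
    sec = secondary_clusters(sym, prim, secondary_threshold, method)
    return select_representatives(
        sym, sec, metadata, primary=prim, s_ani=secondary_threshold, weights=weights
    )


def ani_summary(table: ANITable) -> tuple[float, float, pd.DataFrame]:
    """(min nonzero off-diagonal ANI, max off-diagonal ANI, full matrix).

    Zero entries encode coverage-failed or missing pairs and are excluded
    from the minimum.
    """
    matrix = _require_matrix(table)
    if len(matrix) < 2:
        raise ValueError("need >=2 genomes for an ANI summary")
    arr = matrix.to_numpy().copy()
    np.fill_diagonal(arr, np.nan)
    off = arr[~np.isnan(arr)]
    valid = off[off > 0]
    if valid.size == 0:
        raise ValueError("no coverage-passing genome pairs")
    return float(valid.min()), float(off.max()), matrix
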