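"""Gene presence/absence (PAV) matrices and pangenome partitioning.

The PAV matrix — genomes x gene clusters, binary — is the central object of
the pipeline.  This module parses Roary-style outputs
(``gene_presence_absence.csv`` and ``gene_presence_absence.Rtab``), partitions
genes into core / accessory / singleton classes, counts genes unique to a
genome source group (MAGs vs isolates), and ordinates genomes by PCA on the
accessory submatrix.

Definitions
-----------
core
    gene present in more than ``core_fraction`` (default 0.95) of genomes
    (strict ``>`` by default; the comparator is configurable because the
    common tool convention is ``>=``).
singleton
    gene present in exactly one genome.
accessory
    everything else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "PAVMatrix",
    "GenePartition",
    "GroupUniqueness",
    "PAVError",
    "read_pav",
    "write_roary_csv",
    "write_rtab",
    "partition_genes",
    "group_unique_genes",
    "accessory_pca",
]

#: metadata columns preceding the per-genome columns in a Roary CSV
ROARY_META_COLUMNS = [
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
]


class PAVError(ValueError):
    """Malformed presence/absence input."""


@dataclass
class PAVMatrix:
    """Binary genomes x gene-clusters presence/absence matrix.

    Parameters
    ----------
    presence
        DataFrame with genome ids as the index, gene-cluster ids as the
        columns, and values in {0, 1}.
    source
        Optional per-genome source label (e.g. ``"MAG-food"``, ``"MAG-gut"``,
        ``"isolate"``), indexed like ``presence``.
    subspecies
        Optional per-genome subspecies label.
    """

    presence: pd.DataFrame
    source: pd.Series | None = None
    subspecies: pd.Series | None = None

    def __post_init__(self) -> None:
        values = self.presence.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise PAVError("presence matrix must be strictly binary")
        if self.presence.index.has_duplicates:
            raise PAVError("duplicated genome ids")
        if self.presence.columns.has_duplicates:
            raise PAVError("duplicated gene ids")
        col_sums = values.sum(axis=0)
        if self.n_genes and (col_sums == 0).any():
            bad = self.presence.columns[np.asarray(col_sums) == 0][:3].tolist()
            raise PAVError(f"all-zero gene columns (gene must occur in >=1 genome): {bad}")
        self.presence = self.presence.astype(np.int8)
        for attr in ("source", "subspecies"):
            lab = getattr(self, attr)
            if lab is not None:
                setattr(self, attr, lab.reindex(self.presence.index))

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genes(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_genomes(self) -> int:
        return self.presence.shape[0]

    @property
    def n_genes(self) -> int:
        return self.presence.shape[1]

    def gene_frequencies(self) -> pd.Series:
        """Carrier count per gene (number of genomes carrying it)."""
        return self.presence.sum(axis=0)


@dataclass
class GenePartition:
    """Partition of the gene set into core / accessory / singleton classes."""

    core: list[str]
    accessory: list[str]
    singleton: list[str]
    core_fraction: float
    comparator: str = ">"

    def __post_init__(self) -> None:
        sets = [set(self.core), set(self.accessory), set(self.singleton)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("core/accessory/singleton sets must be disjoint")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "total": len(self.core) + len(self.accessory) + len(self.singleton),
            "core": len(self.core),
            "accessory": len(self.accessory),
            "singleton": len(self.singleton),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "core") for g in self.core]
        rows += [(g, "accessory") for g in self.accessory]
        rows += [(g, "singleton") for g in self.singleton]
        return pd.DataFrame(rows, columns=["gene", "class"])


@dataclass
class GroupUniqueness:
    """Genes unique to each of two genome source groups, plus shared genes."""

    group_a: str
    group_b: str
    unique_a: list[str]
    unique_b: list[str]
    shared: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            f"unique_{self.group_a}": len(self.unique_a),
            f"unique_{self.group_b}": len(self.unique_b),
            "shared": len(self.shared),
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_pav(path: str | Path, dialect: Literal["roary_csv", "rtab"] = "roary_csv") -> PAVMatrix:
    """Read a gene presence/absence matrix.

    ``roary_csv``: Roary's ``gene_presence_absence.csv`` — 14 metadata columns
    followed by one column per genome; a non-empty cell means presence (multi-
    copy, tab-separated locus tags still count as presence 1).
    ``rtab``: tab-separated binary table, genes as rows, genomes as columns.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise PAVError(f"empty file: {path}")
    if dialect == "roary_csv":
        return _read_roary_csv(path)
    if dialect == "rtab":
        return _read_rtab(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_roary_csv(path: Path) -> PAVMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PAVError(f"empty file: {path}") from None
        n_meta = len(ROARY_META_COLUMNS)
        if len(header) <= n_meta or header[0] != "Gene":
            raise PAVError("not a Roary gene_presence_absence.csv header")
        genomes = header[n_meta:]
        if len(set(genomes)) != len(genomes):
            raise PAVError("duplicated genome columns")
        genes: list[str] = []
        rows: list[list[int]] = []
        for rec in reader:
            if not rec:
                continue
            genes.append(rec[0])
            rows.append([1 if cell.strip() else 0 for cell in rec[n_meta:]])
    presence = pd.DataFrame(
        np.asarray(rows, dtype=np.int8).T, index=genomes, columns=genes
    )
    return PAVMatrix(presence)


def _read_rtab(path: Path) -> PAVMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.has_duplicates:
        raise PAVError("duplicated genome columns")
    values = df.to_numpy()
    if not np.isin(values, ("0", "1")).all():
        bad = sorted(set(values.ravel()) - {"0", "1"})
        raise PAVError(f"non-binary Rtab cells: {bad}")
    presence = df.astype(np.int8).T  # to genomes x genes
    presence.index.name = None
    presence.columns.name = None
    return PAVMatrix(presence)


def write_roary_csv(pav: PAVMatrix, path: str | Path) -> None:
    """Write a minimal Roary-dialect CSV (presence cells hold the gene id)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(ROARY_META_COLUMNS + pav.genomes)
        freqs = pav.gene_frequencies()
        arr = pav.presence.to_numpy()
        for j, gene in enumerate(pav.genes):
            meta = [gene, "", "", str(int(freqs.iloc[j])), str(int(freqs.iloc[j])),
                    "1.0", "", "", "", "", "", "", "", ""]
            cells = [f"{gene}_{i}" if arr[i, j] else "" for i in range(pav.n_genomes)]
            writer.writerow(meta + cells)


def write_rtab(pav: PAVMatrix, path: str | Path) -> None:
    """Write the binary Rtab dialect (genes as rows, genomes as columns)."""
    pav.presence.T.to_csv(path, sep="\t", index_label="Gene")


# ---------------------------------------------------------------------------
# partitioning and group analysis
# ---------------------------------------------------------------------------

def partition_genes(
    pav: PAVMatrix,
    core_fraction: float = 0.95,
    comparator: Literal[">", ">="] = ">",
) -> GenePartition:
    """Partition genes into core / accessory / singleton classes.

    A gene is core when its carrier fraction exceeds ``core_fraction``
    (strictly, or inclusively with ``comparator=">="``); a singleton occurs in
    exactly one genome; everything else is accessory.  A gene meeting both the
    core rule and the singleton rule (only possible in tiny collections) is
    classed core.
    """
    if not 0 < core_fraction <= 1:
        raise ValueError(f"core_fraction must be in (0, 1], got {core_fraction}")
    counts = pav.gene_frequencies().to_numpy()
    frac = counts / pav.n_genomes
    is_core = frac > core_fraction if comparator == ">" else frac >= core_fraction
    is_singleton = (counts == 1) & ~is_core
    is_accessory = ~is_core & ~is_singleton
    genes = np.asarray(pav.genes)
    return GenePartition(
        core=genes[is_core].tolist(),
        accessory=genes[is_accessory].tolist(),
        singleton=genes[is_singleton].tolist(),
        core_fraction=core_fraction,
        comparator=comparator,
    )


def group_unique_genes(
    pav: PAVMatrix, grouping: Mapping[str, str] | None = None
) -> GroupUniqueness:
    """Count genes whose carriers all fall in one source group.

    ``grouping`` maps genome id to one of exactly two group labels; when
    omitted, the matrix's own ``source`` labels are used, with any label
    starting with ``"MAG"`` collapsed into group ``"MAG"``.
    """
    if grouping is None:
        if pav.source is None:
            raise ValueError("no grouping supplied and PAV has no source labels")
        grouping = {
            g: ("MAG" if str(lab).startswith("MAG") else str(lab))
            for g, lab in pav.source.items()
        }
    missing = [g for g in pav.genomes if g not in grouping or pd.isna(grouping[g])]
    if missing:
        raise ValueError(f"unlabeled genomes: {missing[:5]}")
    labels = pd.Series({g: grouping[g] for g in pav.genomes})
    groups = sorted(labels.unique())
    if len(groups) == 1:
        groups = [groups[0], "__other__"]
    if len(groups) != 2:
        raise ValueError(f"grouping must define exactly two groups, got {groups}")
    a_mask = (labels == groups[0]).to_numpy()
    arr = pav.presence.to_numpy().astype(bool)
    in_a = arr[a_mask].any(axis=0)
    in_b = arr[~a_mask].any(axis=0)
    genes = np.asarray(pav.genes)
    return GroupUniqueness(
        group_a=groups[0],
        group_b=groups[1],
        unique_a=genes[in_a & ~in_b].tolist(),
        unique_b=genes[in_b & ~in_a].tolist(),
        shared=genes[in_a & in_b].tolist(),
    )


def accessory_pca(
    pav: PAVMatrix, partition: GenePartition, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA ordination of genomes on the mean-centered accessory submatrix.

    Binary columns are centered but not scaled to unit variance, the standard
    treatment for presence/absence ordinations.  Returns per-genome component
    coordinates (columns ``PC1..PCn``) and the explained-variance fractions.
    The sign of each component is arbitrary.
    """
    if len(partition.accessory) < 2:
        raise ValueError("need >=2 accessory genes for PCA")
    if len(partition.accessory) < n_components:
        raise ValueError(
            f"fewer accessory genes ({len(partition.accessory)}) than components"
        )
    sub = pav.presence[partition.accessory].to_numpy(dtype=float)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(sub)
    frame = pd.DataFrame(
        coords,
        index=pav.presence.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_
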