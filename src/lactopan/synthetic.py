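"""Synthetic pipeline inputs with known ground truth.

Every downstream stage of the pipeline can be exercised without any
external download: this module plants a pangenome structure (exact core /
accessory / singleton counts and controllable open-vs-closed accumulation
behaviour), block-structured ANI tables with known cluster assignments,
two-niche community abundance tables with known shared and niche-unique
species, and gene -> term annotation maps with one deliberately
over-represented term.

All generators are deterministic under a fixed integer seed and carry no
hidden global state.  Writers for the on-disk dialects live with their
readers (:mod:`.pangenome`, :mod:`.dereplication`, :mod:`.profiles`,
:mod:`.enrichment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dereplication import ANITable, GenomeMetadata
from .enrichment import AnnotationMap
from .pangenome import PAVMatrix
from .profiles import AbundanceTable

__all__ = [
    "SyntheticPangenomeSpec",
    "SyntheticANISpec",
    "SyntheticCommunitySpec",
    "generate_pav",
    "open_regime_spec",
    "closed_regime_spec",
    "generate_ani_inputs",
    "generate_abundance_table",
    "generate_annotation_map",
]


# ---------------------------------------------------------------------------
# pangenome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPangenomeSpec:
    """Planted pangenome structure.

    ``accessory_freq_spectrum`` lists (presence probability, gene count)
    pairs; each accessory gene is carried by a genome independently with
    its probability, re-drawn until the realized carrier count lies in
    [2, n_genomes - 1] so the planted partition is exact under the
    100%-core / singleton rule.  Each genome additionally receives
    ``singletons_per_genome`` private genes.
    """

    n_genomes: int
    n_core: int
    accessory_freq_spectrum: list[tuple[float, int]] = field(default_factory=list)
    singletons_per_genome: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError(f"need >=2 genomes, got {self.n_genomes}")
        if self.n_core < 0 or self.singletons_per_genome < 0:
            raise ValueError("counts must be non-negative")
        for p, count in self.accessory_freq_spectrum:
            if not 0 < p < 1:
                raise ValueError(f"presence probability must be in (0, 1), got {p}")
            if count < 0:
                raise ValueError("accessory gene counts must be non-negative")

    @property
    def total_genes(self) -> int:
        acc = sum(c for _, c in self.accessory_freq_spectrum)
        return self.n_core + acc + self.n_genomes * self.singletons_per_genome


def generate_pav(spec: SyntheticPangenomeSpec) -> PAVMatrix:
    """Generate a PAV matrix realizing the planted structure exactly.

    Core genes are present everywhere; accessory columns are Bernoulli
    draws conditioned on a carrier count in [2, n-1]; singleton columns
    carry exactly one genome.  Genome ids get alternating ``MAG`` /
    ``isolate`` source labels so group-uniqueness analyses have a surface.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.n_genomes
    columns: list[np.ndarray] = []
    names: list[str] = []
    if spec.n_core:
        columns.append(np.ones((g, spec.n_core), dtype=np.int8))
        names += [f"core_{i:05d}" for i in range(spec.n_core)]
    for block, (p, count) in enumerate(spec.accessory_freq_spectrum):
        if count == 0:
            continue
        cols = np.empty((g, count), dtype=np.int8)
        for j in range(count):
            while True:
                col = (rng.random(g) < p).astype(np.int8)
                if 2 <= col.sum() <= g - 1:
                    break
            cols[:, j] = col
        columns.append(cols)
        names += [f"acc{block}_{j:05d}" for j in range(count)]
    if spec.singletons_per_genome:
        s = spec.singletons_per_genome
        cols = np.zeros((g, g * s), dtype=np.int8)
        for i in range(g):
            cols[i, i * s:(i + 1) * s] = 1
        columns.append(cols)
        names += [f"sing_g{i:03d}_{j}" for i in range(g) for j in range(s)]
    if not columns:
        raise ValueError("spec plants no genes at all")
    presence = pd.DataFrame(
        np.hstack(columns),
        index=[f"genome_{i:03d}" for i in range(g)],
        columns=names,
    )
    source = pd.Series(
        ["MAG-food" if i % 2 == 0 else "isolate" for i in range(g)],
        index=presence.index,
    )
    return PAVMatrix(presence, source=source)


def open_regime_spec(n_genomes: int = 40, seed: int = 0) -> SyntheticPangenomeSpec:
    """An open-pangenome regime: a long tail of rare accessory genes plus
    per-genome singletons, so new genes keep arriving at a non-vanishing
    rate as genomes are added."""
    return SyntheticPangenomeSpec(
        n_genomes=n_genomes,
        n_core=800,
        accessory_freq_spectrum=[(0.5, 300), (0.15, 600), (0.06, 1200)],
        singletons_per_genome=35,
        seed=seed,
    )


def closed_regime_spec(n_genomes: int = 40, seed: int = 0) -> SyntheticPangenomeSpec:
    """A closed-pangenome regime: a finite gene pool with every accessory
    frequency >= 0.5 and no singletons, so the accumulation curve
    plateaus."""
    return SyntheticPangenomeSpec(
        n_genomes=n_genomes,
        n_core=1200,
        accessory_freq_spectrum=[(0.5, 400), (0.7, 300), (0.9, 200)],
        singletons_per_genome=0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ANI / dereplication inputs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticANISpec:
    """Block-structured ANI table with planted clusters.

    Within-cluster pair ANI is drawn uniformly from ``within_ani_range``
    and between-cluster ANI from ``between_ani_range``; the two ranges must
    not overlap (within strictly above between) so thresholds between them
    recover the planted assignment exactly.
    """

    cluster_sizes: list[int]
    within_ani_range: tuple[float, float] = (0.999, 1.0)
    between_ani_range: tuple[float, float] = (0.85, 0.90)
    coverage_value: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cluster_sizes:
            raise ValueError("cluster_sizes must be non-empty")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        for lo, hi in (self.within_ani_range, self.between_ani_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("ANI ranges must satisfy 0 <= low <= high <= 1")
        if self.between_ani_range[1] >= self.within_ani_range[0]:
            raise ValueError("within-ANI range must lie entirely above between-ANI range")
        if not 0 < self.coverage_value <= 1:
            raise ValueError("coverage must be in (0, 1]")


def generate_ani_inputs(
    spec: SyntheticANISpec,
) -> tuple[ANITable, list[GenomeMetadata], pd.Series]:
    """Directed ANI pairs for all genome pairs, metadata, and the planted
    cluster label per genome.

    Both directions of every pair are emitted with the same value, so the
    table is symmetric by construction.  Metadata fields are drawn from
    realistic high-quality ranges: completeness 90-100%, contamination
    0-5%, strain heterogeneity 0-30%, N50 50 kb - 500 kb, genome size
    2.2 - 2.8 Mb (the typical lactococcal span).
    """
    rng = np.random.default_rng(spec.seed)
    genomes: list[str] = []
    planted: list[int] = []
    for c, size in enumerate(spec.cluster_sizes):
        for i in range(size):
            genomes.append(f"genome_c{c:02d}_{i:02d}")
            planted.append(c)
    labels = pd.Series(planted, index=genomes)
    rows = []
    w_lo, w_hi = spec.within_ani_range
    b_lo, b_hi = spec.between_ani_range
    for i, gi in enumerate(genomes):
        for j in range(i + 1, len(genomes)):
            gj = genomes[j]
            if planted[i] == planted[j]:
                ani = float(rng.uniform(w_lo, w_hi))
            else:
                ani = float(rng.uniform(b_lo, b_hi))
            rows.append((gi, gj, ani, spec.coverage_value))
            rows.append((gj, gi, ani, spec.coverage_value))
    pairs = pd.DataFrame(rows, columns=["query", "reference", "ani", "coverage"])
    metadata = []
    for g in genomes:
        size = int(rng.uniform(2.2e6, 2.8e6))
        metadata.append(
            GenomeMetadata(
                genome=g,
                completeness=float(rng.uniform(90, 100)),
                contamination=float(rng.uniform(0, 5)),
                strain_heterogeneity=float(rng.uniform(0, 30)),
                n50=int(rng.uniform(5e4, 5e5)),
                size=size,
                source=str(rng.choice(["MAG-food", "MAG-gut", "isolate"])),
            )
        )
    return ANITable(pairs), metadata, labels


# ---------------------------------------------------------------------------
# community abundance
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCommunitySpec:
    """Two-niche community with planted shared and niche-unique species.

    Each species relevant to a niche occurs in each of that niche's samples
    with probability ``target_prevalence``; occurrences receive a lognormal
    abundance (parameters ``abundance_mu``/``abundance_sigma`` in log
    space) and each sample is then renormalized to sum to exactly 100
    (percent scale).  Every planted species is guaranteed at least one
    occurrence in its niche so overlap counts match the plant exactly.
    """

    n_samples_per_niche: dict[str, int] = field(
        default_factory=lambda: {"food": 30, "human": 30}
    )
    n_shared_species: int = 10
    n_unique_per_niche: int = 8
    target_prevalence: float = 0.6
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples_per_niche:
            raise ValueError("need at least one niche")
        if any(n < 1 for n in self.n_samples_per_niche.values()):
            raise ValueError("every niche needs >=1 sample")
        if self.n_shared_species < 0 or self.n_unique_per_niche < 0:
            raise ValueError("species counts must be non-negative")
        if self.n_shared_species + self.n_unique_per_niche == 0:
            raise ValueError("spec plants no species")
        if not 0 < self.target_prevalence <= 1:
            raise ValueError("target_prevalence must be in (0, 1]")


def generate_abundance_table(spec: SyntheticCommunitySpec) -> AbundanceTable:
    """Generate the sample x species percent-scale abundance table."""
    rng = np.random.default_rng(spec.seed)
    niches = list(spec.n_samples_per_niche)
    shared = [f"shared_{i:03d}" for i in range(spec.n_shared_species)]
    unique = {
        niche: [f"unique_{niche}_{i:03d}" for i in range(spec.n_unique_per_niche)]
        for niche in niches
    }
    species = shared + [s for niche in niches for s in unique[niche]]
    samples: list[str] = []
    niche_labels: list[str] = []
    for niche, n in spec.n_samples_per_niche.items():
        samples += [f"{niche}_{i:03d}" for i in range(n)]
        niche_labels += [niche] * n
    values = pd.DataFrame(0.0, index=samples, columns=species)
    niche_series = pd.Series(niche_labels, index=samples)
    for niche in niches:
        niche_samples = niche_series.index[niche_series == niche]
        relevant = shared + unique[niche]
        present = rng.random((len(niche_samples), len(relevant))) < spec.target_prevalence
        # guarantee each planted species occurs at least once in its niche
        for j in range(len(relevant)):
            if not present[:, j].any():
                present[rng.integers(len(niche_samples)), j] = True
        # and each sample carries at least one species (rows must sum to 100)
        for i in range(len(niche_samples)):
            if not present[i].any():
                present[i, rng.integers(len(relevant))] = True
        abundance = np.where(
            present,
            rng.lognormal(spec.abundance_mu, spec.abundance_sigma, present.shape),
            0.0,
        )
        abundance = abundance / abundance.sum(axis=1, keepdims=True) * 100.0
        values.loc[niche_samples, relevant] = abundance
    return AbundanceTable(values, niche_series)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation_map(
    n_genes: int,
    n_terms: int,
    enriched_term: str = "T000",
    enrichment_factor: float = 1.0,
    seed: int = 0,
    subset_fraction: float = 0.2,
) -> tuple[AnnotationMap, list[str]]:
    """Gene -> term map with one term over-represented in a designated
    gene subset.

    The designated subset is the first ``subset_fraction`` of the gene ids.
    Outside the subset every (gene, term) link is drawn with a common
    background probability (targeting about two terms per gene); inside the
    subset the enriched term's probability is multiplied by
    ``enrichment_factor``.  Genes that come out unannotated get one
    uniformly random term so the universe covers all genes.  Returns the
    map and the designated subset.
    """
    if n_terms < 1:
        raise ValueError("need >=1 term")
    if enrichment_factor < 1:
        raise ValueError(f"enrichment_factor must be >=1, got {enrichment_factor}")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    terms = [f"T{i:03d}" for i in range(n_terms)]
    if enriched_term not in terms:
        raise ValueError(f"enriched_term {enriched_term!r} not among the {n_terms} terms")
    subset = genes[: max(1, int(round(n_genes * subset_fraction)))]
    subset_set = set(subset)
    p0 = min(0.8, 2.0 / n_terms)
    p_enriched = min(0.95, p0 * enrichment_factor)
    gene_terms: dict[str, set[str]] = {}
    for gene in genes:
        carried = set()
        draws = rng.random(n_terms)
        for t, term in enumerate(terms):
            p = p_enriched if (term == enriched_term and gene in subset_set) else p0
            if draws[t] < p:
                carried.add(term)
        if not carried:
            carried.add(terms[rng.integers(n_terms)])
        gene_terms[gene] = carried
    return AnnotationMap(gene_terms), subset
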