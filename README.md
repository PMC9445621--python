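# lactopan

Downstream pangenome and community analysis for bacterial genome catalogs
that mix metagenome-assembled genomes (MAGs) with isolate genomes — built
around the kind of catalog assembled for *Lactococcus lactis* from fermented
foods and the human gut, but applicable to any conspecific genome collection.

Given the standard upstream outputs — a Roary-style gene presence/absence
matrix, fastANI pairwise identities, CheckM-style genome quality metrics, a
MetaPhlAn-style relative-abundance table and a gene → functional-term map —
`lactopan` answers the questions a pangenome study asks of them:

- **Partitioning.** Which genes are core (carried by > 95 % of genomes),
  accessory, or singletons (one genome only)?  Which genes occur only in
  MAGs, or only in isolates?  How do genomes ordinate in a PCA on the
  accessory genes?
- **Openness.** Adding genomes in random order, gene accumulation is
  averaged over permutations and fitted with power laws: new genes
  *n* = *kN*ʳ + *a* and total genes *y* = *kN*^γ + *c*.  The pangenome is
  *open* when the integral ∫ (*kN*ʳ + *a*) d*N* from the catalog size to
  infinity diverges, i.e. *a* > 0 or *r* ≥ −1 — judged on the 95 %
  confidence intervals, with the Heaps'-law signal γ ∈ (0, 1) reported
  alongside.
- **Dereplication.** Two-step ANI clustering (95 % primary, 99.8 %
  secondary, alignment covering ≥ 50 % of the shorter genome), then one
  representative per cluster by the score
  `Completeness − 5·Contamination + Contamination·(SH/100) + 0.5·log10(N50)
  + (centrality − S_ani)`.
- **Community profiles.** Presence at > 0.01 % relative abundance,
  per-niche prevalence and mean abundance, abundance variance on the
  fraction scale, shared/unique species counts between niches, Bray–Curtis
  dissimilarity and a complete-linkage sample tree in Newick.
- **Enrichment.** One-sided hypergeometric over-representation of
  functional terms with Benjamini–Hochberg correction and dual
  p < 0.05 / q < 0.05 thresholds.

A synthetic-data module generates every input with planted ground truth —
exact core/accessory/singleton structure, block-structured ANI matrices
with known clusters, two-niche communities with known species overlap, and
annotation maps with one deliberately enriched term — so the whole pipeline
is testable without downloading anything.

## Worked example

```python
from lactopan import (
    generate_pav, open_regime_spec, partition_genes, accumulation_curves,
    fit_new_gene_model, fit_total_gene_model, assess_openness,
)

pav = generate_pav(open_regime_spec(n_genomes=30, seed=0))
part = partition_genes(pav, core_fraction=0.95)
print(part.counts)

curve = accumulation_curves(pav, n_permutations=10, seed=1)
new_fit = fit_new_gene_model(curve)
total_fit = fit_total_gene_model(curve)
verdict = assess_openness(new_fit, total_fit)
print(verdict.verdict, verdict.reasons)
```

prints

```
{'total': 3950, 'core': 800, 'accessory': 2100, 'singleton': 1050}
open ['r >= -1 supported by CI (-0.353, -0.306)',
      'Heaps exponent gamma = 0.300 in (0, 1)']
```

The partition recovers the planted structure exactly: this open-regime
generator plants 800 core genes, 2 100 accessory genes (with a long tail of
rare ones) and 35 private genes per genome.  The new-gene decay exponent
*r* ≈ −0.33 sits well above −1, so the fitted new-gene curve has a
divergent integral and the catalog is called open; the total-gene Heaps
exponent γ ≈ 0.30 in (0, 1) agrees.  The fits here have R² > 0.998.

The same analysis runs from the shell on real files:

```sh
lactopan pipeline --demo --seed 11 --outdir demo_out   # all-synthetic demo
lactopan pangenome gene_presence_absence.csv           # partition a Roary CSV
lactopan openness pav.Rtab --dialect rtab --seed 3
lactopan dereplicate fastani.tsv genome_metadata.tsv
lactopan profiles abundance.tsv sample_niches.tsv
```

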