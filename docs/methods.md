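# Methods

This note documents the models, conventions and numerical choices behind
`lactopan`, and what its synthetic-data tests do and do not establish.

## Gene presence/absence and partitioning

The central object is the binary genomes × gene-clusters matrix (PAV).
The Roary CSV reader treats any non-empty per-genome cell as presence 1 —
multi-copy entries (tab-separated locus tags) still count once, since the
analysis is strictly presence/absence.  The Rtab reader accepts only 0/1
cells and rejects anything else.  A gene column with no carriers is
invalid: every gene cluster must occur in at least one genome.

Core genes are those whose carrier fraction exceeds `core_fraction`
(default 0.95).  The comparator is strict `>` by default but configurable
to `>=`, because the two conventions coexist in practice (prose
definitions usually say "more than 95 %", while Roary's `-cd 95` flag is
inclusive) and the choice moves genes at exactly the threshold.  Singletons
are genes carried by exactly one genome; everything else is accessory.  A
gene that satisfies both the core and singleton rules (possible only when
`core_fraction < 1/n`) is classed core.

Group uniqueness (MAG-only vs isolate-only genes) assigns a gene to a
group iff *all* its carriers belong to that group.  The PCA ordination
runs on the mean-centered accessory submatrix without unit-variance
scaling — standard for presence/absence data, where scaling would inflate
rare columns.  The exact (full-SVD) solver is used so results are
deterministic; component signs are arbitrary and tests compare up to sign.

## Rarefaction and the openness fit

Accumulation curves add genomes in uniformly random order; at step *N* the
*new* genes are those first observed there, and the total is their running
sum.  Means are taken over `n_permutations` independent orderings (default
10; duplicated orderings are allowed).  An exhaustive mode enumerates all
*G*! orderings for small *G* — it exists so the sampled estimator can be
validated against the exact expectation, and it is what the test suite
uses as the oracle.

Two three-parameter power laws are fitted by Levenberg–Marquardt nonlinear
least squares (`scipy.optimize.curve_fit`) with multi-start initialization
(a direct start from the first point and the tail mean, a log-log-regression
seeded start, and fixed fallbacks); the converged fit with the smallest
residual sum of squares wins, and failure from every start raises an
explicit error with diagnostics:

- new genes: *n*(*N*) = *k·N*ʳ + *a*, fitted on *N* ≥ 2 by default — the
  first point is the first genome's entire gene complement and sits
  off-model, so it is excluded (configurable);
- total genes: *y*(*N*) = *k·N*^γ + *c*, fitted on all points.

95 % confidence intervals come from the asymptotic parameter covariance
with t-quantiles on *n* − 3 degrees of freedom, matching what common
curve-fitting software reports.  R² is defined as 1 − SS_res/SS_tot about
the mean; this is stated explicitly because R² is not unique for nonlinear
models.  A constant input series (or an all-zero new-gene tail) is flagged
degenerate rather than fitted.

The openness verdict uses the divergent-integral criterion:
∫_G^∞ (*k·N*ʳ + *a*) d*N* is infinite iff *a* > 0 or *r* ≥ −1.  To avoid
calling openness on noise around *a* ≈ 0, the criteria are CI-supported:
*open* requires the lower CI bound of *a* to be positive or the upper CI
bound of *r* to reach −1; *closed* requires *a*'s CI not to exceed 0 and
*r*'s CI to lie entirely below −1; anything else (including degenerate
fits) is *indeterminate*.  When a total-gene fit is available, γ ∈ (0, 1)
is reported as a supporting Heaps'-law reason but never decides the
verdict on its own.

## Dereplication

The ANI matrix view is built from directed (query, reference) pairs:
values are fractions in [0, 1] (percent input is divided by 100 at the
reader); pairs whose alignment covers less than `min_cov` (default 0.5) of
the shorter genome are treated as ANI 0; asymmetric reciprocal values are
averaged and a missing reciprocal keeps the present value (fastANI emits
directed pairs, and no principled reason favors one direction).  Both
clustering steps — primary at 0.95, secondary at 0.998 within each primary
cluster — use average-linkage hierarchical clustering on distance 1 − ANI
cut at 1 − threshold, the default of the reference dereplication tool;
single and complete linkage are available, and the test oracle is a naive
O(n³) agglomeration mirroring the configured linkage.  Because the package
consumes one pairwise ANI table, the primary step runs on the same matrix
rather than on separate Mash distances; sketching is upstream and out of
scope.

The representative score is

    Score = A·Completeness − B·Contamination
            + C·(Contamination · strain_heterogeneity/100)
            + D·log10(N50) + E·log10(size) + F·(centrality − S_ani)

with defaults (A..F) = (1, 5, 1, 0.5, 0, 1), base-10 logarithms (the scale
of the reference tool), centrality = mean ANI to the other members of the
genome's secondary cluster (1 for singletons), and S_ani the secondary
threshold.  E = 0 means genome size does not influence the default score;
the term is retained for formula fidelity.  Ties break on lexicographic
genome id.  Two hand-checkable values pin the arithmetic: a perfect
genome (100/0/0, N50 10⁵) at centrality = S_ani scores 102.5, and
(90/4/50, N50 10⁴, centrality − S_ani = 0.001) scores 74.001.

## Community profiles

Abundances are on the MetaPhlAn percent scale (each sample's species sum
≤ 100).  Presence is strict: a species exists in a sample iff its
abundance exceeds 0.01 % — a value exactly at the threshold is absent.
This single presence definition is used everywhere (prevalence, niche
membership, positive-sample selection).

Abundance variance is the n−1 sample variance of the *fraction*-scale
values (percent / 100), over all samples of the niche including zeros.
The fraction scale and divisor are documented choices: variances of
species abundances are only comparable across studies on a stated scale,
and with hundreds of samples the divisor is immaterial.

Bray–Curtis is computed on abundances as given (the index is invariant
under a common row scale): BC = 1 − 2·Σ min / Σ (x + y).  A pair of
all-zero samples has no defined dissimilarity; it is set to 0 with a
runtime warning rather than NaN, so downstream clustering stays total.
The sample tree uses complete linkage; in the Newick output leaves sit at
height 0, each internal node at its merge height, and a child's branch
length is parent height minus child height (a two-leaf tree at distance
*d* joins with two branches of length *d*).

## Enrichment

The universe is the set of annotated genes — genes without any functional
term are outside the test, consistent with ordinary over-representation
practice.  For each term with at least one hit in the gene set,
p = P(X ≥ k) with X ~ Hypergeometric(N, K, n); the test is one-sided
(over-representation only).  BH adjustment runs across the tested terms
(those with ≥ 1 hit), and a term is enriched iff p < 0.05 and q < 0.05.
No ontology-graph propagation is performed; the gene → term map is used as
given.  `bh_adjust` is implemented directly (step-up with monotonicity
enforcement) and cross-checked in the tests against an independent
textbook reimplementation and against statsmodels.

## Synthetic data: what it emulates and what it does not

The generators plant ground truth for every stage:

- **PAV.** Core columns are all-ones; each accessory gene is an
  independent Bernoulli draw per genome at its spectrum probability,
  re-drawn until the carrier count lands in [2, n−1] so the planted
  partition is exact under the 100 %-core/singleton rule; singletons are
  private columns.  The *open regime* (defaults: 800 core, accessory
  spectrum (0.5, 300), (0.15, 600), (0.06, 1200), 35 singletons per
  genome) keeps new genes arriving at a non-vanishing rate; the *closed
  regime* (1200 core, all accessory frequencies ≥ 0.5, no singletons) has
  a finite pool and plateaus.  The defaults were chosen once as a
  plausible bacterial-catalog shape — a few thousand genes across a few
  dozen genomes with singletons roughly half the pool in the open case.
- **ANI.** Within-cluster and between-cluster ANI are drawn from disjoint
  uniform ranges (defaults 0.999–1.0 and 0.85–0.90), both directions of
  each pair emitted with the same value; metadata are drawn from
  high-quality ranges (completeness 90–100 %, contamination 0–5 %, N50
  50–500 kb, size 2.2–2.8 Mb — the typical lactococcal span).
- **Community.** Two niches; shared species occur in both, unique species
  only in theirs, each with the target per-sample prevalence; occurrences
  get lognormal abundances and rows are renormalized to sum to exactly
  100.  Every planted species is guaranteed ≥ 1 occurrence in its niche so
  overlap counts match the plant exactly; realized prevalence is
  binomial around the target.
- **Annotation.** Background gene–term links at a common probability
  (≈ 2 terms per gene); inside a designated subset one term's probability
  is multiplied by the enrichment factor; unannotated genes receive one
  uniform term so the universe covers all genes.

What the synthetic data does *not* emulate: gene linkage (accessory
presence is independent per genome, with no phylogenetic correlation or
co-occurring operons), ANI transitivity noise (real ANI matrices are not
exact block matrices), compositional correlation between species, sequence
content of any kind, or CheckM's estimation behavior.  Passing tests
therefore demonstrate that the *computations* are correct on inputs with
known answers — not that real catalogs satisfy the generators'
independence assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
instances — 30-genome catalogs, 10 permutations, 20 replicates per regime,
10-genome ANI matrices, universes of a few hundred genes — sizes at which
the exhaustive oracles (all 4!–6! orderings, full enumeration of
hypergeometric draws at N ≤ 12, O(n³) agglomeration) remain exact and the
whole suite completes in seconds.  All randomness flows through explicit
integer seeds into `numpy.random.default_rng`; there is no hidden global
state, and the demo pipeline writes byte-identical summaries under a fixed
seed.

## Known limitations

- The openness verdict is tied to the three-parameter power-law family;
  likelihood-based pangenome-size models (binomial mixtures,
  infinitely-many-genes) are out of scope.
- Asymptotic CIs can be optimistic when residuals are autocorrelated
  across N, which rarefaction means are by construction; bootstrap CIs
  over permutations would be the conservative alternative and the CI
  machinery accepts that extension.
- Reproducing published cluster counts from real fastANI output can be
  sensitive to the ANI tool's version and to whether primary clustering
  used Mash or fastANI values; with one input table the package uses the
  same matrix for both steps.
- Enrichment treats terms independently; correlated terms (e.g. nested
  ontology categories) inflate the number of tests.
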