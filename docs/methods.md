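# Methods

## The analysis in one paragraph

Reciprocal crosses between two divergent breeds give four genetic groups
— purebred taurine (1), indicine-sired cross (2), taurine-sired cross
(3), purebred indicine (4) — in which a gene's inheritance mode is
identified from where the two cross means sit relative to the purebred
means on the log2 CPM scale. `crossmode` normalizes counts, finds the
purebred differentially expressed genes per tissue, and classifies each
of them by the ratio system described below. All statistics operate on
per-(tissue, group) mean log2 CPM; sexes are pooled throughout and batch
is removed as a nuisance.

## Normalization chain

- **CPM filter.** Genes below 0.5 CPM in all but < `min_samples` samples
  are removed; the default `min_samples = 3` is the smallest group size
  (3 replicates of one sex). Filtering is applied per tissue, keeps
  library sizes fixed (hence is idempotent), and precedes everything
  else.
- **TMM factors.** Standard trimmed mean of M-values: reference sample =
  the one whose 75th-percentile relative abundance is closest to the
  mean; genes zero in either member of a pair dropped pairwise; 30%
  two-sided trim on M, 5% on A; inverse-delta-method-variance weights;
  factors rescaled to geometric mean 1. The implementation is checked
  against a step-by-step reference and against edgeR's
  `calcNormFactors` on the same matrix (agreement ~1e-8).
- **log2 CPM.** log2((y + pc)/(L_eff + 2·pc)·1e6) with effective library
  L_eff = library × TMM factor and prior pc = `prior_count` (default
  0.5) *on the CPM scale*, i.e. pc = prior·L_eff/1e6 counts. Scaling the
  prior with the library makes the transform exactly invariant to
  rescaling a library together with its counts, and finite at zero.
- **Batch centering.** Per-gene least squares of expression on protected
  design factors plus sum-coded batch; the fitted batch component is
  subtracted. On balanced designs protected-factor contrasts are
  untouched exactly; batch contrasts aliased with protected factors are
  detected by residualization and left uncorrected with a warning.
- **MDS QC.** Pairwise sample distance = root-mean-square of the top 500
  squared log2 fold changes (leading-fold-change style), followed by
  classical scaling (double-centering + eigendecomposition). Coordinates
  are defined up to rotation/reflection; tests compare distances and
  cluster structure, never axes.

## Differential expression

Per gene, a Welch two-sample t on log2 CPM with Satterthwaite degrees of
freedom, BH-adjusted within each contrast; DEGs are q < 0.05 (strict)
with an optional fold-change filter |log2FC| ≥ 1 ("FC ≥ 2", non-strict).
This is a deliberate, documented stand-in for moderated-variance models
(limma-voom style): it shares contrasts, multiplicity control and
selection semantics while remaining a self-contained primitive with an
exact textbook oracle. The DE stage is pluggable — anything producing
the same result columns can feed `deg_select` and the classifier.
Consequences worth knowing: with n = 6 per group the Welch test is
slightly conservative (observed type-I error ≈ 0.045–0.05 after batch
centering), and per-gene variances are estimated without shrinkage, so
power at small effects is below what a moderated model would give.
Constant-and-equal groups are reported as p = 1, constant-but-unequal as
p = 0.

## The inheritance classifier

Inputs per gene and tissue: group means m1..m4, the six absolute
differences d_ij, and ratios d_ij/d14. Relative cross positions
r_g = (m_g − m4)/(m1 − m4) place the gene in a 2-D rule space.

Default thresholds: θ_high = 0.8 (a cross separation d23/d14 above this
flags parental-driven expression), θ_low = 0.2 ("negligible" normalized
difference), min_d14 = 0.5 log2 units (guard below which ratios are
meaningless and the gene is UNCLASSIFIED). Classification is restricted
to purebred 1-vs-4 DEGs, mirroring the source analysis; the guard
matters only for genes selected by q-value with small fold changes.

`consistent` mode (default) uses pairwise-disjoint regions:

| region | condition |
|---|---|
| maternal | d23/d14 > θ_high, r2 > 1−θ_low, r3 < θ_low |
| paternal | d23/d14 > θ_high, r3 > 1−θ_low, r2 < θ_low |
| taurine-dominant | d23/d14 < θ_low, both r > 1−θ_low |
| indicine-dominant | d23/d14 < θ_low, both r < θ_low |
| additive | d23/d14 < θ_low, both r ∈ [θ_low, 1−θ_low] |
| complex | anything else |

Flavors: maternal/paternal calls are *taurine* when m1 > m4 else
*indicine*; dominant calls are *activation* when the dominant breed is
the high expresser, *inhibition* otherwise. Boundary ties follow the
printed inequality directions: strict for the θ_high and θ_low
comparisons, closed interval for the additive band.

`as_printed` mode evaluates the eight originally published inequality
sets verbatim, in printed order, first match wins, no match → complex.
Three caveats are preserved deliberately and covered by tests: (1) the
final rule is printed twice as indicine dominant-*inhibition*; the
second occurrence ("high expression in Bi") is treated as the obvious
typo for *activation*, by symmetry with the taurine pair. (2) The
dominant rules' `< 0.8` inequalities admit additive geometry (the exact
midpoint satisfies them) and *exclude* the exact-dominance prototype
(where d24/d14 = 1), so calls in this mode disagree with the geometric
reading; `consistent` mode replaces them with
proximity-to-the-dominant-parent conditions. (3) No additive rule is
printed, so `as_printed` cannot emit ADDITIVE.

The additive band [θ_low, 1−θ_low] quantifies the informal "approximately
midway" description; it is a design decision of this package, exposed
via `ClassifierThresholds`. Both modes are verified on an exhaustive
(r2, r3) grid against independently coded rule-table oracles, including
region disjointness in consistent mode.

## Synthetic data generator

Each gene gets a category (multinomial; defaults NULL 0.60, ADDITIVE
0.30, each of the eight parent/dominance classes 0.01, COMPLEX 0.02 — a
mix echoing the finding that ~90% of DEGs are additive), a signed breed
effect (|e| uniform on [1, 4] log2 units; sign fixed by the category's
flavor, random for additive/complex, exactly 0 for NULL), a baseline
N(4, 2) log2 CPM, and a log-normal NB dispersion centred at 0.1
(biological replication across animals). Noiseless geometry: m1/m4 at
baseline ± e/2 and crosses at the category's relative positions (0.5
additive; 1/0 maternal; 0/1 paternal; 1/1 or 0/0 dominant). COMPLEX
genes place their crosses by rejection sampling outside every
consistent-mode region (with a 0.01 margin) — complex inheritance is
defined negatively, as whatever the rule system does not cover. Tissue
(sd 1.0), sex (sd 0.1) and batch (sd 0.2) effects are global per-gene
log2 shifts that do not interact with inheritance, matching an analysis
that pools sexes and removes batch. Counts are NB with mean
library × 2^(log2 profile)/Σ and variance μ + φμ²; libraries are
log-normal ~1–3 million reads. Desk scale is intentional: CPM-based
inference is library-scale-free, so tens of millions of reads would add
runtime, not information.

What the generator does **not** emulate: gene–gene correlation,
tissue-specific inheritance (planted modes are shared across tissues, so
cross-tissue DEG overlap is higher and tissue separation in MDS weaker
than in real data), length or GC biases, isoforms, and allele-level
reads (the data model cannot express allele-specific imprinting, only
its group-mean signature). Passing tests therefore certify the
algorithmic chain, not biological discovery performance on real
libraries.

## Genomic context

Neighbor pairs use 1-based closed intervals; distance = gap between
closest gene ends, max(0, max(starts) − min(ends)), with an inclusive
threshold (default 100 kb) — a bit-exact contract chosen because the
prose definition is silent. "Opposite transcriptional direction" means
opposite DE log2FC signs (the strand relation is reported separately per
pair); zero or missing fold changes are excluded from the denominator
and counted. Because one lncRNA may have several neighbors, both
denominators are reported: the pair-level fraction and the lncRNA-level
fraction (a lncRNA counts as opposite when > half of its scored pairs
are). Enrichment is the one-sided hypergeometric tail per set,
intersected with the universe first, BH across sets; GO/KEGG names are
opaque strings from user GMT files.

## Numerical and determinism choices

All randomness flows from `numpy.random.default_rng([seed, stream])`
with fixed per-stage stream ids, so stages are independently
reproducible and a pipeline rerun is byte-identical. Sub-second
runtimes drive the default problem sizes (hundreds to a few thousand
genes); recovery and calibration tests use one tissue (24 samples) with
20 seeds. The recovery benchmark runs at NB dispersion 0.05 and planted
|effect| ≥ 2 with 6 samples per group, the regime in which category
geometry is identifiable at this replication level; mean recovery of
parent/dominance categories across seeds is ≈ 0.97. Known limitation:
genes near region boundaries or with baselines near the detection floor
blur into COMPLEX/neighboring categories under noise, which is why the
additive fraction among DEGs in noisy desk-scale runs (~0.6) is below
the noiseless value.
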