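# Methods

`habprof` implements a cross-habitat comparison of bacterial and fungal
communities from shotgun metagenomes: miTag-style SSU rRNA profiling with
a rank-gated LCA classifier, functional (orthologous-group and CAZyme)
profiling, bacterial:fungal abundance statistics, habitat-level
clustering and nestedness, and indicator-genus analysis. Because the
pipeline is designed to be testable without external sequence archives,
every stage is paired with a synthetic-data generator whose ground truth
is emitted alongside the data. This note records the models, the
parameters that matter, and the design choices made where the underlying
procedure was open.

## Read quality control (`habprof.qc`)

The expected number of sequencing errors of a read is
`E = sum_i 10^(-Q_i/10)` over its Phred scores. Trimming iterates two
rules to a fixed point, so trimming is idempotent and always returns a
prefix:

* while the 3'-terminal window of `trim_window` (15) bases has mean
  quality below `trim_quality` (20), the window is cut off;
* the read is truncated to its longest prefix with `E <=
  trim_accum_error` (1.0).

Filtering then applies, in fixed order: an error-probability rule, an
ambiguity rule (more than 1 non-ACGT base), and a homopolymer rule (a
run strictly longer than 15; a 15-base run passes). The
error-probability rule discards a read when the realized error count is
too likely to exceed `max_accum_error` (2.5): the error count is
modelled as Poisson with mean `E` (a tractable surrogate for the exact
Poisson-binomial over per-base error probabilities), and the read is
discarded when `P(X > 2.5) = 1 - F_Poisson(2; E) >= 0.01`. A plain
`E > 2.5` mode is available via `error_model="simple"`. Finally, reads
strictly shorter than 70% of the sample's expected read length are
removed; the length reference is the modal raw read length (tie broken
towards the larger length), which is robust to a few anomalously long
reads, with the plain maximum available via `length_reference="max"`.

Exact-threshold comparisons carry a relative slack of 1e-9 so that reads
constructed to sit exactly at a boundary (e.g. 100 bases at Q20, `E = 1`)
are not lost to floating-point round-off.

## Taxonomic profiling (`habprof.taxprofile`)

Read pairs are merged when the reverse-complemented mate overlaps the 3'
end of the forward read by at least `min_overlap` bases with a mismatch
fraction at most `max_mismatch_fraction` (the longest acceptable overlap
wins; overlap bases take the higher-quality call). Pairs without an
acceptable overlap are interleaved: the reverse-complemented mate is
appended verbatim to the forward read.

Hits are pre-filtered at e-value < 1e-4. The LCA classifier then:

1. retains hits within `score_margin` (default 1.0) identity percentage
   points of the best hit — an identity margin was chosen over a
   bit-score margin because identity is the quantity the rank gates are
   defined on; the margin is configurable;
2. walks ranks domain -> genus, assigning at each rank the taxon held by
   at least `consensus_fraction` (default 0.9) of retained hits and
   stopping at the first rank without consensus (a consensus fraction
   above 0.5 guarantees the assigned lineage is a single root path);
3. voids any rank whose identity gate exceeds the best-hit identity.
   Gates default to 88% (phylum) and 91% (class), the literature
   thresholds; the deeper defaults {order 92, family 93, genus 94.5} are
   *extrapolations*, exposed in `RankGates` and flagged as such.

Genus-level abundances are normalized by the sample's **total**
quality-filtered read count, not the assigned-read count, so normalized
vectors sum to at most 1.

## Functional profiling (`habprof.funcprofile`)

Mate hits to the same target are combined into one record with the lower
e-value and the summed bit score; identity is carried as the
length-weighted mean and alignment length as the sum (conventions — only
the e-value and bit-score rules feed later thresholds). Best-hit
selection is the lexicographic maximum of (bit score, alignment length,
identity), with any remaining tie broken by the smallest target id so
the choice is independent of input order. Exclusion rules are applied
exactly as written — identity strictly below 50% or e-value strictly
above 1e-9 — so boundary values are kept. Reads are counted in exactly
one domain (prokaryote/eukaryote), that of the best hit's target, and
matrices are normalized by the number of reads used for mapping.

OG -> CAZy-family seeds require identity > 90, e-value < 1e-20 and
subject coverage > 80, all strict. An OG mapped to k families
contributes its full abundance to each family (documented double
counting; per-family counts remain interpretable). The per-sample
CAZyme B/F ratio is total prokaryotic over total eukaryotic CAZyme
abundance, NaN when the denominator is zero.

## Community statistics (`habprof.commstats`)

The B/F ratio is bacterial over fungal SSU counts, with a NaN sentinel
when the fungal count is zero; such samples are excluded (never imputed)
from habitat means and the exclusions are counted. Shannon diversity is
computed at genus level with natural logarithms; since H is computed
from relative abundances, normalizing counts per sample leaves it
unchanged, and the operative depth adjustment is the partial regression:
ordinary least squares of H on log10(depth), returning residuals plus
the grand mean so corrected values stay on the H scale. log10 depth was
chosen over raw depth because diversity-depth relations are close to
log-linear; the predictor scale is switchable. With constant depth the
regression is degenerate and values pass through unchanged. The
Hellinger transform is the square root of relative abundance;
Bray-Curtis is `sum|x-y| / sum(x+y)` (delegated to scipy).

## Habitat structure (`habprof.habitat`)

Counts are scoped to one kingdom and renormalized within it, dropping
taxa with mean fractional abundance strictly below 1e-5. Sample
distances are Bray-Curtis on square-root-transformed relative
abundances; habitat distances are the means over all cross-habitat
sample pairs.

Ward clustering is a hand-written Lance-Williams agglomeration over the
precomputed habitat distance matrix, because both hclust variants are
needed — `ward_d` updates raw distances, `ward_d2` updates squared
distances and reports square-rooted heights — and because a
deterministic tie-break (merge the pair whose smallest-leaf labels sort
first) is required for reproducible trees. Both variants reproduce R's
`hclust` reference values and `ward_d2` matches scipy's Ward linkage;
tiny height inversions are clamped to keep merge heights monotone.
`ward_d` is the default; neither variant is asserted to be canonical.

Entanglement between two dendrograms over the same leaves is
`sum |rank1 - rank2|^1.5` normalized by its maximum (attained by exactly
reversed orders). Leaf orders are canonical — smaller subtree first,
ties by smallest leaf label — a deterministic, documented stand-in for
the rotation optimization a plotting package would apply.

For nestedness, samples are pooled per habitat and rarefied without
replacement (multivariate hypergeometric, one draw per seed) to a common
depth (default: the smallest habitat total). The top-k most abundant
genera (ties broken by name, hence reproducible) form a binary occupancy
matrix with habitats as rows. NODF sums, over every row pair and column
pair with strictly decreasing fill, 100 x (shared presences) / (fill of
the sparser member); equal fills contribute 0; the total is the mean
over all pairs. A perfectly nested staircase scores 100 and an
equal-fill matrix 0 at every size; the implementation is verified
against an independent pair-enumeration oracle and against
`vegan::nestednodf`.

## Indicator genera (`habprof.indicator`)

For genus g and habitat h, specificity `A = mean abundance in h / sum of
per-habitat mean abundances`, fidelity `B = occupancy fraction in h`,
and `IndVal = A x B` (the classic Dufrene-Legendre two-way form; each
genus is reported for its argmax habitat). Significance uses free
permutation of habitat labels across samples with the add-one rule
`p = (1 + #{permuted max IndVal >= observed}) / (1 + n_perm)`, followed
by Benjamini-Hochberg FDR (threshold 0.3 by convention here). Genera
with a total count of at most 10 reads (strictly-greater-than-10 rule)
are excluded before testing. Habitat-association fractions divide the
number of significant genera per kingdom by the total number of genera
in that kingdom, counting each genus once. IndVal is invariant under
global rescaling of all samples, but not under rescaling a single sample
(B is unchanged, A is not) — a documented property of the statistic.

## Synthetic data (`habprof.synth`)

The generators emulate, with known ground truth, the features the
analyses rely on — not realistic sequence content.

* **Reads** are uniform-random nucleotides with Gaussian-jittered Phred
  scores around a per-position profile (default mean Q35, clipped to
  [10, 41]). Violations are injected mutually exclusively per read (two
  N bases, or a 16-base homonucleotide run); clean reads are
  rejection-sampled to contain neither, so with the default profile the
  constructed label fully determines the QC outcome.
* **Hit tables** realize per-read scenarios (a taxonomy node, a hit
  count, an identity level) by sampling hit genera from the scenario
  node's subtree, so the gated-LCA outcome is computable by an
  independent brute-force oracle.
* **Count matrices** use per-habitat mean profiles that are log-normal
  perturbations (scale `habitat_effect`) of a shared base profile,
  within each kingdom. The bacterial-vs-fungal split of each sample is
  binomial at `r/(1+r)` for the habitat's configured B/F ratio `r`;
  within-kingdom counts are Dirichlet-multinomial with concentration
  `p/dispersion` (`dispersion = 0` gives a plain multinomial). The split
  is kept binomial deliberately: a single Dirichlet over the whole
  composition would make the kingdom split itself overdispersed — at
  B/F = 1305 the fungal concentration mass would fall below 1,
  producing degenerate all-or-nothing fungal fractions — whereas the
  analyses assume the ratio is a stable habitat property. Defaults
  (3 habitats x 20 samples, 60 bacterial + 40 fungal genera, depth 1e5,
  B/F ratios {10, 220, 1305} spanning herbivore- to carnivore-gut-like
  regimes, dispersion 0.005) are the conditions the recovery tests run
  under. `n_habitat_groups` arranges habitats into blocks sharing
  group-level profiles (within-group divergence 20% of between-group);
  `n_exclusive_per_habitat` appends bacterial genera confined to one
  habitat (jointly taking a fixed 40% of that habitat's bacterial mass)
  as indicator-analysis ground truth.
* **Occupancy matrices**: a strictly nested staircase, an equal-fill
  permutation matrix, or Bernoulli noise at a requested density.

All generators are driven by `numpy.random.default_rng(seed)` and are
bit-reproducible for a given seed and configuration.

What passing tests show — and what they do not: the suite demonstrates
that every rule and statistic behaves exactly as specified on data whose
generating process is known, and that parameter recovery (B/F ratios,
habitat groups, exclusive genera) works under the stated conditions. It
does not demonstrate robustness to the features real metagenomes add:
chimeric and contaminant reads, reference incompleteness and taxonomic
mislabelling, compositional coupling between kingdoms, or spatial and
batch structure.

## Problem sizes

Tests and the acceptance checks run at desk scale by design: toy
taxonomies with 2^5 genera per domain, 1000-hit-set LCA/oracle
comparisons, 8x8 random occupancy matrices against the NODF oracle,
B/F recovery at depth 1e5 with 20 samples per habitat, indicator power
at 30 samples with 999 permutations, and 50-replicate null batches for
FDR control. The permutation engine is vectorized across genera, so the
full suite completes in seconds.

## Known limitations

* The Poisson error-probability surrogate is a declared stand-in for the
  (unpublished) internals of dedicated read filters, not a claim about
  them; it is stricter than the plain `E > 2.5` rule.
* Gates below class, the LCA retention margin and the consensus fraction
  are conventions, exposed as configuration and tested for monotone
  behaviour rather than asserted as ground truth.
* Overlap merging is a minimal quality-aware merger, not a reimplementation
  of FLASH; alignment itself (SortMeRNA/Lambda/DIAMOND) is out of scope —
  hit tables are the interface.
* Indicator analysis tests single habitats only (no habitat
  combinations), and BH is used for multiple-testing correction.
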