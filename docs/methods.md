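# Methods

This note documents the models and procedures implemented in `chromocline`,
the choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish about real data.

## Scientific setting

In a male-heterogametic (XY) species, two forces shape how synonymous
substitution rates (dS) vary across a genome. First, rates are not uniform
within chromosomes: substitution rates and GC content are elevated near
chromosome ends — plausibly through recombination-associated repair and
GC-biased gene conversion in subtelomeric regions — and decay toward the
chromosome centers, a positional gradient we call a *chromocline*. Because a
short chromosome consists mostly of end-proximal sequence, per-chromosome
summaries (median dS over genes) then correlate negatively with chromosome
length even if length itself has no effect: the classical chromosome-length
effect can be purely compositional. Second, under male-driven evolution the
X chromosome spends one third of its time in males, whose germline
contributes most mutations, so neutral divergence on the X is reduced
genome-wide — independent of gene position.

The package quantifies both effects in a two-species ortholog comparison and
provides the machinery around them: pairwise dS/dN estimation, gene-tree
filtering to single-copy orthologs, identification of the sex chromosomes
from male/female read depth, and a seeded generator that produces inputs
with exactly this statistical structure.

## Pairwise dS/dN estimation (NG86)

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor correction:

- **Sites.** For each sense codon, each of its 9 single-nucleotide neighbors
  contributes 1/3 of a site to the synonymous class if it encodes the same
  amino acid. Mutations to stop codons are counted as nonsynonymous, so
  S + N = 3 holds exactly for every codon. S and N for a pair are averaged
  over the two sequences.
- **Differences.** For a codon pair differing at k sites, synonymous and
  nonsynonymous change counts are averaged uniformly over the k! orderings
  of single-step pathways. Pathways passing through a stop codon are
  excluded and the average renormalized over the remainder (if every
  ordering were blocked — which does not occur between sense codons of the
  standard code — all orderings would be used with stop-crossing steps
  counted as nonsynonymous).
- **Correction.** dS = −(3/4)·ln(1 − 4pS/3) with pS = Sd/S, and likewise for
  dN; a proportion ≥ 3/4 is saturated and flagged invalid rather than raised
  as an error.
- **Total divergence.** t = 3·(S·dS + N·dN)/(S + N), the expected number of
  substitutions per codon. This is the quantity thresholded by the
  divergence filter (defaults: keep 0.01 ≤ t ≤ 2, closed interval, so the
  thresholds exclude strictly more extreme values). Whether "total
  divergence" should be counted per codon or per site is a convention; the
  per-codon form is used and documented here.
- **Exclusions.** Records with invalid (saturated or siteless) estimates are
  dropped with counts reported, and orthologs whose autosome/X assignment
  disagrees between the two species (translocated genes) are removed before
  any X-vs-autosome comparison.

Gapped or ambiguous codon columns are dropped pairwise before counting;
internal stop codons are an input error. A transition/transversion- and
frequency-corrected counting method (YN00-style) is declared as a method
flag but not implemented; all downstream statistics consume (dS, dN, t)
identically, so swapping the estimator would not change the analysis
surface. The NG86 implementation is cross-checked in the test suite against
brute-force enumeration oracles and against Biopython's independent NG86
routine (agreement to ~1e-9 relative).

## Ortholog filtering

Gene trees (Newick, one per ortholog group) are reduced to the groups in
which the two focal species form a single-copy sister pair. The test is
deliberately unrooted: the pair passes iff each focal species has exactly
one leaf and the bipartition {A-leaf, B-leaf} versus everything else exists,
which is invariant under rerooting (trees from ML software carry arbitrary
rootings). Failure is classified as copy-number (0 or ≥2 leaves in either
species) or topology (pair not sisters). A multifurcation containing only
the two focal leaves counts as a pass; a polytomy that also contains other
leaves does not.

## Sex chromosome identification

Per-window depth tracks from one female and one male are each normalized by
their genome-wide length-weighted mean (making the operation idempotent and
scale-free), then summarized per scaffold by the median over windows.
Classification rules:

- **X:** female-to-male ratio within [1.5, 2.5] (closed) — a symmetric band
  operationalizing "ratio ≈ 2", exposed as a parameter.
- **Y:** ratio < 0.1, female depth < 0.1, male depth > 0.3, length >
  100 kb — all four conditions required, all strict inequalities.
- **PAR:** on the X, maximal runs of ≥3 consecutive windows with per-window
  ratio inside [0.75, 1.33] that include the first or last window. The band
  is reciprocal-symmetric (4/3 vs 3/4) around 1; interior sex-balanced runs
  are reported as anomalies, not PARs, and a scaffold whose overall median
  ratio is itself inside the band is flagged not-X-like with no PAR call.

The depth window size is a free parameter, default 10 kb.

## Positional statistics

- **Per-chromosome medians** of dS, dN and dN/dS are computed only for
  chromosomes with strictly more than 10 orthologs (medians over fewer genes
  are unstable); excluded chromosomes are still reported, flagged.
- **Length effect:** OLS of log10(median rate) on log10(length) over
  included chromosomes. The X is included by default (flag to exclude). The
  same regression is run on two positional gene subsets: genes within 5 Mb
  of a chromosome end, and genes inside the central 10 Mb window
  (chromosomes shorter than the window contribute all genes). Chromosome
  inclusion for the subset regressions is decided on genome-wide gene
  counts — the subset only needs ≥3 genes for a median — since applying the
  >10 rule to subset counts would empty the analysis at low gene density.
- **Distance-from-end gradients:** per-chromosome OLS of rate on
  distance-from-end (linear axes; ≥3 genes), tallied by slope sign and raw
  two-sided P < 0.05 with a Benjamini–Hochberg column added for
  transparency; pooled fit on log10–log10 axes with nonpositive values
  excluded and counted.
- **Quadratic fits** of dS on absolute position (internally rescaled to
  [0, 1] for conditioning, coefficients reported in bp units); a chromosome
  is called U-shaped when the 95% CI of the quadratic coefficient is
  entirely positive.
- **LOESS:** local linear regression with tricube weights over the
  span-fraction nearest neighbors (default span 0.75). Pointwise bands are
  fit ± 1.96·σ̂·‖l(x)‖ with l the equivalent kernel and σ̂ estimated from the
  LOESS residuals with the two-delta degrees-of-freedom correction.
- **GC gradients:** per 10-kb window, GC = (G+C)/(A+C+G+T) with N excluded
  from the denominator and windows over 50% N dropped; per-chromosome OLS of
  GC on window distance from the end.
- **X-vs-autosome randomization test:** the statistic is the difference of
  group medians (matching median-based reporting; robust to the heavy right
  tail of per-gene rates). Gene labels are permuted with group sizes fixed;
  the two-sided p is (#{|null| ≥ |observed|} + 1)/(n_perm + 1), default
  10,000 permutations. The test is run for dS, dN and dN/dS on all genes and
  on the 5-Mb ends subset; the subset comparison controls for position,
  since the X is short and hence enriched for end-proximal genes.

Gene position is the annotated midpoint; distance-from-end is
min(midpoint, length − midpoint).

## Synthetic study conditions

The generator reproduces the statistical structure the analyses assume, with
every random element seeded.

- **Karyotype:** 51 chromosomes spanning 3.97–185 Mb, a geometric (log-
  uniform) length progression, X at rank 40. A single geometric progression
  would put rank 40 at ~9.2 Mb, whereas the modeled X is 21 Mb; the spectrum
  is therefore anchored through the X (piecewise log-uniform 185→21→3.97 Mb),
  reflecting that karyotypes with a few macro- and many micro-chromosomes
  are steeper at the top than log-uniform. At ~9 Mb the X's end-proximity
  elevation would largely cancel its genome-wide reduction — a geometric
  fact about the confound, not a property of the test.
- **Rates:** expected dS = ds_center + (ds_end − ds_center)·exp(−d/λ) with
  d the distance from the nearest end — monotone, symmetric, concave-up
  along the chromosome, matching the qualitative gradient and U-shape; the
  true generative form is unknown and any monotone alternative should
  preserve the emergent properties. Defaults ds_center = 0.06,
  ds_end = 0.12 put chromosome medians in ~0.05–0.10, matching the scale of
  a slow-evolving shark-like comparison; λ = 3 Mb concentrates the gradient
  within ~10 Mb of the ends, consistent with a 5-Mb end window capturing
  most of it. On the X, dS (not dN) is multiplied by x_factor = 0.7 —
  male-driven evolution reduces the neutral rate only. Per-gene dispersion
  has two parts: a mutation-rate multiplier shared by dS and dN (gamma,
  CV = 0.25) and a per-gene dN/dS drawn around ω = 0.25 with CV = 1.4
  (gamma shape ≈ 0.5, the familiar shape of ortholog-wide ω distributions);
  making dN far more dispersed than dS, as in real data, is what keeps the
  X-vs-autosome dN test appropriately insensitive to the positional
  confound. Gene density defaults to 3.6/Mb (≈11.6k orthologs on a 3.2-Gb
  genome).
- **Codon pairs:** two descendants diverge from a uniform-sense-codon
  ancestor under a continuous-time process with rate r for every synonymous
  single-nucleotide change and ω·r for every nonsynonymous one; stop codons
  are forbidden. Because the synonymous rate per NG86 synonymous site is 3r
  for every codon, scaling r·T = dS/3 makes the expected synonymous
  divergence exactly the requested dS without iteration. There is no
  transition/transversion bias and no codon-frequency bias — the regime in
  which NG86 is unbiased; the simulator validates the estimator, not the
  reverse.
- **Depth:** expected normalized depth per (class, sex) — autosome 1/1, X
  non-PAR 1/0.5, PAR 1/1, Y 0.02/0.5 (the female Y background models
  spurious mapping) — with mean-preserving multiplicative gamma noise of
  variance `overdispersion − 1` per 10-kb window (default 1.003, i.e. ~5.5%
  CV, the right order for tens-of-reads-deep 10-kb windows).
- **GC:** same exponential distance-from-end form (defaults 0.41 center,
  0.46 at ends), beta noise.
- **Trees:** five-species fixtures with the focal pair as planted pass
  (single-copy sisters), copy-number failure (duplicated focal leaf) or
  topology failure (pair separated by an outgroup).

Seeds are explicit everywhere; the pipeline derives per-stage seeds from the
run seed by fixed offsets, so every table is bit-reproducible from
(config, seed).

### What the synthetic conditions do not show

The generator emulates the *statistical* structure only. It does not model
alignment error, assembly gaps or misjoins, paralogy leaking through the
tree filter, rate variation among sites within genes,
transition/transversion or codon-usage bias, recombination maps, or any
mechanistic cause of the gradient. Passing tests therefore demonstrate that
the analysis battery recovers signals of the assumed form at realistic
magnitudes and sample sizes — not that real genomes satisfy those
assumptions.

## Numerical choices and degenerate inputs

- Saturated Jukes–Cantor corrections (p ≥ 3/4) flag the record invalid; a
  pair with zero synonymous sites (e.g. all-ATG) is invalid rather than
  dS = 0.
- The t-filter interval is closed; boundary records are kept.
- Log regressions drop nonpositive medians/values with a warning and report
  the count; per-gene dS = 0 values are excluded from pooled log fits.
- Quadratic fits reject fewer than 5 genes or fewer than 3 distinct
  positions; LOESS requires ≥10 points and a span large enough for the
  local degree.
- The permutation p-value is never 0 by construction (add-one rule) and is
  bounded below by 1/(n_perm + 1). With counting noise at finite codon
  number, dS lies on a discrete lattice and tied medians make the test
  conservative; this is a property of discreteness, not miscalibration.
- Depth ratio for a scaffold with male median 0 is +inf (female coverage
  present) or undefined/flagged (both zero).

## Problem sizes used in validation

The test suite validates estimator recovery on 50 pairs of 20,000 codons;
sex-chromosome recovery on 20 seeded genomes at full karyotype scale;
randomization-test calibration on 1,000 label-shuffled datasets at default
gene density (199 permutations each) and power on 50 datasets (499
permutations); and the emergent length effect on 50 seeded genomes at
1 gene/Mb. The end-to-end pipeline runs at ~11k genes with 500-codon
alignments. These sizes were chosen so each property is measured with
adequate Monte-Carlo resolution while the whole suite stays desk-scale.

## Known limitations

- NG86 ignores transition/transversion and codon-frequency bias; on real
  data it is biased relative to ML estimators when those biases are strong
  (the simulator's regime is deliberately the one where it is unbiased).
- The PAR detector assumes clean terminal runs; a PAR interrupted by a
  mapping artifact longer than the band tolerance will be truncated at the
  artifact.
- LOESS bands use a global residual scale; strongly heteroscedastic inputs
  get approximate coverage.
- The length-effect regressions treat chromosomes as independent points;
  no phylogenetic or shared-ancestry correction across chromosomes is
  attempted.
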