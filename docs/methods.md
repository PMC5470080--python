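# Methods

## Scope and data model

The package analyses a two-pool (bulked segregant) RNA-seq design: a
*tolerant* bulk pooled from 8 homozygous inbred lines and a *sensitive*
bulk from 10, each sequenced under two conditions (untreated and
waterlogged) with three biological replicates. Two signal channels are
extracted from the same libraries: per-site allele depths (for linkage
mapping) and per-gene tag counts (for differential expression). Internal
tables keep genomic coordinates in the conventions of their source formats
(GFF3/VCF 1-based inclusive); conversions never happen away from the I/O
boundary, and strand is carried but ignored for SNP-in-gene assignment.

## Read QC

A read is discarded iff its fraction of N bases exceeds 5 % or more than
20 % of its bases have phred quality ≤ 10 (offset 33 by default,
configurable). The low-quality rule is interpreted as *exceeds 20 %*: the
filter discards reads whose low-quality fraction is strictly above the
threshold, since discarding at ≤ 20 % would remove nearly every read.
Reads failing both rules are tallied under the N reason; the filter is
idempotent and its summary partitions the input.

## SNP-site validation

Counts are pooled over both bulks and both conditions before typing
(per-condition typing is available via an argument), because linkage
scoring requires the same two types, identically oriented, in both bulks.
A type is *supported* with ≥ `min_type_reads` (3) reads and *frequent*
with ≥ `min_type_fraction` (20 %) of the pooled site total; it qualifies
when both hold. A site passes iff exactly two types qualify and their
combined reads are ≥ `min_two_type_fraction` (90 %) of the total. All
thresholds are inclusive, and fraction comparisons use correctly rounded
division so exact decimal boundaries (e.g. 3/15 vs 0.20) behave as
written.

Failure reasons are assigned with a fixed precedence so each site gets
exactly one:

1. `low_type_support` — ≥ 2 types observed but ≤ 1 reaches the read
   minimum (the site's second type exists only as a handful of reads);
2. `monomorphic` — ≤ 1 type qualifies (including truly single-type sites
   and sites whose well-supported second type stays under 20 %);
3. `too_many_types` — ≥ 3 types qualify;
4. `low_combined_fraction` — exactly two qualify but jointly carry
   < 90 %.

A passing site's two types always leave < 10 % for any third type, so a
pass is stable under count rescaling; a whole-table filter additionally
tallies zero-read sites under `no_reads` so its summary still partitions
the input.

## Linkage model

Let (a_T, b_T) and (a_S, b_S) be the two retained types' reads per bulk at
one site under one condition. Under the *linked* hypothesis each bulk has
its own latent type-1 frequency with a Beta(α, β) prior (default uniform),
giving the product of two beta-binomial marginals; under the *unlinked*
hypothesis both bulks share a single latent frequency, giving one
beta-binomial marginal of the pooled counts. Binomial coefficients cancel
between hypotheses and are omitted. All arithmetic is in log space via
log-gamma; the posterior is a logistic transform of
`log BF + logit(π)`. Ties in output ordering are broken by
(chrom lexicographic, pos ascending).

Design choices made where the design was open:

* **Null structure.** The shared frequency is free rather than fixed at
  1/2 because pools of unrelated inbreds need not sit at 0.5 at unlinked
  sites; `null_mode="half"` restores the fixed-1/2 null.
* **Prior mass.** π defaults to 0.05 — small prior weight for a single
  causal region in a genome-wide scan. With `em_enabled`, π is estimated
  by EM on the two-component mixture (E-step: per-site posteriors;
  M-step: their mean), clamped to [10⁻⁶, 0.5], tolerance 10⁻⁶, at most
  100 iterations; the observed-data log-likelihood is verified
  non-decreasing.
* **Calling.** Strictly greater than 0.9, so a posterior of exactly 0.9
  is not called.

### Known limitation: unlinked drift vs. the shared-frequency null

With bulks of only 8 and 10 unrelated lines, unlinked sites have
*genuinely different* lattice frequencies (independent Bin(8, ½)/8 and
Bin(10, ½)/10), and P(|f_T − f_S| ≥ 0.4) ≈ 0.097 exactly. The
shared-frequency null treats any real frequency divergence as linkage
evidence, so at depth 50 roughly 15 % of unlinked sites per condition
(and ~9 % after the cross-condition intersection) exceed posterior 0.9 in
the default simulation. This is a floor set by the bulk sizes, not by
sequencing noise — it *rises* with depth. Distinguishing finite-bulk
drift from linkage would require a different hypothesis pair (e.g. an
extreme-divergence linked hypothesis against a free-independent null),
which this package deliberately does not switch to: the implemented pair
is the package's defined model, and the cross-condition intersection is
the intended mitigation. Interpret single-condition call counts
accordingly.

## Differential expression

RPKM(g, s) = 10⁹ · C(g,s) / (N(s) · L(g)) with library sizes defaulting
to column sums. Replicates are pooled by summation before testing: the
digital tag-count test is defined for two libraries, not replicated
designs, so biological dispersion is deliberately not modelled — a
documented limitation shared with the library-level framing it
implements. The predictive distribution of the second library's count
given x tags in the first is negative-binomial with x + 1 successes and
success probability N1/(N1+N2); the two-sided p-value is
2·min(P(Y ≤ y), P(Y ≥ y)) capped at 1. Because conditioning on one side
is intrinsically asymmetric, the conditioning library is chosen
canonically (larger library, then larger count), making the statistic
exactly orientation-invariant. Benjamini–Hochberg step-up adjustment is
applied over the tested genes; genes with zero counts on both sides are
excluded from testing entirely.

A gene is significant iff fold change > 2 (strict) and q ≤ 0.001; the
contradiction between an FDR gate and a looser p-value gate in the
emulated protocol is resolved in favour of the FDR gate. Fold changes are
ratios of pseudocounted (0.01) group-mean RPKMs, oriented ≥ 1 with the
direction carried separately and the tolerant pool fixed as numerator in
between-pool contrasts; the pseudocount lets near-zero denominators land
in the > 1000-fold class without dividing by zero. Bins are right-closed
and open at 2: (2,10], (10,100], (100,1000], (1000,∞), so FC = 10 falls in
2–10.

## Candidate integration

Genes significant in both between-pool contrasts form the overlap;
"opposite expression" is a strict direction flip (up→down or down→up),
and genes significant in only one contrast are excluded from the overlap
entirely. Candidate genes are the distinct genes containing at least one
cross-condition high-probability SNP, ranked by (number of contrasts
significant, maximum posterior, SNP count) descending, ties by gene id.
Marker intervals are supplied as coordinates; no marker database is
bundled.

## Synthetic data generator

The generator emulates the assumed study design; its defaults are the
conditions under which the package's claims are tested.

* **Panel.** Three chromosomes (80/60/60 Mb) with the causal locus at
  chr1:40 Mb; 2000 SNPs uniform per chromosome (chromosome choice
  proportional to length, duplicate positions redrawn), one pinned to the
  causal position. Coupling to the causal allele decays as
  c(d) = ½ + ½·exp(−d/L) with L = 10 Mb — an LD-style decay standing in
  for meiotic recombination, appropriate for an unrelated germplasm panel
  rather than an F2 — and c = ½ off-chromosome. Each line carries the
  allele coupled to its own causal-locus allele with probability c, so
  bulk frequencies live on the lattice k/m and the causal SNP has
  f_T = 1, f_S = 0 exactly. SNPs with c ≥ 0.95 are flagged "linked" for
  recovery scoring.
* **Allele depths.** Depth ~ Poisson(50) per (site, bulk, condition)
  cell; focal-type reads ~ Binomial(depth, f(1−ε) + (1−f)ε) with
  ε = 0.01; each remaining read is miscalled to a third base with
  probability ε/2 — the simplest contamination able to violate the
  two-type filter. Conditions share genotypes and differ only in
  sampling noise, reproducing the logic that true signals recur across
  conditions.
* **Expression.** Baseline relative abundances log-uniform over three
  decades; 100 of 2000 genes receive signed 2^±3 multipliers in the
  designated group (default: the tolerant pool); counts are
  negative-binomial with dispersion α = 0.01 (variance μ + αμ²), scaled
  to Poisson library sizes of mean 2·10⁶ reads per replicate — about
  1000 reads per gene, matching the per-gene coverage of ~30 M reads
  over ~32 k expressed transcripts in the emulated study when scaled to
  2000 genes. Gene lengths are uniform on [500, 5000] bp; gene models
  are placed uniformly (overlaps allowed), with one gene re-anchored to
  straddle the causal locus, and the causal gene is planted among the DE
  genes by default — the emulated scenario is precisely a causal gene
  that is both polymorphic between pools and expression-responsive.
* **Determinism.** All draws come from an integer-seeded PCG64 generator
  with fixed stream offsets per component (conditions keyed by a CRC of
  their label), so identical configs and seeds give byte-identical
  outputs on any platform.

What the generator does **not** model — read-level artifacts (mapping
bias, duplicates), indels and multi-allelic sites, population structure
beyond the two bulks, pool-composition imbalance (equal per-line RNA
weights are assumed), and biological dispersion heterogeneity — bounds
what passing tests show about real data: they validate the inference
machinery against its own assumptions, not robustness to violations of
them.

## Numerical choices

Beta functions via `scipy.special.betaln`; posteriors via the logistic
of the log odds; predictive tails via the regularised incomplete beta
behind `scipy.stats.nbinom` rather than explicit summation. EM monotonicity
is asserted at 10⁻⁸ relative slack. Fraction thresholds compare
correctly rounded quotients. Empty inputs: an all-zero site is an error
for single-site classification but tallied separately by the bulk
filter; a site with no reads under one condition is dropped from that
condition's scan; zero-by-zero genes are excluded from testing; an empty
GFF3 yields an empty gene set.

## Problem sizes used in validation

The shipped test-and-acceptance runs use the generator defaults
(2000 SNPs at depth 50, 2000 genes with 100 planted effects, five null
seeds of 2000 genes, a 1000-site EM calibration panel) and exhaustive
oracles where feasible: every bulk-count configuration with per-bulk
totals ≤ 50 against a Gauss–Legendre quadrature oracle, and every
4-base count vector with total ≤ 20 against a straight-line reference of
the filter rules. Measured under those conditions: linkage recall on
c ≥ 0.95 SNPs 100 % in both conditions; unlinked call rates 14.6 %/16.5 %
per condition and 9.4 % after intersection (see the limitation above);
EM estimate 0.145 for a 0.10 planted fraction; planted-DE recall 99 %
with false-discovery proportion 1 %; at most one null call per seed at
q ≤ 0.001.
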