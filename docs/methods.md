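# Methods

This note documents the models, conventions and numerical choices behind
`minpanel`, and what the synthetic-data tests do and do not demonstrate
about real collections.

## Data model

A genotype call at a biallelic SNP is one of four states — hom-X, het,
hom-Y, no-call — stored as an `int8` code; the nucleotide letters belong
to the marker, not the call. Genotypes are unordered ("GA" ≡ "AG") and
are canonicalized on read to the marker's X/Y orientation (alphabetical
when alleles are inferred from the data). Ploidy is sample metadata only:
a triploid still yields one of the three diploid-style cluster calls on a
competitive-allele assay, so the call table stays biallelic regardless of
reported ploidy. The default missing tokens are the empty cell, `NA`,
`--` and `NN`; spreadsheet exports are not dialect-consistent, so the set
is configurable.

## Panel selection

Discrimination is defined on genotype states: a pair of samples is split
by a marker iff both calls are present and differ (heterozygote versus
either homozygote is a difference). A no-call never splits a pair — an
absent call is unknowable, and treating it as informative would let assay
dropouts masquerade as genetic differences.

The greedy selector seeds with the highest-MAF marker (the single most
informative marker in expectation) and then maximizes the per-step count
of newly split pairs. It stops when all splittable pairs are split, when
no remaining marker helps, or at a caller-supplied panel cap. Ties are
broken by higher MAF, then lexicographically smaller marker ID; the tie
rule is arbitrary but fixed, making selection deterministic for a given
input ordering — a requirement for testing, not a scientific claim.

The pair bookkeeping holds unresolved pairs as index arrays and evaluates
all candidate markers against them vectorized, in 200k-pair chunks to
bound memory. On small instances an exhaustive search
(`brute_force_minimum_panel`, subsets enumerated in increasing size with
a 10^6-subset guard) provides the independent optimum; greedy panels are
never smaller, and the test suite checks the greedy gains against a
from-scratch set-based recount on every instance.

Chromosome-coverage augmentation ranks unselected markers by how many
residual pairs they would split (the "differentiation score") and appends
the top-ranked marker from each uncovered chromosome. This trades panel
minimality for genomic spread — desirable when a panel should tolerate
the loss of any one assay or region.

## Profile grouping and replicate merging

Strict grouping treats the no-call as its own symbol: two profiles are
identical only if they match state-for-state. This deliberately
over-counts distinct profiles in the presence of dropouts — the
alternative (no-call matches anything) is provided as `compatible` mode
but warns, because transitive compatibility can chain-merge samples that
would differ if fully called.

Merging of miscall-split replicate groups is label-gated: two groups
merge only when they share a declared replicate label **and** their
representative profiles differ at ≤ `max_diff` markers (default 1, the
single-miscall case; no-call-versus-called positions are not counted).
Unlabelled look-alikes are never merged: without a declared relationship
one cannot know what a missing or differing call "should" have been.

A marker missing in *every* member of a clonal group of ≥ 2 is flagged as
a systematic null — reproducible dropout is best explained by sequence
variation under a primer, making the absence itself part of the profile.
Singleton groups return an empty flag list with a notice, as one missing
call is not evidence of anything systematic.

## Error model

Replicates of a clonal variety should be call-identical, so differences
estimate the per-call error rate. Denominators count **non-missing calls
summed over all members** of a group: a complete pair of 21-marker
profiles contributes 42 calls; a trio with one no-call contributes 62,
not 63. (A per-comparison accounting of 3 × 21 would give 1/63 ≈ 1.59%
for a complete trio with one deviant call; the implementation counts
calls, not comparisons, which is also what makes one no-call shift the
denominator from 63 to 62.)

For groups of ≥ 3 the per-marker strict-majority state is the consensus;
markers with no strict majority (e.g. three members, three states) get a
no-call consensus and are skipped in error counting while their member
calls still appear in the denominator.

The two aggregate assumptions:

* `all_genuine` trusts every declared label. Mislabelled samples then
  contribute their full genotypic distance as "errors", so this estimate
  is an upper bound — deliberately conservative.
* `diff_threshold` (threshold default 2) excludes members differing from
  their partner or consensus at > 2 markers as presumed mislabels. Both
  members of a discordant pair are excluded — neither can be presumed the
  true representative — and groups reduced below two members drop out.
  Exclusion is one pass: consensus is computed once on the full group,
  survivors are re-scored.

Known homonyms (same name, registry-confirmed distinct genotypes) are
handled by the caller editing replicate labels before estimation; the
module does not guess.

Parameter-recovery tests show the pooled `all_genuine` estimate sits in
the 99% binomial band of an injected 1% per-call miscall rate over 200
simulated clone pairs, and that injected label swaps inflate
`all_genuine` while `diff_threshold` continues to recover the injected
rate. Note the pairwise estimator has a small negative bias of order e²
(two independent miscalls can coincide or cancel); at e ≤ 1% this is far
inside the binomial band.

## Similarity, clustering, bootstrap

Similarity is shared calls / comparable markers, comparable meaning
called on both sides. Pairs with zero comparable markers are *undefined*
and block clustering rather than being imputed — silent imputation would
fabricate relatedness. Distances are 1 − similarity, so complete
m-marker profiles are quantized at 1/m (≈ 0.048 for m = 21): a
21-marker tree cannot express finer structure than one-SNP steps, which
is why only clades separated by very few differences can earn high
support.

Linkage defaults to average (UPGMA); complete and single are available.
SciPy's agglomeration is deterministic for a fixed input ordering, which
serves as the documented tie rule. Support is the ordinary Felsenstein
marker bootstrap: resample the m markers with replacement, re-cluster,
and score each reference clade by the percentage of replicate trees
containing exactly its leaf set. Multiscale/AU-style corrected p-values
are out of scope; plain bootstrap percentages are transparent and
sufficient for the clone-versus-non-clone distinction the panel is built
for. Within a bootstrap replicate, pairs left with no comparable marker
by the resampling draw are assigned the maximal distance 1.0 (this can
only occur under heavy missingness). Identical profiles merge at height
0 in every replicate, so clone clades always reach 100%.

Newick export writes branch lengths as height differences and supports
as internal node labels; NEXUS output wraps the same newick in a taxa
block. A flat-cut utility (`cut_clusters`) extracts clusters at a
user-chosen height; no default height is asserted because no principled
cut exists at this marker count.

## Strand harmonization and concordance

When two platforms report opposite strands, each allele maps to its base
complement: homozygotes to the complement homozygote, heterozygotes stay
heterozygous, no-calls pass through. For palindromic SNPs (A/T, C/G) the
complement pair equals the original pair, so the correspondence is
genuinely ambiguous and the function refuses without an explicit
caller-supplied mapping. Harmonization is an involution (applying the
inverse mapping restores the calls) and leaves heterozygosity invariant.

Concordance excludes any cell where either platform gave a no-call:
fails are a completeness statistic, not an agreement statistic.
Heterozygote-called-homozygote and the converse are tallied separately
per marker, since allele-dropout-style discordance is directional.

## Heterozygosity and ploidy

Per-sample heterozygosity is het calls / called loci. The per-ploidy
summary reports group means plus the ploidy composition of the top-k and
bottom-k heterozygosity tails (k default 200, clipped to the sample
count). Even ~20 markers separate triploid from diploid means in
expectation, but the per-sample spread is wide, so the tail composition
is a screening tool for unreported triploids, not an assignment rule.

## Synthetic collections

`simdata` generates founders marker-wise from Hardy–Weinberg proportions
at MAFs drawn uniformly from `maf_range`, then copies founders into
clone groups, applies rare sport mutations (part of the *true*
genotypes — sports are biology, not noise), and overlays observation
noise: uniform state-flip miscalls, no-calls, and replicate-label swaps.
Every observed-versus-true discrepancy is logged exactly once (a flip
that subsequently drops out is logged as missing only).

Defaults describe a plausible fingerprinting run: 300 founders on a
21-marker panel, MAF 0.2–0.5 (panels are chosen for informative
markers), 75% singletons with clone groups of 2–4 for the rest, 12%
triploid-like founders, het-inflation 0.35 (lifting triploid mean
heterozygosity from ≈ 0.45 to ≈ 0.6), miscall rate 0.005, missing rate
0.035, no mislabels. Triploids are emulated phenomenologically — an
elevated probability that a homozygous call reads heterozygous — rather
than as three-allele genotypes, because the observable is the
diploid-style cluster call. Markers are independent: no linkage
disequilibrium, no population structure, no DNA-quality covariance
between a sample's markers. Passing tests therefore validate the
*estimators and algorithms*, not the field behaviour of any particular
assay chemistry.

## Problem sizes in the test suite

Unit and property tests run on collections of tens to hundreds of
samples and 4–21 markers; the greedy-versus-oracle comparison uses 100
random instances of ≤ 12 samples × ≤ 10 markers where exhaustive subset
enumeration is cheap; bootstrap checks use 1000 replicates on ~10
samples. The selector itself is vectorized and chunked and handles
thousands of samples by thousands of markers; the small test sizes are
chosen so the independent oracles (exhaustive enumeration, set-based
recounts) stay exact.

## Known limitations

* Greedy selection is a heuristic; it can exceed the true minimum panel
  (the suite measures the gap on small instances) and no ILP/set-cover
  solver is provided.
* Compatibility-mode grouping can over-merge; it exists for exploration
  and warns on use.
* `diff_threshold` exclusion is single-pass; pathological groups (e.g. a
  consensus dominated by mislabelled members) could in principle evade
  it.
* The simulator's error spectrum is uniform over called states; real
  assays mis-call heterozygotes as homozygotes more often than the
  reverse, which matters for concordance direction but not for the rate
  estimators tested here.
* Which member of a discordant pair is the "true" representative of a
  name is not decidable from genotypes alone, and the package never
  attempts it.
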