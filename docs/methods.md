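# Methods

## Distance model

Distances are Kimura two-parameter (K2P): transitions and transversions
are counted separately over *pairwise-complete* sites — positions where
both sequences carry an unambiguous A/C/G/T. Gaps and every IUPAC
ambiguity code are treated as missing and excluded per pair (pairwise
deletion), which preserves information for fragments of unequal length
and matches the default of the distance tooling used throughout the
barcoding literature. Ambiguities are not resolved probabilistically;
exclusion is simpler and conservative.

With P and Q the transition and transversion difference proportions,
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q). When a log argument is ≤ 0 the
correction has no finite value (saturation); such pairs are flagged
undefined and excluded from intra/inter summaries, threshold scans and
BCM candidate sets rather than capped — substituting any ceiling would
silently distort error counts. Zero-overlap pairs are handled the same
way. Distances are stored as fractions; reporting layers multiply by 100
because the field quotes percentages.

An uncorrected p-distance mode is provided for comparison; K2P ≥ p holds
for every defined pair (convexity of the correction) and is asserted in
the property suite.

## Threshold optimization

Identification error at threshold t is counted **per sequence**, not per
pair: a sequence with at least one conspecific is a false positive when
its *minimum* conspecific distance exceeds t; a sequence is a false
negative when its *minimum* heterospecific distance is ≤ t. This
nearest-neighbour reading keeps the cumulative error CE = FP + FN in
units of sequences and is consistent with best-close-match logic.
Consequences worth noting:

* a sequence can be both FP and FN; it is counted in both tallies and
  the number of doubly-flagged sequences is reported alongside CE so the
  "sequences in error" total is unambiguous;
* singletons can only be FN;
* fp(t) is non-increasing and fn(t) non-decreasing in t, so CE scans are
  well behaved (property-tested on random simulations);
* with a strict barcode gap the smallest zero-error threshold equals the
  largest *nearest-conspecific* distance, which can sit below the largest
  pairwise intraspecific distance — the gap that matters for per-sequence
  error is the nearest-neighbour gap.

The default grid is 0.001–0.10 in 0.001 steps (0.1% resolution, spanning
the 1–6% range where COI thresholds typically land); ties in CE are
broken toward the smallest threshold, the conservative choice against
lumping. Per-partition scans recompute distances within each partition;
partitions with fewer than two species are dropped before scanning.

Family-level and subfamily-level schemes are compared on per-sequence
binary error indicators (1 = FP or FN at the relevant optimal threshold)
restricted to sequences present in both schemes, using a two-sample
Student t test with equal variances. The replicate unit of the published
comparison this mirrors is not recoverable, so this construction is an
explicit design choice of this package, recorded in the report metadata;
degenerate indicator vectors yield an undefined statistic with a note
rather than an error.

## Best Close Match

Candidates for a query are all other sequences within t (undefined
distances count as no match). The candidate set at the minimal distance —
within a 1e−12 floating-point tolerance — decides the status: all
conspecific → correct; none → incorrect; mixed → ambiguous; empty → no
id. Singleton species get the conventional override: with
`singleton_policy="correct"` (default) a singleton with no match inside t
is counted correct, since no heterospecific lies close enough to mislead;
`"no_id"` gives the strict accounting. Both policies are exposed because
published efficiency figures differ in which convention they adopt.

## Haplotype networks

Two specimens share a haplotype iff their sequences agree at every site
where both are unambiguous. That relation is not transitive once Ns are
present, so collapsing is greedy in input order against a *fill-in
consensus*: each haplotype keeps a consensus whose missing sites are
completed as compatible members join, and new sequences are compared to
that consensus. Exact duplicate strings are grouped first, so libraries
without ambiguity codes collapse in linear time and order-dependence can
only affect sequences with missing data.

Edges of the network carry raw substitution counts (Hamming over
pairwise-complete sites between haplotype consensuses) — mutational
steps, not model-corrected distances. The network is the union of all
minimum spanning trees (epsilon = 0): processing edges by ascending
weight level, an edge belongs to some MST iff its endpoints lie in
different components of the strictly-cheaper subgraph (cycle property),
and to *every* MST iff it is a bridge of the component multigraph at its
level. Both facts are verified in tests against exhaustive spanning-tree
enumeration on small graphs. An epsilon > 0 relaxation is available but
off by default.

## Synthetic libraries

The generator emulates the structure of a curated family-level COI
library, not its phylogeny: star topologies within species and within
subfamilies, no coalescent, no codon structure, no indels. Evolution is
exact K2P sampling — per-site substitution probabilities are computed
from the closed-form finite-time transition matrix at the requested
branch length, so branch lengths are additive on the K2P scale and the
K2P estimator recovers path lengths without calibration error (the
targets are recovered by the K2P estimator, not the p-distance).

Default parameters (units: substitutions/site unless noted):

| parameter | default | meaning |
|---|---|---|
| alignment_length | 658 bp | standard COI barcode length |
| n_subfamilies × species_per_subfamily | 10 × 26 | ~260 species |
| singleton_prob | 0.28 | fraction of species with one sequence |
| seqs_poisson_lambda | 2.33 | non-singletons get 2 + Poisson(λ) sequences (mean ≈ 3.4 overall) |
| target_intra | 0.02 | expected conspecific pairwise K2P |
| target_inter | 0.20 | expected within-subfamily heterospecific K2P |
| subfamily_branch | 0.028 | root → subfamily ancestor branch |
| kappa | 2.0 | transition/transversion rate ratio, typical mtDNA bias |
| branch_length_shape | 2.0 | gamma shape of branch-length dispersion |

Cross-subfamily heterospecific distances are target_inter +
2·subfamily_branch; with ~90% of heterospecific pairs crossing
subfamilies the defaults put the family-wide interspecific mean near
25% against a 2% intraspecific mean — the regime of a real leaf-beetle
library, with overlapping distributions and no global gap. Gamma
dispersion (shape 2) of branch lengths supplies the among-lineage rate
variation that creates that overlap; setting `branch_length_shape=None`
makes branch lengths deterministic, which is what strict-gap
(closed-loop) and estimator-calibration tests use, because with
dispersed lineage rates the interspecific mean is itself a random
quantity dominated by the few hundred species branches and converges
only as the species count grows. Targets too close to estimator
saturation are rejected before generation.

Injected failure modes rewrite a generated library with known truth:
verbatim haplotype copies across species (introgression-like; forces
false negatives at every threshold and breaks BCM), sister species at a
stated small divergence, and a deep intraspecific split. These are
closed-loop tested: the downstream modules must detect exactly what was
injected.

What passing tests on these simulations does **not** show: robustness to
alignment error, indels, codon-level rate structure, NUMTs/pseudogenes,
real coalescent genealogies, or geographically structured sampling. The
generator validates the *analysis* chain, not the biology.

All randomness flows from one `numpy.random.default_rng(seed)` consumed
in a documented fixed order; identical seeds give byte-identical
libraries across platforms.

## Quality screens

The reading-frame check strips gaps and looks for the smallest offset in
{0, 1, 2} whose translation under the invertebrate mitochondrial code
(table 5 — required for beetle COI) contains no internal stop; a stop in
the final complete codon is treated as terminal and allowed, since
barcode fragments are mid-gene and trailing partial codons are common.
Reverse-strand frames are not searched by default (inputs are assumed
orientation-normalized by the aligner); a six-frame flag enables them.
Length bounds default to 400–700 bp ungapped and the ambiguity ceiling
to 2%, bracketing the observed range of real COI barcodes; screens are
advisory — reports flag records, callers decide to drop.

## Problem sizes in tests and the acceptance script

Oracle-equivalence suites run on ~30-sequence libraries where brute
force is exact and instant; estimator-calibration runs use L = 10,000
and 50 species (150 sequences); the full-pipeline acceptance run uses
the default family-scale library (~880 sequences, 658 bp), which
evaluates in a few seconds. These sizes were chosen as the smallest at
which each claim is statistically meaningful.

## Known limitations

* The greedy haplotype merge is order-dependent for conflicting
  missing-data patterns (inherent to the non-transitive identity rule).
* The family-vs-subfamily t test is a reimplementation choice; its
  statistic is not comparable across packages that chose a different
  replicate unit.
* No automatic outlier handling: a valid deep intraspecific split (or a
  misidentified voucher) inflates FP counts until the user intervenes.
* Distance-threshold methods only; model-based species delimitation
  (GMYC, bPTP, ASAP) is out of scope.
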