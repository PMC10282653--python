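# Methods

## The tag model

A type IIB restriction endonuclease binds a bipartite recognition site and
cleaves both strands at fixed offsets on both sides, releasing an
iso-length fragment. We model the BcgI digest as a motif-plus-arms scheme:
the recognition site `CGA(N6)TGC` (12 bp, six degenerate positions) with
`arm5` bases kept upstream and `arm3` downstream, giving tags of
`arm5 + 12 + arm3` bp. The defaults are `arm5 = arm3 = 10`, i.e. 32-bp
tags. Published protocol descriptions state only that the gel-selected
library runs near 100 bp including adapters, not the exact arm lengths, so
the 32-bp default is a documented assumption confined to one configurable
dataclass (`DigestScheme`); every other stage treats the tag length as
opaque. Degenerate motif positions match `A/C/G/T` but never an ambiguous
`N` in the data, and any window containing `N` is discarded (reads are
classified by exact match, which an `N` can never satisfy).

Tags are stored in canonical orientation — the lexicographic minimum of
the window and its reverse complement — which makes digestion of a genome
and extraction from a randomly oriented read strand-agnostic. Coordinates
are 0-based, half-open throughout.

### The unique-tag database

Digesting a reference collection yields, per species, a set of canonical
tags. Tags occurring in two or more species are removed entirely (the
exact-match classifier cannot disambiguate them; probabilistic
reassignment of shared tags is out of scope by design), and tags repeated
within a genome count once. The per-species count of distinct unique tags
is the theoretical marker count `T_i`. Species left with no unique tags
stay in the table at `T = 0` and are flagged in the build report, since
they are silently undetectable downstream. The DB serialises to a TSV of
(tag, species) pairs plus a JSON sidecar recording the digest scheme and a
schema version; the loader refuses a scheme mismatch.

## Read processing

Reads are Phred+33 FASTQ. Clean-read filtering applies, in a fixed order,
(1) drop if the fraction of `N` bases strictly exceeds 8%, (2) drop if the
fraction of bases below Q30 strictly exceeds 20%, (3) drop if no
recognition site occurs on either strand. The strict inequalities follow
the usual phrasing of these rules ("more than 8%", "exceeds 20%");
boundary reads are kept. The ordering affects only which reason a
multiply-failing read is tallied under, never the kept set — a property
the tests check directly. The order site-check-last was chosen so the
quality tallies describe the library as a whole rather than only
site-bearing reads; the published descriptions do not pin this down.

Each clean read yields at most one tag (the library geometry puts one
fragment per read): the leftmost plus-strand motif wins, then the leftmost
minus-strand one, and the tag is the canonical form of the
`arm5 + motif + arm3` window around it. Truncated windows (site too close
to a read end) and windows containing `N` yield nothing. No adapter
trimming or error correction is performed — the motif-anchored window is
immune to flanking adapter sequence, and an uncorrected error simply sends
the tag to the unassigned pool.

## Profiling

Classification is exact-match lookup against the unique-tag DB. Per
species, `s` counts read occurrences and `t` counts distinct tags seen;
tags absent from the DB are tallied as unassigned and excluded from all
denominators. The G score `sqrt(s·t)` — the geometric mean of read support
and marker breadth — is computed for every species with `s > 0`, and
species with `G < 5` are discarded. The threshold retains `G = 5` exactly
(sources state the threshold without boundary semantics; `>=` was chosen
so the boundary case `s = t = 5` survives). The exponent 1/2 is a
geometric mean; the score is monotone in both arguments, so additional
evidence can never un-detect a species.

Abundance is coverage-normalised: `coverage_i = s_i / T_i` estimates reads
per marker, proportional to the species' cell count at a given depth, and
relative abundances are coverages normalised to sum to 1 over surviving
species. Species present in the DB but undetected (or G-filtered) in a
sample appear as exact zeros in merged tables. No read deduplication is
performed before counting `t`.

## Ecology

*Alpha.* Chao1 uses the bias-corrected estimator
`S + F1(F1-1)/(2(F2+1))` (finite when doubletons are absent), matching the
de-facto behaviour of the standard ecology packages; the classic form is
available by flag. Chao1 is computed on the integer read counts `s`
(singletons and doubletons are undefined on proportions); Shannon
(natural log) and Simpson (`1 - Σp²`) on relative abundances. Group
contrasts use the two-sided Wilcoxon rank-sum test, exact when both groups
have n ≤ 20 and the pooled values are tie-free, tie-corrected normal
approximation otherwise. No rarefaction is applied anywhere;
sequencing-depth differences are handled only by the coverage
normalisation.

*Beta.* Bray-Curtis and Euclidean distances on the abundance vectors,
binary Jaccard on presence/absence. PCoA double-centres `-D²/2` and
eigendecomposes; axes are returned only for positive eigenvalues (scaled
by their square roots) while negative eigenvalues are reported for
diagnostics. PERMANOVA uses Anderson's pseudo-F from among/within sums of
squared distances with a seeded permutation stream and the
observed-inclusive p-value `(1 + #{F* >= F}) / (1 + n_perm)`; samples are
internally sorted by id so the p-value is invariant to caller row order.
The default 999 permutations is an assumption — published analyses of this
kind rarely state the count. PCoA and PERMANOVA are implemented in-package
(scikit-bio's PERMANOVA exposes no seed and its PCoA clamps negative
eigenvalues); scikit-bio serves as the independent cross-check in the test
suite instead.

## Differential abundance

Species tables aggregate to genus and phylum by summation (mass is
conserved; the tests assert row sums of 1 at every rank). Each taxon gets
a tie-corrected Kruskal-Wallis H and chi-square p (df = groups − 1); raw
p-values, no multiplicity adjustment, matching the common practice of
reporting unadjusted per-taxon tests in this design with significance at
p < 0.05.

The LDA effect-size screen re-implements the published LEfSe description
rather than porting the original tool (whose exact scoring is
under-documented): abundances are scaled to per-million; taxa passing the
Kruskal-Wallis screen (p < alpha) are scored over 30 bootstraps, each
drawing 2/3 of every class and fitting a two-class LDA with Ledoit-Wolf
shrinkage of the within-class covariance; a taxon's per-bootstrap effect
is the mean of (i) the absolute portion of the discriminant-axis
class-mean gap attributed to it (`|w_f · Δμ_f|`) and (ii) its absolute raw
class-mean difference; the score is `log10(max(mean effect, 1))`, so a
signal-free taxon scores 0 and the floor prevents negative scores. Taxa
with score ≥ 4.0 are reported as discriminative. Rank order and the
order-of-magnitude scale are the contract here, not decimal agreement with
any particular LEfSe build. Samples are sorted by id before the bootstrap
draws, making scores exactly invariant to row order; invariance to
swapping group labels holds up to bootstrap noise (different classes
consume different random draws), which is how the tests phrase it. Only
the two-class form is implemented — the class/subclass Wilcoxon stage of
full LEfSe has no counterpart in a two-arm design without subclasses.

## Classifier

Candidates are the top 30 taxa by mean relative abundance. A random
forest (500 trees, sqrt-features splits, bootstrap sampling — none of
these are stated by the analyses this mirrors, so scikit-learn-compatible
defaults are used) ranks candidates by Breiman-style out-of-bag
permutation importance: per tree, the accuracy drop on its out-of-bag
samples when one feature is permuted, averaged over trees. Marker-set
selection sweeps nested sets (top-1 … top-k by importance), scores each
with stratified k-fold cross-validated misclassification error (folds
reduced to the smaller group size when needed), and picks the smallest k
within one standard error of the minimum — the cross-validation-curve
reading of "the best set of markers" made explicit.

POD (probability of disease) is the fraction of trees voting the
designated positive class; training samples are scored by their
out-of-bag trees only, avoiding resubstitution optimism (a sample in-bag
for every tree is an error suggesting more trees). AUC is the
Mann-Whitney U statistic over POD scores divided by `n₁·n₂` (ties count
half — the probabilistic interpretation), and the POD group difference is
the two-sided rank-sum p. AUC is therefore invariant under monotone
transforms of POD and maps to `1 − AUC` under label swap.

## Synthetic studies

The generator emulates the structure of a two-arm tissue-microbiome
cohort so that every stage is testable without downloads:

- **Genomes.** Random sequence scrubbed of spurious recognition sites,
  then the requested number of sites planted at positions spaced at least
  one tag length apart, with random degenerate fillers; the result is
  re-scanned and rejected unless the site count is exact. Optionally one
  tag window is transplanted between the first two species to exercise
  the cross-species uniqueness filter, and a decoy genome (excluded from
  the DB) supplies contaminant reads.
- **Compositions.** Per-sample species loadings are log-normal(0, 1);
  planted differentials multiply one species' loading by `2^lfc` in one
  group; rows are normalised. Group sizes default to 15 vs 7, mirroring
  the imbalanced cohorts this design targets and stressing the rank tests
  at realistic n.
- **Reads.** 100 bp, one tag per read in random orientation inside random
  padding, the padding rejection-checked to introduce no spurious
  recognition site (so extraction provably recovers the planted tag on
  error-free reads). Source species are drawn proportional to composition
  × marker count — the read flux a real digest produces. Errors are
  substitution-only at a configurable rate (default 0.1%), with a separate
  `N` rate (default 0.1%) and a two-state quality model (default: 5% of
  bases from a low-quality state around Q12, the rest around Q38). Indels
  are deliberately absent: exact-match classification makes an indel
  equivalent to a substitution (both kill the tag), so modelling them adds
  nothing the tests could detect.
- **Truth.** The true composition matrix and per-read provenance (source
  species, source tag, error positions) are retained for recovery checks.

Default scale is 12 species × 20 kb genomes × 50 sites and 100k reads per
sample. These are desk-scale stand-ins for a real study (millions of reads
per sample against a database of >10⁵ genomes); the package's own
benchmark sizes were chosen so the full test suite and the acceptance
script each run in minutes on one CPU. What passing tests show is that the
estimator, filters and statistics behave correctly under the generative
model; they do not certify performance on real data, whose error profiles
(quality-by-cycle structure, PCR duplicates, GC bias, incomplete reference
databases, strain-level variation) the generator intentionally omits.

## Numerical and design notes

- Random state: a single study seed fans out to per-stage sub-seeds via a
  fixed derivation (`stage_seed`), so each stage is independently
  reproducible; all sub-seeds stay below 2³¹.
- Abundance rows are validated to sum to 1 within 1e-9 (or be all-zero);
  serialized tables carry 6 significant digits.
- A constant taxon gets H = 0, p = 1 in the Kruskal-Wallis screen rather
  than an error from the tie correction.
- The Wilcoxon "exact" path is used only when tie-free and both n ≤ 20;
  identical groups under ties fall back to the tie-corrected normal
  approximation, which still returns p = 1.
- Degenerate LDA subsamples (every feature constant) fall back to the
  raw-difference term alone; fewer than 5 successful bootstraps is an
  error rather than a silent low-precision score.
- `evaluate_pod` and the G filter treat boundaries inclusively
  (`G >= threshold` retained; AUC ties count half).

## Known limitations

- No strain-level resolution and no handling of shared tags beyond
  exclusion at DB build.
- No UniFrac (no phylogeny is built) and no rarefaction.
- The LDA score is an approximation contract (rank order, not decimals).
- POD is a vote fraction, not a calibrated probability.
- Phred+33 only; paired-end mates are processed independently since a tag
  fits in one mate.
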