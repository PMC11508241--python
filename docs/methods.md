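# Methods

## Problem setting

Revertant clones from a bacterial reversion assay are whole-genome sequenced
and their single-nucleotide variants (SNVs) called against the reference.
Control clones carry almost no mutations; treated clones carry tens of SNVs
whose trinucleotide-context distribution reflects the DNA adducts formed by
the test chemical. The package turns per-clone VCFs into substitution
catalogs, extracts the underlying mutational signatures, quantifies how much
of each clone's burden each signature explains, tests transcriptional strand
asymmetry, and compares the signatures to the human COSMIC SBS reference
set.

## Channel classification

Every SNV is represented on the strand where the mutated base is a
pyrimidine: 6 substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) × 16
flanking-base combinations = 96 channels, ordered canonically (substitution
class major, 5′ then 3′ flank alphabetical). Purine-reference calls are
reverse-complemented, so a `G>A` at context `CGT` and a `C>T` at context
`ACG` land in the same channel; classification of a variant and its
complementary rendering is therefore idempotent by construction, and this is
property-tested. Coordinates are 1-based inclusive throughout (VCF/GFF3
native). The circular bacterial chromosome is treated as linear; the two
terminal positions have no defined context and are rejected — a negligible
loss at genome scale.

Only records whose FILTER is exactly `PASS` enter the analysis.
Multi-allelic records are split per ALT allele; only single-base alleles are
classified; insertions and deletions are tallied separately and appear in
the six-type summary totals.

For stranded (192-channel) catalogs a genic SNV is labeled *transcribed*
when the pyrimidine of the mutated pair lies on the gene's template strand
and *untranscribed* when on the coding strand. This follows the COSMIC
orientation convention; because the literature is not uniform here, a
`convention="inverted"` switch flips the labels, and the convention used is
carried in the catalog object and output metadata. Intergenic SNVs and SNVs
inside overlapping opposite-strand genes are excluded from the 192-channel
matrix and kept in a per-channel side tally, so transcribed + untranscribed
+ excluded always marginalizes exactly to the 96-channel catalog (a tested
invariant).

## Signature extraction

The catalog is factorized as V ≈ W·H (V: channels × samples counts, W:
channels × k signatures, H: k × samples) by multiplicative updates
minimizing the generalized Kullback–Leibler divergence, the natural
objective for count data. Numerical choices:

- pseudocount 1e-9 inside the updates only (never in reported catalogs), so
  all-zero rows/columns — e.g. control clones with zero mutations — are
  tolerated;
- convergence when the relative objective change over 10 iterations falls
  below `tol` (default 1e-8) or at `max_iter` (default 10,000);
- random uniform initialization scaled to the data mean, seeded.

The update rule is monotone non-increasing in the objective; the test suite
tracks the objective across iterations and asserts this. Frobenius error
against the original catalog is retained as the reported
`reconstruction_error` because it is the conventional summary, while the
KL objective drives the optimization.

**Bootstrap stability.** For each of `n_bootstraps` (default 100)
replicates, each sample's channel counts are resampled multinomially with
the sample's own total, preserving per-clone burden. NMF runs for every
bootstrap × restart (default 10 restarts); all resulting W columns
(L1-normalized) are pooled and partitioned into k clusters by cosine
distance (Euclidean k-means on L2-normalized vectors, 20 clustering
restarts). Consensus signatures are the cluster centroids renormalized to
sum to 1; the per-signature stability is the cluster's mean cosine
silhouette. For k = 1 the silhouette is undefined, so stability is the mean
cosine similarity of pooled vectors to the centroid — the same "how tight is
this cluster" quantity on the same [−1, 1] scale.

Determinism and invariance: samples are processed internally in sorted-id
order and each sample's bootstrap stream is seeded from a CRC32 of its id,
so results are bit-identical under row permutation of the input catalog.
Signature columns are ordered by descending stability with a lexicographic
tie-break on the profile.

**Choosing k.** `select_k` scans a k range and recommends the largest k for
which mean stability has stayed at or above the threshold (default 0.8) at
every smaller k — i.e. the last k before the first stability drop, with ties
toward lower k. On the default synthetic experiment stability is ≈0.99 at
k = 1 and ≈0.99 at k = 2, then collapses below 0.7 at k = 3, giving k = 2.

**Exposures.** Per-sample non-negative least squares of the observed counts
against the signature matrix (Lawson–Hanson NNLS). On a consistent system
with full-column-rank signatures this recovers exposures to machine
precision (tested). Relative contributions divide by the per-sample total;
all-zero samples get zero relative exposure by convention.

**Genome renormalization.** A signature expressed against one genome's
trinucleotide availability can be re-weighted to another background:
each channel is multiplied by target/source frequency of its 32-context
class and the vector renormalized. The operation is exactly invertible
(A→B→A reproduces the input to 1e-12, tested) and raises a named error when
a context with signature mass has zero source frequency. Both directions
(divide out the bacterial background, or re-weight toward a human
background before COSMIC comparison) are expressible through the explicit
source/target arguments; outputs record which frequencies were used.

## Strand-bias testing

Per channel, transcribed vs untranscribed counts are tested against a
binomial(n, 0.5) null with an exact two-sided p-value computed as twice the
smaller tail, capped at 1 — appropriate because per-context counts in a
clone experiment are tens, not thousands. BH adjustment runs across the 96
channels; direction flags (`T>`/`U>`) are set at q < 0.05. Pooling across
samples is the default (bias is a property of the mutational process, not
of a clone); a per-sample mode exists. The reported ratio uses a 0.5
pseudocount by default to stay finite at zero counts. No correction for
transcribed/untranscribed sequence-content asymmetry is applied by default,
since the catalogs compare counts of the same context class on the two
strands; the visual "strong bias" calls common in signature figures have no
published test attached, so this binomial/BH procedure is the package's
defined, labeled stand-in.

## COSMIC comparison

COSMIC-format TSVs (`Type` or `MutationType` label column) are read into
canonical channel order regardless of row order, validated for missing or
duplicated channels, and renormalized with a warning when columns are off
by more than 1e-3. Similarity is the cosine of the two 96-vectors —
scale-invariant, in [0, 1] for non-negative profiles — with descending
ranking and alphabetical tie-break. Summaries print two decimals; stored
values keep full precision.

## Gene-set enrichment

For a query gene list against a GMT collection within an explicit
background universe of size N: a = |query ∩ set|, b = |query \ set|,
c = |set \ query|, d = N − a − b − c. The over-representation p-value is the
one-sided hypergeometric upper tail P(X ≥ a) (verified in tests against
full enumeration of all tables with margins ≤ 30), BH-adjusted across sets.
The odds ratio is (a·d)/(b·c), with a Haldane 0.5 correction applied only
when b·c = 0 and a forced 0 when a = 0. The ranking statistic is the
combined score OR × (−ln p). The background size is a required explicit
parameter — no default universe is assumed, because enrichment p-values are
meaningless without one.

## Synthetic-data generator

The generator emulates the statistical structure of the experiment, not its
biology at sequence level:

- **Genome**: bases i.i.d. with P(G) = P(C) = gc/2 (default length 200 kb,
  GC 0.52 — bacterial-like). Independence is sufficient because all
  downstream context use is re-indexed from the realized sequence, never
  assumed. Genes (default 160 × 1 kb, ≈80% coding density) are placed
  without overlap by distributing the intergenic slack uniformly over the
  gaps, strands uniform.
- **Clones**: per clone, mutation count ~ Poisson(group mean). Each mutation
  draws its generating signature from the group's exposure vector, a channel
  from that signature, and a position uniformly among genome sites whose
  collapsed context matches the channel. Genic placements choose the
  template-strand pool with odds r (the signature's strand-bias factor)
  against the coding-strand pool, so the genic template:coding count ratio
  converges to r; genic vs intergenic placement follows the genomic share of
  matching sites. At most one mutation per clone per position (rejection
  resampling) — co-located hits are biologically rare and per-clone VCFs
  stay well-formed. Terminal positions are never used (no context).
- **Defaults**: five groups emulating a two-conjugate-class experiment —
  control 10 × 0.2, taurine-like 10 + 8 × 27, glycine-like 10 + 10 × 14
  SNVs/clone — with a 60-clone repair-deficient variant at burden 44. The
  control mean of 0.2 reproduces "a couple of mutations across all controls";
  the exact per-clone control burden is a modeling choice since only the
  total is typically reported. Planted signatures: a glycine-conjugate-like
  profile concentrated on G[C>T]C/G[C>T]T (GCY) with strand-bias factor 4,
  and a taurine-conjugate-like profile on A[C>T]C, C[C>T]T, T[C>T]G with no
  bias; both carry a 4% uniform floor so spectra are not strictly sparse.
  Treated-group exposure mixes are 0.9/0.1 rather than pure, so exposure
  refitting is genuinely exercised.
- **Reversion mode**: optionally one transition is planted per clone at
  position 205 or 206 (reading orientation) of a designated target gene, to
  exercise the reversion-site report including minus-strand coordinate
  mapping.
- **Fixtures**: COSMIC-format TSVs round-trip to ≤1e-6; GMT collections are
  built with exactly one set sharing a chosen overlap with the query and the
  rest overlapping by hypergeometric chance.

Everything is deterministic given the config seed — outputs are
byte-identical across reruns — with independent substreams per stage, group,
clone and sample.

**What passing these tests shows — and does not.** The generator matches the
analysis model exactly (multinomial channels, Poisson burdens, clean PASS
calls), so recovery tests validate the correctness and statistical
calibration of the pipeline. They do not probe caller artifacts, mapping
bias, contamination, selection at the reversion locus beyond the planted
site, or non-uniform mutation rates along the chromosome — real-data
performance depends on upstream variant-calling quality, which is out of
scope here.

## Problem sizes used in the shipped checks

The default validation experiment uses the 48-clone layout on a 200 kb
genome (≈750 mutations), with model selection over k = 1…4 at 30 bootstraps
× 3 restarts — small enough to run in seconds while leaving the planted
structure comfortably recoverable (recovery cosines ≥ 0.97 and exposure
errors ≤ 0.07 across seeds). Strand-bias detection checks use ≥ 100
mutations per planted context and 200 null replicates. The library defaults
(100 bootstraps × 10 restarts, max_iter 10,000) remain the recommended
settings for real analyses.

## Known limitations

- Only SBS (single-base) channels: no dinucleotide or indel signature
  classes; indels are tallied, not classified.
- De-novo extraction runs on 96-channel catalogs; the 192-channel analysis
  is descriptive (testing), as is conventional for strand-bias reporting.
- The stability heuristic assumes signatures well-separated in cosine
  distance; nearly collinear processes will merge at the recommended k.
- One chromosome per reference is assumed (bacterial use case); multi-contig
  references would need per-contig context tables.
- The enrichment module implements the Fisher/combined-score variant only,
  not rank-based deviation scores.
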