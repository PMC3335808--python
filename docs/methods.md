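# Methods

## The assay model

`dgetag` analyses SAGE-style 3'-anchored tag libraries: poly(A)+ transcripts
are captured at the 3' end, cut at the 3'-most NlaIII site (CATG), and a
type-IIS enzyme releases a 17-nt fragment downstream of the anchor, so each
transcript molecule yields one 21-nt tag (CATG + 17 nt).  Counting tag
instances per library and summing a gene's uniquely assigned tags gives its
expression value.  Four single-replicate libraries form a time course
(labels `0h, 24h, 48h, 72h`); all between-library inference conditions on
fixed library sizes.

## Synthetic data generator

The generator is the package's stand-in for a sequencing experiment and is
itself part of the tested surface.

* **Reference**: `n_genes` i.i.d. uniform ACGT sequences with lengths drawn
  uniformly from a range (default 300–1500 nt, minimum 25 so a tag fits).
  A sequence drawn without any admissible CATG gets one anchor planted at a
  random admissible position, so every gene is taggable by construction;
  the expected anchor count per gene is (L−20)/256 plus the planting
  correction.  Flat GO/pathway annotation is sampled per term (default 30
  GO terms and 15 pathways of 5–40 genes each).
* **Expression truth**: a Bernoulli(`de_fraction`, default 0.2) draw marks
  DE genes; each receives one of six trajectory shapes — peak at one of the
  four time points (A–D) or monotone down/up (E/F) — with every labelled
  consecutive step changing by exactly `fold` (default 4, the calling
  cutoff scale).  Non-DE genes are flat at `base_mean` (default 100, an
  abundance where count noise is moderate).  Shapes are assigned cyclically
  over a shuffled order so all six occur whenever ≥6 genes are DE.
* **Reads**: per-gene counts are one multinomial draw of `depth` reads on
  the normalised means — fixed library size, matching the conditioning of
  the exact test (a Poisson model would leave the total random).  Each
  payload read is the gene's 3'-most tag plus a fixed synthetic 14-nt
  3' adaptor (`TCGTATGCCGTCTT`) to 35 nt.  Contamination classes are
  disjoint: a configured fraction of reads is pure adaptor, another carries
  ≥1 ambiguous base in the tag region; substitution errors (no indels —
  the 1-mismatch mapper has no indel tolerance) hit each base independently.
  Genes with no CATG site emit nothing and are recorded as undetectable.

What the generator does **not** emulate: PCR duplication, quality-score
profiles, indels, antisense or spliced tags, biological replicate
variability, and genuine overdispersion between conditions.  Passing tests
therefore demonstrate correctness of the pipeline's bookkeeping and its
statistics under the stated sampling model, not robustness to every
artefact of real libraries.

## Cleaning

Stages run strictly in order: adaptor-only discard (read begins with the
adaptor), trim at the first *full* adaptor occurrence, discard candidates
containing N, discard candidates that are not 21 nt starting with CATG,
count, drop per-library singletons.  Ordering is observable: a single-copy
read with an N increments the low-quality counter, never the singleton
counter.  Full-match trimming (rather than suffix-overlap trimming) is a
deliberate choice: tags have a fixed length, so in an intact read the
adaptor always occupies positions 22–35, and full-match trimming makes
cleaning provably idempotent on its own output (a clean tag whose suffix
happens to equal an adaptor prefix is never re-trimmed).  The cost is that
a read whose adaptor itself was corrupted by a sequencing error is dropped
at the structure stage instead of being rescued — an acceptable loss at
realistic error rates.  "Low quality" means *contains ambiguous bases*;
no quality-score filtering exists anywhere in the pipeline.

## Mapping

The virtual tag database enumerates every sense-strand CATG window with
≥17 nt downstream, per gene, with 3' rank recorded (1 = 3'-most; rank is
reported, never used as a weight).  Antisense windows are not enumerated
(the protocol captures sense-strand 3' fragments).  Assignment semantics:
exact matches take the best stratum; only a tag without any exact match is
compared against its 63 single-substitution neighbours; whenever the
admissible matches at the best stratum span more than one gene the tag is
discarded as multigene and excluded from the mapped-distinct counter.
Neighbour enumeration against a hash index replaces a BWT aligner — the
result contract (best-stratum, ≤1 mismatch, multigene removal) is what is
normative, not the index structure.  The distinct-tag mapping rate is
100·mapped/distinct rounded to two decimals, half away from zero.

## Normalisation and differential expression

TMM factors are computed exactly as the trimmed weighted mean: for each
library against the reference, M and A statistics over genes positive in
both, rank-based double trimming (30% of M tails, 5% of A tails), weights
equal to inverse asymptotic binomial variances, factor `2**mean`, then
rescaling to unit geometric mean.  Effective size = mapped tag instances ×
factor.  No dispersion estimation or empirical-Bayes machinery is
implemented: with one library per condition the exact conditional test is
the defensible choice, and the TMM factors feed it through the effective
sizes.

The two-sided exact-test p doubles the smaller tail (both tails include
the observation) and caps at 1; tails are evaluated through the negative
binomial representation of the conditional law, which is numerically
stable for all desk-scale inputs (verified against naive high-precision
direct summation to <1e-12).  A subtlety worth recording: swapping
`(x, N1)` with `(y, N2)` is *not* an exact symmetry of this convention —
the conditional point masses transform as `p(x|y) = (N2/N1)·p(y|x)`, so
the doubled-tail p can shift by up to twice the point mass at the
observation.  At tag-library scales (large N, counts with many admissible
values) the point mass is small and the symmetry holds to high accuracy;
the property test asserts it within the discreteness bound.

Fold changes: `log_fold_change` adds its pseudo-count unconditionally
(default 1), which is what reporting code wants; the DEG caller applies the
pseudo-count *only* when a zero count forces it, so threshold semantics for
co-positive genes are exact.  FDR is plain Benjamini–Hochberg within each
comparison; the joint call is log₂FC ≥ 2 (≤ −2), p ≤ 0.01, FDR < 0.01
(strict), and loosening any one threshold can only add calls.

**Boundary behaviour at exactly 4-fold.**  If the true fold equals 4, the
estimated log₂FC is centred on the cutoff 2.0 and each labelled step is
detected with probability ≈0.5 *at any depth* — the six shapes give DE
genes one to three labelled steps, so gene-level sensitivity settles
around 0.7.  Sensitivity approaches 1 only for true folds strictly above
the cutoff.  This is a property of thresholding at the effect size, not of
the implementation, and the recovery test documents it rather than
adjusting the conditions.

## Enrichment

Background N is the set of genes carrying at least one annotation in the
relevant vocabulary, not the whole genome.  GO terms flag significance at
raw p < 0.05; pathways at BH q < 0.05 — the asymmetry is preserved
deliberately.  The upper tail is P(X ≥ m); had the convention been
P(X > m) every p would shift by one term — the inclusive form is fixed
here and the enumeration oracles in the tests pin it.  Top-term reporting
sorts significant terms by enrichment factor (ties: smaller p, then term
id) and takes 15.  The heatmap matrix holds −log₁₀ p for pathways
significant in at least one comparison (missing p ≡ 1), rows ordered by
average-linkage (UPGMA) hierarchical clustering on Euclidean distance;
columns keep time order so stage-specific enrichment stays legible.

## Clustering

Profiles are log₂(TMM CPM + 1) at the four time points for the DEG union;
a common-reference alternative (log₂ ratios vs t-0, `to_common_reference`)
exists as an explicit transform the caller can feed in instead.  Rows are
not standardised by default.  K is fixed at 6; Lloyd's algorithm with
k-means++ seeding runs `n_init` restarts *sequentially* from a seed
sequence derived from one user seed, so the best-of-n inertia is
non-increasing in n with a shared prefix and the whole fit is
deterministic.  Pattern labels: a cluster is "peaked" when the drop from
its centroid's maximum to the runner-up exceeds the spread of the
remaining values; peaked clusters take A–D by peak time (the sharpest
peak wins a contested time point), the rest take the leftover letters
with the largest cluster receiving the last letter (so the bulk class is
F).  The E/F convention is an artifact-level choice — only A–D have a
biological reading (peak at the four successive stages).  Note that
k-means++ initialisation depends on row order; on well-separated data the
recovered partition is order-invariant even though cluster indices may
permute.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which every statistical check is stable across seeds: references
of 50–500 genes, libraries of 2×10⁴–1.5×10⁵ reads, count-level matrices of
1500–2000 genes at depths giving minimum true mean counts of 25–50, 20
null replicates, 40 enrichment replicates.  Degenerate inputs are handled
explicitly: empty read sets yield empty libraries with zero counters;
genes absent from both libraries are NS; empty clusters export empty,
headed files; a zero distinct-clean denominator makes the mapping rate an
error rather than a NaN.  All simulation randomness flows through
`numpy.random.default_rng` seeds; nothing reads the wall clock.
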