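# Methods

## Scope and model

taxbench re-implements, as an offline library, the computational core of a
combined taxonomic classification workflow and its evaluation harness: a
rooted taxonomy with LCA/rank primitives, streaming parsers for the formats
the pipeline touches, per-read LCA assignment over filtered protein hits
combined with a primary k-mer classification, a clade-exclusion benchmark
generator (genome selection + read simulation + truth tracking), genus-level
scoring, alpha-diversity statistics, and a generic observation/attribute
result store. Client/server transport, authentication, workflow engines and
the execution of external classifiers are deliberately absent; their output
*formats* (Kraken-style per-read TSV, BLAST/DIAMOND tabular) are consumed
instead.

## Taxonomy

`TaxonomyTree` accepts the NCBI taxdump dialect (pipe-and-tab) and plain
TSV; only the first three columns of nodes and the "scientific name" rows of
names are consulted, and a missing scientific name falls back to the
stringified taxid. Construction validates the three structural invariants
(resolvable parents, a single self-parent root, acyclicity) and precomputes
depths, so LCA is the standard lift-to-equal-depth walk — O(depth) per pair,
folded pairwise over a set. At desk scale (≤ a few 10⁵ nodes) this beats the
complexity of sparse-table schemes for maintainability; correctness is
pinned by a brute-force path-intersection oracle in the tests. Unknown
taxids follow a tree-wide policy: strict (raise) by default, lenient (skip)
for alignment hits that may reference merged or retired taxa. merged.dmp /
delnodes.dmp are not consulted.

## Hit filtering and combination

`LcaParameters` defaults — top-score fraction 0.10, minimum bitscore 50,
maximum e-value 1e-5 — are the conventional LCA-binning defaults (MEGAN
lineage); all three are exposed on the CLI. At fraction 0 all hits tied at
the best bitscore are retained, keeping the result order-independent.

The combination policy is *primary-with-fallback*: this is the only policy
consistent with the published benchmark pattern in which the combined
pipeline's precision equals the k-mer classifier's while its sensitivity
exceeds it — an intersection or re-vote policy would perturb precision. A
merge policy (LCA of the two calls when both exist) is a possible extension
but is not implemented; requesting an unknown policy raises.

## Read simulation

The simulator draws, per genome, `reads_per_genome` single-end reads: start
uniform over valid windows, strand uniform, minus-strand windows
reverse-complemented *before* error injection, then each base substituted
independently with probability `mismatch_prob` (default 0.03) to a uniformly
chosen different base. This is a deliberate simplification of an
Illumina-specific error profile: no indels, no position-dependent error
rate, no quality-model realism (FASTQ qualities are a constant "I"). The
controlled quantity — the pooled mismatch fraction — is preserved exactly
and verified by a binomial concentration test; conclusions about real
Illumina data that depend on error-position structure or indels are outside
what the passing tests show. Windows containing ambiguity codes are rejected
and resampled (100 tries, then an error naming the genome).

Randomness is organized as one user seed fanned out through named
substreams (`SeedSequence([seed, crc32(accession)])`), so each genome's
reads are independent of catalog composition and all outputs are
byte-identical for identical configurations. Genome selection helpers
implement the two benchmark designs: one-genome-per-species (lexicographic
smallest accession as the deterministic tie-break) and clade exclusion
(species not in the reference set, genus present among reference genera).

## Evaluation semantics

Scoring projects both the truth taxon and the predicted taxon to the target
rank (genus by default). A read is fn when unclassified, absent from the
assignments, or resolvable only *above* the rank; wrong-rank-taxon
predictions are fp; this is the only bucket assignment under which
tp + fp + fn equals the evaluated read count while "wrong genus" stays a
false positive, and it matches the published count tables exactly (every
column closes to its dataset size — which also pins a garbled published
false-negative figure, stored as missing and reconstructed from closure
rather than hard-coded). Truth reads whose own lineage lacks the rank are
excluded from the total with a reported count: their ground truth is
undefined at that rank. The metric formulas (sensitivity tp/(tp+fn),
precision tp/(tp+fp), accuracy tp/total, F1 harmonic mean) reproduce all 40
published metric values to 4 decimal places. Zero denominators yield 0.0
with a flag rather than an error.

Note the analytic expectations for a mock classifier with wrong-genus rate
e and unclassified rate u under these semantics: accuracy 1−e−u,
sensitivity (1−e−u)/(1−e), precision (1−e−u)/(1−u); the parameter-recovery
tests use these forms.

## Diversity statistics

Shannon uses the natural log (the R/vegan convention) with a base override;
"Simpson" is reported as Gini–Simpson 1 − Σp², with the raw dominance form
behind a flag, since the bare name is ambiguous across tools. Chao1 uses the
classic singleton/doubleton form with the bias-corrected branch when f₂ = 0.
ACE uses the textbook coverage-based estimator with the rare/abundant cut at
10 (overridable); in the degenerate case where every rare individual is a
singleton (sample coverage 0) it falls back to Chao1. Exact rarefaction is
computed in log-gamma space to stay stable at large n; the Monte-Carlo mode
(≥100 seeded subsamples without replacement) exists mainly as an internal
cross-check and for irregular use cases. Profiles are built from assignment
streams by rank projection; unclassified and above-rank reads are excluded.
Tests cross-check all four indices against scikit-bio's implementations and
rarefaction against its own Monte-Carlo estimate within three standard
errors.

## Observation store

The store is embedded SQLite (in-memory or single file), keeping the
interface narrow enough that a service layer could wrap it. Discrete
distributions are maintained incrementally on insert (an upsert per
observation), making summary queries independent of store size; the
from-scratch recount used for consistency checking is an independent SQL
aggregation over the observation table. Hierarchical roll-up counts a value
as its direct observations plus all descendants — a documented choice, since
several plausible semantics exist when one sequence is observed at multiple
hierarchy levels. Continuous attribute types are summarized on demand into
fixed-width bins (default 100) over the observed range instead of an
incremental cache. Coordinates are 0-based half-open with an explicit strand
field, matching the truth-manifest convention. Hierarchical types require a
discrete domain; violations raise at registration.

## Numerical and degenerate-input choices

- Empty LCA query sets, empty profiles, zero evaluated reads, depth > n in
  rarefaction: usage errors (ValueError), not silent results.
- Empty hit lists filter to empty lists; reads with no surviving hits are
  UNCLASSIFIED (taxid 0, the k-mer classifier convention kept throughout the
  assignment TSV format).
- Parsers are streaming generators and fail with file/line context.

## Problem sizes

The simulation-backed checks run at deliberately desk-scale sizes chosen to
give tight binomial error bars while completing in seconds: the end-to-end
benchmark uses 20 genera × 5 species × 100 reads (10,000 reads; two-sample
binomial SE for the precision comparison), and the error-rate check pools
10⁶ simulated bases (4σ band ≈ ±0.07 percentage points around 3%). The
full published benchmark (thousands of genomes, >10⁷ reads, external
classifier databases) is represented by its printed confusion counts, which
the metric layer reproduces exactly.

## Known limitations

- No paired-end semantics, indel errors, coverage bias or realistic genome
  composition in the simulator or fixtures.
- Taxonomy snapshots are an input, never pinned or downloaded; merged or
  deleted taxid remapping is out of scope (lenient mode skips them).
- Beta-diversity, ordination (PCA/PCoA), clustering and abundance-profile
  distances are out of scope; only alpha diversity and rarefaction are
  provided.
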