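# Methods

This note documents the models and procedures implemented in `fintax`,
the parameter choices that matter, what the synthetic data generator
does and does not emulate, and the numerical conventions used
throughout.

## Reference curation

**Gene vocabulary.** Reference records carry one of 15 canonical
mitochondrial gene names (two rRNA genes, thirteen protein-coding
genes). Raw labels are normalized case-insensitively, ignoring hyphens,
underscores and spaces, against a table of known alternative spellings;
unknown labels map to `None` rather than raising, so callers decide how
to handle unannotated input.

**Merging.** Identical sequences of the same species and gene are
merged into one record whose accession list and author set are the
unions of the parts; total accession count is conserved. Identical
sequences of one species under *different* gene labels are kept separate
with a logged warning — one annotation is presumably wrong, and merging
would hide that.

**Chunking rule.** Each gene is tiled with 100-bp validation windows
starting at multiples of 100. When the length is not a multiple of 100
the final window is the last 100 bp of the sequence, so the last two
windows overlap rather than leaving a short remainder — 100 bp is about
the smallest scale at which chimeric segments occur in public fish
mitochondrial records, and a sub-100-bp window would make the >99%
identity test degenerate (a single mismatch in an 80-bp window already
drops identity to 98.75%). Genes shorter than 100 bp get one whole-gene
window and are classified normally rather than being dropped.

**Chunk classification.** For each chunk, homologs are collected from
the rest of the database (records sharing an accession with the query
are excluded as non-independent) as best local alignments with identity
strictly greater than 99% and chunk coverage of at least 80%. Local
(HSP-style) identity is deliberate: a corroborating record that is a
few bases shorter than the query still yields a perfect local match,
whereas an end-to-end definition would count the overhang as gap
columns and push identity below the threshold, making legitimate
corroboration by partial-length records impossible. Note that over a
100-bp window the strict >99% rule effectively demands a perfect or
single-gap match (one internal mismatch gives exactly 99.0%).

Author sets are compared after case-folding and stripping punctuation;
two records corroborate each other only when their author sets are
disjoint. Heterospecific calls additionally require the other-species
homologs to span at least two distinct species contributed by at least
two disjoint author groups (connected components under author-set
overlap), which mirrors how chimeric segments present in practice: the
contaminating region matches a clade of closely related species
deposited by several labs. One other species, or several species from a
single lab, leaves the chunk `unknown`. Classification of any chunk
depends only on the database content, never on record iteration order.

**Occurrence deduplication.** Within each species, occurrences are kept
one-per-cell on a `floor(coordinate / tolerance)` grid (default 1°).
Grid binning was chosen over pairwise-distance thinning because it is
deterministic, order-stable for the first record in each cell, and
O(n). Out-of-range coordinates are skipped with a warning.

**Background database.** Non-fish sequences are greedily clustered:
inputs are sorted by decreasing length then id, and each sequence joins
the first centroid with global identity ≥ 97%, else founds a new
centroid. The background database is a filter for off-target
amplification, not an identification tool, so centroid-level resolution
suffices.

## Similarity search

The internal engine mirrors a megablast-style workflow: best local hit
per subject on either strand (plus-strand coordinates reported), a
query-coverage gate at 80%, hits ordered by score with ties broken by
subject id, and at most `max_targets` returned. Scoring is affine DP
with match +2, mismatch −3, gap open −5, gap extend −2, where the
opening gap column costs 5 and each extension 2; `N` matches nothing,
including another `N`. Scores are compared after rounding to one
decimal (bit-score granularity), and identities/coverages are stored to
three decimals so BLAST-tabular round trips are exact.

**Saturation.** Species-complex calling needs the *complete* set of
co-equal best hits. Starting from 10 targets, whenever the returned
list is full with uniform top scores at identities ≥ the species
threshold, the search is repeated with the cap raised by 50 until a
lower-scoring hit bounds the stratum. If the database is exhausted
while scores are still uniform the stratum is returned with
`saturated=False`.

**Fast/sensitive modes.** The fast pass requires subjects to share an
exact 28-mer with the query (either strand) before alignment; queries
with no hits are rerun requiring only an 11-mer. This reproduces the
megablast-to-blastn fallback behaviourally: a ~92%-identity relative
with evenly spread differences has no shared 28-mer but virtually
always an 11-mer. These are documented approximations — the engine does
not reimplement BLAST statistics, and the E-value column of external
hit tables is parsed but unused. An external BLASTN adapter can
implement the same contract for production-scale databases; everything
in this repository runs on the internal engine.

## ASV generation

**Short accurate reads.** Exact dereplication (abundance-descending,
then lexicographic) is followed by a simplified abundance-skew
denoiser: a unique sequence within `max_dist` (default 1) edits of an
already-accepted ASV at least `skew` (default 8) times more abundant is
absorbed as its error shadow. Uniques at or above `min_abundance`
(default 2) otherwise found new ASVs; sub-threshold orphans are
attached to the nearest accepted ASV so that total read count is
conserved exactly — at the 0.1%/base error rates typical of
quality-filtered short reads, an orphan two edits from a template is
overwhelmingly that template's double-error read, and discarding it
would silently leak counts. These defaults are a documented
simplification of UNOISE-style denoising, not a reimplementation of its
error model; paired-end merging, primer trimming and quality filtering
are assumed done upstream.

**Noisy long reads.** Reads are sorted by decreasing length and
greedily clustered: a read joins the first centroid with global
identity ≥ 97%. Identity here is computed on the unit-cost (edit
distance) global alignment, with gap columns counted — at the
divergences relevant to a 97% threshold this is indistinguishable from
affine-gap identity and orders of magnitude faster. Note the geometry:
two reads at error rate *e* from the same template sit at ~2*e*
divergence from each other, so raw reads at 3% error cannot mutually
clear 97% and the initial clustering necessarily fragments. The
clusters are therefore treated as *candidates* for an iterative
consensus-polish loop:

1. merge candidates whose consensi are within the threshold of each
   other (largest first);
2. re-assign every read to its highest-identity candidate, requiring
   identity above the threshold relaxed by 10 percentage points (head
   room for the read's own errors on top of residual consensus noise);
   only multi-read candidates may attract reads — a read is trivially
   100% identical to a singleton candidate it founded, which would
   freeze the partition; reads clearing no candidate stay as singleton
   candidates;
3. recompute each candidate's consensus from its assigned reads
   (per-column plurality against the current consensus, ties toward the
   consensus base; insertions kept when present in more than half the
   members);
4. repeat (up to 5 rounds) until assignments are stable.

Finally, candidates attracting fewer than `max(2, 1% of reads)` reads
are dropped as unpolishable noise. On simulated data (five templates
≥ 5% apart, 50 reads each at 3% error with a 40/30/30
substitution/insertion/deletion mix) this recovers exactly one ASV per
template with every read assigned and consensus identity 100%, across
seeds. No minimum cluster size is imposed beyond the stated floor; real
singleton variants below it are invisible to this path by design.

ASVs carry the MD5 digest of their uppercased sequence and per-sample
read counts. Pre-computed ASV/OTU FASTA input bypasses read processing
entirely (the reanalysis path), so reference updates only cost a fresh
annotation run.

## Taxonomy assignment

Each ASV's saturated top-score stratum is classified:

* no hits → `unassigned`;
* stratum entirely from the background database → `nonfish`, labeled
  with the best background taxon;
* fish hits with best identity below the species threshold (default
  99%, user-adjustable) → `higher_taxon`: the lowest common ancestor of
  the top-hit species over genus/family/order/higher; a single
  sub-threshold species reports its genus. Nonbinomial filtering is not
  applied at this branch — the filters below are species-level
  concepts;
* fish hits at or above the threshold: the distinct species supported
  by ≥-threshold hits are filtered twice. Nonbinomial names
  (qualifiers like "sp.", "cf.", "aff.") are dropped when at least one
  binomial candidate exists. Then any species whose *every* supporting
  hit has at least half of its subject interval covered by
  heterospecific chunks (fraction configurable) is dropped for lack of
  trustworthy evidence. One survivor → `species`; several →
  `species_complex`, members sorted alphabetically and labeled
  `A/B/...`. If the filters eliminate every candidate the unfiltered
  set is reported with an `all-filtered-fallback` flag rather than
  discarding the ASV.

A stratum that ties fish and background subjects is classified as fish
with a `score-tie-with-nonfish` flag — the tool's purpose is fish
detection, and a silent nonfish call would hide a real detection.
Summary tables aggregate species-level read counts over member ASVs per
sample; higher-taxon and nonfish ASVs are listed individually with
their MD5s; total reads are conserved across the species, higher,
nonfish and unassigned tables.

## Multi-sample matrices

The result matrix has one row per species or complex and one column per
manifest sample. Badges: `P`/`N` mark detection (count > 0; no default
minimum-read threshold, a `--min-reads`-style filter is a one-line
predicate) in any positive/negative control. `S` marks, by default,
detection in exactly one `sample`-role column overall where that column
belongs to a replicate group of size ≥ 2; a per-group variant
(`scope="group"`: exactly one detection within some group, other
columns ignored) is available because the single-replicate notion is
genuinely ambiguous for multi-group designs. Badges and habitat /
occurrence annotations only inform manual filtering — species detected
in controls are flagged, never subtracted, and species lacking nearby
occurrence records are never auto-excluded, since occurrence data are
systematically incomplete for undersampled regions.

Occurrence proximity uses box distance (max of |Δlat| and wrapped
|Δlon|), consistent with the 1° deduplication grid; longitudes wrap at
±180°. CSV export is lossless round-trip (badges serialized as
`P;S`-style strings).

**Comparison utility.** Published taxon lists are categorized per entry
as Single (exact species row), Multiple (member of a complex), Clades
(a higher-taxon row contains it), Diff (present but as a different
taxon) or Undetected. By name matching alone, Diff is undecidable — it
requires knowing which observed row the published taxon's reads
produced — so Diff is only emitted when an explicit published→observed
assignment map is supplied; otherwise unmatched taxa are Undetected.
Every published entry receives exactly one category.

## Synthetic data generator

The generator produces every input with explicit truth: reference sets,
taxonomies, habitat and occurrence tables, background contaminants, and
per-sample read sets.

Species sequences derive from one random root, each mutated at half the
nominal pairwise divergence. Substitutions are placed *stratified* —
one per window of `1/rate` bases at a random in-window position —
rather than uniformly, so that every 100-bp chunk of two species at
nominal divergence *d* differs at close to `d × 100` positions for
every seed; uniform placement would occasionally leave near-identical
windows and make identity-threshold behaviour seed-dependent. Records
of one species differ by short random terminal tails (distinct
sequences, so nothing merges away) and carry authors from disjoint
pools, giving every chunk an exact independent same-species homolog.

The chimera preset plants a 150-bp segment shared verbatim by two donor
species into an extra host record from a fourth author pool — two
donors because a heterospecific call requires evidence from at least
two species, matching the empirical pattern of chimeric regions
matching a small clade. Read simulation is platform-specific: Illumina
reads carry independent per-base substitutions only (default 0.1%);
Nanopore reads a mixed process at 3% per base, 40% substitutions, 30%
insertions, 30% deletions. Identical seeds give byte-identical
fixtures.

What the generator does **not** emulate: realistic phylogenies (star
topology only), quality scores, PCR amplification bias, PCR-formed
chimeric reads, length variation between species, and the taxonomic
breadth of real databases. Tests passing on these fixtures demonstrate
the algorithms' contracts — threshold logic, filter semantics,
conservation, determinism — not field-scale accuracy on real
communities, which depends on reference completeness and marker choice.

## Numerical conventions and scale

Identity is matching columns over alignment columns with gaps counted;
semi-global alignments exclude their free terminal gaps from the column
count. Score ties use one-decimal rounding. Greedy clustering ties
resolve by input order after a decreasing-length, then lexicographic
sort. Consensus ties resolve toward the current consensus base.
Alignment-free determinism (no threading, seeded RNGs everywhere) makes
every pipeline output reproducible bit-for-bit.

Test and acceptance problem sizes — references of 3–12 species at
150–600 bp, hundreds to ~1,400 reads, databases of ≤ 50 sequences for
the search-oracle checks — were chosen so the whole suite exercises
every code path in seconds on one core while keeping every quantity
(cluster counts, chunk labels, read conservation) exactly predictable
from the fixture truth. The algorithms contain nothing scale-specific;
production-sized databases would pair the same logic with the external
search adapter.

## Known limitations

* The internal search engine approximates megablast/blastn seeding and
  scoring; E-values and compositional statistics are out of scope.
* The short-read denoiser is a deliberate simplification (fixed skew,
  unit edit distance) of UNOISE-style models; chimera detection during
  denoising is not implemented.
* Heterospecific overlap uses a single coverage fraction (default one
  half) of the hit interval; per-marker calibration is left to the
  user-facing parameter.
* The author-disjointness proxy treats empty author sets as disjoint
  from everything; records without author metadata can therefore
  corroborate, which is optimistic.
* `compare_to_published` without an assignment map cannot distinguish
  "detected as something else" from "not detected".
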