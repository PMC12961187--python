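# fintax

Species-resolution analysis of fish environmental-DNA (eDNA) metabarcoding
data, for ecologists and bioinformaticians monitoring aquatic biodiversity
with mitochondrial markers (12S/16S rRNA, COXI, Cytb) on Illumina or
Nanopore platforms.

Accurate species-level identification from short amplicons is limited by
two things: contaminated or mislabeled reference sequences, and distinct
species that share identical barcode sequences. `fintax` addresses both:

* **Region-level reference validation.** Every reference gene is tiled
  into 100-bp chunks; a chunk whose >99%-identity homologs include the
  same species from independent authors is *homospecific*, while a chunk
  matched only by several other species from independent authors is
  flagged *heterospecific* (chimeric contamination). Formally, for a
  chunk *c* of a record labeled species *s* with author set *A*, and
  homolog set *H(c) = {(sᵢ, Aᵢ) : identity > 99%, coverage ≥ 80%}*:
  *c* is homospecific if ∃(sᵢ, Aᵢ) ∈ H(c) with sᵢ = s and Aᵢ ∩ A = ∅;
  heterospecific if no homolog has sᵢ = s and the independent homologs
  span ≥ 2 species from ≥ 2 disjoint author groups; unknown otherwise.
* **Species complexes instead of over-broad LCAs.** An ASV whose
  saturated top-score hit stratum ties several species at ≥ 99% identity
  is reported as the joint set of exactly those species ("species
  complex"), after dropping nonbinomial names when a binomial
  alternative exists and species whose only supporting hits fall in
  heterospecific regions. Sub-threshold ASVs fall back to the lowest
  common ancestor of the top hits; off-target amplicons are absorbed by
  a clustered non-fish background database.
* **Both sequencing platforms.** Accurate short reads are dereplicated
  and denoised by abundance skew; noisy long reads are greedily
  clustered at 97% identity and refined by an iterative
  consensus-polish loop until each template collapses to one clean ASV.
* **Multi-sample designs.** Results assemble into a species-by-sample
  matrix with badges `P` (seen in a positive control), `N` (negative
  control) and `S` (only a single replicate), habitat and
  geographic-occurrence annotations per complex member, and lossless
  CSV export. Badges flag; they never remove anything automatically.

## Worked example

A reference record of *Aquaticus alpha* carries a planted 150-bp segment
that truly belongs to two donor species. Validation flags the region,
and the heterospecific filter changes the assignment of an amplicon
drawn from it (`python examples/03_taxonomy_annotation.py`):

```
hetero_filter=False: species_complex -> Aquaticus alpha/Aquaticus bravo/Benthicus charlie  (best identity 100.0%, notes=[])
hetero_filter=True: species_complex -> Aquaticus bravo/Benthicus charlie  (best identity 100.0%, notes=['heterospecific-filtered'])
```

Without the filter, the contaminated host record ties the true donors at
100% identity and wrongly drags *Aquaticus alpha* into the complex; with
it, the host's evidence is rejected because it lies in heterospecific
chunks, and only the two genuinely indistinguishable donor species
remain.

The multi-sample workflow (`python examples/04_multisample_matrix.py`)
prints the badge-annotated matrix for a six-species design with
replicates and controls:

```
  Aquaticus bravo        [-  ]  200  150    0    0    0    0
  Aquaticus alpha        [N  ]  300    0    0    0    0    6
  Benthicus delta        [-  ]    0    0  150  140    0    0
  Benthicus charlie      [-  ]    0  220    0    0    0    0
  Currensis foxtrot      [P  ]    0    0    0    0  100    0
  Currensis echo         [S  ]    0    0   25    0    0    0
```

*Aquaticus alpha* leaked into the negative control (`N`), the
positive-control species is flagged `P`, and *Currensis echo* was seen
in only one of two replicates (`S`) — all three are prompts for manual
inspection, not automatic removals. Every one of the 1,401 input reads
is accounted for across the species, higher-taxon, nonfish and
unassigned tables.

Other examples: `01_reference_validation.py` (chunk statuses of the
chimeric record), `02_asv_building.py` (both ASV paths recovering exact
templates), `05_search_engine.py` (top-hit saturation and the sensitive
fallback).

A thin CLI wraps the same library calls; see `fintax --help`
(`validate-refs`, `build-background`, `dedup-occurrences`, `search`,
`asv`, `run`, `simulate`, `matrix-compare`).

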