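# Methods

This note documents the model behind `seabirdid`, the parameters that
matter, the synthetic-data generator's assumptions, and the numerical
and design choices made where the design was genuinely open.

## Markers and reference databases

Three short mitochondrial amplicons are defined as data
(`seabirdid.markers.default_markers`), each with its degenerate primer
pair, expected insert length, annealing temperature (metadata) and
distance thresholds:

| marker | region | insert | species threshold | genus threshold |
|---|---|---|---|---|
| `COI_AP` | cytochrome oxidase I | 367 bp | 1.5% | 4% |
| `Cytb_AP` | cytochrome *b* | 305 bp | 1.5% | 4% |
| `CRBird_AP` | control region copy 2, domain 1 | 379 bp | 1.5% | 7% |

Thresholds are fractions of differing sites: a neighbour at or below the
species threshold shares ≥ 98.5% identity. The control region evolves
faster, hence its wider genus band. `CRBird_AP` carries a set of
*caution genera* (`Phoebastria`, `Procellaria`) in which the control
region is duplicated and the amplified copy is uncertain; CR-based calls
touching those genera are annotated `cr_copy_uncertain` rather than
suppressed.

Reference databases are FASTA files with taxonomy-bearing headers. Two
dialects are auto-detected per file (mixing is an error): a canonical
pipe-delimited form `>accession|family|genus|species[|provenance]`, and
a lenient `>accession Genus_species` form completed from a taxonomy
side-table (TSV: species, genus, family, listed). The packaged
side-table reconstructs the 36 ACAP/TAP species of management concern
from the public ACAP Annex 1 list plus the five Australian TAP
shearwaters/petrels; the `listed` flag is reporting metadata only and
never enters any computation. Curation is a soft delete: excluded
accessions stay in the file model with `provenance=excluded` and a
reason, and every curation pass emits an auditable report (counts per
species and family, exclusions applied and not found, haplotypes shared
across species).

Haplotype collapsing groups sequences of one species that are identical
after uppercasing, or fully nested (one a truncation of the other —
identical over their common overlap). Ambiguous containment (a fragment
nested in two distinct haplotypes) is left as its own haplotype rather
than guessed. Identical sequences appearing in two species are flagged
`shared_haplotype`, since they make those species mutually unresolvable.

In-silico PCR (`extract_amplicon`) matches primers IUPAC-aware — a
primer code matches a template code when their base sets intersect;
inosine and N match anything — on both strands, with a configurable
mismatch budget. The reverse primer is matched as its reverse
complement. When several site pairs qualify, the pair whose insert
length is closest to the expected length wins; exact ties keep the
first by position and log a warning. Coordinates are 0-based half-open
internally; anything reported is 1-based.

## Alignment

Reference alignments use a deterministic center-star strategy: the
longest sequence (ties broken by accession) is the center, every other
sequence is globally aligned to it with affine gap costs (match +2,
mismatch −1, gap open −5, gap extend −1; Gotoh convention, the open
score applying to the first gap position) and **free end gaps**, and the
per-sequence gap patterns are merged into shared columns. Insertion
blocks demanded by different sequences at the same center position are
left-aligned. The scoring is recorded in each alignment and in every
provenance file. For the short, largely indel-free marker fragments this
is adequate and exactly reproducible; it is not a general-purpose MSA.

Queries are placed on the finished alignment as a fixed profile: the
query is pairwise-aligned to every reference, the best-scoring reference
anchors the placement, and query bases are projected into that
reference's columns. Insertions relative to the profile are dropped
(columns are immutable). Two guards reject junk: a query must overlap at
least `min_overlap` (100) non-gap columns with some reference, and its
identity to the closest reference must reach the identity floor, 0.75.
The floor sits in a wide empirical gap: random non-homologous sequence
reaches ~0.55 identity under this scoring (gap moves inflate chance
identity well above the naive 0.25), while any query eligible for even
the coarsest family-level call is within 2 × 7% of a reference, i.e.
≥ 0.86 identity.

## Distances and threshold identification

`p_distance` is the uncorrected distance with **pairwise deletion**:
compared sites are columns where both rows carry A, C, G or T; gaps and
ambiguity codes are excluded pair by pair. This is deliberately
conservative for degraded feather reads — an N never counts as a match.
A complete-deletion mode (drop any column with a gap/ambiguity in any
row, once, before all comparisons) is available as a config switch;
pairwise is the default because short fragments would otherwise erase
most columns. Pairs with fewer than `min_overlap` = 100 comparable sites
are *missing*; classification treats missing as above any threshold.
With 305–379 bp markers, 100 sites bounds the variance of the distance
estimate (binomial standard error ≤ ~1.2 percentage points at p = 1.5%).

Threshold identification classifies each sequence by the species labels
of its neighbours (distance ≤ threshold, ties included): `correct`
(all conspecific), `incorrect` (none), `ambiguous` (mixed), `no_id`
(no neighbours). Species are then scored structurally: build a graph on
species with an edge (A, B) when any sequence of A has a neighbour in B,
and read categories off the connected components — isolated = `species`,
component of two = `sister_species` (the partner recorded), larger =
`multiple_species`; species in the evaluation universe without data =
`no_reference`. Defining sister pairs structurally, rather than from a
curated list, reproduces the known pairings from data alone and
generalizes to any taxon set. A species whose only flaw is a `no_id`
singleton sequence is still `species`: a lone haplotype says nothing
about intraspecific variation but does not make the species confusable
with another.

Marker combination takes, per species, the best category across markers
under the ranking species > sister_species > multiple_species >
no_reference, with partners from the first marker (in the configured
order) achieving the best category. Family summaries report species
counts both as a fraction of species with reference data (marker
utility) and of the full universe (coverage).

## Decision tree and the cauta/steadi SNP

Unknown specimens are identified marker by marker with the same
neighbour semantics: one species within the species threshold → rank
`species`; several species of one genus → `sister_set`; otherwise the
genus threshold is tried for a `genus` call; failing that, a nearest
reference within 2 × the genus threshold supports a `family` bin, else
rank `none`. The family fallback (and its multiplier, config) goes
beyond the genus-level stopping point of threshold identification
because bycatch reporting tallies at family rank; it is labelled as the
weaker inference it is.

The tree consults cytochrome *b* first and the control region only when
species resolution is insufficient — the cheaper marker usually
suffices. A CR sister set of exactly {*Thalassarche cauta*,
*T. steadi*} triggers a diagnostic-SNP call: diagnostic columns are the
alignment columns where the two species' references are fixed and
different (learned from the alignment rather than hard-coded, so the
rule survives re-trimming of the CR amplicon), and the query is called
by majority vote over them. Gaps or ambiguities at every diagnostic
column, or a tied vote, give `indeterminate`. A successful call upgrades
the assignment to species rank but always carries the caveat
`snp_call_~3%_error`, the documented error rate of this discrimination.
The final rank is never coarser than the best single-marker rank among
the evidence, and all per-marker evidence is retained in the output.

Non-procellariiform queries (e.g. a tern) are handled by the same
machinery against whatever databases are configured; without suitable
references they return rank `none` with nearest-family evidence, so the
self-contained target set for sequence-level evaluation is the
procellariiforms.

Genetic-vs-visual comparison joins assignments to e-logbook records on
specimen id and scores agreement at family, genus and species rank:
`Y`/`N` where both identifications reach the rank, `n/a` where either is
coarser or the specimen has no e-log record. Visual taxa are lifted
through a taxonomy table (`Ardenna spp.` → genus *Ardenna* →
Procellariidae, etc.).

## Synthetic data

The generator emulates what the analysis assumes and nothing more:

- several families, genera and species with a few haplotypes each
  (defaults: 4 × 2 × 3 species, 2 haplotypes, 350 bp — marker-length
  fragments);
- a barcode gap: target maximum intraspecific divergence 0.5%, target
  minimum interspecific divergence 5%, well either side of the 1.5%
  threshold;
- optional sister pairs with sub-threshold divergence;
- feather-style degradation: truncation to a random 150–350 bp window
  plus N-masking at ~1%.

Substitutions are uniform over bases (Jukes–Cantor-like); no selection,
no rate heterogeneity, no indels beyond end-truncation, no control-region
duplication. Divergence targets are enforced by rejection-resampling:
a genus is regenerated until the realized maximum intraspecific and
minimum (non-sister) interspecific distances fall within ±20% of the
targets. Two placement rules make truth labels robust to truncation,
which uniform site placement does not guarantee: interspecific
substitutions are *stratified* (one per equal-width stratum), so every
marker-length window retains close to the full-length divergence and a
congener cannot dip under the species threshold by sampling accident;
sister-pair diagnostic sites are spaced ≥ 150 bp apart (which caps a
350 bp pair at 3 diagnostic sites, i.e. realized sister divergence
≤ ~0.9% — the range observed in real sister pairs), and a sister species
mirrors its partner's haplotype structure, as recently diverged pairs
share intraspecific polymorphism. Under these rules every window with
≥ 100 comparable sites sees a sister pair below threshold and a
non-sister congener above it, so the generated answer keys are exact.

Passing the synthetic end-to-end tests therefore shows that the
classifier and decision tree recover a *clean* divergence structure
perfectly; it does not show robustness to the things real data add —
taxonomic errors in references, paralogous control-region copies,
heterogeneous substitution rates, indels, or chimeric reads.

## Determinism and provenance

All randomness flows from one integer seed through
`numpy.random.SeedSequence` (spawned per marker and stage). Every CLI
output directory contains `provenance.json` with the effective config,
the package version and SHA-256 checksums of the inputs (keyed by file
name, deliberately timestamp-free), so identical runs produce
byte-identical artifacts wherever they execute.

## Problem sizes used in the checks

The self-contained verification runs use worlds of 12–24 species
(24–48 sequences per marker), 20–40 degraded queries per scenario,
1000 randomized databases of ≤ 30 sequences for oracle equivalence, and
a 59-specimen case-study record set — sizes chosen so the full battery
runs in well under a minute while still exercising every code path,
including missing-overlap and near-threshold cases.

## Known limitations

- The center-star alignment is anchored to a single center; for
  sequence sets with long indels or extreme divergence a profile method
  (e.g. MAFFT) would place gaps better. Distances use pairwise deletion,
  which limits the damage of a misplaced gap to the affected pairs.
- Query insertions relative to the reference profile are silently
  dropped; a query with a genuine long insertion loses those bases from
  the comparison.
- The sister-set rank assumes neighbours within the species threshold
  spanning several genera are better treated at genus rank; such
  configurations indicate reference-database problems rather than
  biology.
- The listed-species side-table is static configuration; taxonomy moves,
  and the table should be regenerated when the authority lists change.
- The SNP rule needs at least one reference per species and a fixed
  difference in the alignment; reference sets violating that yield
  `indeterminate`, never a guess.
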