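# Methods

This note documents the models and procedures behind `ampliconid`, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic-data results do and do not show about real data.

## The identification problem

A DNA mixture contains genomic DNA from several species at known or unknown
mass ratios. Universal primer pairs amplify short mitochondrial 12S/16S
rRNA fragments from all of them at once; the fragment interior carries the
species signal. After sequencing the pooled amplicons, each read is
assigned to the (species, primer pair) reference region it matches best,
and the per-region read counts are the primary result: they reveal which
species are present, give a rough quantitative signal, and expose
marker-specific amplification failures. Because whole amplicons are
sequenced without fragmentation, one read corresponds to one amplified
molecule, and counts can be read as unbiased detection tallies.

## Reference panel (in-silico PCR)

Primer sites are found by scanning every window of the reference for the
primer (reverse primers are reverse-complemented first, so coordinates are
always top-strand, 0-based, half-open). Matching is IUPAC-aware: an
ambiguity code matches any compatible base at zero cost, the standard
degenerate-primer semantics. The amplicon is the pairing of the best
forward site with a downstream reverse site within `max_product`,
minimizing total primer mismatches, ties broken by shortest product; both
the stored strand and its reverse complement are scanned. Panel regions
EXCLUDE the primers, because reads are primer-trimmed before alignment and
only the interior is species-informative.

Parameters: `max_mismatch` (default 3) is the primer-site mismatch
tolerance. Universal primers are routinely used on taxa whose templates
carry several mismatches under the primer, so a tolerance of 0 would be
unrealistic; 3 accommodates cross-class amplification while keeping the
site search specific. The tolerance used by any given wet-lab panel is
assay-specific, so it is configurable, not asserted. 3'-end mismatches are
not specially weighted — there is no polymerase-extension model; this is a
documented simplification.

Discriminability is reported as a pairwise p-distance matrix per primer
pair (mismatches + gap columns + uncovered reference overhang over total
alignment columns, computed by glocal alignment and symmetrized by
averaging the two directions) instead of a phylogenetic tree: the minimum
inter-species distance is the quantity that actually bounds assignment
ambiguity.

## Synthetic references

The generator emulates the structure the pipeline depends on: each species'
reference carries exact binding sites for every primer pair, with
species-specific targets derived from a per-pair ancestral sequence by
substitutions at 15% per site plus up to a handful of deletions, so full
amplicon lengths spread over the per-pair product ranges (215–222, 112–121,
243–249 bp) as they do across real vertebrate mitogenomes. A deterministic
repair step enforces a minimum pairwise target edit distance of 8, making
species assignment well-posed for every seed (8 differences ≈ a 40-point
score margin, far above the MAPQ≥20 gate). Roughly half the references are
stored reverse-complemented to exercise strand handling.

What this does not emulate: real phylogenetic structure (closely related
species pairs can sit much nearer than 15% divergence — e.g. congeneric
taxa), primer-template mismatches in conserved flanks, intraspecific
variation, and NUMT paralogs. Passing tests on synthetic panels therefore
demonstrate the pipeline's correctness and its behaviour under the modeled
error process, not the field discriminability of any particular marker for
any particular species pair; that must be assessed on the real panel with
`discriminability_report`.

## Read simulation

A pool specification gives per-species stock masses; each PCR uses
`reaction_ng` (default 20 ng) of the pool, so species s contributes
`reaction_ng · mass_s / Σ mass` per reaction. Built-in pools mirror a
standard validation design: equimolar mammalian (a), equimolar avian (b),
all 13 species and a replicate (c1/c2), and mammalian pools with pig and
horse at 1/10 (d) and 1/50 (e).

Read origins are multinomial: P(pair) is uniform (amplicon pools are mixed
at equal volume) and P(species | pair) ∝ per-reaction mass × amplification
weight. Weights default to 1; a weight of 0 encodes amplification failure,
used to reproduce the empirical phenomenon where PCR competition in mixed
pools suppresses avian templates for one 16S pair while the other two
markers still recover all species. Weights can also be derived from the
panel as `decay^(primer mismatches)`.

The error model applies per-base substitutions (default rate 0.002), then
gives every maximal homopolymer run of length L ≥ 2 a ±1 length error with
probability `min(0.01·(L−1), 0.2)` — non-decreasing in L, direction
equiprobable. This is a calibration, not a physical flow-signal model: the
defaults were chosen so simulated per-base error rates land inside the
0.0003–0.018 band observed on real semiconductor amplicon data. Reads are
full-length amplicons (no fragmentation), strand uniform; PCR duplicate
structure, polyclonal wells, chimeras and barcode cross-talk are not
modeled. One RNG stream per library makes identical seeds produce
byte-identical FASTQ and truth tables. Default per-base quality is a
constant Phred 30 (a per-base sampler can be supplied); quality realism is
not needed downstream because filtering acts on length and mapping quality.

## Preprocessing

Demultiplexing assigns a read to the unique barcode within `max_mismatch`
(default 1) of its 5' prefix and clips it; ambiguous or unmatched reads go
to an unassigned bin. A well-formed barcode set has pairwise Hamming
distance > 2·max_mismatch, which makes ambiguity impossible; the check can
be relaxed for exploratory use.

Primer trimming tries every pair in both read orientations and clips a 5'
prefix and, independently, a 3' suffix within a Hamming tolerance of 2
(no indels in the primer match — simple and testable; an indel inside a
primer leaves it unclipped, and the glocal aligner's free reference ends
absorb the residue). Trimming is idempotent; untrimmed reads pass through
flagged rather than being discarded, and typically fail the downstream
filters if they are junk. The length filter keeps post-trim reads of
length ≥ 40 (inclusive); Q20 means Phred ≥ 20 (inclusive), and the Q20
percentage is reported to 2 decimals.

## Alignment and mapping quality

Each read is aligned end-to-end against any contiguous stretch of every
panel region on both strands (glocal = global in the read, local in the
reference), with affine gaps: match +1, mismatch −4, gap of length k costs
6 + k. These mirror widely used short-read defaults. The DP is exact (no
banding or seeding heuristics) and numba-compiled; traceback tie order is
diagonal > up > left with the leftmost maximal reference end, making every
alignment deterministic. An independent pure-Python full-matrix DP oracle
in the test suite verifies optimality on random instances.

MAPQ is a documented surrogate for mapper-specific estimators:
`min(60, 6·(best − second_best))`, 0 on exact ties, where second-best runs
over all other (region, strand) candidates. The downstream filter needs
only a monotone uniqueness score gated at ≥ 20; under this formula a read
within 3 score units of a second region (≲ 1 substitution of margin) is
discarded rather than guessed — species misassignment is the costly error,
so ties are never broken randomly. Reads whose best score is not positive
are reported unmapped. Filters retain read length ≥ 40 and MAPQ ≥ 20
(both inclusive); retained + rejected + unmapped always equals input.

Output is SAM 1.x (one @SQ per region, `species|pair` names, NM/AS/XS tags
plus XM/XI/XD for the separate error counts); BAM is left to external
tools.

## Quantification

Counts are one increment per retained read to its assigned region,
idxstats-style. Error rates per (species, pair) use
(mismatch + inserted + deleted bases) / aligned reference bases:
indels are included because homopolymer indels dominate this platform's
error profile (a substitutions-only mode exists for sensitivity analysis),
and the reference-base denominator keeps rates ≤ 1 under deletions.
Reads-per-ng normalization divides counts by the species' per-reaction
nanograms. Pearson correlations between libraries are computed on raw
counts (that is what replicate repeatability is usually quoted on), with
degenerate slices — constant vectors, all-zero taxon groups, fewer than 3
cells — flagged undefined rather than reported as spurious 1.0.

Detection calls a species present when at least `min_pairs` primer pairs
each contribute at least `min_reads` reads (defaults 2 reads, 1 pair,
prominent CLI flags). There is no field-validated universal read threshold
— it depends on run depth, barcode leakage and contamination control — so
the thresholds are deliberately exposed rather than fixed.

One published-style dilution count table is bundled (`datasets` module) as
a worked example; from it the per-pair totals, replicate correlation
(r = 0.989 over the 15 majority-species cells, 0.99 at 2 decimals) and
minor-species detection calls are recomputed, never hard-coded.

## Pipeline and reproducibility

`run_pipeline` chains panel → simulate → preprocess → align → quantify,
persists every intermediate, and writes a manifest echoing every threshold
and the seed, with per-stage read-conservation checks. Identical config and
seed give byte-identical outputs. Stage failure aborts with the stage name
and the conservation ledger so far; the CLI maps failure classes to
distinct exit codes (2 config, 3 input, 4 stage).

## Problem sizes

The test suite and acceptance script run the simulation studies at
20k reads for the equimolar 13-species pool and its replicate and 50k for
the 1:50 dilution pool — sizes at which the sampling error of every
checked quantity is far below its acceptance margin (e.g. the minor-species
expectation at 1:50 is ≈ 66 reads per pair, ~30σ above a 2-read
threshold) — and 600 reads (~95k aligned bases) for error-rate recovery.

## Known limitations

* The aligner is exact but O(read × reference) per candidate; it is meant
  for amplicon panels (tens of short regions), not genome-scale mapping.
* No thermodynamic PCR model: efficiencies are user-specified weights, and
  the mismatch-decay option is a convenience, not chemistry.
* The homopolymer error model is length-threshold calibrated, not
  flow-order aware; it reproduces rates, not signal artefacts.
* Circular mitogenomes must be supplied linearized such that amplicons do
  not span the junction.
* Quantitative interpretation of counts assumes comparable mtDNA content
  per ng of genomic DNA across species — a stated approximation of the
  underlying experimental design, not a property the software can enforce.
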