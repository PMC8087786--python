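# Methods

## The problem being modelled

A Cas9-edited plant line regenerated from tissue culture carries three
classes of variation relative to the reference assembly: (i) cultivar
variation — the cultivar used for transformation is not the cultivar that
was sequenced for the reference, and differs from it at a rate of roughly
1–2% of positions; (ii) somaclonal background — mutations induced by tissue
culture and *Agrobacterium* infection, private to each regenerant; and
(iii) Cas9 products — NHEJ scars at the intended target site and,
potentially, at near-match sites elsewhere in the genome. The audit's job
is to separate (iii) from (i) and (ii) using only multi-line variant calls
and the guide sequences.

## Search model

A candidate site for spacer *s* (length L, default 20) is any genomic
window, on either strand, whose L-mer protospacer has Hamming distance
≤ `max_mismatches` (default 5) to *s* and whose following 3 bases classify
as NGG, NAG or NGA. The PAM must match its class exactly; mismatches are
counted over the spacer only, and neither DNA nor RNA bulges are modelled.
Perfect matches are included in the enumeration (distance "up to k"
includes 0); report tallies exclude them by default so on-target events are
not double-counted as off-target candidates (`AuditParams.exclude_on_target`).

Genomic ambiguity code N never matches a spacer base and disqualifies a
PAM. This is deliberately conservative: assembly gaps and masked runs
cannot produce phantom sites. `SearchParams.ambiguous_matches_all` flips to
the permissive convention for parity experiments with enumeration tools
that treat N as a wildcard.

The scan itself is a vectorized sliding-window comparison (one pass per
strand per chromosome). Coordinates follow one convention everywhere: the
0-based half-open start of the spacer+PAM footprint on the forward strand,
with minus-strand protospacer and PAM reported as read on the minus strand.
Overlapping sites of the same guide are all reported; deduplication is only
on exact (guide, chrom, start, strand). Correctness is anchored by an
independent all-windows string-scan oracle: the test suite requires exact
site-set equality on >100 random (genome, spacer, k) instances plus
strand-symmetry, k-monotonicity and footprint re-extraction properties.

## Variant semantics

Variants are presence/absence records keyed on (chrom, pos, ref, alt);
genotype is ignored throughout, because the audit compares variant lists
between lines, not zygosity. Three decisions make the set algebra
well-defined:

- **Strict quality filter.** A call survives iff QUAL > 20 and INFO/DP > 4
  and MQ > 30, boundary values failing. All three thresholds are fields of
  `FilterThresholds`.
- **Left-normalization before any comparison.** Shared allele ends are
  trimmed (keeping an anchor base) and indels are left-aligned against the
  genome; otherwise the same deletion inside a repeat run would compare
  unequal between two callers' representations. The implementation is
  checked for exactness and idempotence against a brute-force oracle that
  compares whole local haplotype strings.
- **Private = edited \ union(WT).** A variant observed in even one WT line
  is attributed to shared background, not Cas9. This guarantees
  |private| ≤ |vs-core| for every line, matching the column ordering such
  summaries are reported in (vs-core = edited \ intersection(WT)).

Variant typing: SNP iff both alleles are single bases; insertion/deletion
iff the shorter allele is a prefix of the longer (length = the difference);
anything else is complex and excluded from the indel length histogram. The
12-entry substitution spectrum is reported in percent over SNPs only and
sums to 100 (all-zero for a SNP-free set, so small fixtures do not error).

Region annotation assigns each variant exactly one category with precedence
exonic(CDS) > UTR > intronic > upstream > downstream > intergenic and a
configurable flank window (default 1000 bp, strand-aware). The precedence
order and window are conventional annotator defaults; the underlying data
carry no such definition, so both are parameters rather than constants.

## Audit windows

Each candidate site is screened in two zones: the **core** (protospacer
plus PAM by default — `include_pam_in_core=False` restricts to the 20-mer)
and the **flank** (±100 bp around the footprint, inclusive at both
boundaries). A variant participates via its reference span, except
insertions, which count by their single anchor base — a 35-bp insertion
anchored inside the core is a core hit regardless of its allele length.
Each (site, variant) pair is reported once with the most specific zone.
Off-target matrix cells count distinct core-zone private variants per
(line, guide, PAM class) over that guide's site count; flank-zone hits are
retained in the per-hit table for inspection but do not enter the matrix.

On-target typing considers the 0-mismatch site of each guide, widened by
±3 bp because Cas9 cuts 3 bp 5' of the PAM and NHEJ scars spread from the
cut (`cut_site_slack`, configurable). A deletion spanning the sites of two
guides is reported once per adjacent guide pair — the signature of the
fragment dropped between two simultaneous cuts.

## Cultivar correction and new sites

The WT-shared (core) set is applied to the reference per chromosome in
ascending coordinate order, ties broken by alt allele; a variant whose
reference span overlaps an already-applied one is skipped and reported, a
deterministic and auditable resolution of conflicts that the input data do
not forbid. SNPs substitute in place; indels shift downstream coordinates.
The liftover map stores maximal mapped blocks; positions inside deleted
spans lift to "deleted", and the corrected length always equals the
original plus Σ(len(alt) − len(ref)) over applied variants — an invariant
the tests assert after every application.

A corrected-genome site is **new** iff no original site of the same guide
and strand lifts to an overlapping footprint interval. Overlap, not
sequence identity, is the site identity across genomes: indels move
coordinates, so any exact-position criterion would misclassify every site
downstream of an indel. Sites whose footprint is wholly deleted lift to
the gap between their surviving flanks so that boundary sites are still
comparable. Each new site is tagged by lifting it back: if the back-lifted
interval no longer has the footprint's length an indel rewrote the locus
(`sequence_shifted`); else if the original PAM fails its class the
variation created the PAM (`pam_created`); else if the original protospacer
exceeds the mismatch budget the variation repaired a mismatch
(`mismatch_reduced`).

## Synthetic cohorts

The generator emulates the statistical structure above, not sequencing
itself: no reads, no error model, no heterozygosity, no polyploidy. Its
defaults are the study conditions scaled to a desk-size genome:

| parameter | default | rationale |
|---|---|---|
| genome_length | 50 kb | large enough for multiple genes and well-separated sites |
| gc_content | 0.35 | typical for a plant nuclear genome |
| n_wt_lines / n_edited_lines | 3 / 7 | the audited cohort shape |
| shared_variant_rate | 0.016 /bp | ≈7.1 M cultivar variants over a 430-Mb genome |
| private_variant_rate | 0.0006 /bp | ≈230–330 k private variants per line at the same scale |
| shared_indel_fraction | 0.073 | indel share of the cultivar variant set |

Counts per chromosome are Poisson at rate × length; placement is
collision-free within a line (no overlapping reference spans), variants are
emitted pre-left-normalized, and all QUAL/DP/MQ values are drawn above the
filter thresholds unless `subthreshold_fraction` injects failing records to
exercise the filter. Identical (config, seed) produces byte-identical
fixture files; the VCF writer is a minimal deterministic VCFv4.2 emitter
for exactly this reason.

`make_planted_fixture` builds a complete audit scenario: two guides with
embedded exact on-target sites, one embedded near-match (3 substitutions,
NGG) for guide 1, a +1 and a −3 on-target edit, and a 35-bp off-target core
insertion — the event classes a real audit must distinguish. Background
variants are excluded from every candidate-site flank window, making the
truth table the complete answer key: any other nonzero matrix cell is a
false positive. One subtlety is enforced here: a planted insertion whose
random bases happen to repeat the upstream sequence can left-normalize out
of its zone, so placement re-checks the zone after normalization and
re-draws if needed.

Because backgrounds are windows-free by construction, a passing planted-
recovery suite demonstrates the pipeline's bookkeeping, not its behaviour
under coincidental background hits near sites — with real data, flank-zone
and even core-zone background coincidences are possible and land in the
hit table for manual review, exactly as they would in practice.

## Numerical and degenerate-input choices

- All window arithmetic is 1-based inclusive at both ends; site coordinates
  are 0-based half-open at the API boundary (BED convention).
- Empty variant set → identity correction, identity liftover, zero hits;
  SNP-free set → all-zero spectrum; spacer longer than a chromosome →
  empty site list, not an error.
- Multi-allelic VCF records are split; symbolic alleles are skipped and
  counted, never silently dropped.
- Overlapping shared variants during correction: leftmost-first, ties by
  alt, losers reported in the skip list.
- Problem sizes in the test and acceptance runs (genomes of 0.3–50 kb,
  20–100 replicates) were chosen so the full suite completes in seconds
  while every check retains its discriminating power; all scale linearly
  if larger runs are wanted.

## Known limitations

- Mismatch-only search: bulge-tolerant binding and activity scores
  (CFD/MIT) are out of scope, as is any chromatin-aware ranking.
- Presence/absence semantics cannot represent allele-specific editing or
  chimerism; DV/DP are carried through from the caller, never recomputed.
- The corrected genome is a haploid consensus; heterozygous cultivar
  variation collapses to whichever allele the shared call reports.
- Region annotation classifies by the variant's start position; a long
  deletion spanning a feature boundary is counted once, at its anchor.
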