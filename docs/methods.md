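# Methods

## Marker model

A diagnostic marker is an exact 80-bp substring of a target gene's
annotated genomic span. We use the genomic span (introns and UTRs
included, reverse-complemented for minus-strand genes) rather than the
transcript or CDS: it maximizes the candidate pool and matches the
genomic exact-match counting applied downstream. All matching is on
*canonical* k-mers — the lexicographic minimum of a k-mer and its
reverse complement — so neither read strand nor gene strand affects a
count. "Single-copy" means the canonical form occurs exactly once across
the whole source assembly, both strands counted: a window duplicated
anywhere, including on the opposite strand or in a tandem paralog, is
not diagnostic and is discarded at extraction. Windows containing
ambiguity codes (N) are skipped with a logged tally.

## Typability filter

Candidates are counted by exact canonical match in the short-read
polishing library of each pangenome reference. A marker is typable when
its count in the source's own library lies in [min_count, max_count]
(defaults 1 and 100) and is zero in every other reference's library.
Counts are per occurrence: a marker appearing twice in one read counts
two. "Observed count" could also be read per-read; we chose
per-occurrence as the more natural reading of an exact-match count —
the two differ only for repeat-like markers, which the upper bound
removes anyway. Absence is checked in the other references' *read
libraries*, not their assemblies, so an unassembled but present repeat
still disqualifies a marker. Reads shorter than k contribute nothing
and are tallied.

The filter is monotone in the data: adding reads to an "other" library
can only shrink the panel; adding reads to the source library can move
markers in (count 0 → ≥1) or out (count > max_count).

## Presence calls

For each library, a gene is present when strictly more than
`presence_threshold` (default 0.95) of its typable markers are observed
at least once. The strict inequality fixes the boundary: with 100
typable markers, 96 observed is present and 95 is absent. Marker
multiplicity beyond one is deliberately ignored for the call — the call
is about marker *recovery*, not depth — and no minimum per-marker count
beyond ≥1 is imposed. A gene with an empty panel is *untypable* (NA):
distinguishing "the gene is absent" from "we cannot type it" matters
when paralog sharing empties a panel. The joint haplotype call is the
AND over target genes and is NA if any gene is untypable.

## Entropy profiling

Per-column Shannon entropy H = −Σ p log₂ p is computed in bits over
residue frequencies within each clade's subalignment. Gaps are excluded
from the frequencies rather than treated as a 21st symbol: entropy here
quantifies residue variability, and a column that is all-gap within a
clade is NA, never 0 (0 must mean "invariant residue"). Columns strictly
above 1.5 bits are counted as highly variable; the strict inequality
also applies at the threshold exactly. Pairwise identity between two
aligned sequences is matches / columns-where-at-least-one-has-a-residue,
×100, reported to one decimal; columns gapped in both sequences are
ignored, one-sided gaps count as compared-and-mismatched. Clades need
at least two members; smaller ones are skipped with a warning.

## Synthetic pangenome generator

The generator emulates the data regime the method assumes:

- A family of `n_cluster_genes` paralogs derived from one random
  ancestor, each lineage mutated at `paralog_divergence / 2` so a random
  pair differs at ~`paralog_divergence` (default 4%, a near-identical
  tandem array). Sharing a recent ancestor means a few percent of 80-bp
  windows are identical between paralogs, which deliberately stresses
  the single-copy and typability filters.
- One source assembly carrying every paralog once, in a tandem array of
  random gene strands separated by 100–300-bp random spacers inside a
  random background. The first `n_target_genes` (default 2) paralogs are
  the *target genes* and are private to the source among reference
  assemblies. This is a structural requirement of the method, not a free
  choice: a target gene present in any other reference's polishing
  library would lose its entire panel to the typability filter. The
  scenario mirrors the motivating study, where the causal haplotype was
  unique to one reference among ~30 while segregating in the
  resequencing cohort.
- Other references carry non-target paralogs per independent Bernoulli
  draws at `pav_probability`, then adjusted into `copy_number_range`
  (default 2–8) by adding tandem duplicate copies or dropping copies.
- A resequencing cohort (`simulate_cohort`) of individual genomes, each
  a fresh background carrying each target gene's exact source allele
  with probability `pav_probability`; carrier status is the recorded
  truth the genotype calls are scored against.
- Reads: uniform start positions over both strands, Poisson read count
  with expectation coverage × genome length / read length, i.i.d.
  substitution errors at `error_rate`, constant placeholder qualities
  ("I"). No indels, no quality model, no diploidy — the pipeline uses
  exact 80-mer matching, so substitution-only errors are the only error
  mode that matters to it.

Randomness: a single config seed feeds `numpy.random.SeedSequence`;
child streams are spawned in a fixed order (gene family, then one per
assembly; polishing libraries and the cohort use seed families
`(seed, 1)` and `(seed, 2)`), making every output byte-reproducible.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| k | 80 bp | marker length the method is defined for |
| min_count / max_count | 1 / 100 | typability bounds on source polishing counts |
| presence_threshold | 0.95 (strict >) | fraction of typable markers required for a presence call |
| n_assemblies | 30 | pangenome size the method targets |
| copy_number_range | (2, 8) | cluster CNV span across assemblies |
| paralog_divergence | 0.04 | near-identical tandem paralogs |
| coverage | 15× | resequencing-cohort depth |
| error_rate | 0.005 | Illumina-like substitution rate |
| read_length | 150 bp | standard paired-end Illumina read length; also required for internal consistency (below) |
| background_length / gene_length | 8 kb / 1.5 kb | desk-scale stand-ins for chromosomes and genes; large enough that panels exceed 500 markers per gene |
| polishing coverage | 10× | enough that <5% of true single-copy markers are missed by the min-count bound |

Read length interacts with the presence threshold: a marker is observed
only by reads spanning all 80 bp without error, so the expected clean
spanning-read count is coverage × (L−79)/L × (1−e)⁸⁰. At 15× and
e = 0.005 this is ≈ 4.8 for L = 150 (marker miss rate ≈ 0.9%, recovery
≈ 99% > 95%) but only ≈ 2.1 for L = 100 (recovery ≈ 88% < 95%, i.e.
carriers would be called absent). The 150-bp default keeps the stated
coverage/error/threshold regime self-consistent.

## What the simulation does and does not show

Passing tests demonstrate the pipeline's logic — extraction, filtering,
strand handling, thresholds, truth recovery — under uniform coverage,
substitution-only errors, exact shared alleles, and random (repeat-free)
backgrounds. Real data add GC-dependent coverage bias, indels and
quality-dependent errors (each of which only removes marker
observations, pushing borderline carriers toward absence calls),
genome-wide repeat families that shrink the single-copy pool, and
allelic variation between the source haplotype and cohort carriers,
which exact matching does not tolerate. Concordance numbers measured
here are therefore an upper bound on real-data performance; the
structure (which markers survive, how calls respond to the threshold)
transfers.

## Numerical and degenerate-input choices

- Boundaries are strict exactly where the call semantics say "more
  than": presence threshold, high-entropy threshold, and the typability
  bounds are closed ([1, 100] retained).
- Counting is pure accumulation, so results are independent of read
  order and library iteration order; entropy values are reproducible up
  to float summation order (~1 ulp) under row permutation.
- Empty FASTQ → all counts zero → fraction 0 → absent. Empty source
  count table → empty panel with a warning. All-gap column → NaN.
  Invariant columns return exactly 0.0 (a −0.0 is normalized).
- Sequences shorter than k enumerate to an empty list (not an error);
  configs with gene_length < 80 are rejected outright.

## Scaled problem sizes

Tests and the acceptance script run the full method at reduced genome
scale (kilobase backgrounds, 1.5-kb genes, ≤30 assemblies, ≤20-library
cohorts, 5 seeds), chosen so panels stay in the hundreds-to-thousands of
markers — the regime where the 95% threshold is statistically meaningful
— while a complete run finishes in seconds. Oracle-equivalence checks
compare every stage against naive brute-force reimplementations on ≥20
random instances; parameter-recovery checks score calls against
simulated truth (≥99% of gene × library cells over 5 seeds; the
error-free control is exact).

## Known limitations

Exact matching cannot genotype carriers whose allele diverges from the
source haplotype (any SNP erases 80 overlapping markers); the method is
a haplotype-identity test, not a homology test. Copy number is not
estimated from depth — presence is binary. The generator's uniform-
coverage, substitution-only read model understates real-data failure
modes (see above). The entropy module consumes alignments and clade
labels as given; it neither aligns nor builds trees.
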