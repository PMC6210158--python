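# Methods

## Problem and model

Personal de novo assemblies of human genomes routinely contain several
megabases of sequence that cannot be matched to the reference genome.  These
*novel sequences* (NS) are typically repeat-rich (dominated by satellites and
simple repeats), slightly GC-elevated, and concentrated near centromeres and
telomeres.  When short-read cohort data are re-aligned against a reference
extended with NS, reads that previously mis-aligned onto the chromosomes move
to the NS: some SNV calls disappear (*Lost* — likely false positives against
the base reference) and others become callable (*Gained*).

`refgap` implements that whole procedure as a reusable, testable pipeline:

1. **Discovery.**  Assembly contigs (primary contigs ≥ 20 kb) are aligned to
   the reference with strict nucmer-style parameters (`-l 150 -c 400`) and
   best-hit filtered.  Contigs and internal contig segments left unaligned
   become candidates; candidates are re-aligned with relaxed parameters
   (`-l 100 -c 200`), and any candidate sub-interval that aligns at identity
   ≥ 0.80 is removed.  Survivors of at least 100 bp are the NS.  Duplicates
   are removed by a containment rule (below).
2. **Characterization.**  Sharing of NS across other assemblies (three-way /
   pair / unique), BLAST top-hit species assignment (E ≤ 1e-50, highest
   bitscore), and repeat/GC summaries from RepeatMasker-style tables.
3. **Anchoring.**  NS are placed on hybrid scaffolds (relaxed parameters),
   and each placement's two scaffold flanks (up to 50 kb) are aligned to the
   reference with strict parameters; a chromosome locus is assigned only when
   both flanks agree (same chromosome and strand, gap < 100 kb).  Placements
   on decoy sequences are recorded and excluded.  One remaining locus →
   `unique`; two or more → `multiple`; none → `unanchored`/`decoy_excluded`.
4. **Extension.**  Surviving NS are appended to the reference as separate
   sequences, with priority-ordered cross-individual dedup (the first NS
   set's copy wins on a duplicate).  The original reference bytes are never
   edited.
5. **Reconciliation.**  Per sample, SNV keys `(contig, pos, ref, alt)` from
   the paired call sets are classified Lost / Both / Gained (Gained split
   into chromosome vs NS contigs).  A variant is *consistently* lost
   (gained) when it is lost (gained) in at least `ceil(min_frac · n)` samples
   (default `min_frac` = 0.05), appears in **no** sample's opposing or Both
   set, and lies outside the centromere mask.

## The built-in aligner

The seed-and-chain aligner exists so that every stage is testable without an
external aligner; externally produced PAF or show-coords-style TSV is the
first-class input path for real data.  Exact matches of length ≥
`min_match_len` are found on both strands via a k-mer index (adjacent hits on
a diagonal merged into maximal matches), then chained when colinear with
query/target gaps ≤ `max_seed_gap` (default 500 bp).  Chains whose summed
exact-match length is below `min_cluster_len` are discarded — the analog of
nucmer's `-c`.

Numerical choices:

* **Identity** = matches / alignment columns.  Junction gaps contribute
  `max(query_gap, target_gap)` columns; equal-length gaps (the substitution
  case) are compared base-by-base so matching bases inside unseeded
  stretches still count, as a DP-extending aligner would score them.
  Without this, clustered substitutions (inter-substitution spacing below
  the seed length) would deflate identity several-fold relative to true
  divergence.
* **N bases** never seed and always fall into gap columns.
* After a chain is extracted, remaining seeds overlapping its query span on
  the same target and strand are dropped; cross-target alternatives are
  arbitrated by the best-hit filter.  Self-similar inputs are capped at
  4000 seeds / 64 chains per (target, strand) group.
* Deterministic: output sorted by (query, interval, target, interval,
  strand); invariant under query input order.

**Best-hit filter.**  Per query, a maximum-weight (weight = matches) set of
query-intervals with pairwise overlap ≤ 10 bp, via weighted interval
scheduling; ties break toward higher identity, then lower target id, then
lower target start.  The 10 bp tolerance reflects that query-side repeat
filtering in practice permits slight overlap; the exact value is a project
choice, exposed as a parameter.  Anchoring uses an opt-in `keep_ties` mode
that also retains co-optimal records (equal matches and span) displaced only
by query overlap: a sequence present verbatim at two genomic loci has two
equally good placements, and a strict best-hit choice would make the
`multiple` anchor class unreachable.

**Deduplication predicate** (shared between discovery dedup and reference
extension): a sequence is a duplicate when ≥ 80 % of its length aligns to an
already-kept NS at identity ≥ 0.90, visiting NS by descending length
(keep-longest).  The thresholds are consistent with the 0.80 novelty ceiling
while conservative enough not to merge distinct satellite families.
Byte-identical and exact-substring duplicates (including rotated tandem
phases, checked against a doubled copy of the kept sequence) short-circuit
without alignment.  Sequences shorter than the relaxed `min_cluster_len`
(200 bp) can never be flagged as duplicates by the alignment path.

## The synthetic-data generator

The generator emulates the statistical structure of real NS rather than any
particular genome:

* **Reference**: i.i.d. sequence at 41 % GC (the human genome-wide level),
  two 200 kb chromosomes by default, one 30 kb decoy, and a centered
  centromere mask covering 10 % of each chromosome.
* **Implants**: tandem arrays of a random unit (20–200 bp) at 43 % GC —
  satellite-like, hence "repetitive" by construction — totaling 0.5–10 kb
  each, eight per donor.  Building implants from random non-reference
  sequence guarantees < 80 % identity to the reference by construction, so
  discovery's ground truth is unambiguous (verified independently with an
  edlib infix-alignment oracle in the tests).  One implant is always placed
  at two loci on different chromosomes (the `multiple` anchor case), one
  inside the centromere mask, and one inside the decoy-derived sequence (the
  `decoy_excluded` case).
* **Divergence** is substitution-only at 0.001/bp, so alignment-identity
  accounting is exact; indel handling is an aligner concern tested
  separately.
* **Contigs**: the donor genome is fragmented at 2×10⁻⁵ breaks/bp with all
  contigs ≥ 20 kb; breaks never fall inside an implant, so each truth locus
  lies on one contig.
* **Cohort**: 40 samples, 500 designed variant fates (150 lost, 200 gained
  — split between chromosomes and NS contigs — 150 both) at carrier
  frequencies drawn from 0.02–1.0, realized as independent Bernoulli draws
  per sample.  Twenty private noise variants per sample appear in both call
  sets.  The first lost variant is placed inside the centromere mask, and
  one lost variant (frequency 1.0) is additionally written to a single
  sample's extended-reference VCF, so the "never seen as Gained or Both"
  exclusion always has a positive test case.  Fates partition the designed
  variants; no variant key carries two fates.

What the generator does **not** model — and what passing tests therefore do
not show about real data: read-level artefacts (mis-mapping, coverage,
genotype quality), indels and larger SVs, diploidy and phasing, GC- or
repeat-dependent error processes, and real satellite sequence families.
Variant fates are imposed directly at the VCF level because the
reconciliation procedure consumes VCFs; the claim under test is the set
algebra and filtering, not the variant caller.

## Problem sizes

The shipped configurations are desk-scale by design: 2 × 200 kb chromosomes
per genome, ~45 kb of implanted NS per donor, 40-sample cohorts, anchoring
checked across 20 simulation replicates (10 in the acceptance script).  These
sizes keep each full run in tens of seconds while still exercising every
code path (multi-locus repeats, centromere masking, decoy exclusion,
cross-donor dedup).

## Degenerate inputs and edge behavior

* Empty query/target sets align to an empty record list; a contig with no
  alignments yields one whole-contig candidate.
* A candidate that never aligns in round 2 has `best_ref_identity` 0.0 and
  `round_detected` 1; one touched by any round-2 alignment records round 2
  and the maximum identity over touching alignments (the conservative choice
  against calling novelty).
* Identity exactly 0.80 is *not* novel (strict `< 0.80`); length exactly
  100 bp *is* kept; a 20 kb contig passes the pre-filter (boundaries
  verified against the thresholds' printed precision).
* Cohort thresholds use `ceil(min_frac · n)`; `min_frac` outside (0, 1] is a
  configuration error; zero total NS length makes the density statistic an
  error rather than 0/0.
* VCF positions are 1-based; BED/FASTA/PAF intervals 0-based half-open; a
  VCF position `p` lies in BED `[s, e)` iff `s ≤ p−1 < e`.

## Known limitations

* Contig tips whose first ~100–200 bp contain two or more substitutions can
  fail to seed in either round and be reported as short false-positive NS;
  at the default divergence this affects well under 1 % of called bases
  (the measured base-level precision is ≥ 0.99 at default conditions).
* The aligner has no affine-gap DP extension; alignments stop at the last
  exact seed, so interval boundaries are accurate only to within a seed
  length.
* Anchoring projects an NS to the reference gap between its flank
  alignments; when a flank contains other implants the projected interval
  can be off by their size, though chromosome and status assignment are
  unaffected.
* `best_ref_identity` is the per-touching-alignment maximum, not a
  cumulative coverage-weighted identity; a candidate tiled by many disjoint
  0.79-identity alignments is still called novel.
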