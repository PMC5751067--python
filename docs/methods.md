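# Methods

`asmcurate` implements the post-assembly curation computations used to turn
a raw long-read contig assembly of a highly heterozygous diploid genome
(the motivating case is an insect genome) into a curated haploid
reference, plus the bookkeeping statistics such projects report. This note
describes each model/procedure, its assumptions, the parameters that
matter, and the numerical choices made where the design was open.

## Genome-size estimation from the k-mer spectrum

The estimator is the classic spectrum formula

    G = (K_total − K_error) / D

where `K_total = Σ_m m·c_m` over the multiplicity histogram `c_m` of
distinct k-mers in a read set, `K_error` is the same sum restricted to
multiplicities at or below `error_multiplicity_max` (default 1 — k-mers
seen once are attributed to sequencing error), and `D` is the multiplicity
of the spectrum's main peak. Assumptions: reads sample the genome roughly
uniformly, k (default 17) is large enough that most genomic k-mers are
unique, and the error and coverage modes of the spectrum are separated by
a valley.

Counting is canonical (each k-mer pooled with its reverse complement
under the lexicographically smaller representative) because depth peaks
are defined on strand-collapsed spectra; windows containing N are
skipped. The implementation packs bases 2 bits each into `uint64` codes
and counts with a sort — exact, deterministic, and sized for the
~10^7–10^8 k-mers of the synthetic studies here, not for disk-backed
10^9-scale counting.

Peak detection: the error valley is the first local minimum of the dense
spectrum at multiplicity ≥ 2; `D` is the argmax strictly beyond it, ties
toward smaller multiplicity. A monotonically decreasing spectrum has no
coverage peak and is an error, not a guess. `D` is an integer; on
synthetic reads the true per-base depth times the (L−k+1)/L window factor
is generally not an integer, so recovered genome sizes carry a ~2–3%
discretisation bias — within the 5% band the recovery test asserts.
`G` is rounded half-up to integer bp; Mb figures are reported to 0
decimals, matching how such estimates are printed.

## Short-read cleaning

Five rules, in order per read: (i) discard reads containing an adapter as
an exact substring (the rule is a filter, not cutadapt-style trimming);
(ii) trim a fixed 2 bp from the 5′ end and 3 bp from the 3′ end (the rule
is stated as counts, not quality conditions; counts are configurable);
(iii) discard if N bases exceed 10% of the post-trim read (strict
inequality); (iv) discard PCR duplicates — a pair is a duplicate iff its
(r1, r2) sequence tuple is byte-identical to an earlier pair's (qualities
and ids ignored, since PCR duplicates share sequence, not quality
strings); (v) discard if more than 50% of post-trim bases have
Phred ≤ 5. Counts are conserved: input pairs = kept + Σ discards, checked
on every run.

## Whole-assembly self-alignment

The built-in matcher finds exact shared segments between all contig
pairs so the purge stage is testable without external aligners, emitting
the same `AlignmentBlock` atoms that PAF / show-coords / BLAST tables
parse into (external tables can be substituted or pooled transparently).

Mechanics: every canonical `anchor_k`-mer (default 21, odd so no anchor
is its own reverse complement) occurring at most `max_anchor_occurrence`
times (default 10, a repeat guard) is indexed; shared anchors between a
contig pair are grouped by relative strand and diagonal; maximal runs of
co-diagonal anchors whose starts are ≤ k apart become blocks. Because
consecutive anchors in a run overlap or abut, the whole span matches
base-for-base: `matched_bases` equals the span and block identity is
exactly 1.0. There is deliberately no mismatch extension: heterozygous
divergence appears as breaks *between* blocks, which is precisely what
the chaining stage bridges. Consequently per-block identity carries no
information about divergence; divergence shows up as the density of
breaks instead.

## Haplotig purging

The core procedure, per contig pair:

1. **Chaining (LIS).** Blocks from all sources are pooled, split by
   strand, and chained by a dynamic program that selects the
   maximum-weight subset strictly increasing in both query and target
   coordinates (weight = matched bases). Ties break toward the chain
   whose first block has the smaller q_start, then toward the chain with
   the smaller total gap (tighter diagonal) — making the output
   order-independent and deterministic. Leftover blocks are re-chained
   until none remain or the best chain weighs less than 100 bp.
2. **Merging.** Consecutive chained blocks whose gaps on *both*
   sequences are ≤ `max_chain_gap` (default 500 bp) fuse into one block;
   gap bases are not counted as matched. Where blocks overlap on the
   query, only the higher-score block contributes (repeat alignments
   filtered by score).
3. **Coverage and identity.** Pair coverage is the union of merged block
   spans projected on the shorter contig, divided by its length. Pair
   identity is the matched-bases-weighted mean of *chain* identities,
   where a chain's identity is Σ matched / Σ per-block span computed
   before merging. Carrying identity through merging unchanged is a
   deliberate choice: merging widens spans across unaligned gaps and adds
   no evidence about base-level agreement, so recomputing identity over
   merged spans would conflate coverage holes with divergence.
4. **Removal.** Pairs are processed in decreasing order of long-contig
   length; the short contig is removed iff coverage ≥ 0.80 and the long
   contig has not itself been removed earlier in the pass. The no-cascade
   rule prevents chain reactions that could delete both haplotypes of a
   region, and the fixed order makes results independent of input order.
5. **Review.** Removals with identity < 0.90 are auto-restored — the
   mechanised form of a manual dot-plot review, with the floor set just
   below the 0.94 of the worked demonstration pair. Every removal also
   exports a TSV of block endpoints for an actual dot plot, and an
   operator restore list re-adds contigs by id (the recorded decision is
   left unchanged so that the restored flag keeps meaning "identity rule
   fired").

**Composition note.** The pipeline entry point (`purge_pipeline`) runs
the internal matcher in sensitive mode (blocks down to a single anchor)
and lets the 100-bp weight floor act at the *chain* level, while the
standalone matcher defaults to a 100-bp block floor. At 1% heterozygosity
the exact-match segments between variants average ~90 bp, so a strict
100-bp block floor discards a third of the evidence and opens coverage
holes wider than the 500-bp merge gap; feeding all anchor runs to the
chainer and enforcing the floor on chains mirrors pooling a strict
aligner with a sensitive one and clustering their union — the reason two
aligners are used in this kind of curation in the first place.

## Mitochondrial and contamination filters

A contig is flagged mitochondrial when hits against mitochondrial
references with E-value < 1e−5 cover ≥ 80% of its length (hits must carry
E-values, i.e. come from a BLAST-style table). The contamination rule is
blobplot-style: discard iff read coverage < 10, or the best database hit
is outside the target clade (default Arthropoda) *and* the contig has
neither transcript evidence nor a single-copy-ortholog gene. Contigs with
no best hit are treated as in-clade. Taxonomy is a single best-hit label
per contig — a deliberate simplification of multi-hit taxonomy rules,
which operate on hit tables this pipeline treats as upstream inputs.

## Microsatellites and marker selection

Detection is MISA-style: maximal perfect runs of 1–7 bp units with minimum
unit counts 10 (mono), 6 (di), 5 (tri- through hepta-); loci span whole
units only; runs whose unit is itself periodic are reported at the
smallest period; N terminates runs. Adjacent SSRs separated by at most
100 bp (MISA's default interruption) fuse transitively into compound
loci. Marker candidates are scored on four criteria: perfect di/tri/tetra
repeats at ≥ 6/5/5 units; no *other* SSR within the ±2 kb windows
adjoining the locus (read literally the window would contain the locus
itself, which is self-contradictory); location outside the repeat mask;
and 200-bp flanks each occurring exactly once in the assembly as an exact
match counting both strands (an exact search keeps the criterion
deterministic and oracle-checkable; mismatch-tolerant mapping is out of
scope). Flanks truncated by contig ends fail. Motifs are canonicalised
over rotations and reverse complements for frequency tables, while the
raw motif is retained so that unit-vs-type distinctions remain visible.

## Assembly statistics and report arithmetic

N50 (N90) length is the length of the contig at which the cumulative
sum over descending lengths first reaches 50% (90%) of the total; the
"count" is that contig's 1-based rank. GC excludes N. Repeat occupancy is
the per-class interval union against assembly length; classes are trusted
as disjoint (masker precedence applied upstream) and inter-class overlap
warns rather than errors. Published masker reports sometimes print a
deduplicated total smaller than the sum of their class rows; an explicit
total can be supplied for that case. Percentages round half-up: 2
decimals for table figures, 1 for size concordance, 0 for Mb. The
consensus QV is floor(−10·log10(homozygous-variant rate)), floored
because QV is an integer class, capped at 60 (zero variants returns the
cap, flagged).

## Synthetic data

The generator emulates the diploid-assembly failure mode with known
truth. Disjoint windows of one ancestral sequence (GC 0.35, a typical
insect composition) become:

- **Haplotig pairs** (default 20): a long haplotype-A contig and a
  shorter haplotype-B contig whose drawn fraction (uniform 0.85–0.95) of
  its length lies inside the long one's window, the remainder extending
  past it. Haplotype B carries substitutions at the heterozygosity rate
  (default 0.01) and 1–10 bp indels at one tenth that rate — a typical
  substitution:indel ratio for insect heterozygosity, and the indels
  exercise diagonal-breaking in the matcher.
- **Unique contigs** (default 20) from homozygous regions; contig
  lengths uniform 10–30 kb throughout, giving ~1.3 Mb assemblies that
  keep a 20-seed recovery study in minutes on one CPU.
- **Contaminants** (default 3): random sequence with GC shifted +0.25
  and coverage label 5 (below the blobplot floor), best hit "Bacteria",
  no rescue evidence.
- **Mitochondrion**: a 16-kb circular reference emitted as a rotated
  contig, with the corresponding two-segment exact hit table (labelled
  synthetic) so the mitochondrial rule is testable without a search tool.
- **Planted SSRs** at recorded coordinates, with boundary bases forced
  to break the repeat so detection must recover the exact span.
- **Reads**: uniform shotgun, random strand, substitution errors at a
  flat rate (Q40 correct / Q10 error), host depth 60 (the approximate
  short-read depth of the motivating project: ~47 Gb over a ~785 Mb
  genome).

Coverage labels are written directly into the per-contig annotations
rather than recomputed by read mapping, keeping the contamination stage
testable without an aligner. What the generator does *not* emulate:
repeat landscapes (so the repeat-occurrence guard is barely exercised),
GC-coverage covariance, structural variation beyond small indels, PacBio
error profiles, and coverage dips in real haplotigs. Passing recovery
tests therefore demonstrate correctness of the procedure's logic under
clean duplication structure, not robustness to repeat-rich real
assemblies.

## Problem sizes used in tests and the acceptance script

Chain/LIS correctness is checked against exhaustive subset enumeration on
1,000 random instances of ≤ 12 blocks; SSR detection against a lookahead
regex oracle on 1,000 repeat-enriched 2-kb sequences; N50/N90 invariants
on 1,000 random length multisets; purge precision/recall as the mean over
20 simulated genomes at the defaults above; k-mer recovery on a 1-Mb
random genome at depth 40 (error-free within 5%, 1% error within 10%).
These sizes keep the whole suite within a few minutes on one CPU while
leaving each statistical check comfortably powered.

## Known limitations

- The exact-anchor matcher reports identity 1.0 on its own blocks; pair
  identity from internal alignments is therefore an upper bound, and the
  identity-based restore rule only discriminates when external alignment
  tables (which carry real percent identity) are supplied.
- Flank-uniqueness for markers is exact-match only; a flank with one
  mismatched copy elsewhere still counts as unique.
- The duplicate-read filter is exact-sequence; sequencing errors make
  true PCR duplicates escape it, as with any sequence-keyed definition.
- `find_peak_depth` assumes a unimodal coverage mode beyond the valley;
  strongly bimodal heterozygous spectra may need the operator depth
  override exposed on the CLI.
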