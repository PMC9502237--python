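# Methods

## Coordinate model

A variant-aware ("source") reference S is the standard ("target")
reference T with the ALT alleles of a VCF applied. Because every variant
is a local substitution, insertion or deletion, S and T admit a canonical
gapless pairwise alignment; liftkit represents it per contig as two bit
vectors over *alignment columns*. Column c has `src_bv[c]=1` iff it
contributes a source base and `tgt_bv[c]=1` iff it contributes a target
base; no column is empty. SNVs and MNPs do not move coordinates and leave
both bits set. Rank/select queries over these vectors answer all
coordinate questions:

* `lift(s) = rank1(tgt_bv, select1(src_bv, s+1))` — the target position
  aligned to source position s.
* `target_length = popcount(tgt_bv)`, `source_length = popcount(src_bv)`.
* Column conservation: `n_columns = target_length + inserted bases
  = source_length + deleted bases`.

The bitvector is implemented as little-endian 64-bit words with a
per-word cumulative popcount directory: rank is O(1); select binary-
searches the directory and scans one word. Conventions are rank1
exclusive-prefix (`[0, i)`) and select1 1-based, giving the inverse laws
`rank1(select1(k)) = k−1` and `bits[select1(k)] = 1`.

## Position of bases inside insertions

A source base inserted relative to the target has no aligned target
base. liftkit maps it to the **next** target base — `rank1(tgt_bv, c)`
for its column c — clamped to `target_length − 1` for an insertion at the
contig end. This choice yields a valid, sortable POS for reads starting
inside insertions and makes the half-open end lift
(`lift_end(e) = rank1(tgt_bv, select1(src_bv, e) + 1)`) consistent with
the lifted reference span, which is what keeps TLEN symmetric for pairs
whose fragment ends inside an insertion. The alternative (previous target
base) was rejected because it can produce a POS before the anchor base of
the insertion.

## VCF ingestion

Only CHROM/POS/REF/ALT are read; genotype columns are ignored (the
source reference is built from the site list, not per-sample
haplotypes). Alleles are normalized by stripping shared prefix and
suffix, so anchored VCF indels emit an ordinary aligned column for the
anchor and one-sided columns only for the surplus bases; an
equal-length remainder is a substitution (no columns change); an
unequal remainder emits the deleted target bases first, then the
inserted source bases. Multi-allelic records apply the first ALT with a
warning (the intended use case carries one chosen allele per site).
Overlapping records keep the first by position and skip later ones with
a warning rather than aborting a stream; symbolic ALTs (`<DEL>`,
breakends) and non-ACGTN alleles are skipped likewise — structural
variation is out of scope. A VCF unsorted within or across contigs is an
error. Contig lengths come from an explicit mapping, a FASTA `.fai`, or
`##contig` headers, in that priority; contigs with no variants get
identity maps.

## CIGAR composition

Lifting walks the read→source CIGAR once, classifying each covered
source base by its column:

* both-sided column: the op (M/=/X/D/N) survives;
* source-only column: M/=/X become I (the read base is an insertion in
  target coordinates, losing any =/X distinction by construction); D and
  N spans shrink;
* target-only columns between consecutive source bases: joined to an
  adjacent D or N run if one borders them (a splice gap absorbs deleted
  bases inside it; D and N are never merged with each other), otherwise
  emitted as a new D.

Adjacent identical ops merge and zero-length ops drop. Query-only ops
(I/S/H/P) pass through in place. The output position is the lift of the
first source base on a both-sided column; a read covering *no* such
column (entirely inside an insertion) has no target interval and is
flagged unmapped, keeping the lifted anchor position so pairing and sort
order survive — silently dropping records would break mates. Terminal I
runs created by the conversion are kept by default;
`--clip-leading-ins` converts them to soft clips for downstream tools
that reject I-first CIGARs. A fast path handles the common case of a
read whose columns are contiguous and all both-sided (no indel within
the span): the CIGAR is returned unchanged.

## Record fields

MAPQ, FLAG, QNAME, SEQ and QUAL are contractually untouched. Mate
position is lifted statelessly through the index (no pairing of records
in memory, so streaming needs bounded memory); TLEN is recomputed from
lifted coordinates under the outermost-coordinate convention whenever
both mates are mapped to the same indexed contig — for the leftmost mate
via the lifted source fragment end, for the rightmost from its own lifted
end and lifted PNEXT — and copied through otherwise. Records on contigs
absent from the index pass through unchanged and are counted. Unmapped
records pass through untouched.

## MD/NM

With a target FASTA available, MD and NM are rebuilt in target
coordinates: NM = mismatched aligned bases + inserted + deleted bases;
MD alternates match-run counts, mismatched reference bases and
^-prefixed deleted runs, always starting and ending with a (possibly
zero) count. N ops contribute to neither tag. Existing MD/NM values are
replaced; all other tags are preserved verbatim. No realignment or score
recomputation is attempted.

## Streaming and determinism

Records are processed in fixed batches of 8192. With T threads, up to
2·T batches are in flight, but completed batches are written strictly in
input order, so output is byte-identical for every T; determinism is a
stated contract, not an accident of scheduling. Per-record errors never
abort the stream — they downgrade to pass-through plus a counter, and a
summary (records in / lifted / passed through / unmapped-by-lift /
warnings) goes to stderr.

## Serialization and chain export

The `.lft` container is: magic `LFTKIDX\0`, u32 format version, u32
contig count, then per contig a length-prefixed name, u64 column count
and the two bit-packed vectors as little-endian 64-bit words, followed by
the source→target name map. Loads verify magic and version and fail
loudly on truncation. Chain export run-length-scans the columns into
`size dt dq` triples (dt = source-only, dq = target-only columns between
aligned blocks; score emitted as the source size, no alignment scoring);
leading/trailing gaps are carried by zero-size blocks so block sums always
match the declared sizes. Within a gap the deleted columns precede the
inserted ones, mirroring the builder's emission order.

## Synthetic data and oracles

The fixture generator emulates the intended workflow at desk scale: a
uniform-random ACGT target contig; a sorted, anchored, non-overlapping
bi-allelic VCF with per-base SNV/insertion/deletion probabilities
(defaults 0.01 / 0.002 / 0.002 per bp — roughly the genome-wide density
of a human major-allele call set, with the indel share deliberately
overweighted to exercise coordinate shifts — and indel lengths uniform in
1–10 bp); the source contig obtained by splicing the ALTs in; and reads
sampled uniformly from the source. Reads are error-free all-M by
default, with configurable fractions of soft/hard-clipped, spliced (N
gaps of 20–200 bp) and indel-bearing reads, optional injected
substitutions for NM checks, and FR proper pairs with consistent
FLAG/PNEXT/TLEN. What it does *not* model: sequencing-error and quality
profiles, coverage bias, repeats/mappability, real aligner behaviour
(soft-clip placement, MAPQ distributions) and structural variation —
passing tests therefore demonstrate coordinate-arithmetic correctness,
not robustness to real aligner output.

The oracles are deliberately naive: an explicit column list
(`ColumnMap`) built by splicing — an independent construction path whose
bitvector conversion must equal the VCF-replay builder bit for bit — with
position and CIGAR lifts done by linear scans over that list, and a
brute-force chain interpreter that walks exported chain blocks. The
oracles implement the same insertion/N conventions as the succinct path
on purpose: disagreements then expose bugs rather than convention drift.

## Problem sizes and numerical choices

Fixture genomes are capped at 10 kb and read sets at 100 000 so the full
suite completes in minutes on one CPU: the ensemble checks use 200 random
5–10 kb genome/VCF scenarios with every source position compared against
the oracle and 500–1000 simulated reads per scenario; thread-determinism
runs 100 000 records at threads 1/4/16; serialization uses 50 random
indexes. All randomness is explicitly seeded (the acceptance script
derives sub-seeds from `--seed`); there is no global RNG state. Ties and
degenerate inputs are pinned down by tests: empty VCFs give identity
maps, empty bitvector selects raise, reads with no reference-consuming
op have no target interval, and an insertion at a contig end clamps to
the last target base.

## Known limitations

Only SNV/indel differences are supported — no inversions,
rearrangements or copy-number records. Lifting is per-site, so two
haplotype-resolved references require two indexes. Identity maps
allocate two bits per target base per contig, so whole-genome identity
contigs cost memory proportional to genome size. Threading shares the
Python interpreter, so worker counts buy ordering semantics and I/O
overlap rather than linear CPU scaling.
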