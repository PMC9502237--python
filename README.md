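# liftkit

Lift SAM/BAM alignments from a **variant-aware reference** back to the
standard reference, using only the VCF that defines the difference between
the two.

Aligning reads to a single linear reference biases alignments toward
reference alleles. A common remedy is to align against a variant-aware
reference — the standard genome with known population SNVs and indels
spliced in (e.g. a major-allele reference) — and then translate ("lift")
the resulting alignments back to standard coordinates for downstream
tools. Chain-file lift-over tools do not fit this workflow well: the
natural description of a variant-aware reference is a VCF, and a correct
lift must rewrite not just POS but the CIGAR (including spliced `N`
alignments), mate fields, TLEN, and the MD/NM tags. liftkit does all of
that as a streaming, order-preserving library and command-line tool.

## The coordinate model

Applying a VCF's ALT alleles to the target reference T induces a gapless
pairwise alignment between the source reference S and T. liftkit encodes
that alignment per contig as two bit vectors over alignment columns:

```
column c:    src_bv[c] = 1  iff c contributes a source base
             tgt_bv[c] = 1  iff c contributes a target base
```

SNVs leave both bits set; an insertion of length L (len(ALT) − len(REF) > 0)
contributes L columns with `src=1, tgt=0`; a deletion contributes L columns
with `src=0, tgt=1`. With rank/select support on these vectors (rank1
counts set bits in `[0, i)`, select1 finds the k-th set bit), every
coordinate query is two O(1) operations:

```
lift(s) = rank1(tgt_bv, select1(src_bv, s + 1))
```

A base inside an insertion maps to the next target base (clamped at the
contig end). CIGAR lifting composes the read→source alignment with this
column map: source-only columns turn aligned ops into `I` and shrink `D`/`N`
spans; target-only columns inject `D` ops or widen an adjacent `D`/`N` run.
MAPQ, FLAG, SEQ, QUAL and QNAME are never modified. The index is
serializable (`.lft`) and exportable as a UCSC chain file.

## Worked example

`examples/01_build_index.py` builds an index for a 16 bp toy contig with a
2 bp insertion (`G→GAA` at position 3) and a 2 bp deletion (`GTA→G` at
position 11) and prints:

```
target (16 bp): ACGTACGTACGTACGT
source (16 bp): ACGAATACGTACGCGT
index serialized to variants.lft: 68 bytes
columns=18 source=16 target=16
  source  0 -> target 0
  source  3 -> target 3
  source  4 -> target 3
  source  5 -> target 3
  source  8 -> target 6
  source 12 -> target 10
```

Source positions 3 and 4 are the inserted `AA`: they have no target
counterpart and map to the next target base (3), as does the first base
after them. Positions past the insertion shift left by 2; positions past
the deletion shift back right. The other examples lift a simulated read
set (`02`), recompute MD/NM against the target FASTA (`03`) and export a
chain file (`04`).

## Command line

```sh
liftkit index -v variants.vcf.gz -F ref.fa.fai -o variants.lft
liftkit lift  -l variants.lft -a aln.bam -o lifted.bam -t 8 \
              --md -f ref.fa --chain variants.chain
```

`-` means stdin/stdout, so the lifter can run directly downstream of an
aligner in a pipe. Output is byte-identical for every `-t` value:
batches are lifted concurrently but reassembled in input order.

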