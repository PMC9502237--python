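"""Recompute MD and NM tags against the target reference after lifting.

A read that matched the source genome perfectly can disagree with the
target wherever the VCF placed an SNV, and lifting across indels adds I/D
ops; MD/NM must therefore be rebuilt in target coordinates.
"""

import tempfile
from pathlib import Path

import pysam

from liftkit import LiftIndex, LiftOptions, build_contig_lift, lift_record
from liftkit.fixtures import make_fixture, simulate_reads, write_fasta

fx = make_fixture(seed=7, length=5000)
cl = build_contig_lift("chr1", 5000, fx.variants)
index = LiftIndex(contigs={"chr1": cl})

with tempfile.TemporaryDirectory() as tmp:
    fa_path = Path(tmp) / "target.fa"
    write_fasta({"chr1": fx.target}, fa_path)
    fasta = pysam.FastaFile(str(fa_path))
    opts = LiftOptions(recompute_tags=True, target_fasta=fasta)

    _, records, _ = simulate_reads(fx.source, fx.cmap, 2000, read_len=100,
                                   seed=8, frac_softclip=0, frac_hardclip=0,
                                   frac_splice=0, frac_indel=0)
    shown = 0
    for rec in records:
        lift_record(rec, index, opts)
        if rec.is_unmapped:
            continue
        if shown < 3 and rec.get_tag("NM") > 0:
            print(f"{rec.query_name}: pos={rec.reference_start} "
                  f"CIGAR={rec.cigarstring} NM={rec.get_tag('NM')} "
                  f"MD={rec.get_tag('MD')}")
            shown += 1

# NM counts mismatches (source reads crossing an SNV site differ from the
# target there) plus inserted and deleted bases introduced by lifting
# across indels; the MD string lets tools rebuild the target slice without
# the FASTA.
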