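"""Build a coordinate-lift index from a VCF and query it.

Creates a toy target contig and two variants (an insertion and a
deletion), writes them as a VCF, builds the succinct lift index and shows
how source positions map back to target positions across the indels.
"""

import tempfile
from pathlib import Path

from liftkit import build_index
from liftkit.fixtures import Variant, apply_variants, write_vcf

target = "ACGTACGTACGTACGT"  # 16 bp toy target contig
variants = [
    Variant(2, "G", "GAA"),   # 2 bp insertion after the G at position 3
    Variant(10, "GTA", "G"),  # 2 bp deletion after the G at position 11
]
source, cmap = apply_variants(target, variants)
print(f"target ({len(target)} bp): {target}")
print(f"source ({len(source)} bp): {source}")

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "variants.vcf"
    write_vcf(variants, {"chr1": len(target)}, vcf)
    index = build_index(vcf)
    lft = Path(tmp) / "variants.lft"
    index.save(lft)
    print(f"index serialized to {lft.name}: {lft.stat().st_size} bytes")

    cl = index.contig("chr1")
    print(f"columns={cl.n_columns} source={cl.source_length} target={cl.target_length}")
    for s in (0, 3, 4, 5, 8, 12):
        print(f"  source {s:>2} -> target {cl.lift_pos(s)}")

# source 3 and 4 sit inside the insertion: both map to the next target
# base (3); positions after the insertion are shifted left by 2, and
# positions after the deletion shift right by 2 relative to the source.
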