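"""Export the lift index as a UCSC chain file.

Chain files describe the same source→target pairwise alignment in the
format classic lift-over tools consume; the blocks below encode the toy
insertion and deletion of the first example.
"""

import io

from liftkit import LiftIndex, build_contig_lift, export_chain
from liftkit.fixtures import Variant, parse_chain, chain_lift_pos

variants = [Variant(2, "G", "GAA"), Variant(10, "GTA", "G")]
cl = build_contig_lift("chr1", 16, variants)
index = LiftIndex(contigs={"chr1": cl})

buf = io.StringIO()
export_chain(index, buf)
print(buf.getvalue())

chains = parse_chain(buf.getvalue())
agree = all(chain_lift_pos(chains, "chr1", s) == cl.lift_pos(s)
            for s in range(cl.source_length))
print(f"chain interpreter agrees with lift_pos at every source position: {agree}")

# Data lines are `size dt dq` triples: `size` aligned bases, `dt` bases
# present only in the source (the insertion), `dq` bases present only in
# the target (the deletion); the final bare number closes the chain.
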