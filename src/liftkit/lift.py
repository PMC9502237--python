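"""Lift single alignment records from source to target coordinates.

The core operation composes two pairwise alignments: the read→source
alignment (the record's CIGAR) and the source→target alignment implied by
the VCF (the :class:`~liftkit.index.ContigLift` column map). Walking the
CIGAR left to right, every covered source base is classified by its column:

* both-1 column — the op survives unchanged (M/=/X/D/N);
* source-only column (base inserted in the source) — M/=/X become I, and
  D/N spans shrink, because the base has no target counterpart;
* target-only columns falling *between* consecutive source bases are target
  bases deleted from the source: they inject D ops, or widen an adjacent
  D/N run (a splice gap absorbs deletions inside it; N and D are never
  merged with each other).

Query-consuming length, SEQ, QUAL, MAPQ, FLAG and QNAME are never altered
by lifting; MAPQ pass-through is a deliberate contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import pysam

from .index import ContigLift, LiftIndex

__all__ = [
    "LiftOptions",
    "NoTargetSpan",
    "lift_cigar",
    "lift_record",
    "compute_md_nm",
    "recompute_tags",
    "rewrite_header",
    "reference_span",
    "query_length",
]

logger = logging.getLogger("liftkit")

# pysam numeric CIGAR op codes
M, I, D, N, S, H, P, EQ, X = range(9)

QUERY_OPS = frozenset((M, I, S, EQ, X))
REF_OPS = frozenset((M, D, N, EQ, X))
_MATCH_OPS = (M, EQ, X)

Cigar = List[Tuple[int, int]]


class NoTargetSpan(Exception):
    """The alignment lies entirely inside an insertion: no target interval.

    ``anchor`` carries the target position of the nearest target base so the
    caller can keep the record placeable (and the output sortable).
    """

    def __init__(self, anchor: int):
        super().__init__("alignment covers no target base")
        self.anchor = anchor


def reference_span(cigar: Sequence[Tuple[int, int]]) -> int:
    """Number of reference bases consumed by a CIGAR."""
    return sum(ln for op, ln in cigar if op in REF_OPS)


def query_length(cigar: Sequence[Tuple[int, int]], *, with_hard_clips: bool = False) -> int:
    """Number of query bases consumed by a CIGAR (H optional)."""
    ops = QUERY_OPS | {H} if with_hard_clips else QUERY_OPS
    return sum(ln for op, ln in cigar if op in ops)


def _emit(out: Cigar, op: int, ln: int) -> None:
    if ln <= 0:
        return
    if out and out[-1][0] == op:
        out[-1] = (op, out[-1][1] + ln)
    else:
        out.append((op, ln))


def _clip_terminal_insertions(cigar: Cigar) -> Cigar:
    """Convert terminal I runs (ignoring flanking S/H) to soft clips."""
    ops = [list(t) for t in cigar]
    idxs = [i for i, (op, _) in enumerate(ops) if op not in (S, H)]
    if idxs and ops[idxs[0]][0] == I:
        ops[idxs[0]][0] = S
    if len(idxs) > 1 and ops[idxs[-1]][0] == I:
        ops[idxs[-1]][0] = S
    merged: Cigar = []
    for op, ln in ops:
        _emit(merged, op, ln)
    return merged


def lift_cigar(
    contig_lift: ContigLift,
    s_pos: int,
    cigar: Sequence[Tuple[int, int]],
    *,
    clip_leading_insertions: bool = False,
) -> Tuple[int, Cigar]:
    """Lift an alignment's position and CIGAR through a contig's column map.

    Parameters
    ----------
    contig_lift
        The source→target column map for the record's contig.
    s_pos
        0-based source alignment start.
    cigar
        Sequence of ``(op, length)`` pairs in pysam numeric encoding.
    clip_leading_insertions
        Convert terminal I runs of the lifted CIGAR to soft clips.

    Returns
    -------
    (t_pos, t_cigar)
        Target start (0-based) and lifted CIGAR, canonical (merged,
        no zero-length ops).

    Raises
    ------
    NoTargetSpan
        If no covered source base aligns to a target base (read entirely
        inside an insertion).
    """
    cigar = [(int(op), int(ln)) for op, ln in cigar]
    for op, ln in cigar:
        if not 0 <= op <= X or ln <= 0:
            raise ValueError(f"malformed CIGAR op ({op}, {ln})")
    refspan = reference_span(cigar)
    if refspan == 0:
        anchor = contig_lift.lift_pos(min(s_pos, contig_lift.source_length - 1))
        raise NoTargetSpan(anchor)
    if s_pos < 0 or s_pos + refspan > contig_lift.source_length:
        raise IndexError(
            f"alignment [{s_pos}, {s_pos + refspan}) exceeds source contig "
            f"{contig_lift.name!r} of length {contig_lift.source_length}"
        )

    src_bv, tgt_bv = contig_lift.src_bv, contig_lift.tgt_bv
    cols = src_bv.select_consecutive(s_pos + 1, refspan)
    both = tgt_bv.get_bits(cols)

    # Fast path: the covered columns are contiguous and all both-1 — the
    # read does not straddle any indel, so the CIGAR survives as-is.
    if int(cols[-1] - cols[0]) == refspan - 1 and bool(both.all()):
        t_pos = tgt_bv.rank1(int(cols[0]))
        out = list(cigar)
        if clip_leading_insertions:
            out = _clip_terminal_insertions(out)
        return t_pos, out

    out: Cigar = []
    i = 0  # index into cols/both
    prev_col = -1
    prev_ref_op = -1
    first_both = -1
    for op, ln in cigar:
        if op not in REF_OPS:  # I, S, H, P: query-only, pass through in place
            _emit(out, op, ln)
            continue
        for _ in range(ln):
            c = int(cols[i])
            if prev_col >= 0 and c - prev_col > 1:
                gap = c - prev_col - 1  # target-only columns in between
                if prev_ref_op in (D, N):
                    _emit(out, prev_ref_op, gap)
                elif op in (D, N):
                    _emit(out, op, gap)
                else:
                    _emit(out, D, gap)
            if both[i]:
                _emit(out, op, 1)
                if first_both < 0:
                    first_both = c
            else:  # source-only column: inserted base
                if op in _MATCH_OPS:
                    _emit(out, I, 1)
                # D/N over an inserted base simply shrinks
            prev_col = c
            prev_ref_op = op
            i += 1

    if first_both < 0:
        raise NoTargetSpan(contig_lift.lift_pos(s_pos))
    t_pos = tgt_bv.rank1(first_both)
    if clip_leading_insertions:
        out = _clip_terminal_insertions(out)
    return t_pos, out


# ---------------------------------------------------------------------------
# Whole-record lifting
# ---------------------------------------------------------------------------

@dataclass
class LiftOptions:
    """Knobs for :func:`lift_record`.

    ``recompute_tags`` requires ``target_fasta`` (any object with a
    ``fetch(reference, start, end)`` method, e.g. ``pysam.FastaFile``).
    """

    recompute_tags: bool = False
    clip_leading_insertions: bool = False
    target_fasta: Optional[object] = None

    def __post_init__(self):
        if self.recompute_tags and self.target_fasta is None:
            raise ValueError("recompute_tags requires a target reference FASTA")


@dataclass
class _NullSummary:
    records_in: int = 0
    records_lifted: int = 0
    records_passed_through: int = 0
    records_unmapped_by_lift: int = 0
    warnings: int = 0
    _warned_contigs: set = field(default_factory=set)


def lift_record(
    rec: pysam.AlignedSegment,
    index: LiftIndex,
    opts: Optional[LiftOptions] = None,
    summary=None,
) -> pysam.AlignedSegment:
    """Lift one SAM/BAM record in place from source to target coordinates.

    Mapped records get position and CIGAR from :func:`lift_cigar`; mate
    position is lifted statelessly through the index; TLEN is recomputed
    from the lifted coordinates when both mates map to the same contig
    (outermost-coordinate convention). MAPQ, FLAG, SEQ, QUAL and QNAME are
    never modified. Unmapped records pass through untouched. Records on
    contigs absent from the index pass through unchanged (counted, warned
    once per contig). A read aligned entirely within an insertion has no
    target interval: it is flagged unmapped, keeping the lifted anchor
    position for sort stability.
    """
    if opts is None:
        opts = LiftOptions()
    if summary is None:
        summary = _NullSummary()

    if rec.is_unmapped or rec.reference_id < 0:
        summary.records_passed_through += 1
        return rec

    contig = rec.reference_name
    cl = index.contigs.get(contig)
    if cl is None:
        summary.records_passed_through += 1
        if contig not in summary._warned_contigs:
            summary._warned_contigs.add(contig)
            summary.warnings += 1
            logger.warning(
                "contig %s is not in the lift index; records pass through unchanged",
                contig,
            )
        return rec

    s_pos = rec.reference_start
    old_tlen = rec.template_length
    lifted_ok = True
    t_pos = s_pos
    t_cigar: Optional[Cigar] = None
    try:
        t_pos, t_cigar = lift_cigar(
            cl, s_pos, rec.cigartuples or (),
            clip_leading_insertions=opts.clip_leading_insertions,
        )
    except NoTargetSpan as e:
        lifted_ok = False
        summary.records_unmapped_by_lift += 1
        summary.warnings += 1
        logger.warning(
            "read %s lies entirely within an insertion; flagged unmapped",
            rec.query_name,
        )
        rec.is_unmapped = True
        rec.reference_start = e.anchor
        rec.cigartuples = None

    if lifted_ok:
        summary.records_lifted += 1
        rec.reference_start = t_pos
        rec.cigartuples = t_cigar

    # Mate fields: stateless lift of PNEXT through the mate contig's map.
    new_pnext = rec.next_reference_start
    if (
        rec.is_paired
        and not rec.mate_is_unmapped
        and rec.next_reference_id >= 0
    ):
        mate_cl = index.contigs.get(rec.next_reference_name)
        if mate_cl is not None and 0 <= new_pnext < mate_cl.source_length:
            new_pnext = mate_cl.lift_pos(new_pnext)
            rec.next_reference_start = new_pnext

    # TLEN: recompute from the lifted coordinates when well-defined.
    if (
        lifted_ok
        and rec.is_paired
        and not rec.mate_is_unmapped
        and old_tlen != 0
        and rec.next_reference_id == rec.reference_id
    ):
        if old_tlen > 0:
            mate_end_src = s_pos + old_tlen
            if 0 < mate_end_src <= cl.source_length:
                rec.template_length = cl.lift_end(mate_end_src) - t_pos
        else:
            t_end = t_pos + reference_span(t_cigar)
            rec.template_length = -(t_end - new_pnext)

    if lifted_ok and opts.recompute_tags and rec.query_sequence:
        recompute_tags(rec, opts.target_fasta)

    return rec


# ---------------------------------------------------------------------------
# MD/NM recomputation
# ---------------------------------------------------------------------------

def compute_md_nm(
    cigar: Sequence[Tuple[int, int]], seq: str, ref: str
) -> Tuple[str, int]:
    """MD string and NM edit distance for an alignment in target coordinates.

    ``ref`` is the target reference slice starting at the alignment start
    and covering its full reference span (including N-skipped introns,
    which contribute nothing to either tag). NM counts mismatched aligned
    bases plus all inserted and deleted bases; MD alternates match-run
    counts, mismatched reference bases and ^-prefixed deleted runs, always
    beginning and ending with a (possibly zero) count.
    """
    qi = ri = nm = run = 0
    md: List[str] = []
    for op, ln in cigar:
        if op in _MATCH_OPS:
            for j in range(ln):
                rb = ref[ri + j].upper()
                qb = seq[qi + j].upper()
                if rb == qb:
                    run += 1
                else:
                    nm += 1
                    md.append(str(run))
                    md.append(rb)
                    run = 0
            qi += ln
            ri += ln
        elif op == I:
            nm += ln
            qi += ln
        elif op == D:
            nm += ln
            md.append(str(run))
            md.append("^" + ref[ri : ri + ln].upper())
            run = 0
            ri += ln
        elif op == N:
            ri += ln
        elif op == S:
            qi += ln
        # H and P consume nothing
    md.append(str(run))
    return "".join(md), nm


def recompute_tags(rec: pysam.AlignedSegment, fasta) -> None:
    """Replace MD/NM on a target-coordinate record; other tags untouched."""
    cigar = rec.cigartuples or ()
    span = reference_span(cigar)
    contig = rec.reference_name
    ref = fasta.fetch(contig, rec.reference_start, rec.reference_start + span)
    if len(ref) < span:
        raise ValueError(
            f"target reference {contig!r} too short: need "
            f"[{rec.reference_start}, {rec.reference_start + span})"
        )
    md, nm = compute_md_nm(cigar, rec.query_sequence, ref)
    rec.set_tag("MD", md, value_type="Z")
    rec.set_tag("NM", nm, value_type="i")


# ---------------------------------------------------------------------------
# Header rewriting
# ---------------------------------------------------------------------------

def rewrite_header(
    header,
    index: LiftIndex,
    cmdline: str,
    *,
    program_name: str = "liftkit",
    program_version: Optional[str] = None,
) -> pysam.AlignmentHeader:
    """Rename/resize @SQ lines to target coordinates and append a @PG line.

    @SQ entries for contigs absent from the index are kept as-is; every
    other header line is preserved in order.
    """
    from . import __version__

    if program_version is None:
        program_version = __version__
    d = header.to_dict() if hasattr(header, "to_dict") else dict(header)
    d = {k: (list(v) if isinstance(v, list) else dict(v)) for k, v in d.items()}
    sq = []
    for entry in d.get("SQ", []):
        entry = dict(entry)
        sn = entry.get("SN")
        if sn in index.contigs:
            entry["SN"] = index.target_name(sn)
            entry["LN"] = index.target_length(sn)
        sq.append(entry)
    if sq:
        d["SQ"] = sq
    pg = [dict(e) for e in d.get("PG", [])]
    existing_ids = {e.get("ID") for e in pg}
    pg_id = program_name
    k = 1
    while pg_id in existing_ids:
        k += 1
        pg_id = f"{program_name}.{k}"
    entry = {"ID": pg_id, "PN": program_name, "VN": program_version, "CL": cmdline}
    if pg:
        entry["PP"] = pg[-1].get("ID")
    pg.append(entry)
    d["PG"] = pg
    return pysam.AlignmentHeader.from_dict(d)
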