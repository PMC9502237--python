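"""Synthetic data generation and brute-force oracles.

Everything the lift machinery does can be checked against an *explicit*
representation of the source↔target alignment: the :class:`ColumnMap`, a
plain list of alignment columns each tagged with the base it contributes
on the source and/or target side. The oracles here work by linear scans
over that list — no rank/select, no bit packing — so a disagreement with
the succinct path exposes a real bug rather than a convention mismatch.

The generators emulate the study conditions of a variant-aware-reference
workflow at desk scale: a random target contig, a sorted non-overlapping
anchored SNV/indel VCF against it, the source contig obtained by applying
those variants, and error-free (optionally mutated/clipped/spliced) reads
sampled from the source with known truth coordinates. All randomness is
seeded explicitly; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .bitvec import BitVec

__all__ = [
    "Variant",
    "ColumnMap",
    "Fixture",
    "gen_genome",
    "gen_variants",
    "apply_variants",
    "oracle_lift",
    "oracle_lift_all",
    "oracle_lift_cigar",
    "simulate_reads",
    "make_fixture",
    "write_vcf",
    "write_fasta",
    "write_sam",
    "write_truth_table",
    "parse_chain",
    "chain_lift_pos",
    "chain_lift_all",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# pysam numeric CIGAR op codes (kept in sync with lift.py by the SAM spec)
M, I, D, N, S, H, P, EQ, X = range(9)
_REF_OPS = (M, D, N, EQ, X)
_MATCH_OPS = (M, EQ, X)
_CIGAR_CHARS = "MIDNSHP=X"


class Variant(NamedTuple):
    """A bi-allelic site in target coordinates (anchored, VCF-style)."""

    pos0: int  # 0-based target position of the first REF base
    ref: str
    alt: str


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def cigartuples_to_str(cigar: Sequence[Tuple[int, int]]) -> str:
    return "".join(f"{ln}{_CIGAR_CHARS[op]}" for op, ln in cigar)


# ---------------------------------------------------------------------------
# ColumnMap: the explicit oracle representation
# ---------------------------------------------------------------------------

@dataclass
class ColumnMap:
    """Explicit list of alignment columns between source and target.

    Each column is a ``(src_base, tgt_base)`` pair where either side may be
    ``None``: ``(b, None)`` is a base inserted in the source, ``(None, b)``
    a target base deleted from the source, and ``(a, b)`` an aligned pair
    (possibly a substitution). Reading the non-None bases of either side in
    order reconstructs that contig exactly.
    """

    columns: List[Tuple[Optional[str], Optional[str]]]
    name: str = "chr1"
    _src_cols: Optional[np.ndarray] = field(default=None, repr=False)
    _tgt_before: Optional[np.ndarray] = field(default=None, repr=False)

    def source_seq(self) -> str:
        return "".join(c[0] for c in self.columns if c[0] is not None)

    def target_seq(self) -> str:
        return "".join(c[1] for c in self.columns if c[1] is not None)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def source_length(self) -> int:
        return sum(1 for c in self.columns if c[0] is not None)

    @property
    def target_length(self) -> int:
        return sum(1 for c in self.columns if c[1] is not None)

    def to_bitvecs(self) -> Tuple[BitVec, BitVec]:
        src = np.fromiter((c[0] is not None for c in self.columns), bool,
                          count=len(self.columns))
        tgt = np.fromiter((c[1] is not None for c in self.columns), bool,
                          count=len(self.columns))
        return BitVec(src), BitVec(tgt)

    def _tables(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-source-base column index and per-column target-prefix count,
        each built by one linear scan (cached)."""
        if self._src_cols is None:
            src_cols = []
            tgt_before = np.zeros(len(self.columns) + 1, dtype=np.int64)
            t = 0
            for c, (sb, tb) in enumerate(self.columns):
                tgt_before[c] = t
                if sb is not None:
                    src_cols.append(c)
                if tb is not None:
                    t += 1
            tgt_before[len(self.columns)] = t
            self._src_cols = np.asarray(src_cols, dtype=np.int64)
            self._tgt_before = tgt_before
        return self._src_cols, self._tgt_before


def oracle_lift(cmap: ColumnMap, s: int) -> int:
    """Brute-force position lift: linear scan, no rank/select."""
    src_cols, tgt_before = cmap._tables()
    if not 0 <= s < len(src_cols):
        raise IndexError(f"source position {s} out of range")
    t = int(tgt_before[src_cols[s]])
    return min(t, cmap.target_length - 1)


def oracle_lift_all(cmap: ColumnMap) -> np.ndarray:
    src_cols, tgt_before = cmap._tables()
    out = tgt_before[src_cols]
    return np.minimum(out, cmap.target_length - 1)


def oracle_lift_cigar(
    cmap: ColumnMap,
    s_pos: int,
    cigar: Sequence[Tuple[int, int]],
    *,
    clip_leading_insertions: bool = False,
) -> Optional[Tuple[int, List[Tuple[int, int]]]]:
    """Brute-force CIGAR lift over the explicit column list.

    Implements the same conventions as the succinct path (inserted bases
    map M/=/X to I and shrink D/N; deleted columns widen an adjacent D/N
    run or inject a D; terminal I optionally soft-clipped) so that any
    disagreement is a bug. Returns ``None`` when the alignment covers no
    target base (unmapped after lift).
    """
    src_cols, tgt_before = cmap._tables()
    refspan = sum(ln for op, ln in cigar if op in _REF_OPS)
    if refspan == 0 or s_pos + refspan > len(src_cols):
        return None

    out: List[List[int]] = []

    def emit(op: int, ln: int) -> None:
        if ln <= 0:
            return
        if out and out[-1][0] == op:
            out[-1][1] += ln
        else:
            out.append([op, ln])

    i = s_pos
    prev_col = -1
    prev_ref_op = -1
    first_both = -1
    for op, ln in cigar:
        if op not in _REF_OPS:
            emit(op, ln)
            continue
        for _ in range(ln):
            c = int(src_cols[i])
            if prev_col >= 0:
                gap = sum(
                    1 for cc in range(prev_col + 1, c)
                    if cmap.columns[cc][1] is not None
                )
                if gap:
                    if prev_ref_op in (D, N):
                        emit(prev_ref_op, gap)
                    elif op in (D, N):
                        emit(op, gap)
                    else:
                        emit(D, gap)
            if cmap.columns[c][1] is not None:
                emit(op, 1)
                if first_both < 0:
                    first_both = c
            elif op in _MATCH_OPS:
                emit(I, 1)
            prev_col = c
            prev_ref_op = op
            i += 1

    if first_both < 0:
        return None
    t_pos = int(tgt_before[first_both])
    cig = [(op, ln) for op, ln in out]
    if clip_leading_insertions:
        idxs = [k for k, (op, _) in enumerate(cig) if op not in (S, H)]
        as_lists = [list(t) for t in cig]
        if idxs and as_lists[idxs[0]][0] == I:
            as_lists[idxs[0]][0] = S
        if len(idxs) > 1 and as_lists[idxs[-1]][0] == I:
            as_lists[idxs[-1]][0] = S
        merged: List[List[int]] = []
        for op, ln in as_lists:
            if merged and merged[-1][0] == op:
                merged[-1][1] += ln
            else:
                merged.append([op, ln])
        cig = [(op, ln) for op, ln in merged]
    return t_pos, cig


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_genome(length: int, seed: int) -> str:
    """Uniform-random ACGT contig, reproducible by seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def gen_variants(
    genome: str,
    snv_rate: float = 0.01,
    ins_rate: float = 0.002,
    del_rate: float = 0.002,
    max_indel: int = 10,
    seed: int = 0,
) -> List[Variant]:
    """Sorted, anchored, non-overlapping bi-allelic variants against ``genome``.

    Per-position event probabilities; indel lengths uniform in
    ``[1, max_indel]``; collisions (overlap with a previous record or a
    deletion running off the contig end) are skipped so the guarantee is
    enforced by construction.
    """
    for r in (snv_rate, ins_rate, del_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: List[Variant] = []
    L = len(genome)
    p = 0
    while p < L:
        u = rng.random()
        if u < snv_rate:
            ref = genome[p]
            alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
            out.append(Variant(p, ref, alt))
            p += 1
        elif u < snv_rate + ins_rate:
            k = int(rng.integers(1, max_indel + 1))
            ins = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=k)])
            out.append(Variant(p, genome[p], genome[p] + ins))
            p += 1
        elif u < snv_rate + ins_rate + del_rate:
            k = int(rng.integers(1, max_indel + 1))
            if p + 1 + k <= L:
                out.append(Variant(p, genome[p : p + 1 + k], genome[p]))
                p += 1 + k
            else:
                p += 1
        else:
            p += 1
    return out


def apply_variants(
    genome: str, variants: Sequence[Variant], name: str = "chr1"
) -> Tuple[str, ColumnMap]:
    """Splice ALT alleles into ``genome``; record every alignment column.

    Variants must be sorted and non-overlapping and every REF must match
    the genome (error with the offending position otherwise). Shared
    prefix/suffix bases of REF/ALT emit ordinary aligned columns; for an
    equal-length remainder the bases pair up as substitution columns;
    otherwise the surplus REF bases become deleted columns followed by the
    surplus ALT bases as inserted columns.
    """
    cols: List[Tuple[Optional[str], Optional[str]]] = []
    cur = 0
    for pos0, ref, alt in variants:
        if pos0 < cur:
            raise ValueError(f"variant at {pos0} overlaps previous record")
        if genome[pos0 : pos0 + len(ref)] != ref:
            raise ValueError(
                f"REF mismatch at position {pos0}: VCF says {ref!r}, "
                f"genome has {genome[pos0:pos0 + len(ref)]!r}"
            )
        for i in range(cur, pos0):
            cols.append((genome[i], genome[i]))
        p = 0
        while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
            cols.append((ref[p], ref[p]))
            p += 1
        r, a = ref[p:], alt[p:]
        sfx = 0
        while sfx < len(r) and sfx < len(a) and r[-1 - sfx] == a[-1 - sfx]:
            sfx += 1
        r_mid = r[: len(r) - sfx]
        a_mid = a[: len(a) - sfx]
        if len(r_mid) == len(a_mid):
            for rb, ab in zip(r_mid, a_mid):
                cols.append((ab, rb))
        else:
            for rb in r_mid:
                cols.append((None, rb))
            for ab in a_mid:
                cols.append((ab, None))
        for j in range(sfx, 0, -1):
            cols.append((r[-j], r[-j]))
        cur = pos0 + len(ref)
    for i in range(cur, len(genome)):
        cols.append((genome[i], genome[i]))
    cmap = ColumnMap(cols, name=name)
    return cmap.source_seq(), cmap


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def source_header(contig: str, source_length: int) -> pysam.AlignmentHeader:
    """Minimal SAM header describing the source contig."""
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": contig, "LN": source_length}]}
    )


def _make_record(
    header: pysam.AlignmentHeader,
    qname: str,
    flag: int,
    contig: str,
    pos: int,
    mapq: int,
    cigar: Sequence[Tuple[int, int]],
    seq: str,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = qname
    rec.flag = flag
    rec.reference_name = contig
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigartuples = list(cigar)
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return rec


def simulate_reads(
    source: str,
    cmap: ColumnMap,
    n: int,
    read_len: int = 100,
    paired: bool = False,
    seed: int = 0,
    *,
    contig: str = "chr1",
    frac_softclip: float = 0.1,
    frac_hardclip: float = 0.05,
    frac_splice: float = 0.1,
    frac_indel: float = 0.1,
    n_subs: int = 0,
    header: Optional[pysam.AlignmentHeader] = None,
) -> Tuple[pysam.AlignmentHeader, List[pysam.AlignedSegment], List[dict]]:
    """Sample reads from the source contig with known lifted truth.

    Error-free reads at uniform positions, all-M CIGARs, plus configurable
    fractions of soft/hard-clipped, spliced (N) and indel-bearing (I/D)
    reads; ``n_subs`` injects that many substitution errors per read
    (recorded in the truth table for NM checks). Paired mode emits FR
    proper pairs with consistent FLAG/PNEXT/TLEN in source coordinates.

    Returns the source-coordinate header, the records, and one truth dict
    per record with the oracle-lifted coordinates (``expected_pos`` is
    0-based; ``None`` when the read has no target interval).
    """
    if read_len > len(source):
        raise ValueError("read_len exceeds source length")
    rng = np.random.default_rng(seed)
    if header is None:
        header = source_header(contig, len(source))
    L = len(source)
    records: List[pysam.AlignedSegment] = []
    truth: List[dict] = []

    def add(qname, flag, pos, cigar, seq, pnext=-1, tlen=0, mate_pos=None):
        k = 0
        if n_subs and seq:
            seq = list(seq)
            q_offsets = _m_query_offsets(cigar)
            if q_offsets:
                picks = rng.choice(len(q_offsets), size=min(n_subs, len(q_offsets)),
                                   replace=False)
                for pick in np.atleast_1d(picks):
                    qo = q_offsets[int(pick)]
                    seq[qo] = _BASES[(_BASES.index(seq[qo].upper()) +
                                      int(rng.integers(1, 4))) % 4]
                    k += 1
            seq = "".join(seq)
        rec = _make_record(header, qname, flag, contig, pos, 60, cigar, seq)
        if pnext >= 0:
            rec.next_reference_id = rec.reference_id
            rec.next_reference_start = pnext
            rec.template_length = tlen
        res = oracle_lift_cigar(cmap, pos, cigar)
        row = {
            "qname": qname,
            "contig": contig,
            "src_pos": pos,
            "src_cigar": cigartuples_to_str(cigar),
            "expected_pos": None if res is None else res[0],
            "expected_cigar": None if res is None else cigartuples_to_str(res[1]),
            "n_subs": k,
        }
        records.append(rec)
        truth.append(row)

    if paired:
        for idx in range(n):
            frag = int(rng.integers(2 * read_len + 10, max(2 * read_len + 11,
                                                           min(450, L) + 1)))
            frag = min(frag, L)
            p1 = int(rng.integers(0, L - frag + 1))
            p2 = p1 + frag - read_len
            q = f"pair{idx}"
            cig = [(M, read_len)]
            add(q, 0x1 | 0x2 | 0x20 | 0x40, p1, cig, source[p1 : p1 + read_len],
                pnext=p2, tlen=frag)
            add(q, 0x1 | 0x2 | 0x10 | 0x80, p2, cig,
                revcomp(source[p2 : p2 + read_len]), pnext=p1, tlen=-frag)
        return header, records, truth

    for idx in range(n):
        u = rng.random()
        q = f"read{idx}"
        if u < frac_softclip:
            k = int(rng.integers(3, max(4, read_len // 4)))
            cigar = [(S, k), (M, read_len - k)]
            refspan = read_len - k
            p = int(rng.integers(0, L - refspan + 1))
            clip = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=k)])
            seq = clip + source[p : p + refspan]
        elif u < frac_softclip + frac_hardclip:
            k = int(rng.integers(3, 20))
            cigar = [(H, k), (M, read_len)]
            p = int(rng.integers(0, L - read_len + 1))
            seq = source[p : p + read_len]
        elif u < frac_softclip + frac_hardclip + frac_splice:
            a = read_len // 2
            b = read_len - a
            g = int(rng.integers(20, 200))
            refspan = read_len + g
            if refspan >= L:
                g = max(1, L - read_len - 1)
                refspan = read_len + g
            cigar = [(M, a), (N, g), (M, b)]
            p = int(rng.integers(0, L - refspan + 1))
            seq = source[p : p + a] + source[p + a + g : p + refspan]
        elif u < frac_softclip + frac_hardclip + frac_splice + frac_indel:
            a = read_len // 3
            k = int(rng.integers(1, 7))
            if rng.random() < 0.5:  # insertion in the read
                c = read_len - a - k
                cigar = [(M, a), (I, k), (M, c)]
                refspan = a + c
                p = int(rng.integers(0, L - refspan + 1))
                ins = "".join(np.array(list(_BASES))[rng.integers(0, 4, size=k)])
                seq = source[p : p + a] + ins + source[p + a : p + refspan]
            else:  # deletion in the read
                cigar = [(M, a), (D, k), (M, read_len - a)]
                refspan = read_len + k
                p = int(rng.integers(0, L - refspan + 1))
                seq = source[p : p + a] + source[p + a + k : p + refspan]
        else:
            cigar = [(M, read_len)]
            p = int(rng.integers(0, L - read_len + 1))
            seq = source[p : p + read_len]
        add(q, 0, p, cigar, seq)
    return header, records, truth


def _m_query_offsets(cigar: Sequence[Tuple[int, int]]) -> List[int]:
    """Query offsets of aligned (M/=/X) bases — substitution targets."""
    out = []
    qi = 0
    for op, ln in cigar:
        if op in _MATCH_OPS:
            out.extend(range(qi, qi + ln))
            qi += ln
        elif op in (I, S):
            qi += ln
    return out


# ---------------------------------------------------------------------------
# One-call fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A complete synthetic scenario: target genome, VCF, source, column map."""

    name: str
    target: str
    variants: List[Variant]
    source: str
    cmap: ColumnMap


def make_fixture(
    seed: int,
    length: int = 10_000,
    snv_rate: float = 0.01,
    ins_rate: float = 0.002,
    del_rate: float = 0.002,
    max_indel: int = 10,
    name: str = "chr1",
) -> Fixture:
    target = gen_genome(length, seed)
    variants = gen_variants(target, snv_rate, ins_rate, del_rate, max_indel,
                            seed=seed + 1)
    source, cmap = apply_variants(target, variants, name=name)
    return Fixture(name, target, variants, source, cmap)


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------

def write_fasta(seqs: Dict[str, str], path: Union[str, Path], *, faidx: bool = True) -> None:
    path = str(path)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    if faidx:
        pysam.faidx(path)


def write_vcf(
    variants: Sequence[Variant],
    contig_lengths: Dict[str, int],
    path: Union[str, Path],
    *,
    contig: str = "chr1",
) -> None:
    """Minimal sorted VCF v4.2 with ##contig length headers (single contig)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos0, ref, alt in variants:
            fh.write(f"{contig}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_sam(
    path: Union[str, Path],
    header: pysam.AlignmentHeader,
    records: Sequence[pysam.AlignedSegment],
) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def write_truth_table(truth: Sequence[dict], path: Union[str, Path]) -> None:
    """TSV: qname, expected contig, 1-based expected position, expected CIGAR."""
    with open(path, "w") as fh:
        fh.write("qname\texpected_rname\texpected_pos_1based\texpected_cigar\n")
        for row in truth:
            pos = "*" if row["expected_pos"] is None else str(row["expected_pos"] + 1)
            cig = row["expected_cigar"] or "*"
            fh.write(f"{row['qname']}\t{row['contig']}\t{pos}\t{cig}\n")


# ---------------------------------------------------------------------------
# Chain-file interpreter (independent check for export_chain)
# ---------------------------------------------------------------------------

def parse_chain(text: str) -> List[dict]:
    """Parse UCSC chain text into block dicts with (size, dt, dq) triples."""
    chains: List[dict] = []
    cur: Optional[dict] = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            cur = None
            continue
        if line.startswith("chain"):
            f = line.split()
            cur = {
                "score": int(f[1]),
                "src_name": f[2], "src_size": int(f[3]),
                "src_start": int(f[5]), "src_end": int(f[6]),
                "tgt_name": f[7], "tgt_size": int(f[8]),
                "tgt_start": int(f[10]), "tgt_end": int(f[11]),
                "id": int(f[12]),
                "blocks": [],
            }
            chains.append(cur)
        else:
            f = [int(x) for x in line.split()]
            if len(f) == 1:
                cur["blocks"].append((f[0], 0, 0))
            else:
                cur["blocks"].append((f[0], f[1], f[2]))
    return chains


def chain_lift_all(ch: dict) -> np.ndarray:
    """Lift every source position of one parsed chain by walking its blocks.

    Same conventions as :func:`chain_lift_pos`; returns an array of length
    ``src_end - src_start``.
    """
    out = np.empty(ch["src_end"] - ch["src_start"], dtype=np.int64)
    sp, tp = ch["src_start"], ch["tgt_start"]
    base = ch["src_start"]
    for size, dt, dq in ch["blocks"]:
        out[sp - base : sp - base + size] = np.arange(tp, tp + size)
        if dt:
            out[sp - base + size : sp - base + size + dt] = min(
                tp + size + dq, ch["tgt_size"] - 1
            )
        sp += size + dt
        tp += size + dq
    return out


def chain_lift_pos(chains: List[dict], contig: str, s: int) -> int:
    """Lift one source position through parsed chains by brute-force walk.

    Positions inside a source gap (``dt``) map to the next target base,
    clamped to the final target base — the same convention as the index.
    """
    for ch in chains:
        if ch["src_name"] != contig:
            continue
        if not ch["src_start"] <= s < ch["src_end"]:
            continue
        sp, tp = ch["src_start"], ch["tgt_start"]
        for size, dt, dq in ch["blocks"]:
            if s < sp + size:
                return tp + (s - sp)
            if s < sp + size + dt:
                # Inside a source-only gap: the next target base. Target-only
                # columns of the same inter-block gap precede the source-only
                # ones (deletion emitted before insertion), hence `+ dq`.
                return min(tp + size + dq, ch["tgt_size"] - 1)
            sp += size + dt
            tp += size + dq
        raise IndexError(f"position {s} not covered by chain for {contig!r}")
    raise KeyError(f"no chain covers {contig!r}:{s}")
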