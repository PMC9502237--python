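"""VCF-derived coordinate-lift index.

A variant-aware ("source") reference is the standard ("target") reference
with the ALT alleles of a VCF spliced in. SNVs leave coordinates alone;
indels shift them. The implied pairwise alignment of the two references
is encoded, per contig, as two bitvectors over *alignment columns*:

* ``src_bv[c] = 1``  iff column ``c`` contributes a source base,
* ``tgt_bv[c] = 1``  iff column ``c`` contributes a target base.

A column with ``src=1, tgt=0`` is a base inserted in the source (ALT longer
than REF); ``src=0, tgt=1`` is a target base deleted from the source. No
column is 0 in both. Rank/select over these bitvectors answers every
coordinate query:

    lift_pos(s)  =  rank1(tgt_bv, select1(src_bv, s + 1))

i.e. the target position aligned to source position ``s`` — or, for a base
inside an insertion, the position of the next target base (clamped to the
final base for an insertion at the contig end).

All positions here are 0-based, half-open; conversion to SAM's 1-based POS
happens only at record I/O boundaries.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .bitvec import BitVec

__all__ = [
    "ContigLift",
    "LiftIndex",
    "LiftError",
    "IndexFormatError",
    "VcfOrderError",
    "build_index",
    "build_contig_lift",
    "save_index",
    "load_index",
    "read_fai",
]

logger = logging.getLogger("liftkit")

MAGIC = b"LFTKIDX\x00"
FORMAT_VERSION = 1

_VALID_BASES = frozenset("ACGTNacgtn")


class LiftError(Exception):
    """Base class for lift-index errors."""


class IndexFormatError(LiftError):
    """Raised when a serialized index is truncated, corrupt or unsupported."""


class VcfOrderError(LiftError):
    """Raised when the input VCF is not sorted by contig and position."""


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def normalize_allele_pair(pos0: int, ref: str, alt: str) -> Tuple[int, int, int]:
    """Reduce a REF/ALT pair to ``(t0, n_del, n_ins)``.

    Shared prefix and suffix bases are stripped (standard anchored-indel
    convention: the anchor base emits an ordinary both-1 column, only the
    surplus bases emit one-sided columns). ``t0`` is the 0-based target
    position of the first deleted base / the insertion point; ``n_del``
    target bases are deleted there and ``n_ins`` source bases inserted.
    Length-preserving substitutions come back as ``(t0, 0, 0)``.
    """
    ref = ref.upper()
    alt = alt.upper()
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    r, a = ref[p:], alt[p:]
    s = 0
    while s < len(r) and s < len(a) and r[len(r) - 1 - s] == a[len(a) - 1 - s]:
        s += 1
    if s:
        r, a = r[:-s], a[:-s]
    if len(r) == len(a):
        return pos0 + p, 0, 0  # SNV/MNP: coordinates unaffected
    return pos0 + p, len(r), len(a)


def _allele_ok(allele: str) -> bool:
    return bool(allele) and all(ch in _VALID_BASES for ch in allele)


# ---------------------------------------------------------------------------
# ContigLift
# ---------------------------------------------------------------------------

@dataclass
class ContigLift:
    """The column map of one contig: a pair of rank/select bitvectors."""

    name: str
    src_bv: BitVec
    tgt_bv: BitVec

    def __post_init__(self):
        if len(self.src_bv) != len(self.tgt_bv):
            raise ValueError("src/tgt bitvectors must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.src_bv)

    @property
    def source_length(self) -> int:
        return self.src_bv.popcount

    @property
    def target_length(self) -> int:
        return self.tgt_bv.popcount

    def lift_pos(self, s: int) -> int:
        """Target position of source position ``s`` (0-based).

        For a base inside an insertion this is the position of the next
        target base; an insertion at the very end of the contig maps to
        ``target_length - 1``.
        """
        if not 0 <= s < self.source_length:
            raise IndexError(
                f"source position {s} out of range [0, {self.source_length}) "
                f"on contig {self.name!r}"
            )
        c = self.src_bv.select1(s + 1)
        t = self.tgt_bv.rank1(c)
        return min(t, self.target_length - 1)

    def lift_end(self, e: int) -> int:
        """Lift a half-open source end coordinate ``e`` to a target end.

        ``e`` is one past the last aligned source base; the result is one
        past the last aligned target base (equal to the lifted reference
        span end, also when the alignment ends inside an insertion).
        """
        if not 1 <= e <= self.source_length:
            raise IndexError(f"source end {e} out of range [1, {self.source_length}]")
        c = self.src_bv.select1(e)
        return self.tgt_bv.rank1(c + 1)

    def lift_all_positions(self) -> np.ndarray:
        """Vectorized ``lift_pos`` over every source position (bulk checks)."""
        src_cols = self.src_bv.ones_positions()
        tgt_cum = np.concatenate(
            ([0], np.cumsum(self.tgt_bv.to_bool_array(), dtype=np.int64))
        )
        out = tgt_cum[src_cols]
        np.minimum(out, self.target_length - 1, out=out)
        return out

    @classmethod
    def identity(cls, name: str, length: int) -> "ContigLift":
        ones = np.ones(length, dtype=bool)
        return cls(name, BitVec(ones), BitVec(ones))


def build_contig_lift(
    name: str,
    target_length: int,
    variants: Sequence[Tuple[int, str, str]],
    *,
    validate_sorted: bool = True,
) -> ContigLift:
    """Build one contig's column map from ``(pos0, REF, ALT)`` triples.

    Variants must be position-sorted; overlapping records (by raw REF span)
    are skipped with a warning, never an error. Emission per variant: the
    stripped deleted bases become ``n_del`` target-only columns at the
    deletion point, followed by ``n_ins`` source-only columns.
    """
    ops: List[Tuple[int, int, int]] = []
    prev_pos = -1
    prev_end = 0
    for pos0, ref, alt in variants:
        if validate_sorted and pos0 < prev_pos:
            raise VcfOrderError(
                f"contig {name!r}: record at position {pos0 + 1} follows "
                f"position {prev_pos + 1}; input VCF must be coordinate-sorted"
            )
        prev_pos = pos0
        if pos0 < prev_end:
            logger.warning(
                "contig %s: record at position %d overlaps the previous record; skipped",
                name, pos0 + 1,
            )
            continue
        if not _allele_ok(ref) or not _allele_ok(alt):
            logger.warning(
                "contig %s: record at position %d has a symbolic or non-ACGTN "
                "allele (%s>%s); skipped", name, pos0 + 1, ref, alt,
            )
            continue
        if pos0 + len(ref) > target_length:
            logger.warning(
                "contig %s: record at position %d extends past the contig end; skipped",
                name, pos0 + 1,
            )
            continue
        prev_end = pos0 + len(ref)
        t0, n_del, n_ins = normalize_allele_pair(pos0, ref, alt)
        if n_del or n_ins:
            ops.append((t0, n_del, n_ins))

    total_ins = sum(op[2] for op in ops)
    n_columns = target_length + total_ins
    src = np.ones(n_columns, dtype=bool)
    tgt = np.ones(n_columns, dtype=bool)
    shift = 0
    for t0, n_del, n_ins in ops:
        col = t0 + shift
        if n_del:
            src[col : col + n_del] = False
        if n_ins:
            tgt[col + n_del : col + n_del + n_ins] = False
        shift += n_ins
    return ContigLift(name, BitVec(src), BitVec(tgt))


# ---------------------------------------------------------------------------
# LiftIndex
# ---------------------------------------------------------------------------

@dataclass
class LiftIndex:
    """Collection of per-contig lift maps plus a source→target name map."""

    contigs: Dict[str, ContigLift] = field(default_factory=dict)
    name_map: Dict[str, str] = field(default_factory=dict)
    version: int = FORMAT_VERSION

    def __post_init__(self):
        for name in self.contigs:
            self.name_map.setdefault(name, name)
        for name in self.name_map:
            if name not in self.contigs:
                raise LiftError(f"name_map entry {name!r} has no contig map")

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def contig(self, name: str) -> ContigLift:
        try:
            return self.contigs[name]
        except KeyError:
            raise LiftError(f"contig {name!r} not present in lift index") from None

    def target_name(self, source_contig: str) -> str:
        return self.name_map.get(source_contig, source_contig)

    def lift_pos(self, contig: str, s: int) -> int:
        return self.contig(contig).lift_pos(s)

    def target_length(self, contig: str) -> int:
        return self.contig(contig).target_length

    def source_length(self, contig: str) -> int:
        return self.contig(contig).source_length

    # -- serialization ----------------------------------------------------------

    def save(self, sink: Union[str, Path, BinaryIO]) -> None:
        save_index(self, sink)

    @classmethod
    def load(cls, source: Union[str, Path, BinaryIO]) -> "LiftIndex":
        return load_index(source)


def _write_str(fh: BinaryIO, s: str) -> None:
    data = s.encode("utf-8")
    fh.write(struct.pack("<I", len(data)))
    fh.write(data)


def _read_exact(fh: BinaryIO, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise IndexFormatError(
            f"truncated index stream: wanted {n} bytes, got {len(data)}"
        )
    return data


def _read_str(fh: BinaryIO) -> str:
    (n,) = struct.unpack("<I", _read_exact(fh, 4))
    return _read_exact(fh, n).decode("utf-8")


def save_index(index: LiftIndex, sink: Union[str, Path, BinaryIO]) -> None:
    """Write the binary ``.lft`` container.

    Layout: magic, u32 format version, u32 contig count; per contig the
    length-prefixed name, u64 column count, then the bit-packed src and tgt
    bitvectors as little-endian 64-bit words; finally the name map as u32
    count + (source, target) string pairs.
    """
    own = isinstance(sink, (str, Path))
    fh: BinaryIO = open(sink, "wb") if own else sink  # type: ignore[arg-type]
    try:
        fh.write(MAGIC)
        fh.write(struct.pack("<II", index.version, len(index.contigs)))
        for name, cl in index.contigs.items():
            _write_str(fh, name)
            fh.write(struct.pack("<Q", cl.n_columns))
            fh.write(cl.src_bv.words.astype("<u8").tobytes())
            fh.write(cl.tgt_bv.words.astype("<u8").tobytes())
        fh.write(struct.pack("<I", len(index.name_map)))
        for src_name, tgt_name in index.name_map.items():
            _write_str(fh, src_name)
            _write_str(fh, tgt_name)
    finally:
        if own:
            fh.close()


def load_index(source: Union[str, Path, BinaryIO]) -> LiftIndex:
    """Read a ``.lft`` container written by :func:`save_index`."""
    own = isinstance(source, (str, Path))
    fh: BinaryIO = open(source, "rb") if own else source  # type: ignore[arg-type]
    try:
        magic = fh.read(len(MAGIC))
        if magic != MAGIC:
            raise IndexFormatError(
                f"not a lift index: bad magic {magic!r} (expected {MAGIC!r})"
            )
        version, n_contigs = struct.unpack("<II", _read_exact(fh, 8))
        if version != FORMAT_VERSION:
            raise IndexFormatError(
                f"unsupported index format version {version} "
                f"(this build reads version {FORMAT_VERSION})"
            )
        contigs: Dict[str, ContigLift] = {}
        for _ in range(n_contigs):
            name = _read_str(fh)
            (n_columns,) = struct.unpack("<Q", _read_exact(fh, 8))
            n_words = (n_columns + 63) // 64
            src = np.frombuffer(_read_exact(fh, n_words * 8), dtype="<u8")
            tgt = np.frombuffer(_read_exact(fh, n_words * 8), dtype="<u8")
            contigs[name] = ContigLift(
                name,
                BitVec._from_words(src, n_columns),
                BitVec._from_words(tgt, n_columns),
            )
        (n_names,) = struct.unpack("<I", _read_exact(fh, 4))
        name_map = {}
        for _ in range(n_names):
            k = _read_str(fh)
            name_map[k] = _read_str(fh)
        return LiftIndex(contigs=contigs, name_map=name_map, version=version)
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# VCF → index
# ---------------------------------------------------------------------------

def read_fai(path: Union[str, Path]) -> Dict[str, int]:
    """Contig name → length from a FASTA ``.fai`` (two-column minimum)."""
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            lengths[fields[0]] = int(fields[1])
    return lengths


def _vcf_contig_lengths(vcf: pysam.VariantFile) -> Dict[str, int]:
    out = {}
    for name, rec in vcf.header.contigs.items():
        if rec.length is not None:
            out[name] = rec.length
    return out


def build_index(
    vcf: Union[str, Path, pysam.VariantFile],
    contig_lengths: Optional[Mapping[str, int]] = None,
    *,
    fai: Optional[Union[str, Path]] = None,
) -> LiftIndex:
    """Build a :class:`LiftIndex` from a coordinate-sorted VCF.

    Variant coordinates are relative to the *target* reference; the source
    reference is the target with the (first) ALT allele of each record
    applied. Contig lengths come from ``contig_lengths``, a FASTA ``.fai``
    (``fai=``), or ``##contig`` headers, in that priority; contigs with no
    variants get identity maps. Genotype columns are ignored — only
    CHROM/POS/REF/ALT matter.
    """
    own = not isinstance(vcf, pysam.VariantFile)
    vf = pysam.VariantFile(str(vcf)) if own else vcf
    try:
        lengths: Dict[str, int] = {}
        lengths.update(_vcf_contig_lengths(vf))
        if fai is not None:
            lengths.update(read_fai(fai))
        if contig_lengths is not None:
            lengths.update(contig_lengths)

        per_contig: Dict[str, List[Tuple[int, str, str]]] = {}
        seen_order: List[str] = []
        for rec in vf:
            chrom = rec.chrom
            if chrom not in per_contig:
                if chrom in seen_order:
                    raise VcfOrderError(
                        f"contig {chrom!r} appears in non-contiguous blocks; "
                        "input VCF must be sorted by contig"
                    )
                per_contig[chrom] = []
                seen_order.append(chrom)
            alts = rec.alts
            if not alts:
                continue
            if len(alts) > 1:
                logger.warning(
                    "%s:%d is multi-allelic; applying the first ALT only",
                    chrom, rec.pos,
                )
            per_contig[chrom].append((rec.start, rec.ref or "", alts[0] or ""))

        missing = [c for c in per_contig if c not in lengths]
        if missing:
            raise LiftError(
                f"no length available for contig(s) {', '.join(sorted(missing))}; "
                "add ##contig=<ID=...,length=...> headers to the VCF or supply a "
                "FASTA .fai index"
            )

        contigs: Dict[str, ContigLift] = {}
        for name, length in lengths.items():
            contigs[name] = build_contig_lift(name, length, per_contig.get(name, ()))
        return LiftIndex(contigs=contigs)
    finally:
        if own:
            vf.close()
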