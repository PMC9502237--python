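"""Streaming SAM/BAM lift-over: batched, order-preserving, pipe-friendly.

Records are processed in fixed-size batches. With T worker threads the
batches are lifted concurrently but written back strictly in input order,
so the output is byte-identical for every thread count — determinism is a
contract here, not an accident. ``-`` means stdin/stdout, letting the
lifter sit directly downstream of an aligner in a pipe.
"""

from __future__ import annotations

import logging
import sys
from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, TextIO, Union

import numpy as np
import pysam

from .index import LiftIndex, build_index, load_index
from .lift import LiftOptions, lift_record, rewrite_header

__all__ = ["RunConfig", "RunSummary", "run_index", "run_lift", "export_chain"]

logger = logging.getLogger("liftkit")

BATCH_SIZE = 8192  # records per worker batch; fixed so output layout is stable


@dataclass
class RunSummary:
    """Counters reported to stderr at the end of a run."""

    records_in: int = 0
    records_lifted: int = 0
    records_passed_through: int = 0
    records_unmapped_by_lift: int = 0
    warnings: int = 0
    _warned_contigs: set = field(default_factory=set)

    def merge(self, other: "RunSummary") -> None:
        self.records_in += other.records_in
        self.records_lifted += other.records_lifted
        self.records_passed_through += other.records_passed_through
        self.records_unmapped_by_lift += other.records_unmapped_by_lift
        self.warnings += other.warnings
        self._warned_contigs |= other._warned_contigs

    def report(self, stream: TextIO = sys.stderr) -> None:
        print(
            f"[liftkit] records in: {self.records_in}  "
            f"lifted: {self.records_lifted}  "
            f"passed through: {self.records_passed_through}  "
            f"unmapped by lift: {self.records_unmapped_by_lift}  "
            f"warnings: {self.warnings}",
            file=stream,
        )


@dataclass
class RunConfig:
    """Configuration for one index/lift run (mirrors the CLI flags)."""

    command: str = "lift"
    vcf_path: Optional[str] = None
    index_path: Optional[str] = None
    input_path: str = "-"
    output_path: str = "-"
    output_format: Optional[str] = None  # "SAM" | "BAM"; inferred from suffix
    threads: int = 1
    md_flag: bool = False
    fasta_path: Optional[str] = None
    fai_path: Optional[str] = None
    clip_leading_ins: bool = False
    chain_out: Optional[str] = None

    def __post_init__(self):
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.md_flag and not self.fasta_path:
            raise ValueError("MD/NM recomputation requires a target FASTA (-f)")
        if self.command == "lift" and bool(self.vcf_path) == bool(self.index_path):
            raise ValueError("lift needs exactly one of a VCF or a .lft index")
        if self.output_format is None:
            self.output_format = (
                "BAM" if str(self.output_path).endswith(".bam") else "SAM"
            )


def run_index(config: RunConfig) -> LiftIndex:
    """Build a lift index from a VCF and serialize it to ``index_path``."""
    if not config.vcf_path:
        raise ValueError("run_index requires a VCF path")
    if not config.index_path:
        raise ValueError("run_index requires an output .lft path")
    index = build_index(config.vcf_path, fai=config.fai_path)
    index.save(config.index_path)
    n_cols = sum(cl.n_columns for cl in index.contigs.values())
    logger.info(
        "wrote %s: %d contig(s), %d alignment columns",
        config.index_path, len(index.contigs), n_cols,
    )
    return index


def _load_or_build(config: RunConfig) -> LiftIndex:
    if config.index_path:
        return load_index(config.index_path)
    return build_index(config.vcf_path, fai=config.fai_path)


def _batches(
    records: Iterable[pysam.AlignedSegment], size: int
) -> Iterator[List[pysam.AlignedSegment]]:
    batch: List[pysam.AlignedSegment] = []
    for rec in records:
        batch.append(rec)
        if len(batch) >= size:
            yield batch
            batch = []
    if batch:
        yield batch


def run_lift(
    config: RunConfig,
    *,
    index: Optional[LiftIndex] = None,
    cmdline: Optional[str] = None,
) -> RunSummary:
    """Lift a SAM/BAM stream from source to target coordinates.

    The header is rewritten once; records are lifted in sequence-numbered
    batches (reassembled before writing, so output order equals input
    order for any thread count) and no record is ever dropped: per-record
    failures downgrade to pass-through and a counter.
    """
    if index is None:
        index = _load_or_build(config)
    if cmdline is None:
        cmdline = " ".join(sys.argv) if sys.argv else "liftkit lift"

    fasta = pysam.FastaFile(config.fasta_path) if config.md_flag else None
    opts = LiftOptions(
        recompute_tags=config.md_flag,
        clip_leading_insertions=config.clip_leading_ins,
        target_fasta=fasta,
    )
    summary = RunSummary()

    with pysam.AlignmentFile(config.input_path, "r", check_sq=False) as infile:
        out_header = rewrite_header(infile.header, index, cmdline)
        mode = "wb" if config.output_format == "BAM" else "w"
        with pysam.AlignmentFile(config.output_path, mode, header=out_header) as out:

            def work(batch: List[pysam.AlignedSegment]):
                local = RunSummary()
                local.records_in = len(batch)
                for rec in batch:
                    lift_record(rec, index, opts, local)
                return batch, local

            def write(result):
                batch, local = result
                summary.merge(local)
                for rec in batch:
                    out.write(rec)

            if config.threads == 1:
                for batch in _batches(infile, BATCH_SIZE):
                    write(work(batch))
            else:
                with ThreadPoolExecutor(max_workers=config.threads) as ex:
                    pending = deque()
                    for batch in _batches(infile, BATCH_SIZE):
                        pending.append(ex.submit(work, batch))
                        while len(pending) > config.threads * 2:
                            write(pending.popleft().result())
                    while pending:
                        write(pending.popleft().result())

    if config.chain_out:
        with open(config.chain_out, "w") as fh:
            export_chain(index, fh)
    if fasta is not None:
        fasta.close()
    summary.report()
    return summary


# ---------------------------------------------------------------------------
# UCSC chain export
# ---------------------------------------------------------------------------

def export_chain(index: LiftIndex, sink: Union[TextIO, str, Path]) -> None:
    """Write the source→target column maps as a UCSC chain file.

    One chain block per contig: a header line
    ``chain <score> <srcName> <srcSize> + 0 <srcSize> <tgtName> <tgtSize> +
    0 <tgtSize> <id>`` (score is emitted as srcSize; no alignment scoring
    is performed) followed by ``size dt dq`` triples from a run-length
    scan of the columns — ``dt`` counts source-only (inserted) columns,
    ``dq`` target-only (deleted) columns between aligned blocks. Leading or
    trailing gaps are carried by zero-size blocks so the block sums always
    reach the declared contig sizes. Blocks end with a blank line.
    """
    own = isinstance(sink, (str, Path))
    fh: TextIO = open(sink, "w") if own else sink  # type: ignore[arg-type]
    try:
        for cid, (name, cl) in enumerate(index.contigs.items(), start=1):
            src_size = cl.source_length
            tgt_size = cl.target_length
            tgt_name = index.target_name(name)
            fh.write(
                f"chain {src_size} {name} {src_size} + 0 {src_size} "
                f"{tgt_name} {tgt_size} + 0 {tgt_size} {cid}\n"
            )
            srcb = cl.src_bv.to_bool_array()
            tgtb = cl.tgt_bv.to_bool_array()
            cat = srcb.astype(np.int8) + 2 * tgtb.astype(np.int8)  # 1 src, 2 tgt, 3 both
            if cat.size == 0:
                fh.write("0\n\n")
                continue
            change = np.flatnonzero(cat[1:] != cat[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [cat.size]))
            blk: Optional[int] = None
            dt = dq = 0
            for st, en in zip(starts, ends):
                val = int(cat[st])
                ln = int(en - st)
                if val == 3:
                    if blk is None and (dt or dq):
                        fh.write(f"0 {dt} {dq}\n")
                        dt = dq = 0
                        blk = ln
                    elif blk is not None:
                        fh.write(f"{blk} {dt} {dq}\n")
                        dt = dq = 0
                        blk = ln
                    else:
                        blk = ln
                elif val == 1:
                    dt += ln
                else:
                    dq += ln
            if dt or dq:
                fh.write(f"{0 if blk is None else blk} {dt} {dq}\n0\n")
            else:
                fh.write(f"{0 if blk is None else blk}\n")
            fh.write("\n")
    finally:
        if own:
            fh.close()
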