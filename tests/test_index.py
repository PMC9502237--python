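import io
import logging

import numpy as np
import pytest

from liftkit import (
    IndexFormatError,
    LiftError,
    LiftIndex,
    VcfOrderError,
    build_contig_lift,
    build_index,
    load_index,
    save_index,
)
from liftkit.index import MAGIC, normalize_allele_pair, read_fai
from liftkit.fixtures import Variant, apply_variants, make_fixture, oracle_lift_all, write_vcf


# ---------------------------------------------------------------------------
# Column-map construction
# ---------------------------------------------------------------------------

def test_identity_map_from_no_variants(identity_map):
    cl = identity_map
    assert cl.n_columns == 8
    assert cl.source_length == cl.target_length == 8
    assert [cl.lift_pos(s) for s in range(8)] == list(range(8))


def test_insertion_emits_source_only_columns(ins_map):
    cl, cmap, source = ins_map
    assert cl.n_columns == 10
    assert cl.source_length == 10 and cl.target_length == 8
    src_only = [c for c in range(10) if cl.src_bv[c] and not cl.tgt_bv[c]]
    assert src_only == [3, 4]
    assert source == "ACGAATACGT"


def test_deletion_emits_target_only_columns(del_map):
    cl, cmap, source = del_map
    assert cl.n_columns == 8
    assert cl.source_length == 6 and cl.target_length == 8
    tgt_only = [c for c in range(8) if not cl.src_bv[c] and cl.tgt_bv[c]]
    assert tgt_only == [2, 3]
    assert source == "ACACGT"


def test_no_column_is_empty_on_random_maps():
    for seed in range(5):
        fx = make_fixture(seed, length=2000)
        cl = build_contig_lift("chr1", 2000, fx.variants)
        src = cl.src_bv.to_bool_array()
        tgt = cl.tgt_bv.to_bool_array()
        assert bool((src | tgt).all())


@pytest.mark.parametrize(
    "pos0,ref,alt,expected",
    [
        (4, "G", "GAA", (5, 0, 2)),     # anchored insertion
        (4, "CGT", "C", (5, 2, 0)),     # anchored deletion
        (4, "G", "T", (4, 0, 0)),       # SNV: no coordinate change
        (4, "AC", "GT", (4, 0, 0)),     # MNP: no coordinate change
        (4, "ACGT", "AAAT", (5, 0, 0)), # shared anchor+suffix, equal middle
        (4, "AA", "A", (5, 1, 0)),      # right-anchored: strip suffix too
        (4, "ACGT", "ATT", (5, 2, 1)),  # complex: delete 2, insert 1
    ],
)
def test_allele_normalization(pos0, ref, alt, expected):
    assert normalize_allele_pair(pos0, ref, alt) == expected


def test_lift_pos_examples(ins_map, del_map):
    cl_i, _, _ = ins_map
    cl_d, _, _ = del_map
    assert cl_i.lift_pos(5) == 3   # first base after the insertion
    assert cl_i.lift_pos(3) == 3   # inserted base maps to next target base
    assert cl_d.lift_pos(2) == 4   # base after the deleted GT
    with pytest.raises(IndexError):
        cl_i.lift_pos(10)
    with pytest.raises(IndexError):
        cl_d.lift_pos(-1)


def test_insertion_at_contig_end_clamps():
    cl = build_contig_lift("chr1", 4, [(3, "T", "TAA")])
    assert cl.source_length == 6
    assert cl.lift_pos(5) == 3  # clamped to final target base


def test_lift_pos_monotone_and_matches_oracle():
    for seed in (1, 2, 3):
        fx = make_fixture(seed, length=4000)
        cl = build_contig_lift("chr1", 4000, fx.variants)
        lifted = cl.lift_all_positions()
        assert bool((np.diff(lifted) >= 0).all())
        assert np.array_equal(lifted, oracle_lift_all(fx.cmap))


def test_column_conservation():
    fx = make_fixture(9, length=3000)
    cl = build_contig_lift("chr1", 3000, fx.variants)
    n_ins = sum(max(0, len(a) - len(r)) for _, r, a in fx.variants)
    n_del = sum(max(0, len(r) - len(a)) for _, r, a in fx.variants)
    assert cl.n_columns == cl.target_length + n_ins
    assert cl.n_columns == cl.source_length + n_del


def test_lift_end_is_half_open():
    cl = build_contig_lift("chr1", 8, [(2, "G", "GAA")])
    # alignment ending on the last inserted base spans no extra target base
    assert cl.lift_end(5) == 3
    # ordinary end
    assert cl.lift_end(10) == 8
    with pytest.raises(IndexError):
        cl.lift_end(11)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def _vcf(tmp_path, body, contigs="##contig=<ID=chr1,length=8>\n"):
    p = tmp_path / "v.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n" + contigs +
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + body
    )
    return str(p)


def test_build_index_empty_vcf_gives_identity(tmp_path):
    idx = build_index(_vcf(tmp_path, ""))
    cl = idx.contig("chr1")
    assert cl.source_length == cl.target_length == 8
    assert idx.target_length("chr1") == 8


def test_build_index_matches_columnmap_construction(tmp_path):
    """Two independent construction paths (VCF replay vs explicit column
    splice) must produce bitwise-identical bitvectors."""
    for seed in range(4):
        fx = make_fixture(seed, length=5000)
        vp = tmp_path / f"f{seed}.vcf"
        write_vcf(fx.variants, {"chr1": 5000}, vp)
        cl = build_index(str(vp)).contig("chr1")
        sbv, tbv = fx.cmap.to_bitvecs()
        assert cl.src_bv == sbv and cl.tgt_bv == tbv


def test_multiallelic_record_uses_first_alt(tmp_path, caplog):
    with caplog.at_level(logging.WARNING, logger="liftkit"):
        idx = build_index(_vcf(tmp_path, "chr1\t3\t.\tG\tGAA,GT\t.\tPASS\t.\n"))
    cl = idx.contig("chr1")
    assert cl.source_length == 10  # the 2bp insertion of the first ALT
    assert "multi-allelic" in caplog.text


def test_overlapping_records_keep_first(tmp_path, caplog):
    body = "chr1\t2\t.\tCGT\tC\t.\tPASS\t.\nchr1\t3\t.\tG\tGAA\t.\tPASS\t.\n"
    with caplog.at_level(logging.WARNING, logger="liftkit"):
        idx = build_index(_vcf(tmp_path, body))
    cl = idx.contig("chr1")
    assert cl.source_length == 6  # only the deletion applied
    assert "overlaps" in caplog.text


def test_symbolic_and_invalid_alleles_are_skipped(tmp_path, caplog):
    body = "chr1\t2\t.\tC\t<DEL>\t.\tPASS\t.\nchr1\t5\t.\tA\tA[chr2:1[\t.\tPASS\t.\n"
    with caplog.at_level(logging.WARNING, logger="liftkit"):
        idx = build_index(_vcf(tmp_path, body))
    assert idx.contig("chr1").source_length == 8
    assert "symbolic" in caplog.text


def test_unsorted_vcf_errors(tmp_path):
    body = "chr1\t5\t.\tA\tAT\t.\tPASS\t.\nchr1\t2\t.\tC\tCA\t.\tPASS\t.\n"
    with pytest.raises(VcfOrderError):
        build_index(_vcf(tmp_path, body))


def test_missing_lengths_error_names_both_remedies(tmp_path):
    path = _vcf(tmp_path, "chr1\t3\t.\tG\tGA\t.\tPASS\t.\n", contigs="")
    with pytest.raises(LiftError, match=r"##contig.*\.fai|\.fai.*##contig"):
        build_index(path)


def test_lengths_from_fai(tmp_path):
    path = _vcf(tmp_path, "chr1\t3\t.\tG\tGA\t.\tPASS\t.\n", contigs="")
    fai = tmp_path / "ref.fa.fai"
    fai.write_text("chr1\t8\t6\t60\t61\nchr2\t5\t20\t60\t61\n")
    assert read_fai(fai) == {"chr1": 8, "chr2": 5}
    idx = build_index(path, fai=fai)
    assert idx.contig("chr1").source_length == 9
    assert idx.contig("chr2").source_length == 5  # identity, no variants


def test_contigs_without_variants_get_identity(tmp_path):
    path = _vcf(
        tmp_path, "chr1\t3\t.\tG\tGA\t.\tPASS\t.\n",
        contigs="##contig=<ID=chr1,length=8>\n##contig=<ID=chr2,length=6>\n",
    )
    idx = build_index(path)
    assert [idx.contig("chr2").lift_pos(s) for s in range(6)] == list(range(6))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_roundtrip_is_bitwise_identical(tmp_path):
    fx = make_fixture(17, length=4000)
    idx = LiftIndex(contigs={"chr1": build_contig_lift("chr1", 4000, fx.variants)})
    p = tmp_path / "x.lft"
    idx.save(p)
    idx2 = load_index(p)
    cl, cl2 = idx.contig("chr1"), idx2.contig("chr1")
    assert cl.src_bv == cl2.src_bv and cl.tgt_bv == cl2.tgt_bv
    assert idx2.name_map == idx.name_map
    lifted = cl.lift_all_positions()
    assert np.array_equal(lifted, cl2.lift_all_positions())


def test_truncated_stream_rejected(tmp_path):
    idx = LiftIndex(contigs={"chr1": build_contig_lift("chr1", 100, [])})
    buf = io.BytesIO()
    save_index(idx, buf)
    data = buf.getvalue()
    with pytest.raises(IndexFormatError, match="truncated"):
        load_index(io.BytesIO(data[: len(data) // 2]))


def test_bad_magic_rejected():
    with pytest.raises(IndexFormatError, match="magic"):
        load_index(io.BytesIO(b"NOTANIDX" + b"\x00" * 64))


def test_unsupported_version_reports_version_found():
    idx = LiftIndex(contigs={"chr1": build_contig_lift("chr1", 10, [])})
    buf = io.BytesIO()
    save_index(idx, buf)
    data = bytearray(buf.getvalue())
    data[len(MAGIC)] = 99  # bump the version field
    with pytest.raises(IndexFormatError, match="99"):
        load_index(io.BytesIO(bytes(data)))
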