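import pytest
import pysam

from liftkit import (
    LiftIndex,
    LiftOptions,
    NoTargetSpan,
    build_contig_lift,
    compute_md_nm,
    lift_cigar,
    lift_record,
    rewrite_header,
)
from liftkit.lift import M, I, D, N, S, H, query_length, reference_span
from liftkit.fixtures import (
    make_fixture,
    oracle_lift_cigar,
    simulate_reads,
    source_header,
    write_fasta,
)


# ---------------------------------------------------------------------------
# lift_cigar
# ---------------------------------------------------------------------------

def test_identity_map_leaves_alignment_unchanged(identity_map):
    for pos, cig in [(0, [(M, 8)]), (2, [(S, 3), (M, 4)]), (1, [(M, 2), (N, 3), (M, 2)])]:
        t_pos, t_cig = lift_cigar(identity_map, pos, cig)
        assert (t_pos, t_cig) == (pos, cig)


def test_read_over_insertion_gains_insertion_op(ins_map):
    cl, _, _ = ins_map
    assert lift_cigar(cl, 2, [(M, 5)]) == (2, [(M, 1), (I, 2), (M, 2)])


def test_read_over_deletion_gains_deletion_op(del_map):
    cl, _, _ = del_map
    assert lift_cigar(cl, 0, [(M, 4)]) == (0, [(M, 2), (D, 2), (M, 2)])


def test_splice_gap_absorbs_deleted_bases(del_map):
    cl, _, _ = del_map
    assert lift_cigar(cl, 0, [(M, 2), (N, 1), (M, 2)]) == (0, [(M, 2), (N, 3), (M, 2)])


def test_deletion_op_absorbs_deleted_bases(del_map):
    cl, _, _ = del_map
    # a read deletion abutting the reference deletion widens the D run
    assert lift_cigar(cl, 0, [(M, 2), (D, 1), (M, 2)]) == (0, [(M, 2), (D, 3), (M, 2)])


def test_read_inside_insertion_has_no_target_span():
    cl = build_contig_lift("chr1", 8, [(2, "G", "GAAAAA")])
    with pytest.raises(NoTargetSpan) as exc:
        lift_cigar(cl, 3, [(M, 3)])  # entirely within the AAAAA insertion
    assert exc.value.anchor == 3


def test_terminal_insertions_clip_to_soft_clips(ins_map):
    cl, _, _ = ins_map
    # alignment starting on the 2nd inserted base: leading I after conversion
    t_pos, t_cig = lift_cigar(cl, 4, [(M, 4)])
    assert t_cig[0] == (I, 1)
    t_pos2, clipped = lift_cigar(cl, 4, [(M, 4)], clip_leading_insertions=True)
    assert clipped[0] == (S, 1)
    assert t_pos == t_pos2
    assert query_length(clipped) == query_length(t_cig) == 4


def test_malformed_cigar_rejected(identity_map):
    with pytest.raises(ValueError):
        lift_cigar(identity_map, 0, [(M, 0)])
    with pytest.raises(IndexError):
        lift_cigar(identity_map, 5, [(M, 10)])


def test_lift_cigar_agrees_with_oracle_on_random_reads(random_fixture):
    fx = random_fixture
    cl = build_contig_lift("chr1", len(fx.target), fx.variants)
    _, records, truth = simulate_reads(fx.source, fx.cmap, 400, read_len=120, seed=77)
    for rec, row in zip(records, truth):
        expected = oracle_lift_cigar(fx.cmap, rec.reference_start, rec.cigartuples)
        try:
            got = lift_cigar(cl, rec.reference_start, rec.cigartuples)
        except NoTargetSpan:
            got = None
        assert got == expected
        if got is not None:
            t_pos, t_cig = got
            # query conservation and reference-span consistency
            assert query_length(t_cig) == query_length(rec.cigartuples)
            assert t_pos + reference_span(t_cig) <= cl.target_length
            s_end = rec.reference_start + reference_span(rec.cigartuples)
            assert t_pos + reference_span(t_cig) == cl.lift_end(s_end)


# ---------------------------------------------------------------------------
# lift_record
# ---------------------------------------------------------------------------

def _single(header, pos, cigar, seq, flag=0, name="chr1"):
    rec = pysam.AlignedSegment(header)
    rec.query_name = "r"
    rec.flag = flag
    rec.reference_name = name
    rec.reference_start = pos
    rec.mapping_quality = 37
    rec.cigartuples = cigar
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return rec


def _index_for(cl):
    return LiftIndex(contigs={cl.name: cl})


def test_unmapped_record_passes_through(ins_map):
    cl, _, source = ins_map
    header = source_header("chr1", len(source))
    rec = _single(header, 0, None, "ACGT", flag=0x4)
    rec.cigartuples = None
    before = rec.to_string()
    lift_record(rec, _index_for(cl))
    assert rec.to_string() == before


def test_lift_record_updates_pos_and_cigar_only(ins_map):
    cl, _, source = ins_map
    header = source_header("chr1", len(source))
    rec = _single(header, 5, [(M, 3)], source[5:8])
    lift_record(rec, _index_for(cl))
    assert rec.reference_start == 3
    assert rec.cigartuples == [(M, 3)]
    assert rec.mapping_quality == 37
    assert rec.flag == 0
    assert rec.query_name == "r"
    assert rec.query_sequence == source[5:8]


def test_insertion_only_read_flagged_unmapped(caplog):
    cl = build_contig_lift("chr1", 8, [(2, "G", "GAAAAA")])
    header = source_header("chr1", cl.source_length)
    rec = _single(header, 3, [(M, 3)], "AAA")
    lift_record(rec, _index_for(cl))
    assert rec.is_unmapped
    assert rec.reference_start == 3  # lifted anchor kept for sort stability
    assert rec.cigartuples is None


def test_unknown_contig_passes_through_with_counter():
    cl = build_contig_lift("chr1", 8, [])
    header = pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "chrX", "LN": 50}]}
    )
    rec = _single(header, 10, [(M, 4)], "ACGT", name="chrX")
    before = rec.to_string()
    from liftkit.stream import RunSummary
    summary = RunSummary()
    lift_record(rec, _index_for(cl), summary=summary)
    assert rec.to_string() == before
    assert summary.records_passed_through == 1
    assert summary.warnings == 1


def test_mate_fields_lift_consistently(del_map):
    cl, _, source = del_map
    # two 2bp mates straddling the deletion on the 6bp source
    header = source_header("chr1", len(source))
    a = _single(header, 0, [(M, 2)], source[0:2], flag=0x1 | 0x2 | 0x20 | 0x40)
    b = _single(header, 4, [(M, 2)], source[4:6], flag=0x1 | 0x2 | 0x10 | 0x80)
    for rec, mate_pos, tlen in ((a, 4, 6), (b, 0, -6)):
        rec.next_reference_id = rec.reference_id
        rec.next_reference_start = mate_pos
        rec.template_length = tlen
    idx = _index_for(cl)
    lift_record(a, idx)
    lift_record(b, idx)
    assert a.next_reference_start == b.reference_start
    assert b.next_reference_start == a.reference_start
    assert a.template_length == -b.template_length
    span = (b.reference_start + b.reference_length) - a.reference_start
    assert a.template_length == span


# ---------------------------------------------------------------------------
# MD/NM recomputation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cigar,seq,ref,md,nm",
    [
        ([(M, 5)], "ACGTA", "ACGTA", "5", 0),                 # error-free
        ([(M, 1), (I, 2), (M, 2)], "GAATA", "GTA", "3", 2),   # insertion
        ([(M, 2), (D, 2), (M, 2)], "ACAC", "ACGTAC", "2^GT2", 2),  # deletion
        ([(M, 3)], "AGG", "ACG", "1C1", 1),                   # one mismatch
        ([(M, 2)], "TT", "AC", "0A0C0", 2),                   # adjacent mismatches
        ([(M, 2), (N, 3), (M, 2)], "ACAC", "ACGGGAC", "4", 0),  # N contributes nothing
        ([(S, 2), (M, 3)], "TTACG", "ACG", "3", 0),           # soft clip skipped
        ([(M, 1), (D, 1), (M, 1)], "AG", "ACT", "1^C0T0", 2), # mismatch after deletion
    ],
)
def test_md_nm_per_base_cases(cigar, seq, ref, md, nm):
    assert compute_md_nm(cigar, seq, ref) == (md, nm)


def test_recomputed_tags_roundtrip_against_reference(tmp_path, random_fixture):
    """MD + CIGAR + read must reconstruct the exact target reference slice."""
    fx = random_fixture
    cl = build_contig_lift("chr1", len(fx.target), fx.variants)
    idx = _index_for(cl)
    write_fasta({"chr1": fx.target}, tmp_path / "t.fa")
    fa = pysam.FastaFile(str(tmp_path / "t.fa"))
    opts = LiftOptions(recompute_tags=True, target_fasta=fa)
    _, records, _ = simulate_reads(fx.source, fx.cmap, 150, read_len=100, seed=3,
                                   n_subs=2)
    checked = 0
    for rec in records:
        try:
            lift_record(rec, idx, opts)
        except NoTargetSpan:
            continue
        if rec.is_unmapped or any(op == N for op, _ in rec.cigartuples):
            continue
        # pysam reconstructs the reference from MD + CIGAR + SEQ
        assert rec.get_reference_sequence().upper() == fa.fetch(
            "chr1", rec.reference_start, rec.reference_start + rec.reference_length
        ).upper()
        checked += 1
    assert checked > 50


def test_recompute_tags_requires_fasta():
    with pytest.raises(ValueError):
        LiftOptions(recompute_tags=True)


def test_short_reference_is_reported(ins_map):
    cl, _, source = ins_map

    class ShortFasta:
        def fetch(self, contig, start, end):
            return "A"  # always too short

    header = source_header("chr1", len(source))
    rec = _single(header, 0, [(M, 3)], "ACG")
    from liftkit import recompute_tags
    with pytest.raises(ValueError, match="chr1"):
        recompute_tags(rec, ShortFasta())


# ---------------------------------------------------------------------------
# Header rewriting
# ---------------------------------------------------------------------------

def test_header_sq_lengths_become_target_lengths(ins_map):
    cl, _, _ = ins_map
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"},
         "SQ": [{"SN": "chr1", "LN": 10}, {"SN": "chrU", "LN": 99}],
         "RG": [{"ID": "rg1", "SM": "s1"}]}
    )
    out = rewrite_header(header, _index_for(cl), "liftkit lift -v v.vcf").to_dict()
    assert out["SQ"][0] == {"SN": "chr1", "LN": 8}
    assert out["SQ"][1] == {"SN": "chrU", "LN": 99}  # absent from index: kept
    assert out["RG"] == [{"ID": "rg1", "SM": "s1"}]  # preserved verbatim
    assert out["PG"][-1]["PN"] == "liftkit"
    assert out["PG"][-1]["CL"] == "liftkit lift -v v.vcf"


def test_header_pg_chain_links_previous_program():
    cl = build_contig_lift("chr1", 8, [])
    header = pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "chr1", "LN": 8}],
         "PG": [{"ID": "bwa", "PN": "bwa"}]}
    )
    out = rewrite_header(header, _index_for(cl), "cmd").to_dict()
    assert [e["ID"] for e in out["PG"]] == ["bwa", "liftkit"]
    assert out["PG"][-1]["PP"] == "bwa"
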