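import pytest

from liftkit import build_contig_lift
from liftkit.fixtures import Variant, apply_variants, make_fixture

TARGET8 = "ACGTACGT"


@pytest.fixture
def identity_map():
    """8 bp contig with no variants: every column is an aligned pair."""
    return build_contig_lift("chr1", 8, [])


@pytest.fixture
def ins_map():
    """ACGTACGT with a 2 bp insertion after the anchor G at 1-based pos 3.

    Returns (ContigLift, ColumnMap, source_seq): source is ACGAATACGT.
    """
    variants = [Variant(2, "G", "GAA")]
    cl = build_contig_lift("chr1", 8, variants)
    source, cmap = apply_variants(TARGET8, variants)
    return cl, cmap, source


@pytest.fixture
def del_map():
    """ACGTACGT with GT deleted after the anchor C at 1-based pos 2.

    Returns (ContigLift, ColumnMap, source_seq): source is ACACGT.
    """
    variants = [Variant(1, "CGT", "C")]
    cl = build_contig_lift("chr1", 8, variants)
    source, cmap = apply_variants(TARGET8, variants)
    return cl, cmap, source


@pytest.fixture(scope="session")
def random_fixture():
    """A mid-sized random scenario shared by the slower integration tests."""
    return make_fixture(seed=20240, length=8000)
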