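import pytest

from cmtriage import (
    AnnotatedVariant,
    Consequence,
    FamilyRecord,
    Genotype,
    LiteratureEvidence,
    Member,
    PhenotypeMatch,
    MissenseVerdict,
    RegionClass,
    SpliceVerdict,
    default_panel,
    load_fixture,
)

P = MissenseVerdict.PATHOGENIC
B = MissenseVerdict.BENIGN
U = MissenseVerdict.UNAVAILABLE
L = SpliceVerdict.LOSS_OR_GAIN
N = SpliceVerdict.NO_CHANGE
SU = SpliceVerdict.UNAVAILABLE


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_fixture()


def make_variant(
    gene="MFN2",
    pos=100,
    ref="A",
    alt="G",
    region=RegionClass.EXONIC,
    consequence=Consequence.NONSYNONYMOUS,
    carriers=None,
    literature=None,
    splice=(N, N, N, N, N),
    missense=(B, B, B, B),
    **kw,
):
    return AnnotatedVariant(
        gene=gene,
        chrom=gene,
        pos=pos,
        ref=ref,
        alt=alt,
        region_class=region,
        consequence=consequence,
        carriers=carriers or {"X-1": Genotype.HET},
        literature=literature or LiteratureEvidence(),
        splice_verdicts=splice,
        missense_verdicts=missense,
        **kw,
    )


def make_family(family_id="X", members=None, **kw):
    members = members or [Member("X-1", "M", affected=True)]
    return FamilyRecord(family_id, members, **kw)


@pytest.fixture
def trio():
    """Child with both genotyped parents."""
    return FamilyRecord(
        "T",
        [
            Member("T-c", "F", affected=True, father_id="T-f", mother_id="T-m"),
            Member("T-f", "M", affected=False),
            Member("T-m", "F", affected=False),
        ],
    )
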