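import random

import pytest
from hypothesis import given, settings, strategies as st

from cmtriage import (
    ClassPolicy,
    Fit,
    Genotype,
    Inheritance,
    LiteratureEvidence,
    PhenotypeMatch,
    SegregationResult,
    SpliceCall,
    Verdict,
    ZygosityContext,
    assign_class,
    classify_cohort,
    missense_consensus,
    splice_consensus,
)
from cmtriage.classifier import apply_class2_lift
from cmtriage.models import Consequence

from conftest import B, L, N, P, SU, U, make_variant, make_family
from oracle import oracle_assign_class

AD = frozenset({Inheritance.AUTOSOMAL_DOMINANT})
AR = frozenset({Inheritance.AUTOSOMAL_RECESSIVE})


def zctx(genotype=Genotype.HET, partner=None, modes=AD):
    return ZygosityContext(
        patient="X-1", gene="MFN2", genotype=genotype,
        putative_comphet_partner=partner, gene_modes=modes,
    )


SEG_FITS = SegregationResult(Verdict.FITS, 2, 0, 0)
SEG_UNINF = SegregationResult(Verdict.UNINFORMATIVE)
SEG_CONFL = SegregationResult(Verdict.CONFLICTS, 1, 1, 0)


@pytest.mark.parametrize(
    "verdicts,expected",
    [
        ((P, P, B, B), True),
        ((P, B, B, B), False),
        ((P, P, U, U), True),  # absolute count: unavailable is not benign
        ((U, U, U, U), False),
        ((), False),
    ],
)
def test_missense_consensus(verdicts, expected):
    assert missense_consensus(verdicts) is expected


@pytest.mark.parametrize(
    "verdicts,expected",
    [
        ((L, L, L, L, N), SpliceCall.SUPPORTS_PATHOGENIC),
        ((N, N, N, N, N), SpliceCall.SUPPORTS_BENIGN),
        ((L, L, L, SU, SU), SpliceCall.NEUTRAL),
        ((N, N, N, N, SU), SpliceCall.NEUTRAL),
    ],
)
def test_splice_consensus(verdicts, expected):
    assert splice_consensus(verdicts) == expected


class TestAssignClassExamples:
    def test_recessive_founder_nonsense_hom_is_certain_despite_carrier_controls(self):
        v = make_variant(
            gene="SH3TC2",
            consequence=Consequence.NONSENSE,
            missense=(U, U, U, U),
            inhouse_control_count=5,
            carriers={"X-1": Genotype.HOM},
            literature=LiteratureEvidence(
                reported_pathogenic_cases=2, phenotype_match=PhenotypeMatch.MATCH
            ),
        )
        call = assign_class(v, SEG_FITS, Fit.FITS, zctx(Genotype.HOM, modes=AR))
        assert call.pclass == 5
        assert "EXEMPT.hom_comphet" in call.rule_trace

    def test_same_codon_known_pathogenic_reaches_certain(self):
        v = make_variant(
            missense=(P, P, P, P),
            literature=LiteratureEvidence(
                same_codon_known_pathogenic=True,
                near_known_pathogenic=True,
                phenotype_match=PhenotypeMatch.MATCH,
            ),
        )
        call = assign_class(v, SEG_FITS, Fit.FITS, zctx())
        assert call.pclass == 5
        assert "C5.same_codon" in call.rule_trace

    def test_same_codon_gate_can_be_disabled(self):
        v = make_variant(
            missense=(P, P, P, P),
            literature=LiteratureEvidence(
                same_codon_known_pathogenic=True,
                near_known_pathogenic=True,
                phenotype_match=PhenotypeMatch.MATCH,
            ),
        )
        policy = ClassPolicy(allow_same_codon_as_certain=False)
        call = assign_class(v, SEG_FITS, Fit.FITS, zctx(), policy)
        assert call.pclass == 4

    def test_predicted_benign_but_near_known_is_likely(self):
        v = make_variant(
            missense=(B, B, B, B),
            literature=LiteratureEvidence(
                near_known_pathogenic=True, phenotype_match=PhenotypeMatch.MATCH
            ),
        )
        call = assign_class(v, SEG_UNINF, Fit.FITS, zctx())
        assert call.pclass == 4
        assert "C4.near_known" in call.rule_trace

    def test_common_variant_is_certainly_not_pathogenic(self):
        v = make_variant(freq_1000g=0.02)
        assert assign_class(v, SEG_UNINF, Fit.FITS, zctx()).pclass == 1

    def test_lone_het_in_recessive_only_gene_capped_at_uncertain(self):
        v = make_variant(
            gene="MTMR2",
            missense=(P, P, P, P),
            literature=LiteratureEvidence(
                reported_pathogenic_cases=2, phenotype_match=PhenotypeMatch.MATCH
            ),
        )
        # caller forcing a dominant-style fit still cannot exceed class 3
        call = assign_class(v, SEG_FITS, Fit.FITS, zctx(modes=AR))
        assert call.pclass <= 3
        assert call.capped_by_recessive_het

    def test_segregation_conflict_vetoes_pathogenic_classes(self):
        v = make_variant(
            missense=(P, P, P, P),
            literature=LiteratureEvidence(
                reported_pathogenic_cases=2, phenotype_match=PhenotypeMatch.MATCH
            ),
        )
        call = assign_class(v, SEG_CONFL, Fit.FITS, zctx())
        assert call.pclass == 2

    def test_rare_variant_without_evidence_is_uncertain(self):
        v = make_variant()
        call = assign_class(v, SEG_UNINF, Fit.FITS, zctx())
        assert call.pclass == 3
        assert "C3.rare" in call.rule_trace


def _random_bundle(rng):
    freq = lambda: rng.choice([None, None, 0.0005, 0.002, 0.005, 0.02, 0.08])
    genotype = rng.choice(["het", "het", "het", "hom", "hemi"])
    return {
        "dbsnp": freq(),
        "kg": freq(),
        "inhouse": rng.choice([0, 0, 1, 2, 3, 4, 5]),
        "genotype": genotype,
        "has_partner": genotype == "het" and rng.random() < 0.2,
        "recessive_only": rng.random() < 0.3,
        "silent": rng.random() < 0.3,
        "n_missense_path": rng.randint(0, 4),
        "n_splice_loss": rng.choice([0, 0, 0, 3, 4, 5]),
        "cases": rng.choice([0, 0, 0, 1, 2, 3]),
        "functional": rng.random() < 0.1,
        "same_codon": rng.random() < 0.1,
        "near": rng.random() < 0.2,
        "benign_reported": rng.random() < 0.1,
        "match": rng.choice(["match", "match", "mismatch", "unknown"]),
        "fit": rng.choice(["fits", "fits", "violates"]),
        "seg": rng.choice(["fits", "conflicts", "uninformative"]),
    }


def _bundle_to_engine_inputs(b):
    n_loss = b["n_splice_loss"]
    n_nochange = 5 - n_loss if not b["silent"] else (5 - n_loss)
    splice = (L,) * n_loss + (N,) * (5 - n_loss)
    n_path = b["n_missense_path"]
    missense = (P,) * n_path + (B,) * (4 - n_path)
    v = make_variant(
        consequence=Consequence.SYNONYMOUS if b["silent"] else Consequence.NONSYNONYMOUS,
        freq_dbsnp=b["dbsnp"],
        freq_1000g=b["kg"],
        inhouse_control_count=b["inhouse"],
        missense=missense,
        splice=splice,
        literature=LiteratureEvidence(
            reported_pathogenic_cases=b["cases"],
            functional_effect_shown=b["functional"],
            near_known_pathogenic=b["near"] or b["same_codon"],
            same_codon_known_pathogenic=b["same_codon"],
            reported_benign=b["benign_reported"],
            phenotype_match=PhenotypeMatch(b["match"]),
        ),
        carriers={"X-1": Genotype(b["genotype"])},
    )
    partner = ("MFN2", 999, "A", "T", "MFN2") if b["has_partner"] else None
    zyg = ZygosityContext(
        patient="X-1", gene="MFN2", genotype=Genotype(b["genotype"]),
        putative_comphet_partner=partner,
        gene_modes=AR if b["recessive_only"] else AD,
    )
    seg = {
        "fits": SEG_FITS,
        "conflicts": SEG_CONFL,
        "uninformative": SEG_UNINF,
    }[b["seg"]]
    return v, seg, Fit(b["fit"]), zyg


def test_engine_matches_bruteforce_oracle_on_random_bundles():
    """10,000 random evidence bundles: engine equals the flat-predicate oracle."""
    rng = random.Random(20140616)
    for i in range(10_000):
        b = _random_bundle(rng)
        # the oracle's splice-benign rule assumes verdicts cover all 5 tools
        v, seg, fit, zyg = _bundle_to_engine_inputs(b)
        b_oracle = dict(b)
        b_oracle["n_splice_nochange"] = 5 - b["n_splice_loss"]
        expected = oracle_assign_class(b_oracle)
        got = assign_class(v, seg, fit, zyg).pclass
        assert got == expected, (i, b, got, expected)


@settings(max_examples=200, derandomize=True)
@given(
    f1=st.one_of(st.none(), st.floats(0, 0.2)),
    f2=st.floats(0, 0.2),
    delta=st.floats(0.0001, 0.2),
)
def test_frequency_monotonicity(f1, f2, delta):
    """Raising the 1000-genomes frequency never raises the class."""
    lit = LiteratureEvidence(
        reported_pathogenic_cases=2, phenotype_match=PhenotypeMatch.MATCH
    )
    lo = make_variant(freq_dbsnp=f1, freq_1000g=f2, literature=lit)
    hi = make_variant(freq_dbsnp=f1, freq_1000g=min(1.0, f2 + delta), literature=lit)
    c_lo = assign_class(lo, SEG_UNINF, Fit.FITS, zctx()).pclass
    c_hi = assign_class(hi, SEG_UNINF, Fit.FITS, zctx()).pclass
    assert c_hi <= c_lo


@settings(max_examples=200, derandomize=True)
@given(data=st.data())
def test_adding_pathogenic_evidence_never_lowers_class(data):
    rng_bundle = {
        "cases": data.draw(st.integers(0, 2)),
        "near": data.draw(st.booleans()),
        "n_path": data.draw(st.integers(0, 4)),
    }
    lit = LiteratureEvidence(
        reported_pathogenic_cases=rng_bundle["cases"],
        near_known_pathogenic=rng_bundle["near"],
        phenotype_match=PhenotypeMatch.MATCH,
    )
    base = make_variant(
        missense=(P,) * rng_bundle["n_path"] + (B,) * (4 - rng_bundle["n_path"]),
        literature=lit,
    )
    more = make_variant(
        missense=(P,) * rng_bundle["n_path"] + (B,) * (4 - rng_bundle["n_path"]),
        literature=LiteratureEvidence(
            reported_pathogenic_cases=rng_bundle["cases"] + 1,
            near_known_pathogenic=rng_bundle["near"],
            phenotype_match=PhenotypeMatch.MATCH,
        ),
    )
    c_base = assign_class(base, SEG_UNINF, Fit.FITS, zctx()).pclass
    c_more = assign_class(more, SEG_UNINF, Fit.FITS, zctx()).pclass
    assert c_more >= c_base


def test_cap_soundness_no_lone_recessive_het_reaches_class4():
    rng = random.Random(5)
    for _ in range(2_000):
        b = _random_bundle(rng)
        b["genotype"], b["has_partner"], b["recessive_only"] = "het", False, True
        v, seg, fit, zyg = _bundle_to_engine_inputs(b)
        assert assign_class(v, seg, fit, zyg).pclass <= 3


class TestClassifyCohort:
    def test_empty_candidates_give_empty_output(self, panel):
        fam = make_family()
        assert classify_cohort({"X": []}, {"X": fam}, panel) == []

    def test_input_order_invariance(self, panel):
        fam = make_family()
        variants = [
            make_variant(gene="MFN2", pos=p,
                         literature=LiteratureEvidence(
                             reported_pathogenic_cases=p % 3,
                             phenotype_match=PhenotypeMatch.MATCH))
            for p in range(1, 8)
        ]
        a = classify_cohort({"X": variants}, {"X": fam}, panel)
        b = classify_cohort({"X": variants[::-1]}, {"X": fam}, panel)
        key = lambda c: (c.variant, c.family_id, c.pclass)
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_recurrent_class2_calls_lift_to_uncertain(self, panel):
        lit = LiteratureEvidence(phenotype_match=PhenotypeMatch.MATCH)
        fams = {
            "A": make_family("A", [__import__("cmtriage").Member("A-1", "M", True)]),
            "B": make_family("B", [__import__("cmtriage").Member("B-1", "M", True)]),
        }
        shared = dict(gene="MFN2", pos=50, freq_1000g=0.004, literature=lit)
        va = make_variant(carriers={"A-1": Genotype.HET}, **shared)
        vb = make_variant(carriers={"B-1": Genotype.HET}, **shared)
        calls = classify_cohort({"A": [va], "B": [vb]}, fams, panel)
        assert {c.pclass for c in calls} == {3}
        assert all("C3.lifted" in c.rule_trace for c in calls)
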