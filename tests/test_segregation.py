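import pytest

from cmtriage import (
    FamilyRecord,
    Fit,
    Genotype,
    Member,
    Verdict,
    ZygosityContext,
    check_segregation,
    detect_compound_het,
    inheritance_fit,
)
from cmtriage.segregation import PairStatus

from conftest import make_variant


def zctx(genotype, gene="SH3TC2", partner=None, modes=None, patient="X-1"):
    from cmtriage import Inheritance

    return ZygosityContext(
        patient=patient,
        gene=gene,
        genotype=genotype,
        putative_comphet_partner=partner,
        gene_modes=modes or frozenset({Inheritance.AUTOSOMAL_RECESSIVE}),
    )


class TestCompoundHet:
    def test_two_hets_without_parents_form_putative_pair(self, panel):
        fam = FamilyRecord("62", [Member("62-1", "M", affected=True)])
        v1 = make_variant(gene="POLG", pos=1491, carriers={"62-1": Genotype.HET})
        v2 = make_variant(gene="POLG", pos=2243, carriers={"62-1": Genotype.HET})
        pairs = detect_compound_het([v1, v2], panel.gene("POLG"), fam)
        assert len(pairs) == 1
        assert pairs[0].status == PairStatus.PUTATIVE

    def test_single_het_yields_no_pair(self, panel):
        fam = FamilyRecord("F", [Member("F-1", "M", affected=True)])
        v = make_variant(gene="POLG", carriers={"F-1": Genotype.HET})
        assert detect_compound_het([v], panel.gene("POLG"), fam) == []

    def test_hom_variants_are_not_paired(self, panel):
        fam = FamilyRecord("F", [Member("F-1", "M", affected=True)])
        v1 = make_variant(gene="SH3TC2", pos=1, carriers={"F-1": Genotype.HOM})
        v2 = make_variant(gene="SH3TC2", pos=2, carriers={"F-1": Genotype.HET})
        assert detect_compound_het([v1, v2], panel.gene("SH3TC2"), fam) == []

    def test_dominant_only_gene_yields_no_pairs(self, panel):
        fam = FamilyRecord("F", [Member("F-1", "M", affected=True)])
        v1 = make_variant(gene="MPZ", pos=1, carriers={"F-1": Genotype.HET})
        v2 = make_variant(gene="MPZ", pos=2, carriers={"F-1": Genotype.HET})
        assert detect_compound_het([v1, v2], panel.gene("MPZ"), fam) == []

    def test_cis_pair_rejected_when_mother_carries_both(self, panel, trio):
        v1 = make_variant(
            gene="SH3TC2", pos=1,
            carriers={"T-c": Genotype.HET, "T-m": Genotype.HET},
        )
        v2 = make_variant(
            gene="SH3TC2", pos=2,
            carriers={"T-c": Genotype.HET, "T-m": Genotype.HET},
        )
        assert detect_compound_het([v1, v2], panel.gene("SH3TC2"), trio) == []

    def test_trans_pair_confirmed_by_parental_origin(self, panel, trio):
        v1 = make_variant(
            gene="SH3TC2", pos=1,
            carriers={"T-c": Genotype.HET, "T-m": Genotype.HET},
        )
        v2 = make_variant(
            gene="SH3TC2", pos=2,
            carriers={"T-c": Genotype.HET, "T-f": Genotype.HET},
        )
        pairs = detect_compound_het([v1, v2], panel.gene("SH3TC2"), trio)
        assert len(pairs) == 1
        assert pairs[0].status == PairStatus.CONFIRMED_TRANS

    def test_pairs_are_order_symmetric_and_unique(self, panel):
        fam = FamilyRecord("F", [Member("F-1", "M", affected=True)])
        vs = [
            make_variant(gene="POLG", pos=p, carriers={"F-1": Genotype.HET})
            for p in (1, 2, 3)
        ]
        fwd = detect_compound_het(vs, panel.gene("POLG"), fam)
        rev = detect_compound_het(vs[::-1], panel.gene("POLG"), fam)
        assert set(fwd) == set(rev)
        assert len(fwd) == len(set(fwd)) == 3


class TestInheritanceFit:
    def test_lone_het_in_recessive_only_gene_violates(self, panel):
        fam = FamilyRecord("F", [Member("X-1", "M", affected=True)])
        v = make_variant(gene="SH3TC2")
        assert (
            inheritance_fit(v, zctx(Genotype.HET), panel.gene("SH3TC2"), fam)
            == Fit.VIOLATES
        )

    def test_hom_in_recessive_gene_fits(self, panel):
        fam = FamilyRecord("F", [Member("X-1", "M", affected=True)])
        v = make_variant(gene="SH3TC2", carriers={"X-1": Genotype.HOM})
        assert (
            inheritance_fit(v, zctx(Genotype.HOM), panel.gene("SH3TC2"), fam)
            == Fit.FITS
        )

    def test_comphet_in_recessive_gene_fits(self, panel):
        fam = FamilyRecord("F", [Member("X-1", "M", affected=True)])
        v = make_variant(gene="POLG")
        partner = ("POLG", 999, "A", "T", "POLG")
        assert (
            inheritance_fit(
                v, zctx(Genotype.HET, gene="POLG", partner=partner),
                panel.gene("POLG"), fam,
            )
            == Fit.FITS
        )

    def test_hemizygous_male_in_x_linked_gene_fits(self, panel):
        fam = FamilyRecord("F", [Member("X-1", "M", affected=True)])
        v = make_variant(gene="GJB1", carriers={"X-1": Genotype.HEMI})
        from cmtriage import Inheritance

        assert (
            inheritance_fit(
                v,
                zctx(Genotype.HEMI, gene="GJB1",
                     modes=frozenset({Inheritance.X_LINKED})),
                panel.gene("GJB1"),
                fam,
            )
            == Fit.FITS
        )

    def test_dominant_dose_monotonicity(self, panel):
        """If het fits a gene, hom fits it too."""
        fam = FamilyRecord("F", [Member("X-1", "F", affected=True)])
        for symbol in ("MPZ", "MFN2", "LMNA", "GJB1"):
            gene = panel.gene(symbol)
            v_het = make_variant(gene=symbol)
            v_hom = make_variant(gene=symbol, carriers={"X-1": Genotype.HOM})
            het_fit = inheritance_fit(
                v_het, zctx(Genotype.HET, gene=symbol, modes=gene.inheritance_modes),
                gene, fam,
            )
            hom_fit = inheritance_fit(
                v_hom, zctx(Genotype.HOM, gene=symbol, modes=gene.inheritance_modes),
                gene, fam,
            )
            if het_fit == Fit.FITS:
                assert hom_fit == Fit.FITS


class TestSegregation:
    def test_affected_carriers_unaffected_noncarrier_fits(self, panel):
        fam = FamilyRecord(
            "102",
            [
                Member("102-1", "M", affected=True),
                Member("102-2", "F", affected=True),
                Member("102-3", "F", affected=False),
            ],
        )
        v = make_variant(
            gene="HSPB1",
            carriers={"102-1": Genotype.HET, "102-2": Genotype.HET},
        )
        res = check_segregation(v, fam, panel.gene("HSPB1"))
        assert res.verdict == Verdict.FITS
        assert res.n_affected_carriers == 2
        assert res.n_unaffected_carriers == 0

    def test_unaffected_het_carriers_tolerated_in_recessive_gene(self, panel):
        members = [Member("F-1", "M", affected=True)] + [
            Member(f"F-{i}", "F", affected=False) for i in range(2, 12)
        ]
        fam = FamilyRecord("F", members)
        carriers = {"F-1": Genotype.HOM}
        carriers.update({f"F-{i}": Genotype.HET for i in range(2, 12)})
        v = make_variant(gene="SH3TC2", carriers=carriers)
        res = check_segregation(v, fam, panel.gene("SH3TC2"))
        assert res.verdict == Verdict.FITS
        assert res.n_unaffected_carriers == 10

    def test_unaffected_dominant_carrier_conflicts_when_strict(self, panel):
        fam = FamilyRecord(
            "F",
            [Member("F-1", "M", affected=True), Member("F-2", "F", affected=False)],
        )
        v = make_variant(
            gene="MPZ", carriers={"F-1": Genotype.HET, "F-2": Genotype.HET}
        )
        assert check_segregation(v, fam, panel.gene("MPZ")).verdict == Verdict.CONFLICTS
        relaxed = check_segregation(v, fam, panel.gene("MPZ"), penetrance_allowance=1)
        assert relaxed.verdict == Verdict.FITS

    def test_affected_noncarrier_conflicts(self, panel):
        fam = FamilyRecord(
            "F",
            [Member("F-1", "M", affected=True), Member("F-2", "F", affected=True)],
        )
        v = make_variant(gene="MPZ", carriers={"F-1": Genotype.HET})
        res = check_segregation(v, fam, panel.gene("MPZ"))
        assert res.verdict == Verdict.CONFLICTS
        assert res.n_affected_noncarriers == 1

    def test_single_genotyped_member_is_uninformative(self, panel):
        fam = FamilyRecord(
            "F",
            [
                Member("F-1", "M", affected=True),
                Member("F-2", "F", affected=True, genotyped=False),
            ],
        )
        v = make_variant(gene="MPZ", carriers={"F-1": Genotype.HET})
        assert (
            check_segregation(v, fam, panel.gene("MPZ")).verdict
            == Verdict.UNINFORMATIVE
        )
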