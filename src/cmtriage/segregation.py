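"""Family-genetics logic: zygosity, compound heterozygotes, segregation.

Three separable questions are answered here for a (variant, family) pair:

* compound-heterozygote detection — which unordered pairs of heterozygous
  candidate variants in the same recessive-capable gene could sit on
  opposite alleles of the index patient.  Data are unphased; a pair is
  *putative* unless parental genotypes prove the trans (confirmed) or cis
  (rejected) configuration.
* inheritance fit — whether the patient's zygosity is adequate for one of
  the gene's inheritance modes (dominant: het suffices; recessive:
  homozygous or compound het required; X-linked: hemizygous male or
  het/hom female).
* segregation — whether carrying the variant co-occurs with affection
  status among the genotyped family members.  Unaffected heterozygous
  carriers of recessive-gene variants never conflict; unaffected carriers
  under a dominant model count against a configurable penetrance
  allowance (default 0, i.e. strict).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Optional

from .models import (
    AnnotatedVariant,
    FamilyRecord,
    Genotype,
    Inheritance,
    Member,
    VariantKey,
)
from .panel import GeneRecord


class Fit(str, enum.Enum):
    FITS = "fits"
    VIOLATES = "violates"


class Verdict(str, enum.Enum):
    FITS = "fits"
    CONFLICTS = "conflicts"
    UNINFORMATIVE = "uninformative"


class PairStatus(str, enum.Enum):
    PUTATIVE = "putative"
    CONFIRMED_TRANS = "confirmed_trans"


@dataclass(frozen=True)
class CompoundHetPair:
    """Unordered pair of het variants in one gene of one patient."""

    first: VariantKey
    second: VariantKey
    status: PairStatus = PairStatus.PUTATIVE

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError("a compound-het pair needs two distinct variants")
        # canonical order so pairs compare equal regardless of input order
        if self.second < self.first:
            a, b = self.first, self.second
            object.__setattr__(self, "first", b)
            object.__setattr__(self, "second", a)

    def partner_of(self, key: VariantKey) -> Optional[VariantKey]:
        if key == self.first:
            return self.second
        if key == self.second:
            return self.first
        return None


@dataclass
class ZygosityContext:
    """Zygosity of one variant in one patient, with comphet bookkeeping."""

    patient: str
    gene: str
    genotype: Genotype
    putative_comphet_partner: Optional[VariantKey] = None
    phase_known: bool = False
    gene_modes: frozenset[Inheritance] = field(
        default_factory=lambda: frozenset({Inheritance.AUTOSOMAL_DOMINANT})
    )

    def __post_init__(self) -> None:
        if self.putative_comphet_partner is not None and self.genotype != Genotype.HET:
            raise ValueError("a compound-het partner requires a het genotype")

    @property
    def hom_or_comphet(self) -> bool:
        return self.genotype == Genotype.HOM or (
            self.genotype == Genotype.HET
            and self.putative_comphet_partner is not None
        )

    @property
    def lone_het_in_recessive_only_gene(self) -> bool:
        return (
            self.genotype == Genotype.HET
            and self.putative_comphet_partner is None
            and self.gene_modes == frozenset({Inheritance.AUTOSOMAL_RECESSIVE})
        )


@dataclass
class SegregationResult:
    verdict: Verdict
    n_affected_carriers: int = 0
    n_affected_noncarriers: int = 0
    n_unaffected_carriers: int = 0


def _cis_trans(
    v1: AnnotatedVariant,
    v2: AnnotatedVariant,
    patient: Member,
    pedigree: FamilyRecord,
) -> Optional[PairStatus]:
    """Resolve phase of two het variants from parental genotypes.

    Returns None when the pair is provably cis (both variants transmitted
    by the same parent while the other parent carries neither).
    """
    parents = []
    for pid in (patient.father_id, patient.mother_id):
        if pid is None:
            continue
        try:
            parent = pedigree.member(pid)
        except KeyError:
            continue
        if parent.genotyped:
            parents.append(parent)
    if not parents:
        return PairStatus.PUTATIVE

    def carries(parent: Member, v: AnnotatedVariant) -> bool:
        return v.genotype_of(parent.member_id) != Genotype.ABSENT

    both = [p for p in parents if carries(p, v1) and carries(p, v2)]
    if both:
        # one parent carries both variants: cis unless the other parent
        # independently carries one of them
        others = [p for p in parents if p not in both]
        if not any(carries(p, v1) or carries(p, v2) for p in others):
            return None
    if len(parents) == 2:
        p1, p2 = parents
        if (carries(p1, v1) and not carries(p1, v2) and carries(p2, v2) and not carries(p2, v1)) or (
            carries(p1, v2) and not carries(p1, v1) and carries(p2, v1) and not carries(p2, v2)
        ):
            return PairStatus.CONFIRMED_TRANS
    return PairStatus.PUTATIVE


def detect_compound_het(
    variants: list[AnnotatedVariant],
    gene: GeneRecord,
    pedigree: FamilyRecord,
    patient_id: Optional[str] = None,
) -> list[CompoundHetPair]:
    """All compatible unordered het pairs in ``gene`` for one patient.

    Homozygous variants never pair (they already satisfy the recessive
    state on their own).  Genes without a recessive mode yield no pairs.
    Pairs proven cis by parental genotypes are dropped.
    """
    if Inheritance.AUTOSOMAL_RECESSIVE not in gene.inheritance_modes:
        return []
    patient = (
        pedigree.member(patient_id) if patient_id is not None else pedigree.index_patient
    )
    hets = [
        v
        for v in variants
        if v.gene == gene.symbol and v.genotype_of(patient.member_id) == Genotype.HET
    ]
    pairs: list[CompoundHetPair] = []
    for v1, v2 in itertools.combinations(hets, 2):
        status = _cis_trans(v1, v2, patient, pedigree)
        if status is None:
            continue
        pairs.append(CompoundHetPair(v1.key, v2.key, status))
    return pairs


def inheritance_fit(
    variant: AnnotatedVariant,
    zygosity: ZygosityContext,
    gene: GeneRecord,
    pedigree: FamilyRecord,
) -> Fit:
    """Does the patient's zygosity satisfy any of the gene's modes?"""
    gt = zygosity.genotype
    if gt == Genotype.ABSENT:
        return Fit.VIOLATES
    patient = pedigree.member(zygosity.patient)
    for mode in gene.inheritance_modes:
        if mode == Inheritance.AUTOSOMAL_DOMINANT:
            if gt in (Genotype.HET, Genotype.HOM):
                return Fit.FITS
        elif mode == Inheritance.AUTOSOMAL_RECESSIVE:
            if gt == Genotype.HOM or zygosity.hom_or_comphet:
                return Fit.FITS
        elif mode == Inheritance.X_LINKED:
            if patient.sex == "M" and gt in (Genotype.HEMI, Genotype.HOM):
                return Fit.FITS
            if patient.sex == "F" and gt in (Genotype.HET, Genotype.HOM):
                return Fit.FITS
    return Fit.VIOLATES


def _segregation_mode(gene: GeneRecord, fit: Optional[Fit]) -> Inheritance:
    """Mode governing unaffected-carrier tolerance.

    Prefer a recessive reading when the gene allows one (heterozygous
    unaffected carriers are then expected and harmless); otherwise X-linked
    before dominant.
    """
    modes = gene.inheritance_modes
    if Inheritance.AUTOSOMAL_RECESSIVE in modes:
        return Inheritance.AUTOSOMAL_RECESSIVE
    if Inheritance.X_LINKED in modes:
        return Inheritance.X_LINKED
    return Inheritance.AUTOSOMAL_DOMINANT


def check_segregation(
    variant: AnnotatedVariant,
    pedigree: FamilyRecord,
    gene: GeneRecord,
    penetrance_allowance: int = 0,
) -> SegregationResult:
    """Co-segregation of a variant with affection status.

    ``fits`` iff every genotyped affected member carries the variant and no
    genotyped unaffected member carries a disease-sufficient genotype;
    ``conflicts`` as soon as a genotyped affected lacks it, or the number
    of unaffected disease-genotype carriers exceeds the penetrance
    allowance.  Fewer than two genotyped members are uninformative (this
    covers sporadic single-patient families).
    """
    members = pedigree.genotyped_members
    n_aff_car = n_aff_non = n_unaff_car = 0
    mode = _segregation_mode(gene, None)
    conflict = False
    for m in members:
        gt = variant.genotype_of(m.member_id)
        if m.affected:
            if gt == Genotype.ABSENT:
                n_aff_non += 1
                conflict = True
            else:
                n_aff_car += 1
        else:
            if gt == Genotype.ABSENT:
                continue
            n_unaff_car += 1
            if mode == Inheritance.AUTOSOMAL_RECESSIVE:
                if gt == Genotype.HOM:  # unaffected with the full recessive genotype
                    conflict = True
            elif mode == Inheritance.X_LINKED:
                if m.sex == "M" and gt in (Genotype.HEMI, Genotype.HOM):
                    conflict = True
            # dominant: counted, judged against the allowance below
    if mode == Inheritance.AUTOSOMAL_DOMINANT and n_unaff_car > penetrance_allowance:
        conflict = True
    result = SegregationResult(
        verdict=Verdict.CONFLICTS if conflict else Verdict.FITS,
        n_affected_carriers=n_aff_car,
        n_affected_noncarriers=n_aff_non,
        n_unaffected_carriers=n_unaff_car,
    )
    if len(members) < 2:
        result.verdict = Verdict.UNINFORMATIVE
    return result
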