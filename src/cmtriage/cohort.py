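"""Family-level genotype resolution and cohort prevalence summaries.

A family's finding is resolved in this order: a positive copy-number flag
(PMP22 or MPZ duplication, detected outside the sequencing pipeline) wins;
otherwise the family's highest-class point-mutation calls with class >= 4
define a point-mutation finding; class <= 3 only means no established
genotype.  Compound-heterozygous pairs in one gene count as a single
finding; when two different genes both reach class >= 4 (digenic), the
declared primary gene — or, failing a declaration, the highest-class then
alphabetically first gene — determines the family's gene category.

Dual pathology is flagged whenever one family carries candidate variants
of class >= 3 in two different genes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .models import CnvResult, FamilyRecord, InputError, Subgroup
from .panel import GeneCategory, PanelConfig
from .classifier import PathogenicityCall


class FindingStatus(str, enum.Enum):
    CNV = "cnv"
    POINT_MUTATION = "point_mutation"
    NONE = "none"


class CausalCategory(str, enum.Enum):
    CMT_GENE = "cmt_gene"
    OTHER_NEUROPATHY_GENE = "other_neuropathy_gene"
    CNV = "cnv"


@dataclass
class FamilyGenotype:
    family_id: str
    status: FindingStatus
    causal_variants: list[tuple[str, str, int]] = field(default_factory=list)
    # (gene, hgvs, pclass) per causal variant
    causal_category: Optional[CausalCategory] = None
    dual_pathology: list[tuple[str, str]] = field(default_factory=list)
    cnv_gene: Optional[str] = None

    @property
    def identified(self) -> bool:
        return self.status != FindingStatus.NONE


@dataclass
class CohortSummary:
    """Counts and fractions per neurophysiology subgroup and overall."""

    denominators: dict[Subgroup, int]
    cnv_by_subgroup: dict[Subgroup, int]
    point_by_subgroup: dict[Subgroup, int]
    point_cmt_gene: int
    point_other_gene: int
    dual_pathology_families: int
    per_gene_families: dict[str, int]
    sporadic_total: int
    sporadic_cnv: int
    sporadic_point: int

    @property
    def total_families(self) -> int:
        return sum(self.denominators.values())

    @property
    def cnv_total(self) -> int:
        return sum(self.cnv_by_subgroup.values())

    @property
    def point_total(self) -> int:
        return sum(self.point_by_subgroup.values())

    @property
    def identified_total(self) -> int:
        return self.cnv_total + self.point_total

    def identified_by_subgroup(self, subgroup: Subgroup) -> int:
        return self.cnv_by_subgroup[subgroup] + self.point_by_subgroup[subgroup]

    def fraction_identified(self, subgroup: Optional[Subgroup] = None) -> float:
        if subgroup is None:
            n, d = self.identified_total, self.total_families
        else:
            n, d = self.identified_by_subgroup(subgroup), self.denominators[subgroup]
        return n / d if d else 0.0

    def to_dict(self) -> dict:
        return {
            "denominators": {s.value: n for s, n in self.denominators.items()},
            "identified_total": self.identified_total,
            "total_families": self.total_families,
            "cnv_total": self.cnv_total,
            "point_total": self.point_total,
            "point_cmt_gene": self.point_cmt_gene,
            "point_other_gene": self.point_other_gene,
            "dual_pathology_families": self.dual_pathology_families,
            "by_subgroup": {
                s.value: {
                    "denominator": self.denominators[s],
                    "cnv": self.cnv_by_subgroup[s],
                    "point": self.point_by_subgroup[s],
                    "identified": self.identified_by_subgroup(s),
                    "fraction": self.fraction_identified(s),
                }
                for s in self.denominators
            },
            "per_gene_families": dict(sorted(self.per_gene_families.items())),
            "sporadic": {
                "total": self.sporadic_total,
                "cnv": self.sporadic_cnv,
                "point": self.sporadic_point,
                "identified": self.sporadic_cnv + self.sporadic_point,
            },
        }


def detect_dual_pathology(
    family: FamilyRecord, calls: Iterable[PathogenicityCall], min_class: int = 3
) -> list[tuple[str, str]]:
    """Unordered pairs of distinct genes each holding a call >= min_class.

    Compound-het pairs within one gene are not dual pathology.
    """
    genes = sorted(
        {c.gene for c in calls if c.family_id == family.family_id and c.pclass >= min_class}
    )
    return [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]


def resolve_family_genotype(
    family: FamilyRecord,
    calls: Iterable[PathogenicityCall],
    cnvs: Iterable[CnvResult],
    panel: PanelConfig,
    digenic_primary: Optional[Mapping[str, str]] = None,
    causal_min_class: int = 4,
) -> FamilyGenotype:
    """Resolve one family's finding from its calls and CNV flags."""
    digenic_primary = digenic_primary or {}
    fam_calls = [c for c in calls if c.family_id == family.family_id]
    dual = detect_dual_pathology(family, fam_calls)

    for cnv in cnvs:
        if cnv.family_id != family.family_id or not cnv.present:
            continue
        if cnv.gene not in panel:
            raise InputError(
                f"CNV flag for off-panel gene {cnv.gene!r} (family {family.family_id})"
            )
        return FamilyGenotype(
            family_id=family.family_id,
            status=FindingStatus.CNV,
            causal_category=CausalCategory.CNV,
            dual_pathology=dual,
            cnv_gene=cnv.gene,
        )

    causal = sorted(
        (c for c in fam_calls if c.pclass >= causal_min_class),
        key=lambda c: (-c.pclass, c.gene, c.variant),
    )
    if not causal:
        return FamilyGenotype(
            family_id=family.family_id,
            status=FindingStatus.NONE,
            dual_pathology=dual,
        )

    primary_gene = digenic_primary.get(family.family_id)
    if primary_gene is None or primary_gene not in {c.gene for c in causal}:
        primary_gene = causal[0].gene
    category = (
        CausalCategory.CMT_GENE
        if panel.gene(primary_gene).category == GeneCategory.CMT_GENE
        else CausalCategory.OTHER_NEUROPATHY_GENE
    )
    return FamilyGenotype(
        family_id=family.family_id,
        status=FindingStatus.POINT_MUTATION,
        causal_variants=[(c.gene, c.hgvs_c or c.hgvs_p, c.pclass) for c in causal],
        causal_category=category,
        dual_pathology=dual,
    )


def summarize_cohort(
    genotypes: Iterable[FamilyGenotype],
    families: Iterable[FamilyRecord],
    panel: Optional[PanelConfig] = None,
) -> CohortSummary:
    """Aggregate family genotypes into the cohort prevalence summary.

    Counting is per family: a variant shared by four families contributes
    four to its gene's tally.
    """
    families = list(families)
    by_id = {f.family_id: f for f in families}
    genotypes = list(genotypes)
    seen = {g.family_id for g in genotypes}
    missing = [f.family_id for f in families if f.family_id not in seen]
    if missing:
        raise InputError(f"families without a genotype record: {missing[:5]}")

    denominators = {s: 0 for s in Subgroup}
    for f in families:
        denominators[f.neurophysiology] += 1

    cnv_by = {s: 0 for s in Subgroup}
    point_by = {s: 0 for s in Subgroup}
    point_cmt = point_other = 0
    per_gene: dict[str, int] = {}
    dual_families = 0
    sporadic_total = sum(f.sporadic for f in families)
    sporadic_cnv = sporadic_point = 0

    for g in genotypes:
        family = by_id.get(g.family_id)
        subgroup = family.neurophysiology if family else Subgroup.UNKNOWN
        if g.dual_pathology:
            dual_families += 1
        if g.status == FindingStatus.CNV:
            cnv_by[subgroup] += 1
            if g.cnv_gene:
                per_gene[g.cnv_gene] = per_gene.get(g.cnv_gene, 0) + 1
            if family and family.sporadic:
                sporadic_cnv += 1
        elif g.status == FindingStatus.POINT_MUTATION:
            point_by[subgroup] += 1
            if g.causal_category == CausalCategory.CMT_GENE:
                point_cmt += 1
            else:
                point_other += 1
            for gene in {gene for gene, _, _ in g.causal_variants}:
                per_gene[gene] = per_gene.get(gene, 0) + 1
            if family and family.sporadic:
                sporadic_point += 1

    return CohortSummary(
        denominators=denominators,
        cnv_by_subgroup=cnv_by,
        point_by_subgroup=point_by,
        point_cmt_gene=point_cmt,
        point_other_gene=point_other,
        dual_pathology_families=dual_families,
        per_gene_families=per_gene,
        sporadic_total=sporadic_total,
        sporadic_cnv=sporadic_cnv,
        sporadic_point=sporadic_point,
    )
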