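"""The five-class pathogenicity rule engine.

Classes run from 1 (certainly not pathogenic) to 5 (certainly pathogenic).
Evaluation order, from the strongest *benign* evidence down to the default:

1. class 1 — common polymorphism: >= 1% in dbSNP or 1000 genomes, or >= 4
   carriers among the 180 in-house controls;
2. class 2 — unlikely: frequency in the 0.1-1% band, 2-3 in-house
   carriers, a silent variant with a unanimous no-splice-effect consensus,
   or a variant reported benign;
3. class 5 — certain: reported pathogenic in >= 2 unrelated cases, a shown
   functional effect, or (policy-gated) a known pathogenic mutation in the
   same codon — each additionally requiring inheritance fit, phenotype
   match, and no segregation conflict;
4. class 4 — likely: one reported case, a missense-predictor consensus
   (>= 2 of 4 pathogenic), a splice-predictor consensus (>= 4 of 5 loss or
   gain), or proximity to a known pathogenic mutation — same gates;
5. class 3 — uncertain: rare (<= 0.1%, <= 1 in-house carrier) without a
   segregation conflict;
6. otherwise class 2.

Two cross-cutting rules:

* recessive-het cap — a lone heterozygous variant in a gene with only
  recessive inheritance can never exceed class 3;
* the frequency-based benign rules (classes 1 and 2) are skipped for
  variants found homozygous or compound-heterozygous in the index patient:
  heterozygous carriers of a recessive allele in the control population do
  not argue against its pathogenicity.  (The engine would otherwise call a
  recessive founder nonsense allele, carried het by a handful of controls,
  a polymorphism.)
* lift — a class-2 call rises to class 3 when the same variant is carried
  by several unrelated affected patients with a matching phenotype
  (cohort-level pass, threshold configurable).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .models import (
    AnnotatedVariant,
    Consequence,
    EvaluationError,
    Genotype,
    MissenseVerdict,
    PhenotypeMatch,
    PROTEIN_CHANGING,
    RegionClass,
    SpliceVerdict,
    VariantKey,
)
from .panel import PanelConfig
from .segregation import (
    Fit,
    SegregationResult,
    Verdict,
    ZygosityContext,
    check_segregation,
    inheritance_fit,
)

CLASS_LABELS = {
    1: "certainly_not",
    2: "unlikely",
    3: "uncertain",
    4: "likely",
    5: "certain",
}


class SpliceCall(str, enum.Enum):
    SUPPORTS_PATHOGENIC = "supports_pathogenic"
    SUPPORTS_BENIGN = "supports_benign"
    NEUTRAL = "neutral"


@dataclass
class ClassPolicy:
    benign_freq_min: float = 0.01
    benign_controls_min: int = 4
    unlikely_freq_band: tuple[float, float] = (0.001, 0.01)  # [low, high)
    unlikely_controls_band: tuple[int, int] = (2, 3)  # inclusive
    uncertain_freq_max: float = 0.001
    uncertain_controls_max: int = 1
    missense_tools_required: int = 2  # of 4
    splice_tools_required: int = 4  # of 5
    class5_min_reported_cases: int = 2
    lift_min_similar_patients: int = 2
    allow_same_codon_as_certain: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.unlikely_freq_band
        if not (0 < lo < hi <= self.benign_freq_min):
            raise ValueError("unlikely band must be ordered below the benign cutoff")
        if self.uncertain_freq_max > lo:
            raise ValueError("uncertain cutoff must not overlap the unlikely band")


@dataclass
class PathogenicityCall:
    variant: VariantKey
    family_id: str
    pclass: int
    rule_trace: tuple[str, ...]
    capped_by_recessive_het: bool = False
    gene: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        if self.pclass not in CLASS_LABELS:
            raise ValueError(f"pclass must be 1..5, got {self.pclass}")
        if not self.rule_trace:
            raise ValueError("rule_trace must not be empty")
        if self.capped_by_recessive_het and self.pclass > 3:
            raise ValueError("a capped call cannot exceed class 3")

    @property
    def label(self) -> str:
        return CLASS_LABELS[self.pclass]


def missense_consensus(
    verdicts: Iterable[MissenseVerdict], tools_required: int = 2
) -> bool:
    """True iff enough tools call the variant pathogenic.

    The count is absolute over the four tool slots: an unavailable verdict
    never contributes.
    """
    verdicts = tuple(verdicts)
    if len(verdicts) > 4:
        raise ValueError("at most 4 missense verdicts")
    return sum(v == MissenseVerdict.PATHOGENIC for v in verdicts) >= tools_required


def splice_consensus(
    verdicts: Iterable[SpliceVerdict], tools_required: int = 4
) -> SpliceCall:
    """Consensus of the five splice predictors.

    Pathogenic support needs >= 4 of 5 loss-or-gain calls; benign support
    needs a unanimous 5/5 no-change; anything else is neutral.
    """
    verdicts = tuple(verdicts)
    if len(verdicts) > 5:
        raise ValueError("at most 5 splice verdicts")
    if sum(v == SpliceVerdict.LOSS_OR_GAIN for v in verdicts) >= tools_required:
        return SpliceCall.SUPPORTS_PATHOGENIC
    if sum(v == SpliceVerdict.NO_CHANGE for v in verdicts) == 5:
        return SpliceCall.SUPPORTS_BENIGN
    return SpliceCall.NEUTRAL


def _is_silent(variant: AnnotatedVariant) -> bool:
    if variant.consequence in PROTEIN_CHANGING:
        return False
    return variant.consequence == Consequence.SYNONYMOUS or variant.region_class in (
        RegionClass.INTRONIC_FLANK,
        RegionClass.UTR5,
        RegionClass.UTR3,
    )


def _freq_at_least(variant: AnnotatedVariant, threshold: float) -> bool:
    return any(
        f is not None and f >= threshold
        for f in (variant.freq_dbsnp, variant.freq_1000g)
    )


def _freq_in_band(variant: AnnotatedVariant, lo: float, hi: float) -> bool:
    return any(
        f is not None and lo <= f < hi
        for f in (variant.freq_dbsnp, variant.freq_1000g)
    )


def _rare(variant: AnnotatedVariant, policy: ClassPolicy, exempt: bool) -> bool:
    freq_ok = all(
        f is None or f <= policy.uncertain_freq_max
        for f in (variant.freq_dbsnp, variant.freq_1000g)
    )
    controls_ok = exempt or variant.inhouse_control_count <= policy.uncertain_controls_max
    return freq_ok and controls_ok


def assign_class(
    variant: AnnotatedVariant,
    seg: SegregationResult,
    fit: Fit,
    zygosity: ZygosityContext,
    policy: Optional[ClassPolicy] = None,
    family_id: str = "",
) -> PathogenicityCall:
    """Classify one variant in one family.  See the module docstring."""
    policy = policy or ClassPolicy()
    if variant.literature is None or seg is None:  # pragma: no cover - guarded
        raise EvaluationError("incomplete evidence bundle")
    lit = variant.literature
    trace: list[str] = []
    # recessive exemption: het carriers of a hom/comphet allele in the
    # control population do not argue for benignity -- but a variant at
    # polymorphism frequency (>= 1%) is never rescued by zygosity
    exempt = zygosity.hom_or_comphet and not _freq_at_least(
        variant, policy.benign_freq_min
    )
    if exempt:
        trace.append("EXEMPT.hom_comphet")

    pclass: Optional[int] = None

    # -- benign classes first -------------------------------------------
    if not exempt:
        if _freq_at_least(variant, policy.benign_freq_min):
            trace.append("C1.freq")
            pclass = 1
        if variant.inhouse_control_count >= policy.benign_controls_min:
            trace.append("C1.controls")
            pclass = 1
    if pclass is None:
        lo, hi = policy.unlikely_freq_band
        c_lo, c_hi = policy.unlikely_controls_band
        if not exempt and _freq_in_band(variant, lo, hi):
            trace.append("C2.freq_band")
            pclass = 2
        if not exempt and c_lo <= variant.inhouse_control_count <= c_hi:
            trace.append("C2.controls_band")
            pclass = 2
        if (
            _is_silent(variant)
            and splice_consensus(variant.splice_verdicts, policy.splice_tools_required)
            == SpliceCall.SUPPORTS_BENIGN
        ):
            trace.append("C2.splice_benign")
            pclass = 2
        if lit.reported_benign:
            trace.append("C2.reported_benign")
            pclass = 2

    # -- pathogenic classes ---------------------------------------------
    if pclass is None:
        gates_ok = (
            fit == Fit.FITS
            and lit.phenotype_match == PhenotypeMatch.MATCH
            and seg.verdict != Verdict.CONFLICTS
        )
        if gates_ok:
            strong = []
            if lit.reported_pathogenic_cases >= policy.class5_min_reported_cases:
                strong.append("C5.reported")
            if lit.functional_effect_shown:
                strong.append("C5.functional")
            if lit.same_codon_known_pathogenic and policy.allow_same_codon_as_certain:
                strong.append("C5.same_codon")
            if strong:
                trace.extend(strong)
                pclass = 5
        if pclass is None and gates_ok:
            moderate = []
            if lit.reported_pathogenic_cases >= 1:
                moderate.append("C4.reported_once")
            if missense_consensus(variant.missense_verdicts, policy.missense_tools_required):
                moderate.append("C4.missense_consensus")
            if (
                splice_consensus(variant.splice_verdicts, policy.splice_tools_required)
                == SpliceCall.SUPPORTS_PATHOGENIC
            ):
                moderate.append("C4.splice_consensus")
            if lit.near_known_pathogenic:
                moderate.append("C4.near_known")
            if moderate:
                trace.extend(moderate)
                pclass = 4

    if pclass is None:
        if _rare(variant, policy, exempt) and seg.verdict != Verdict.CONFLICTS:
            trace.append("C3.rare")
            pclass = 3
        else:
            trace.append("C2.default")
            pclass = 2

    # -- recessive-het cap ----------------------------------------------
    # a lone het in a recessive-only gene is at most uncertain; the flag is
    # set whenever the ceiling is active on a class-3 call
    capped = False
    if zygosity.lone_het_in_recessive_only_gene and pclass >= 3:
        trace.append("CAP.recessive_het")
        pclass = min(pclass, 3)
        capped = True

    return PathogenicityCall(
        variant=variant.key,
        family_id=family_id,
        pclass=pclass,
        rule_trace=tuple(trace),
        capped_by_recessive_het=capped,
        gene=variant.gene,
        hgvs_c=variant.hgvs_c,
        hgvs_p=variant.hgvs_p,
    )


def apply_class2_lift(
    calls: list[PathogenicityCall],
    variants: Mapping[VariantKey, AnnotatedVariant],
    policy: Optional[ClassPolicy] = None,
) -> list[PathogenicityCall]:
    """Cohort-level lift of recurrent class-2 calls to class 3.

    A class-2 call rises to 3 when the same variant occurs, with a
    matching phenotype, in at least ``lift_min_similar_patients`` unrelated
    families.
    """
    policy = policy or ClassPolicy()
    families_by_site: dict[VariantKey, set[str]] = {}
    for call in calls:
        v = variants.get(call.variant)
        if v is not None and v.literature.phenotype_match == PhenotypeMatch.MATCH:
            families_by_site.setdefault(call.variant, set()).add(call.family_id)
    lifted: list[PathogenicityCall] = []
    for call in calls:
        n_fam = len(families_by_site.get(call.variant, ()))
        if call.pclass == 2 and n_fam >= policy.lift_min_similar_patients:
            lifted.append(
                PathogenicityCall(
                    variant=call.variant,
                    family_id=call.family_id,
                    pclass=3,
                    rule_trace=call.rule_trace + ("C3.lifted",),
                    capped_by_recessive_het=call.capped_by_recessive_het,
                    gene=call.gene,
                    hgvs_c=call.hgvs_c,
                    hgvs_p=call.hgvs_p,
                )
            )
        else:
            lifted.append(call)
    return lifted


def classify_family(
    candidates: list[AnnotatedVariant],
    family,
    panel: PanelConfig,
    zygosity: Mapping[VariantKey, ZygosityContext],
    policy: Optional[ClassPolicy] = None,
    penetrance_allowance: int = 0,
) -> list[PathogenicityCall]:
    """Classify every candidate variant of one family's index patient."""
    policy = policy or ClassPolicy()
    calls = []
    for v in sorted(candidates, key=lambda x: x.key):
        gene = panel.gene(v.gene)
        zyg = zygosity[v.key]
        fit = inheritance_fit(v, zyg, gene, family)
        seg = check_segregation(v, family, gene, penetrance_allowance)
        calls.append(
            assign_class(v, seg, fit, zyg, policy, family_id=family.family_id)
        )
    return calls


def classify_cohort(
    candidates_by_family: Mapping[str, list[AnnotatedVariant]],
    families: Mapping[str, object],
    panel: PanelConfig,
    policy: Optional[ClassPolicy] = None,
    zygosity_by_family: Optional[Mapping[str, Mapping[VariantKey, ZygosityContext]]] = None,
    penetrance_allowance: int = 0,
) -> list[PathogenicityCall]:
    """One call per candidate per family, plus the cohort-level lift.

    Deterministic and invariant to input order: families and variants are
    processed in sorted order.
    """
    from .filtering import build_zygosity_contexts

    policy = policy or ClassPolicy()
    calls: list[PathogenicityCall] = []
    all_variants: dict[VariantKey, AnnotatedVariant] = {}
    for family_id in sorted(candidates_by_family):
        family = families[family_id]
        variants = candidates_by_family[family_id]
        if not variants:
            continue
        index = family.index_patient.member_id
        if zygosity_by_family is not None and family_id in zygosity_by_family:
            zyg = zygosity_by_family[family_id]
        else:
            zyg = build_zygosity_contexts(variants, index, panel, family)
        calls.extend(
            classify_family(variants, family, panel, zyg, policy, penetrance_allowance)
        )
        for v in variants:
            all_variants[v.key] = v
    return apply_class2_lift(calls, all_variants, policy)
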