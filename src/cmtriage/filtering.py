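"""Region restriction and the frequency / silent-variant filters.

Variants enter the analysis only from exons, the first ``region_padding_bp``
bases of the flanking introns, and the 5'/3' UTRs.  Two frequency stages
then run, mirroring the two thresholds used in practice:

* stage 1 — the coarse polymorphism screen: remove at >= 1% population
  frequency (dbSNP or 1000 genomes) or >= 4 carriers among the 180
  in-house controls;
* stage 2 — the candidate screen: remove at >= 0.1% or >= 2 in-house
  carriers.

Both stages honour the recessive exemption: a variant found homozygous, or
heterozygous with a putative compound-het partner, in the index patient is
never removed on frequency (recessive carriers circulate in the healthy
population).  A heterozygous variant qualifies as a comphet partner for
the exemption only if the other member of the pair passes the frequency
screen on its own merits; without this, any two common polymorphisms in a
recessive gene would shield each other.

Finally, synonymous, intronic-flank, and UTR variants are removed unless
the splice-predictor consensus supports a splice effect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .models import (
    AnnotatedVariant,
    ConfigurationError,
    Genotype,
    Inheritance,
    PROTEIN_CHANGING,
    RegionClass,
    VariantKey,
)
from .panel import PanelConfig
from .segregation import CompoundHetPair, ZygosityContext, detect_compound_het


class Stage(str, enum.Enum):
    STAGE1 = "stage1"
    STAGE2 = "stage2"


class Removal(str, enum.Enum):
    NONE = "none"
    REGION = "region"
    STAGE1 = "stage1"
    STAGE2_FREQ = "stage2_freq"
    STAGE2_SILENT = "stage2_silent"


class CombineRule(str, enum.Enum):
    EITHER_SOURCE_REMOVES = "either_source_removes"
    BOTH_REQUIRED = "both_required"


@dataclass
class FilterPolicy:
    stage1_freq_max: float = 0.01
    stage1_control_max: int = 4  # remove at >= 4 in-house carriers
    stage2_freq_max: float = 0.001
    stage2_control_max: int = 2  # remove at >= 2 in-house carriers
    combine_rule: CombineRule = CombineRule.EITHER_SOURCE_REMOVES
    exempt_hom_comphet: bool = True
    drop_silent_without_splice: bool = True

    def __post_init__(self) -> None:
        if self.stage2_freq_max > self.stage1_freq_max:
            raise ConfigurationError("stage2_freq_max must be <= stage1_freq_max")
        if min(self.stage1_freq_max, self.stage2_freq_max) <= 0:
            raise ConfigurationError("frequency thresholds must be positive")
        if min(self.stage1_control_max, self.stage2_control_max) <= 0:
            raise ConfigurationError("control thresholds must be positive")

    def thresholds(self, stage: Stage) -> tuple[float, int]:
        if stage == Stage.STAGE1:
            return self.stage1_freq_max, self.stage1_control_max
        if stage == Stage.STAGE2:
            return self.stage2_freq_max, self.stage2_control_max
        raise ConfigurationError(f"unknown filter stage {stage!r}")


@dataclass
class FilterOutcome:
    variant: VariantKey
    stage_removed: Removal = Removal.NONE
    exemption_applied: bool = False

    @property
    def is_candidate(self) -> bool:
        return self.stage_removed == Removal.NONE


def in_region(variant: AnnotatedVariant, panel: PanelConfig) -> bool:
    region = variant.region_class
    if region is None:
        raise ConfigurationError(f"variant {variant.key} has no region_class")
    if region == RegionClass.OUTSIDE:
        return False
    if region in (RegionClass.UTR5, RegionClass.UTR3):
        return panel.include_utr
    if region == RegionClass.INTRONIC_FLANK:
        offset = variant.intron_offset_bp
        return offset is None or offset <= panel.region_padding_bp
    return True  # exonic


def restrict_regions(
    variants: Iterable[AnnotatedVariant], panel: PanelConfig
) -> list[AnnotatedVariant]:
    """Keep exonic, UTR and near-intronic variants; drop everything else."""
    return [v for v in variants if in_region(v, panel)]


def _freq_exceeds(variant: AnnotatedVariant, threshold: float) -> bool:
    # absent frequencies never trigger a removal
    return any(
        f is not None and f >= threshold
        for f in (variant.freq_dbsnp, variant.freq_1000g)
    )


def frequency_filter(
    variant: AnnotatedVariant,
    zygosity: Optional[ZygosityContext],
    policy: FilterPolicy,
    stage: Stage,
) -> FilterOutcome:
    """One frequency stage applied to one variant."""
    freq_max, control_max = policy.thresholds(stage)
    by_freq = _freq_exceeds(variant, freq_max)
    by_controls = variant.inhouse_control_count >= control_max
    if policy.combine_rule == CombineRule.EITHER_SOURCE_REMOVES:
        hit = by_freq or by_controls
    else:
        hit = by_freq and by_controls
    if not hit:
        return FilterOutcome(variant.key)
    # The recessive exemption rescues control-count hits and sub-polymorphism
    # frequency hits; a variant at >= 1% population frequency is a
    # polymorphism regardless of zygosity and is never rescued.
    if (
        policy.exempt_hom_comphet
        and zygosity is not None
        and zygosity.hom_or_comphet
        and not _freq_exceeds(variant, policy.stage1_freq_max)
    ):
        return FilterOutcome(variant.key, exemption_applied=True)
    removal = Removal.STAGE1 if stage == Stage.STAGE1 else Removal.STAGE2_FREQ
    return FilterOutcome(variant.key, stage_removed=removal)


def _is_silent(variant: AnnotatedVariant) -> bool:
    if variant.consequence in PROTEIN_CHANGING:
        return False
    from .models import Consequence

    return variant.consequence == Consequence.SYNONYMOUS or variant.region_class in (
        RegionClass.INTRONIC_FLANK,
        RegionClass.UTR5,
        RegionClass.UTR3,
    )


def silent_filter(variant: AnnotatedVariant, policy: FilterPolicy) -> FilterOutcome:
    """Remove silent variants without splice-consensus support."""
    if not policy.drop_silent_without_splice or not _is_silent(variant):
        return FilterOutcome(variant.key)
    from .classifier import SpliceCall, splice_consensus

    if splice_consensus(variant.splice_verdicts) == SpliceCall.SUPPORTS_PATHOGENIC:
        return FilterOutcome(variant.key)
    return FilterOutcome(variant.key, stage_removed=Removal.STAGE2_SILENT)


def build_zygosity_contexts(
    variants: list[AnnotatedVariant],
    patient_id: str,
    panel: PanelConfig,
    pedigree,
    policy: Optional[FilterPolicy] = None,
) -> dict[VariantKey, ZygosityContext]:
    """Zygosity context per variant for one patient, with comphet partners.

    Partners are sought among het variants of the same recessive-capable
    gene; when a filter policy is given, a variant only serves as a partner
    if it passes both frequency stages without any exemption.
    """
    policy = policy or FilterPolicy()

    def passes_alone(v: AnnotatedVariant) -> bool:
        return not (
            _freq_exceeds(v, policy.stage1_freq_max)
            or v.inhouse_control_count >= policy.stage1_control_max
            or _freq_exceeds(v, policy.stage2_freq_max)
            or v.inhouse_control_count >= policy.stage2_control_max
        )

    contexts: dict[VariantKey, ZygosityContext] = {}
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)

    for gene_symbol, gene_variants in by_gene.items():
        gene = panel.gene(gene_symbol) if gene_symbol in panel else None
        pairs: list[CompoundHetPair] = []
        if gene is not None and Inheritance.AUTOSOMAL_RECESSIVE in gene.inheritance_modes:
            pairs = detect_compound_het(gene_variants, gene, pedigree, patient_id)
        for v in gene_variants:
            gt = v.genotype_of(patient_id)
            partner: Optional[VariantKey] = None
            if gt == Genotype.HET:
                for pair in pairs:
                    other = pair.partner_of(v.key)
                    if other is None:
                        continue
                    other_v = next(x for x in gene_variants if x.key == other)
                    if passes_alone(other_v):
                        partner = other
                        break
            contexts[v.key] = ZygosityContext(
                patient=patient_id,
                gene=gene_symbol,
                genotype=gt,
                putative_comphet_partner=partner,
                gene_modes=gene.inheritance_modes
                if gene is not None
                else frozenset({Inheritance.AUTOSOMAL_DOMINANT}),
            )
    return contexts


def candidate_pipeline(
    variants: list[AnnotatedVariant],
    zygosity: dict[VariantKey, ZygosityContext],
    policy: Optional[FilterPolicy] = None,
) -> tuple[list[AnnotatedVariant], list[FilterOutcome]]:
    """Stage 1, stage 2, then the silent filter, for one patient.

    Input variants must already be region-restricted.  Every variant gets
    exactly one outcome; candidates are the variants whose outcome is
    ``Removal.NONE``.
    """
    policy = policy or FilterPolicy()
    outcomes: list[FilterOutcome] = []
    candidates: list[AnnotatedVariant] = []
    for v in variants:
        ctx = zygosity.get(v.key)
        out = frequency_filter(v, ctx, policy, Stage.STAGE1)
        if out.is_candidate:
            exemption = out.exemption_applied
            out = frequency_filter(v, ctx, policy, Stage.STAGE2)
            out.exemption_applied = out.exemption_applied or exemption
        if out.is_candidate:
            exemption = out.exemption_applied
            out = silent_filter(v, policy)
            out.exemption_applied = exemption
        outcomes.append(out)
        if out.is_candidate:
            candidates.append(v)
    return candidates, outcomes
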