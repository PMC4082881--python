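"""Core data model for panel variant triage.

The pipeline works on annotated variant calls: each variant carries its
genomic coordinates, the region and consequence assigned by an external
annotator, population frequencies (dbSNP, 1000 genomes, ESP), a carrier
count among 180 ethnicity-matched in-house controls, pre-computed verdicts
from four missense predictors and five splice-site predictors, literature
evidence, and the genotypes observed in the sequenced family members.

Frequencies are stored as fractions in [0, 1].  An *absent* frequency
(``None``) means the variant was not observed in that database; it is never
coerced to 0, and absent values never trigger a frequency-based removal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

N_INHOUSE_CONTROLS = 180


class CmtriageError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(CmtriageError):
    """Invalid panel / policy / simulation configuration."""


class InputError(CmtriageError):
    """Malformed or mutually inconsistent input files."""


class PackagingError(CmtriageError):
    """Packaged data failed its integrity check."""


class EvaluationError(CmtriageError):
    """A rule engine was invoked with an incomplete evidence bundle."""


class RegionClass(str, enum.Enum):
    EXONIC = "exonic"
    INTRONIC_FLANK = "intronic_flank"
    UTR5 = "utr5"
    UTR3 = "utr3"
    OUTSIDE = "outside"


class Consequence(str, enum.Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    STOP_LOSS = "stop_loss"
    SPLICE_REGION = "splice_region"
    NONCODING = "noncoding"


#: consequences that can never be removed by the silent-variant filter
PROTEIN_CHANGING = frozenset(
    {
        Consequence.NONSYNONYMOUS,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.STOP_LOSS,
    }
)


class Genotype(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"
    ABSENT = "absent"


class MissenseVerdict(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNAVAILABLE = "unavailable"


class SpliceVerdict(str, enum.Enum):
    LOSS_OR_GAIN = "loss_or_gain"
    NO_CHANGE = "no_change"
    UNAVAILABLE = "unavailable"


class PhenotypeMatch(str, enum.Enum):
    MATCH = "match"
    MISMATCH = "mismatch"
    UNKNOWN = "unknown"


class Inheritance(str, enum.Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED = "x_linked"


class Subgroup(str, enum.Enum):
    """Neurophysiological subgroup of a family (median motor NCV based)."""

    CMT1 = "CMT1"
    CMT2 = "CMT2"
    ICMT = "ICMT"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class LiteratureEvidence:
    """Literature and functional evidence attached to a variant.

    ``reported_pathogenic_cases`` counts *unrelated* previously reported
    cases.  ``same_codon_known_pathogenic`` implies
    ``near_known_pathogenic`` (same codon is the strongest form of
    proximity to a known mutation).
    """

    reported_pathogenic_cases: int = 0
    functional_effect_shown: bool = False
    near_known_pathogenic: bool = False
    same_codon_known_pathogenic: bool = False
    reported_benign: bool = False
    phenotype_match: PhenotypeMatch = PhenotypeMatch.UNKNOWN

    def __post_init__(self) -> None:
        if self.reported_pathogenic_cases < 0:
            raise ValueError("reported_pathogenic_cases must be >= 0")
        if self.same_codon_known_pathogenic and not self.near_known_pathogenic:
            # same codon is a special case of proximity; keep the implication
            object.__setattr__(self, "near_known_pathogenic", True)


VariantKey = tuple[str, int, str, str, str]  # (chrom, pos, ref, alt, gene)


@dataclass
class AnnotatedVariant:
    """One ALT allele at one site, with annotations and family genotypes."""

    gene: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    region_class: Optional[RegionClass] = None
    consequence: Optional[Consequence] = None
    hgvs_c: str = ""
    hgvs_p: str = ""
    intron_offset_bp: Optional[int] = None  # distance into the intron, flank variants
    freq_dbsnp: Optional[float] = None
    freq_1000g: Optional[float] = None
    freq_esp: Optional[float] = None  # guidance only, never filtered on
    inhouse_control_count: int = 0
    missense_verdicts: tuple[MissenseVerdict, ...] = ()
    splice_verdicts: tuple[SpliceVerdict, ...] = ()
    literature: LiteratureEvidence = field(default_factory=LiteratureEvidence)
    carriers: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("freq_dbsnp", "freq_1000g", "freq_esp"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if not (0 <= self.inhouse_control_count <= N_INHOUSE_CONTROLS):
            raise ValueError(
                f"inhouse_control_count must lie in [0, {N_INHOUSE_CONTROLS}]"
            )
        if len(self.missense_verdicts) > 4:
            raise ValueError("at most 4 missense verdicts")
        if len(self.splice_verdicts) > 5:
            raise ValueError("at most 5 splice verdicts")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt, self.gene)

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype_of(self, member_id: str) -> Genotype:
        return self.carriers.get(member_id, Genotype.ABSENT)


@dataclass(frozen=True)
class Member:
    member_id: str
    sex: str  # "M" / "F"
    affected: bool
    genotyped: bool = True
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    affected_known: bool = True  # False when the PED phenotype code was 0/-9

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass
class FamilyRecord:
    """A family: its members, neurophysiology subgroup, and sporadic flag.

    A family is *sporadic* when exactly one member is affected; the flag is
    derived from the member list, never stored independently.
    """

    family_id: str
    members: list[Member]
    neurophysiology: Subgroup = Subgroup.UNKNOWN

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id} has no members")
        ids = [m.member_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate member id in family {self.family_id}")

    @property
    def sporadic(self) -> bool:
        return sum(m.affected for m in self.members) == 1

    @property
    def genotyped_members(self) -> list[Member]:
        return [m for m in self.members if m.genotyped]

    @property
    def index_patient(self) -> Member:
        """First genotyped affected member (the sequenced index case)."""
        for m in self.members:
            if m.affected and m.genotyped:
                return m
        raise InputError(f"family {self.family_id} has no genotyped affected member")

    def member(self, member_id: str) -> Member:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)


@dataclass(frozen=True)
class CnvResult:
    """Per-family copy-number result, produced outside the sequencing pipeline."""

    family_id: str
    gene: str
    event: str = "duplication"
    present: bool = False
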