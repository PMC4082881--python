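"""The packaged cohort fixture: the published 81-family study, encoded.

The fixture holds every family of the cohort (38 demyelinating / CMT1,
33 axonal / CMT2, 2 intermediate, 8 with unknown neurophysiology), the
certain and likely pathogenic point variants with their full evidence
bundles, the uncertain dual-pathology partner variants, and the per-family
PMP22/MPZ duplication flags.  Variants identified before the sequencing
study are marked ``era == "prior"``; they enter cohort aggregation exactly
like the sequencing-era findings.

Pedigree structures, the sporadic flags of families not explicitly
described, and the coordinates of partner variants whose nucleotide change
was never printed are synthetic reconstructions, chosen to be consistent
with the published marginal counts (27 sporadic families of 81; ten
unaffected heterozygous relatives across the four SH3TC2 families; ...).

File integrity is verified against SHA-256 checksums recorded in
``meta.json``.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .models import (
    AnnotatedVariant,
    CnvResult,
    Consequence,
    FamilyRecord,
    Genotype,
    LiteratureEvidence,
    Member,
    PackagingError,
    PhenotypeMatch,
    MissenseVerdict,
    RegionClass,
    SpliceVerdict,
    Subgroup,
)

_MISSENSE = {"P": MissenseVerdict.PATHOGENIC, "B": MissenseVerdict.BENIGN,
             "U": MissenseVerdict.UNAVAILABLE}
_SPLICE = {"L": SpliceVerdict.LOSS_OR_GAIN, "N": SpliceVerdict.NO_CHANGE,
           "U": SpliceVerdict.UNAVAILABLE}


@dataclass
class FixtureVariant:
    family_id: str
    era: str  # "ngs" | "prior"
    variant: AnnotatedVariant


@dataclass
class Fixture:
    families: list[FamilyRecord]
    era_by_family: dict[str, str]
    variants: list[FixtureVariant]
    cnvs: list[CnvResult]
    denominators: dict[Subgroup, int]
    digenic_primary: dict[str, str]

    @property
    def families_by_id(self) -> dict[str, FamilyRecord]:
        return {f.family_id: f for f in self.families}

    def ngs_variants(self) -> list[FixtureVariant]:
        return [fv for fv in self.variants if fv.era == "ngs"]

    def variants_by_family(self, era: Optional[str] = None) -> dict[str, list[AnnotatedVariant]]:
        out: dict[str, list[AnnotatedVariant]] = {}
        for fv in self.variants:
            if era is not None and fv.era != era:
                continue
            out.setdefault(fv.family_id, []).append(fv.variant)
        return out


def _fixture_dir():
    return resources.files("cmtriage.data") / "fixture"


def _verify_checksums(root: Path, checksums: dict[str, str]) -> None:
    for name, expected in checksums.items():
        actual = hashlib.sha256((root / name).read_bytes()).hexdigest()
        if actual != expected:
            raise PackagingError(
                f"fixture file {name} failed its checksum "
                f"(expected {expected[:12]}..., got {actual[:12]}...)"
            )


def _parse_carriers(cell: str) -> dict[str, Genotype]:
    out = {}
    for part in cell.split(";"):
        if not part:
            continue
        member, gt = part.split(":")
        out[member] = Genotype(gt)
    return out


def load_fixture() -> Fixture:
    """Load and integrity-check the packaged cohort fixture."""
    ref = _fixture_dir()
    with resources.as_file(ref) as root:
        meta = json.loads((root / "meta.json").read_text())
        _verify_checksums(root, meta["checksums"])

        era_by_family: dict[str, str] = {}
        subgroup_by_family: dict[str, Subgroup] = {}
        with open(root / "families.tsv", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                era_by_family[row["family_id"]] = row["era"]
                subgroup_by_family[row["family_id"]] = Subgroup(row["subgroup"])

        members: dict[str, list[Member]] = {}
        with open(root / "members.tsv", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                members.setdefault(row["family_id"], []).append(
                    Member(
                        member_id=row["member_id"],
                        sex=row["sex"],
                        affected=row["affected"] == "1",
                        genotyped=row["genotyped"] == "1",
                        father_id=None if row["father_id"] == "0" else row["father_id"],
                        mother_id=None if row["mother_id"] == "0" else row["mother_id"],
                    )
                )

        families = [
            FamilyRecord(
                family_id=fam,
                members=members[fam],
                neurophysiology=subgroup_by_family[fam],
            )
            for fam in subgroup_by_family
        ]

        variants: list[FixtureVariant] = []
        with open(root / "variants.tsv", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                v = AnnotatedVariant(
                    gene=row["gene"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    hgvs_c=row["hgvs_c"],
                    hgvs_p=row["hgvs_p"],
                    region_class=RegionClass(row["region_class"]),
                    consequence=Consequence(row["consequence"]),
                    freq_dbsnp=float(row["freq_dbsnp135"]) if row["freq_dbsnp135"] else None,
                    freq_1000g=float(row["freq_1000g"]) if row["freq_1000g"] else None,
                    freq_esp=float(row["freq_esp"]) if row["freq_esp"] else None,
                    inhouse_control_count=int(row["inhouse_n"]),
                    missense_verdicts=tuple(
                        _MISSENSE[t] for t in row["missense_verdicts"].split(",") if t
                    ),
                    splice_verdicts=tuple(
                        _SPLICE[t] for t in row["splice_verdicts"].split(",") if t
                    ),
                    literature=LiteratureEvidence(
                        reported_pathogenic_cases=int(row["lit_cases"]),
                        functional_effect_shown=row["lit_functional"] == "1",
                        near_known_pathogenic=row["lit_near_known"] == "1",
                        same_codon_known_pathogenic=row["lit_same_codon"] == "1",
                        reported_benign=row["lit_benign"] == "1",
                        phenotype_match=PhenotypeMatch(row["phenotype_match"]),
                    ),
                    carriers=_parse_carriers(row["carriers"]),
                )
                variants.append(FixtureVariant(row["family_id"], row["era"], v))

        cnvs: list[CnvResult] = []
        with open(root / "cnv.tsv", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                cnvs.append(
                    CnvResult(
                        family_id=row["family_id"],
                        gene=row["gene"],
                        event=row["event"],
                        present=row["present"] == "1",
                    )
                )

    denominators = {Subgroup(k): v for k, v in meta["denominators"].items()}
    observed = {s: 0 for s in Subgroup}
    for f in families:
        observed[f.neurophysiology] += 1
    if observed != denominators:
        raise PackagingError(
            f"fixture family subgroups {observed} do not match the recorded "
            f"denominators {denominators}"
        )
    return Fixture(
        families=families,
        era_by_family=era_by_family,
        variants=variants,
        cnvs=cnvs,
        denominators=denominators,
        digenic_primary=dict(meta["digenic_primary"]),
    )
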