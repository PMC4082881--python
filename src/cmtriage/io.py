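"""Readers and writers for the standard formats the pipeline touches.

VCF v4.x (multi-sample per family, read through pysam), 6-column PED with
an optional 7th neurophysiology-subgroup column, a documented annotation
TSV, and a per-family CNV flag TSV.  All coordinates are 1-based VCF
convention at every interface.

Annotation TSV header (tab-separated)::

    chrom pos ref alt gene region_class consequence intron_offset
    freq_dbsnp135 freq_1000g freq_esp inhouse_n missense_verdicts
    splice_verdicts lit_cases lit_functional lit_near_known lit_same_codon
    lit_benign phenotype_match

Empty frequency cells mean *absent* (never 0).  Verdict cells are
comma-separated tokens: ``P``/``B``/``U`` for the four missense tools,
``L``/``N``/``U`` for the five splice predictors.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import pysam

from .models import (
    AnnotatedVariant,
    CnvResult,
    Consequence,
    FamilyRecord,
    Genotype,
    InputError,
    LiteratureEvidence,
    Member,
    PhenotypeMatch,
    MissenseVerdict,
    RegionClass,
    SpliceVerdict,
    Subgroup,
)

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "region_class", "consequence",
    "intron_offset", "freq_dbsnp135", "freq_1000g", "freq_esp", "inhouse_n",
    "missense_verdicts", "splice_verdicts", "lit_cases", "lit_functional",
    "lit_near_known", "lit_same_codon", "lit_benign", "phenotype_match",
]

_MISSENSE_TOKENS = {
    "P": MissenseVerdict.PATHOGENIC,
    "B": MissenseVerdict.BENIGN,
    "U": MissenseVerdict.UNAVAILABLE,
}
_SPLICE_TOKENS = {
    "L": SpliceVerdict.LOSS_OR_GAIN,
    "N": SpliceVerdict.NO_CHANGE,
    "U": SpliceVerdict.UNAVAILABLE,
}
_MISSENSE_BACK = {v: k for k, v in _MISSENSE_TOKENS.items()}
_SPLICE_BACK = {v: k for k, v in _SPLICE_TOKENS.items()}

AnnotationKey = tuple[str, int, str, str]


def _parse_freq(cell: str, where: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError:
        raise InputError(f"bad frequency {cell!r} at {where}") from None
    if not (0.0 <= value <= 1.0):
        raise InputError(f"frequency {value} out of [0,1] at {where}")
    return value


def _parse_verdicts(cell: str, tokens: dict, where: str) -> tuple:
    cell = cell.strip()
    if cell == "":
        return ()
    out = []
    for tok in cell.split(","):
        tok = tok.strip()
        if tok not in tokens:
            raise InputError(f"unknown verdict token {tok!r} at {where}")
        out.append(tokens[tok])
    return tuple(out)


def _parse_bool(cell: str) -> bool:
    return cell.strip() in ("1", "true", "True", "yes")


def read_annotations(path: Union[str, Path]) -> dict[AnnotationKey, dict]:
    """Annotation table keyed by (chrom, pos, ref, alt) -> field dict.

    Multi-gene sites yield one entry per gene under the same key via a
    list; in practice panel genes do not overlap and each site maps to one
    record.
    """
    table: dict[AnnotationKey, list[dict]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(ANNOTATION_COLUMNS) - set(reader.fieldnames):
            missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
            raise InputError(f"annotation table missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            where = f"{path}:{i}"
            offset = row["intron_offset"].strip()
            rec = {
                "gene": row["gene"],
                "region_class": RegionClass(row["region_class"]),
                "consequence": Consequence(row["consequence"]),
                "intron_offset_bp": int(offset) if offset else None,
                "hgvs_c": row.get("hgvs_c", ""),
                "hgvs_p": row.get("hgvs_p", ""),
                "freq_dbsnp": _parse_freq(row["freq_dbsnp135"], where),
                "freq_1000g": _parse_freq(row["freq_1000g"], where),
                "freq_esp": _parse_freq(row["freq_esp"], where),
                "inhouse_control_count": int(row["inhouse_n"] or 0),
                "missense_verdicts": _parse_verdicts(
                    row["missense_verdicts"], _MISSENSE_TOKENS, where
                ),
                "splice_verdicts": _parse_verdicts(
                    row["splice_verdicts"], _SPLICE_TOKENS, where
                ),
                "literature": LiteratureEvidence(
                    reported_pathogenic_cases=int(row["lit_cases"] or 0),
                    functional_effect_shown=_parse_bool(row["lit_functional"]),
                    near_known_pathogenic=_parse_bool(row["lit_near_known"]),
                    same_codon_known_pathogenic=_parse_bool(row["lit_same_codon"]),
                    reported_benign=_parse_bool(row["lit_benign"]),
                    phenotype_match=PhenotypeMatch(row["phenotype_match"] or "unknown"),
                ),
            }
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            table.setdefault(key, []).append(rec)
    return table


def write_annotations(
    variants: Iterable[AnnotatedVariant], path: Union[str, Path]
) -> None:
    seen: set[tuple] = set()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS + ["hgvs_c", "hgvs_p"])
        for v in sorted(variants, key=lambda x: x.key):
            if v.key in seen:
                continue
            seen.add(v.key)
            lit = v.literature
            writer.writerow(
                [
                    v.chrom, v.pos, v.ref, v.alt, v.gene,
                    v.region_class.value, v.consequence.value,
                    "" if v.intron_offset_bp is None else v.intron_offset_bp,
                    "" if v.freq_dbsnp is None else repr(v.freq_dbsnp),
                    "" if v.freq_1000g is None else repr(v.freq_1000g),
                    "" if v.freq_esp is None else repr(v.freq_esp),
                    v.inhouse_control_count,
                    ",".join(_MISSENSE_BACK[m] for m in v.missense_verdicts),
                    ",".join(_SPLICE_BACK[s] for s in v.splice_verdicts),
                    lit.reported_pathogenic_cases,
                    int(lit.functional_effect_shown),
                    int(lit.near_known_pathogenic),
                    int(lit.same_codon_known_pathogenic),
                    int(lit.reported_benign),
                    lit.phenotype_match.value,
                    v.hgvs_c, v.hgvs_p,
                ]
            )


def annotate_variants(
    variants: Iterable[AnnotatedVariant], annotations: dict[AnnotationKey, list[dict]]
) -> list[AnnotatedVariant]:
    """Attach annotation fields to bare VCF calls; unannotated calls are
    skipped with a warning."""
    out = []
    n_missing = 0
    for v in variants:
        recs = annotations.get(v.site)
        if not recs:
            n_missing += 1
            continue
        for rec in recs:
            out.append(
                AnnotatedVariant(
                    gene=rec["gene"],
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    region_class=rec["region_class"],
                    consequence=rec["consequence"],
                    hgvs_c=rec.get("hgvs_c", ""),
                    hgvs_p=rec.get("hgvs_p", ""),
                    intron_offset_bp=rec["intron_offset_bp"],
                    freq_dbsnp=rec["freq_dbsnp"],
                    freq_1000g=rec["freq_1000g"],
                    freq_esp=rec["freq_esp"],
                    inhouse_control_count=rec["inhouse_control_count"],
                    missense_verdicts=rec["missense_verdicts"],
                    splice_verdicts=rec["splice_verdicts"],
                    literature=rec["literature"],
                    carriers=dict(v.carriers),
                )
            )
    if n_missing:
        logger.warning("%d VCF calls without annotation were skipped", n_missing)
    return out


def read_vcf_cohort(
    vcf_path: Union[str, Path], pedigree: FamilyRecord
) -> list[AnnotatedVariant]:
    """Read a family VCF into per-ALT variant calls with carrier maps.

    Multi-allelic records are decomposed into one call per ALT allele.
    Genotype mapping per sample and ALT index i: missing or 0/0 -> absent,
    one copy of i -> het, two copies -> hom, haploid i in a male -> hemi.
    Malformed records are skipped with a warning.
    """
    members = {m.member_id: m for m in pedigree.members}
    calls: list[AnnotatedVariant] = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = set(samples) - set(members)
        if unknown:
            raise InputError(
                f"VCF samples {sorted(unknown)} not in family {pedigree.family_id}"
            )
        for rec in vcf:
            try:
                alts = rec.alts or ()
                for i, alt in enumerate(alts, start=1):
                    if alt is None:
                        continue
                    carriers: dict[str, Genotype] = {}
                    for sample in samples:
                        gt = rec.samples[sample].get("GT")
                        if gt is None or all(a is None for a in gt):
                            continue
                        dose = sum(1 for a in gt if a == i)
                        if dose == 0:
                            continue
                        if len(gt) == 1:
                            carriers[sample] = (
                                Genotype.HEMI
                                if members[sample].sex == "M"
                                else Genotype.HOM
                            )
                        elif dose >= 2:
                            carriers[sample] = Genotype.HOM
                        else:
                            carriers[sample] = Genotype.HET
                    calls.append(
                        AnnotatedVariant(
                            gene="",
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            carriers=carriers,
                        )
                    )
            except Exception as exc:  # malformed record: skip, keep count
                n_skipped += 1
                warnings.warn(f"skipping malformed VCF record at {rec.chrom}:{rec.pos}: {exc}")
    if n_skipped:
        logger.warning("skipped %d malformed VCF records in %s", n_skipped, vcf_path)
    return calls


def write_vcf(
    family: FamilyRecord,
    variants: Iterable[AnnotatedVariant],
    path: Union[str, Path],
    contigs: Optional[Iterable[str]] = None,
) -> None:
    """Write one family's calls as a plain multi-sample VCF."""
    samples = [m.member_id for m in family.genotyped_members]
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    if contigs is None:
        contigs = sorted({v.chrom for v in variants})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length=2000000>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    gt_strings = {
        Genotype.ABSENT: "0/0",
        Genotype.HET: "0/1",
        Genotype.HOM: "1/1",
        Genotype.HEMI: "1",
    }
    for v in variants:
        row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", "."]
        row.append("GT")
        for s in samples:
            row.append(gt_strings[v.genotype_of(s)])
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


_SUBGROUP_TOKENS = {s.value: s for s in Subgroup}


def read_ped(path: Union[str, Path]) -> list[FamilyRecord]:
    """Standard 6-column PED, optional 7th column = neurophysiology subgroup.

    Affection: 2 -> affected, 1 -> unaffected, 0/-9 -> unknown (treated as
    unaffected for segregation but flagged).  An 8th optional column with
    value ``0`` marks an ungenotyped member.
    """
    per_family: dict[str, list[Member]] = {}
    subgroups: dict[str, Subgroup] = {}
    member_owner: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise InputError(f"{path}:{lineno}: expected >= 6 PED columns")
            fam, member, father, mother, sex, pheno = cols[:6]
            if member in member_owner and member_owner[member] != fam:
                raise InputError(
                    f"{path}:{lineno}: member {member!r} listed in two families"
                )
            member_owner[member] = fam
            affected_known = pheno in ("1", "2")
            per_family.setdefault(fam, []).append(
                Member(
                    member_id=member,
                    sex="M" if sex == "1" else "F",
                    affected=pheno == "2",
                    genotyped=not (len(cols) >= 8 and cols[7] == "0"),
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    affected_known=affected_known,
                )
            )
            if len(cols) >= 7 and cols[6] in _SUBGROUP_TOKENS:
                subgroups[fam] = _SUBGROUP_TOKENS[cols[6]]
    return [
        FamilyRecord(
            family_id=fam,
            members=members,
            neurophysiology=subgroups.get(fam, Subgroup.UNKNOWN),
        )
        for fam, members in per_family.items()
    ]


def write_ped(families: Iterable[FamilyRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for f in sorted(families, key=lambda x: x.family_id):
            for m in f.members:
                fh.write(
                    "\t".join(
                        [
                            f.family_id,
                            m.member_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            "1" if m.sex == "M" else "2",
                            "2" if m.affected else ("1" if m.affected_known else "0"),
                            f.neurophysiology.value,
                            "1" if m.genotyped else "0",
                        ]
                    )
                    + "\n"
                )


def read_cnv(path: Union[str, Path]) -> list[CnvResult]:
    """CNV flag TSV: family_id, gene, event, present."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"family_id", "gene", "event", "present"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise InputError(f"CNV table must have columns {sorted(required)}")
        for row in reader:
            out.append(
                CnvResult(
                    family_id=row["family_id"],
                    gene=row["gene"],
                    event=row["event"],
                    present=_parse_bool(row["present"]),
                )
            )
    return out


def write_cnv(cnvs: Iterable[CnvResult], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["family_id", "gene", "event", "present"])
        for c in sorted(cnvs, key=lambda x: (x.family_id, x.gene)):
            writer.writerow([c.family_id, c.gene, c.event, int(c.present)])
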