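"""End-to-end orchestration: region -> filter -> segregation -> classify ->
aggregate, plus the fixture analysis used to reproduce the published
cohort arithmetic.

``run_pipeline`` is the file-based entry point (VCF directory, PED,
annotation TSV, CNV TSV); ``analyze_cohort`` is the in-memory equivalent
that the simulator and the fixture share.  Both return the per-variant
filter outcomes, the pathogenicity calls, the family genotypes, and the
cohort summary; file runs also produce a manifest (input checksums,
policy snapshots, per-stage counts) so a run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

from . import __version__
from . import io as vio
from .classifier import ClassPolicy, PathogenicityCall, classify_cohort
from .cohort import (
    CohortSummary,
    FamilyGenotype,
    resolve_family_genotype,
    summarize_cohort,
)
from .filtering import (
    FilterOutcome,
    FilterPolicy,
    Removal,
    build_zygosity_contexts,
    candidate_pipeline,
    in_region,
)
from .fixture import Fixture, load_fixture
from .models import AnnotatedVariant, CnvResult, FamilyRecord, InputError
from .panel import PanelConfig, default_panel

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    filter_policy: dict = field(default_factory=dict)
    class_policy: dict = field(default_factory=dict)
    seed: Optional[int] = None
    version: str = __version__
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    outcomes: dict[str, list[FilterOutcome]]  # per family
    calls: list[PathogenicityCall]
    genotypes: list[FamilyGenotype]
    summary: CohortSummary
    manifest: RunManifest
    candidates_by_family: dict[str, list[AnnotatedVariant]] = field(
        default_factory=dict
    )


def _sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _policy_dict(policy) -> dict:
    out = {}
    for f in dataclasses.fields(policy):
        value = getattr(policy, f.name)
        out[f.name] = value.value if hasattr(value, "value") else value
    return out


def analyze_cohort(
    variants_by_family: Mapping[str, list[AnnotatedVariant]],
    families: list[FamilyRecord],
    cnvs: list[CnvResult],
    panel: Optional[PanelConfig] = None,
    filter_policy: Optional[FilterPolicy] = None,
    class_policy: Optional[ClassPolicy] = None,
    digenic_primary: Optional[Mapping[str, str]] = None,
    penetrance_allowance: int = 0,
    skip_filters: bool = False,
) -> PipelineResult:
    """Run the full in-memory analysis over a cohort.

    ``skip_filters`` treats the provided variants as candidates already
    (used for the packaged fixture, which encodes candidate variants).
    """
    panel = panel or default_panel()
    filter_policy = filter_policy or FilterPolicy()
    class_policy = class_policy or ClassPolicy()
    by_id = {f.family_id: f for f in families}

    outcomes: dict[str, list[FilterOutcome]] = {}
    candidates_by_family: dict[str, list[AnnotatedVariant]] = {}
    zygosity_by_family = {}
    n_input = n_region = n_candidates = 0

    for family_id in sorted(variants_by_family):
        family = by_id[family_id]
        variants = variants_by_family[family_id]
        n_input += len(variants)
        index = family.index_patient.member_id
        in_panel_region = [v for v in variants if in_region(v, panel)]
        region_outcomes = [
            FilterOutcome(v.key, stage_removed=Removal.REGION)
            for v in variants
            if not in_region(v, panel)
        ]
        n_region += len(in_panel_region)
        zygosity = build_zygosity_contexts(
            in_panel_region, index, panel, family, filter_policy
        )
        if skip_filters:
            candidates, fam_outcomes = in_panel_region, [
                FilterOutcome(v.key) for v in in_panel_region
            ]
        else:
            candidates, fam_outcomes = candidate_pipeline(
                in_panel_region, zygosity, filter_policy
            )
        outcomes[family_id] = region_outcomes + fam_outcomes
        candidates_by_family[family_id] = candidates
        zygosity_by_family[family_id] = zygosity
        n_candidates += len(candidates)

    calls = classify_cohort(
        candidates_by_family,
        by_id,
        panel,
        class_policy,
        zygosity_by_family=zygosity_by_family,
        penetrance_allowance=penetrance_allowance,
    )
    genotypes = [
        resolve_family_genotype(
            f, calls, cnvs, panel, digenic_primary=digenic_primary
        )
        for f in families
    ]
    summary = summarize_cohort(genotypes, families, panel)
    manifest = RunManifest(
        filter_policy=_policy_dict(filter_policy),
        class_policy=_policy_dict(class_policy),
        stage_counts={
            "input_variants": n_input,
            "region_restricted": n_region,
            "candidates": n_candidates,
            "calls": len(calls),
            "families": len(families),
        },
    )
    logger.info("pipeline: %s", manifest.stage_counts)
    return PipelineResult(
        outcomes=outcomes,
        calls=calls,
        genotypes=genotypes,
        summary=summary,
        manifest=manifest,
        candidates_by_family=candidates_by_family,
    )


def run_pipeline(
    vcf_dir: Union[str, Path],
    ped: Union[str, Path],
    annotations: Union[str, Path],
    cnv: Optional[Union[str, Path]] = None,
    panel: Optional[PanelConfig] = None,
    filter_policy: Optional[FilterPolicy] = None,
    class_policy: Optional[ClassPolicy] = None,
    out_dir: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """File-based pipeline run.

    ``vcf_dir`` holds one ``<family_id>.vcf`` per family.  Raises
    :class:`InputError` (with the failing stage in the message) on
    mutually inconsistent inputs.
    """
    panel = panel or default_panel()
    families = vio.read_ped(ped)
    ann = vio.read_annotations(annotations)
    cnvs = vio.read_cnv(cnv) if cnv else []

    variants_by_family: dict[str, list[AnnotatedVariant]] = {}
    vcf_dir = Path(vcf_dir)
    for family in families:
        vcf_path = vcf_dir / f"{family.family_id}.vcf"
        if not vcf_path.exists():
            raise InputError(f"stage read_vcf: no VCF for family {family.family_id}")
        try:
            calls = vio.read_vcf_cohort(vcf_path, family)
        except InputError as exc:
            raise InputError(f"stage read_vcf: {exc}") from exc
        variants_by_family[family.family_id] = vio.annotate_variants(calls, ann)

    result = analyze_cohort(
        variants_by_family,
        families,
        cnvs,
        panel=panel,
        filter_policy=filter_policy,
        class_policy=class_policy,
    )
    result.manifest.seed = seed
    result.manifest.inputs = {
        str(ped): _sha256(ped),
        str(annotations): _sha256(annotations),
        **({str(cnv): _sha256(cnv)} if cnv else {}),
    }
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: Union[str, Path]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "outcomes.tsv", "w") as fh:
        fh.write("family_id\tchrom\tpos\tref\talt\tgene\tstage_removed\texemption\n")
        for fam in sorted(result.outcomes):
            for o in result.outcomes[fam]:
                chrom, pos, ref, alt, gene = o.variant
                fh.write(
                    f"{fam}\t{chrom}\t{pos}\t{ref}\t{alt}\t{gene}\t"
                    f"{o.stage_removed.value}\t{int(o.exemption_applied)}\n"
                )
    with open(out / "calls.tsv", "w") as fh:
        fh.write("family_id\tgene\thgvs_c\thgvs_p\tpclass\tlabel\trule_trace\tcapped\n")
        for c in result.calls:
            fh.write(
                f"{c.family_id}\t{c.gene}\t{c.hgvs_c}\t{c.hgvs_p}\t{c.pclass}\t"
                f"{c.label}\t{';'.join(c.rule_trace)}\t{int(c.capped_by_recessive_het)}\n"
            )
    with open(out / "family_genotypes.tsv", "w") as fh:
        fh.write("family_id\tstatus\tcategory\tcausal\tdual_pathology\n")
        for g in result.genotypes:
            causal = ";".join(f"{gene}:{hgvs}:{p}" for gene, hgvs, p in g.causal_variants)
            dual = ";".join(f"{a}+{b}" for a, b in g.dual_pathology)
            fh.write(
                f"{g.family_id}\t{g.status.value}\t"
                f"{g.causal_category.value if g.causal_category else ''}\t{causal}\t{dual}\n"
            )
    (out / "summary.json").write_text(
        json.dumps(result.summary.to_dict(), indent=2) + "\n"
    )
    (out / "manifest.json").write_text(result.manifest.to_json() + "\n")


def analyze_fixture(
    fixture: Optional[Fixture] = None,
    panel: Optional[PanelConfig] = None,
    class_policy: Optional[ClassPolicy] = None,
) -> PipelineResult:
    """Classify and aggregate the packaged published cohort.

    The fixture's variants are the study's candidate variants, so the
    frequency filters are not re-applied; classification, family-genotype
    resolution, dual-pathology detection and the prevalence summary are
    all recomputed from the encoded evidence.
    """
    fixture = fixture or load_fixture()
    return analyze_cohort(
        fixture.variants_by_family(),
        fixture.families,
        fixture.cnvs,
        panel=panel,
        class_policy=class_policy,
        digenic_primary=fixture.digenic_primary,
        skip_filters=True,
    )


def export_fixture(out_dir: Union[str, Path], fixture: Optional[Fixture] = None) -> dict:
    """Write the packaged fixture as standard pipeline input files."""
    fixture = fixture or load_fixture()
    panel = default_panel()
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    by_family = fixture.variants_by_family()
    contigs = panel.symbols()
    for family in fixture.families:
        vio.write_vcf(
            family, by_family.get(family.family_id, []),
            out / "vcf" / f"{family.family_id}.vcf", contigs=contigs,
        )
    vio.write_ped(fixture.families, out / "cohort.ped")
    all_variants = [fv.variant for fv in fixture.variants]
    vio.write_annotations(all_variants, out / "annotations.tsv")
    vio.write_cnv(fixture.cnvs, out / "cnv.tsv")
    return {
        "vcf_dir": out / "vcf",
        "ped": out / "cohort.ped",
        "annotations": out / "annotations.tsv",
        "cnv": out / "cnv.tsv",
    }
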