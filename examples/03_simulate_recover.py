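"""Simulate a cohort, run the full pipeline, and measure truth recovery.

Generates a synthetic 59-family cohort (70 sequenced patients, ~202
panel-region variants each), applies region restriction, both frequency
stages, the silent-variant filter, classification and family-genotype
resolution, then compares everything against the generator's planted
truth.
"""

import numpy as np

from cmtriage import Genotype, SimConfig, analyze_cohort, generate_cohort
from cmtriage.filtering import Removal

cohort = generate_cohort(SimConfig(seed=1))
result = analyze_cohort(
    cohort.variants_by_family, cohort.families, cohort.cnvs, panel=cohort.panel
)

calls = {(c.family_id, c.variant): c.pclass for c in result.calls}
statuses = {g.family_id: g.status.value for g in result.genotypes}
n_variants = n_variant_hits = n_family_hits = 0
for fam_id, truth in cohort.truth.by_family.items():
    n_family_hits += statuses[fam_id] == truth.expected_status
    for pv in truth.planted:
        n_variants += 1
        n_variant_hits += calls.get((fam_id, tuple(pv.key))) == pv.planted_class

survivors = []
for fam_id, patient in cohort.patients:
    keys = {
        v.key
        for v in cohort.variants_by_family[fam_id]
        if v.genotype_of(patient) != Genotype.ABSENT
    }
    survivors.append(
        sum(
            1
            for o in result.outcomes[fam_id]
            if o.variant in keys
            and o.stage_removed not in (Removal.REGION, Removal.STAGE1)
        )
    )

print(f"families: {len(cohort.families)}; sequenced patients: {len(cohort.patients)}")
print(f"planted variant classes recovered: {n_variant_hits}/{n_variants}")
print(f"family genotypes recovered: {n_family_hits}/{len(cohort.families)}")
print(f"variants per patient after the 1%-polymorphism screen: "
      f"mean {np.mean(survivors):.1f} (min {min(survivors)}, max {max(survivors)})")
# Full recovery is expected: the generator plants evidence bundles that
# satisfy exactly one class and the default pipeline has no noise knobs on.
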