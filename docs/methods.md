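# Methods

## Scope and model

`cmtriage` implements the interpretation half of a targeted-sequencing
diagnostic workflow for inherited neuropathies. It consumes variant calls
and *pre-computed* annotations — population frequencies, in-house control
carrier counts, in-silico predictor verdicts, literature evidence — and
produces per-variant pathogenicity classes, per-family causal genotypes,
and cohort prevalence tables. Alignment, variant calling, annotation
computation, and copy-number detection are out of scope; duplications
(PMP22, MPZ) enter only as per-family flags because they are detected by
qPCR/MLPA, not by short-read panel sequencing.

## The panel

The default panel holds 51 genes, each with a reference transcript, its
neuropathy phenotypes, and curated inheritance modes. A gene is a *CMT
gene* when its phenotype set intersects the CMT spectrum (CMT1, CMT2,
CMT4, CMTX, intermediate CMT, Dejerine-Sottas, HNPP); all other genes
(dHMN, HSAN, HNA, CCFDN, PCWH, slow-NCV, CMT-associated) are
*other-neuropathy genes*. Two borderline genes carry explicit category
overrides in the shipped config: GAN (giant axonal neuropathy) and
SLC12A6 (ACCPN) cause severe hereditary motor-and-sensory neuropathies
conventionally counted within the CMT spectrum; with these overrides the
default panel splits 32 CMT / 19 other. The mapping is data, not code —
users can re-map any gene via `category_override`.

Inheritance modes are not printed in panel configs of record; they are
curated per gene from clinical genetics practice (e.g. SH3TC2, MTMR2, GAN
recessive-only; GJB1, PRPS1, ATP7A X-linked; MFN2, LMNA, SETX, GDAP1,
EGR2, NEFL dominant-and-recessive; POLG recessive in its neuropathy
presentation). These assignments drive the inheritance-fit check and the
recessive-het cap and are the package's own curation.

## Filtering

Regions: exonic, 5'/3' UTR, and intronic positions within
`region_padding_bp` (default 10) of an exon are analysed; everything else
is dropped.

Two frequency stages run in sequence, reflecting the two thresholds such
studies use:

| stage | frequency cutoff | in-house controls | role |
|---|---|---|---|
| 1 | ≥ 1% (dbSNP or 1000 genomes) | ≥ 4 of 180 | polymorphism screen |
| 2 | ≥ 0.1% | ≥ 2 of 180 | candidate screen |

Either evidence source alone removes (`either_source_removes`, default;
`both_required` is provided for sensitivity analysis). An *absent*
frequency is never coerced to zero and never removes: an unobserved
variant is a candidate by definition. ESP frequencies are carried for
reporting but excluded from all automated rules, since that resource mixes
affected and control individuals.

**Recessive exemption.** A variant observed homozygous — or heterozygous
with a putative compound-het partner — in the index patient is not removed
by control counts or by sub-polymorphism frequency: heterozygous carriers
of a recessive allele circulate in any healthy control panel (a recessive
founder nonsense allele may legitimately show several in-house carriers).
The exemption deliberately stops at the 1% polymorphism line: a variant at
polymorphism frequency is benign regardless of zygosity, and without this
bound any two common variants in one recessive gene would shield each
other from the filter. A heterozygous variant counts as a comphet partner
for the exemption only if it passes both frequency stages on its own.

Finally, synonymous, intronic-flank and UTR variants are removed unless
the splice-predictor consensus (≥ 4 of 5 loss-or-gain) supports an effect.

## Family genetics

Compound-het detection pairs heterozygous candidates within one
recessive-capable gene of one patient. Data are unphased: pairs are
*putative* by default, *confirmed-in-trans* when genotyped parents show the
two variants arriving on different alleles, and rejected when one parent
demonstrably carries both (cis). Putative pairs count for the filter
exemption and the recessive fit — the practice such studies follow when
parental DNA is unavailable.

Segregation asks a narrower question than inheritance fit: does *carrying*
the variant co-occur with affection among genotyped members? Every
genotyped affected must carry it; unaffected heterozygous carriers in
recessive or X-linked genes are expected and never conflict; unaffected
carriers under a dominant reading count against a penetrance allowance
(default 0, strict — late-onset nonpenetrance is handled by raising the
allowance, a judgement call the package exposes rather than hard-codes).
Fewer than two genotyped members is uninformative, which covers sporadic
single-patient families; their classification then rests on the other
criteria. Zygosity adequacy (hom/comphet for recessive genes, hemizygous
male for X-linked) is assessed separately as *inheritance fit*.

## The five-class rule engine

Classes: 1 certainly not, 2 unlikely, 3 uncertain, 4 likely, 5 certainly
pathogenic. Evaluation order is benign-first, then strongest pathogenic
evidence, then the rare-variant default:

1. **class 1** — ≥ 1% frequency or ≥ 4 in-house controls;
2. **class 2** — frequency in [0.1%, 1%), 2–3 controls, a silent variant
   with a unanimous 5/5 no-splice-effect consensus, or reported benign;
3. **class 5** — ≥ 2 unrelated reported cases, a demonstrated functional
   effect, or (policy-gated, default on) a known pathogenic mutation in
   the same codon;
4. **class 4** — ≥ 1 reported case, ≥ 2/4 missense-predictor consensus,
   ≥ 4/5 splice consensus, or proximity to a known pathogenic mutation;
5. **class 3** — rare (≤ 0.1%, ≤ 1 control) without a segregation
   conflict; otherwise class 2.

Classes 4 and 5 additionally require inheritance fit, a phenotype match
with the published genotype-phenotype correlations, and no segregation
conflict; a conflict demotes to class 2. Predictor consensus counts are
absolute over the tool slots — an unavailable verdict never counts toward
either side. The same-codon gate exists because a novel substitution at a
codon with an established pathogenic change is treated as certain in
practice even with no case report of the exact allele; the gate is
recorded in the rule trace and can be disabled.

Cross-cutting rules: the classifier honours the same recessive exemption
as the filter (frequency/control benign rules are skipped for hom/comphet
variants below the 1% line); a lone heterozygous variant in a
recessive-only gene is capped at class 3 and flagged; and a cohort-level
*lift* raises a class-2 call to 3 when the same variant occurs with a
matching phenotype in ≥ 2 unrelated families (configurable).

The ordering of rule evaluation (benign before pathogenic, 5 before 4
before 3) is a design choice the published criteria leave implicit; it is
what reproduces the published per-variant calls, and every call carries an
ordered trace of the criteria that fired, so any decision can be audited.

## Cohort aggregation

A family's genotype resolves as: duplication flag → CNV; otherwise the
highest-class calls with class ≥ 4 → point mutation; otherwise none.
Compound-het pairs in one gene are one finding. When two genes both reach
class ≥ 4 (digenic), a declared primary gene — or, failing that, the
highest class then alphabetical order — sets the family's gene category;
the packaged cohort declares SETX primary over REEP1 in its digenic
family, attributing the CMT phenotype to SETX and the spasticity to REEP1.
Dual pathology is flagged at class ≥ 3 in two distinct genes, the
threshold that matches the published six-family list (mixtures of certain,
likely and uncertain partners). Counting is per family throughout: a
founder variant carried by four families contributes four occurrences.

## The synthetic cohort generator

The generator emulates the *statistical structure* of the study's inputs,
not sequence: evidence bundles are planted directly because the real
pipeline consumes them as externals too.

Defaults are the sequenced sub-cohort's conditions: 59 families (22 CMT1,
29 CMT2, 1 intermediate, 7 unknown), 22 sporadic, eleven families
contributing a second sequenced patient (70 patients in total); per-patient
region-restricted load drawn from a truncated normal (mean 202, sd 18.2,
bounds [163, 241]); a background frequency spectrum of 95% common (1–20%,
log-uniform), 4% in the 0.1–1% band, 1% rare/novel, which puts the
expected per-patient count surviving the polymorphism screen at ~11;
in-house counts drawn Binomial(180, carrier probability) from each
variant's frequency. Planted variants get bundles satisfying exactly their
target class (class 5: two reported cases; class 4: missense consensus;
class 3: rarity only), genotypes matching the gene's mode (hom or a
two-variant comphet in recessive-only genes, hemizygous male index for
X-linked), and carrier patterns that segregate perfectly. Background
variants never receive literature evidence, a pathogenic consensus, or a
phenotype match, so by construction none can reach class ≥ 4.

What the simulation does *not* emulate: linkage and haplotype sharing
(background sites are independent across patients, so common variants are
not recurrent across families and per-patient survivor counts are
slightly overdispersed relative to a real cohort), phenocopies, reduced
penetrance (available as a knob, off by default), annotation errors, and
genotype errors. Passing recovery tests therefore demonstrate that the
pipeline's logic is faithful to its rules under clean inputs — not that
the rules are robust to noisy real-world annotation.

Coordinates are synthesised on one toy contig per gene; no reference
genome is shipped or required.

## The packaged cohort fixture

The fixture encodes a published population cohort of 81 CMT families: the
subgroup denominators (38/33/2/8), every certain and likely pathogenic
point variant with its evidence bundle and carrier genotypes, the
uncertain dual-pathology partner variants, the twelve duplication
families, and the prior-study findings (flagged `era = prior`; they enter
aggregation identically). Pedigree structures, sporadic flags beyond the
explicitly described families, and coordinates of partner variants whose
nucleotide change was never printed are synthetic reconstructions chosen
to match the printed marginal counts (27 sporadic families; ten unaffected
heterozygous SH3TC2 carriers across four families). Files are TSV plus a
JSON metadata record with SHA-256 checksums, verified at load.

## Numerical and degenerate-input choices

Frequencies are exact fractions; band boundaries follow the printed
conventions (class 2 band is [0.001, 0.01), class 3 at ≤ 0.001, so a
variant at exactly 0.1% is unlikely-pathogenic, matching benign-first
precedence). Empty inputs yield empty outputs everywhere; a zero-family
summary is all-zero with fractions reported as 0. Ties among equal-class
causal candidates are broken by (class desc, gene asc, coordinates asc)
for determinism; cohort classification is input-order invariant. All
randomness flows from a single integer seed through one generator.

## Problem sizes used in validation

The test suite and the acceptance script run the generator at its default
59-family / 70-patient scale (one simulated cohort per seed, ~14,000
variants), the rule-engine cross-check on 10,000 random evidence bundles,
and filter property checks on batches of 150–200 random variants — sizes
chosen because every statistic they feed is already stable there.
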