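# Default 51-gene inherited-neuropathy panel: reference transcripts,
# associated phenotypes, inheritance modes.  Inheritance modes are curated
# from the clinical genetics literature for each gene's neuropathy
# phenotype.  GAN and SLC12A6 carry a category override: giant axonal
# neuropathy and ACCPN are severe hereditary motor-and-sensory neuropathies
# conventionally counted within the CMT spectrum.
region_padding_bp: 10
include_utr: true
genes:
  - {symbol: AARS,     transcript: NM_001605.2,    phenotypes: [CMT2],                  inheritance: [autosomal_dominant]}
  - {symbol: ARHGEF10, transcript: NM_014629.2,    phenotypes: [slow-NCV],              inheritance: [autosomal_dominant]}
  - {symbol: ATP7A,    transcript: NM_000052.6,    phenotypes: [dHMN],                  inheritance: [x_linked]}
  - {symbol: BSCL2,    transcript: NM_001122955.3, phenotypes: [dHMN],                  inheritance: [autosomal_dominant]}
  - {symbol: CTDP1,    transcript: NM_004715.4,    phenotypes: [CCFDN],                 inheritance: [autosomal_recessive]}
  - {symbol: DCTN1,    transcript: NM_001135041.2, phenotypes: [dHMN],                  inheritance: [autosomal_dominant]}
  - {symbol: DNM2,     transcript: NM_001005361.2, phenotypes: [CMT2, ICMT],            inheritance: [autosomal_dominant]}
  - {symbol: DYNC1H1,  transcript: NM_001376.4,    phenotypes: [CMT2],                  inheritance: [autosomal_dominant]}
  - {symbol: EGR2,     transcript: NM_000399.3,    phenotypes: [CMT1, DSN, CMT4],       inheritance: [autosomal_dominant, autosomal_recessive]}
  - {symbol: FAM134B,  transcript: NM_001034850.2, phenotypes: [HSAN],                  inheritance: [autosomal_recessive]}
  - {symbol: FGD4,     transcript: NM_139241.2,    phenotypes: [CMT4],                  inheritance: [autosomal_recessive]}
  - {symbol: FIG4,     transcript: NM_014845.5,    phenotypes: [CMT4],                  inheritance: [autosomal_recessive]}
  - {symbol: GAN,      transcript: NM_022041.3,    phenotypes: [GAN],                   inheritance: [autosomal_recessive], category_override: cmt_gene}
  - {symbol: GARS,     transcript: NM_002047.2,    phenotypes: [CMT2, dHMN],            inheritance: [autosomal_dominant]}
  - {symbol: GDAP1,    transcript: NM_001040875.2, phenotypes: [CMT2, CMT4, ICMT],      inheritance: [autosomal_dominant, autosomal_recessive]}
  - {symbol: GJB1,     transcript: NM_000166.5,    phenotypes: [CMTX],                  inheritance: [x_linked]}
  - {symbol: HK1,      transcript: NM_033500.2,    phenotypes: [CMT4],                  inheritance: [autosomal_recessive]}
  - {symbol: HSPB1,    transcript: NM_001540.3,    phenotypes: [CMT2, dHMN],            inheritance: [autosomal_dominant]}
  - {symbol: HSPB3,    transcript: NM_006308.2,    phenotypes: [dHMN],                  inheritance: [autosomal_dominant]}
  - {symbol: HSPB8,    transcript: NM_014365.2,    phenotypes: [CMT2, dHMN],            inheritance: [autosomal_dominant]}
  - {symbol: IGHMBP2,  transcript: NM_002180.2,    phenotypes: [dHMN],                  inheritance: [autosomal_recessive]}
  - {symbol: IKBKAP,   transcript: NM_003640.3,    phenotypes: [HSAN],                  inheritance: [autosomal_recessive]}
  - {symbol: KIF1B,    transcript: NM_015074.3,    phenotypes: [CMT2],                  inheritance: [autosomal_dominant]}
  - {symbol: LITAF,    transcript: NM_001136472.1, phenotypes: [CMT1],                  inheritance: [autosomal_dominant]}
  - {symbol: LMNA,     transcript: NM_170708.3,    phenotypes: [CMT2],                  inheritance: [autosomal_dominant, autosomal_recessive]}
  - {symbol: MED25,    transcript: NM_030973.3,    phenotypes: [CMT2],                  inheritance: [autosomal_recessive]}
  - {symbol: MFN2,     transcript: NM_001127660.1, phenotypes: [CMT2],                  inheritance: [autosomal_dominant, autosomal_recessive]}
  - {symbol: MPZ,      transcript: NM_000530.6,    phenotypes: [CMT1, CMT2, ICMT, DSN], inheritance: [autosomal_dominant]}
  - {symbol: MTMR2,    transcript: NM_016156.5,    phenotypes: [CMT4],                  inheritance: [autosomal_recessive]}
  - {symbol: NDRG1,    transcript: NM_001135242.1, phenotypes: [CMT4],                  inheritance: [autosomal_recessive]}
  - {symbol: NEFL,     transcript: NM_006158.4,    phenotypes: [CMT1, CMT2],            inheritance: [autosomal_dominant, autosomal_recessive]}
  - {symbol: NGF,      transcript: NM_002506.2,    phenotypes: [HSAN],                  inheritance: [autosomal_recessive]}
  - {symbol: NTRK1,    transcript: NM_001012331.1, phenotypes: [HSAN],                  inheritance: [autosomal_recessive]}
  - {symbol: PLEKHG5,  transcript: NM_001042664.1, phenotypes: [ICMT, dHMN],            inheritance: [autosomal_recessive]}
  - {symbol: PMP22,    transcript: NM_153322.2,    phenotypes: [CMT1, DSN, HNPP],       inheritance: [autosomal_dominant]}
  - {symbol: POLG,     transcript: NM_001126131.1, phenotypes: [CMT-associated],        inheritance: [autosomal_recessive]}
  - {symbol: PRPS1,    transcript: NM_002764.3,    phenotypes: [CMTX],                  inheritance: [x_linked]}
  - {symbol: PRX,      transcript: NM_181882.2,    phenotypes: [CMT4, DSN],             inheritance: [autosomal_recessive]}
  - {symbol: RAB7,     transcript: NM_004637.5,    phenotypes: [CMT2],                  inheritance: [autosomal_dominant]}
  - {symbol: REEP1,    transcript: NM_001164731.1, phenotypes: [dHMN],                  inheritance: [autosomal_dominant]}
  - {symbol: SBF2,     transcript: NM_030962.3,    phenotypes: [CMT4],                  inheritance: [autosomal_recessive]}
  - {symbol: SEPT9,    transcript: NM_001113493.1, phenotypes: [HNA],                   inheritance: [autosomal_dominant]}
  - {symbol: SETX,     transcript: NM_015046.5,    phenotypes: [dHMN],                  inheritance: [autosomal_dominant, autosomal_recessive]}
  - {symbol: SH3TC2,   transcript: NM_024577.3,    phenotypes: [CMT4],                  inheritance: [autosomal_recessive]}
  - {symbol: SLC12A6,  transcript: NM_001042497.1, phenotypes: [ACCPN],                 inheritance: [autosomal_recessive], category_override: cmt_gene}
  - {symbol: SOD1,     transcript: NM_000454.4,    phenotypes: [CMT-associated],        inheritance: [autosomal_dominant]}
  - {symbol: SOX10,    transcript: NM_006941.3,    phenotypes: [PCWH],                  inheritance: [autosomal_dominant]}
  - {symbol: SPTLC1,   transcript: NM_001281303.1, phenotypes: [HSAN],                  inheritance: [autosomal_dominant]}
  - {symbol: TRPV4,    transcript: NM_001177428.1, phenotypes: [CMT2, dHMN],            inheritance: [autosomal_dominant]}
  - {symbol: WNK1,     transcript: NM_014823.2,    phenotypes: [HSAN],                  inheritance: [autosomal_recessive]}
  - {symbol: YARS,     transcript: NM_003680.3,    phenotypes: [ICMT],                  inheritance: [autosomal_dominant]}
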