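version: ICC-2022/WHO-HAEM5 synthetic-curation-v1
subtypes:
- icc_label: BCR::ABL1
  who_label: B-ALL with BCR::ABL1 fusion
  expression:
  - BCR::ABL1
  - BCR::ABL1-like
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: BCR::ABL1-like, ABL-class
  who_label: B-ALL with BCR::ABL1-like features
  expression:
  - BCR::ABL1-like
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: BCR::ABL1-like, JAK/STAT
  who_label: B-ALL with BCR::ABL1-like features
  expression:
  - BCR::ABL1-like
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: BCR::ABL1-like, NOS
  who_label: B-ALL with BCR::ABL1-like features
  expression:
  - BCR::ABL1-like
  defining_fusions: false
  defining_snvs: []
  defining_karyotype: null
  allowance: true
- icc_label: KMT2A-r
  who_label: B-ALL with KMT2A rearrangement
  expression:
  - KMT2A
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: ETV6::RUNX1
  who_label: B-ALL with ETV6::RUNX1 fusion
  expression:
  - ETV6::RUNX1
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: ETV6::RUNX1-like
  who_label: B-ALL with ETV6::RUNX1-like features
  expression:
  - ETV6::RUNX1-like
  - ETV6::RUNX1
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: TCF3::PBX1
  who_label: B-ALL with TCF3::PBX1 fusion
  expression:
  - TCF3::PBX1
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: TCF3::HLF
  who_label: B-ALL with TCF3::HLF fusion
  expression:
  - HLF
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: Hyperdiploid
  who_label: B-ALL with high hyperdiploidy
  expression:
  - Hyperdiploid
  - Near haploid
  defining_fusions: false
  defining_snvs: []
  defining_karyotype: high_hyperdiploid
  allowance: false
- icc_label: Low hypodiploid
  who_label: B-ALL with hypodiploidy
  expression:
  - Low hypodiploid
  defining_fusions: false
  defining_snvs: []
  defining_karyotype: low_hypodiploid
  allowance: false
- icc_label: Near haploid
  who_label: B-ALL with hypodiploidy
  expression:
  - Near haploid
  - Hyperdiploid
  defining_fusions: false
  defining_snvs: []
  defining_karyotype: near_haploid
  allowance: false
- icc_label: iAMP21/chr21-amplification
  who_label: B-ALL with iAMP21
  expression:
  - iAMP21
  - BCR::ABL1-like
  defining_fusions: false
  defining_snvs: []
  defining_karyotype: iamp21_chr21amp
  allowance: false
- icc_label: DUX4-r
  who_label: ''
  expression:
  - DUX4
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: true
- icc_label: MEF2D-r
  who_label: ''
  expression:
  - MEF2D
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: ZNF384-r
  who_label: ''
  expression:
  - ZNF384
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: ZNF384-like
  who_label: ''
  expression:
  - ZNF384
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: NUTM1-r
  who_label: ''
  expression:
  - NUTM1
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: PAX5alt
  who_label: ''
  expression:
  - PAX5alt
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: true
- icc_label: PAX5 P80R
  who_label: ''
  expression:
  - PAX5 P80R
  defining_fusions: false
  defining_snvs:
  - PAX5 P80R
  defining_karyotype: null
  allowance: false
- icc_label: IKZF1 N159Y
  who_label: ''
  expression:
  - IKZF1 N159Y
  defining_fusions: false
  defining_snvs:
  - IKZF1 N159Y
  defining_karyotype: null
  allowance: false
- icc_label: ZEB2 H1038R
  who_label: ''
  expression:
  - CEBP
  defining_fusions: false
  defining_snvs:
  - ZEB2 H1038R
  defining_karyotype: null
  allowance: false
- icc_label: CEBP
  who_label: ''
  expression:
  - CEBP
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: true
- icc_label: CDX2/UBTF
  who_label: ''
  expression:
  - CDX2/UBTF
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: IGH::MYC
  who_label: ''
  expression:
  - BCL2/MYC
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
- icc_label: IGH::BCL2
  who_label: ''
  expression:
  - BCL2/MYC
  defining_fusions: true
  defining_snvs: []
  defining_karyotype: null
  allowance: false
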