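# English term dictionary for the 12 extraction targets.
# Curated for the synthetic note templates and common report phrasings;
# user-extensible (terms are matched as contiguous token sequences after
# lowercasing and punctuation-stripping tokenization).
language: en
window: 3
negators:
  - "no"
  - not
  - without
  - absent
  - absence
  - denies
  - denied
  - negative
  - excluded
  - free
concepts:
  vascular_invasion:
    terms:
      - portal vein thrombosis
      - portal thrombosis
      - vascular invasion
      - tumor thrombus
      - tumour thrombus
  severe_comorbidities:
    terms:
      - severe comorbidities
      - severe comorbidity
      - major comorbidities
  metastatic_disease:
    terms:
      - metastatic disease
      - metastases
      - metastasis
      - extrahepatic disease
      - extrahepatic spread
  previous_hcc_treatment:
    terms:
      - previous hcc treatment
      - previous treatment
      - prior treatment
      - previously treated
  complete_response_last_treatment:
    terms:
      - complete response
  esophageal_varices:
    terms:
      - esophageal varices
      - oesophageal varices
      - varices
numerics:
  afp_ng_ml:
    keywords: [afp, alpha fetoprotein]
  albumin_g_dl:
    keywords: [albumin, serum albumin]
  ecog_ps:
    keywords: [ecog, performance status, ecog ps]
    domain: [0, 4]
  child_pugh_score:
    keywords: [child pugh]
    compound_class: true
    domain: [5, 15]
  meld_score:
    keywords: [meld, meld score]
    domain: [6, 40]
diameter:
  section_keywords: [imaging, ct, mri, ultrasound, scan, radiology]
  mm_units: [mm]
  cm_units: [cm]
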