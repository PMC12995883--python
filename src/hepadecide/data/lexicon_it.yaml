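# Italian term dictionary for the 12 extraction targets.
language: it
window: 3
negators:
  - "no"
  - non
  - senza
  - assenza
  - assente
  - assenti
  - nessun
  - nessuna
  - negativo
  - negativa
  - escluso
  - esclusa
  - esclude
concepts:
  vascular_invasion:
    terms:
      - trombosi della vena porta
      - trombosi portale
      - trombosi della porta
      - invasione vascolare
      - trombosi neoplastica
  severe_comorbidities:
    terms:
      - comorbidita severe
      - comorbidità severe
      - comorbidita gravi
      - gravi comorbidita
      - gravi comorbidità
  metastatic_disease:
    terms:
      - malattia metastatica
      - metastasi
      - malattia extraepatica
  previous_hcc_treatment:
    terms:
      - pregresso trattamento
      - trattamento precedente
      - precedente trattamento
      - pregressi trattamenti
  complete_response_last_treatment:
    terms:
      - risposta completa
  esophageal_varices:
    terms:
      - varici esofagee
      - varici
numerics:
  afp_ng_ml:
    keywords: [afp, alfa fetoproteina, alfafetoproteina]
  albumin_g_dl:
    keywords: [albumina, albumina sierica]
  ecog_ps:
    keywords: [ecog, performance status, ecog ps]
    domain: [0, 4]
  child_pugh_score:
    keywords: [child pugh]
    compound_class: true
    domain: [5, 15]
  meld_score:
    keywords: [meld]
    domain: [6, 40]
diameter:
  section_keywords: [imaging, tc, rm, rmn, ecografia, radiologia]
  mm_units: [mm]
  cm_units: [cm]
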