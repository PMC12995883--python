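# Synthetic HCC management guideline (fixture)

This document is a SYNTHETIC stand-in for a clinical practice guideline on
the management of hepatocellular carcinoma (HCC). It exists so that the
retrieval stage has a structurally realistic reference corpus to chunk,
embed and query. It is written for testing only and must never be used for
patient care. Point the configuration at your institution's licensed
guideline texts for real use.

## Surveillance and follow-up

Patients who achieved a complete response to their last HCC treatment and
show no measurable lesion, no vascular invasion and no metastatic disease on
the most recent imaging should continue clinical and radiological follow-up
at six-month intervals. Alpha-fetoprotein (AFP) monitoring complements
imaging surveillance.

## Performance status and supportive care

Patients with an ECOG performance status of 3 or 4 do not derive benefit
from tumour-directed therapy; best supportive care is recommended regardless
of tumour burden. Severely decompensated cirrhosis (Child-Pugh score 13 or
higher) without a transplant option is likewise an indication for best
supportive care.

## Advanced disease

Vascular invasion (for example portal vein thrombosis) or extrahepatic
metastatic disease with preserved liver function (Child-Pugh class A or B)
indicates systemic therapy. When vascular invasion or metastases coexist
with decompensated cirrhosis (Child-Pugh class C), supportive care is
preferred.

## Liver transplantation

Liver transplantation is recommended for lesions up to 50 mm in patients
with good performance status (ECOG 0-1), no vascular invasion and no
metastases, when the underlying cirrhosis is decompensated (Child-Pugh
score 7-12) or complicated by clinically significant portal hypertension
(esophageal varices).

## Surgical resection

Surgical resection is the first option for a resectable lesion in
compensated cirrhosis: Child-Pugh class A, no esophageal varices, ECOG
performance status 0-1, no vascular invasion and no metastatic disease.

## Ablation

Percutaneous ablation is indicated for lesions up to 30 mm with preserved
liver function (Child-Pugh A or B) in patients who are not surgical or
transplant candidates, including those with ECOG performance status 2.

## Transarterial treatment

Transarterial treatment (chemoembolization or radioembolization) is
indicated for multinodular or large intermediate-stage disease confined to
the liver with preserved liver function (Child-Pugh A or B) and ECOG
performance status up to 2.

## Multidisciplinary discussion

Every transplant candidate must be discussed by the multidisciplinary team.
Resection candidates with severe comorbidities, portal hypertension or a
MELD score of 10 or more, and any high-complexity case considered for
active treatment, should also be referred for multidisciplinary discussion.
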