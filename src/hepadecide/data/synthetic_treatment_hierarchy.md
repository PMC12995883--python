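# Synthetic multiparametric treatment-hierarchy note (fixture)

A SYNTHETIC stand-in for a review article describing a multiparametric
therapeutic hierarchy for hepatocellular carcinoma. Testing fixture only;
not clinical guidance.

## The therapeutic hierarchy

Treatments for HCC can be ordered by expected survival benefit: liver
transplantation, surgical resection, ablation, transarterial treatment,
systemic therapy, best supportive care. The guiding principle is to offer
the highest feasible rung of the hierarchy, moving down only when a
contraindication is identified.

## Multiparametric assessment

Feasibility is decided on the combination of tumour burden (number of
nodules, maximum diameter, vascular invasion, extrahepatic spread), liver
function (Child-Pugh score, MELD score, serum albumin, portal hypertension),
and the patient's condition (age, ECOG performance status, severe
extrahepatic comorbidities). No single staging variable suffices: two
patients at the same radiological stage may receive different allocations
when liver function or performance status differ.

## Clinical complexity

Decision complexity grows with the number of borderline criteria a case
accumulates: intermediate liver function (Child-Pugh B or C), reduced
performance status, portal hypertension, severe comorbidities, vascular
invasion, metastatic spread, markedly elevated AFP (above 400 ng/ml), a
MELD score of 15 or more, or hypoalbuminemia below 2.8 g/dl. Cases with
several such criteria benefit most from multidisciplinary evaluation, while
single-criterion cases can usually be allocated by a single specialist.
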