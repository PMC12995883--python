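=== TASK ===
You are a clinical information extraction system for hepatocellular carcinoma
(HCC) reports. From the clinical report given at the end, extract the
following 12 parameters:
- Vascular invasion: present / absent
- Severe comorbidities: present / absent
- Metastatic disease: present / absent
- Previous HCC treatment: present / absent
- Complete response to last treatment: present / absent
- Esophageal varices: present / absent
- AFP (ng/ml): number
- Albumin (g/dl): number
- ECOG performance status: integer 0-4
- Child-Pugh score: integer 5-15
- MELD score: integer 6-40
- Maximum nodule diameter (mm): number, from the most recent imaging only

=== EXAMPLES ===
{exemplars}

=== INSTRUCTIONS ===
Reason step by step: locate the relevant section of the report, extract the
specific value or condition, validate it against the expected format, then
answer. Output exactly 12 lines in the format "Field: value", in the order
listed above. If a parameter cannot be confidently extracted, output
"not reported" for it. Do not output anything else.

=== REPORT ===
{note}

=== EXTRACTION ===
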