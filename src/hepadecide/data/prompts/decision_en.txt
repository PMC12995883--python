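{evidence}{examples}=== TASK ===
You are a hepatology decision-support assistant. For the hepatocellular
carcinoma (HCC) case below, make three decisions:
1. Treatment allocation — exactly one of: liver transplantation, surgical
   resection, ablation, transarterial treatment, systemic therapy, best
   supportive care, follow-up continuation.
2. Clinical complexity — exactly one of: low, moderate, high.
3. Multidisciplinary team (MDT) discussion — yes or no.
Answer in exactly three labeled lines:
Treatment: <category>
Complexity: <grade>
MDT: <yes/no>

=== TARGET CASE ===
{case}

=== DECISION ===
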