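"""Generate a small synthetic cohort of HCC clinical notes with gold labels.

Each case carries a full clinical profile (liver function, tumour burden,
performance status), the narrative note rendered from it, and the reference
decision triple (treatment allocation, complexity grade, MDT referral)
assigned by the documented rule table.
"""

from collections import Counter

from hepadecide import GeneratorConfig, generate_bundles

config = GeneratorConfig(n_cases=50, seed=42, language="en")
bundles = generate_bundles(config)

print("=== first note ===")
print(bundles[0].note.text)
print()
print("=== its gold profile ===")
gold = bundles[0].gold
print(f"Child-Pugh {gold.child_pugh_class}{gold.child_pugh_score}, MELD {gold.meld_score}, "
      f"ECOG {gold.ecog_ps}, {gold.n_nodules} nodule(s)")
print("reference decision:", gold.reference_decision)
print()

mix = Counter(b.gold.reference_decision.treatment for b in bundles)
print("treatment mix over", config.n_cases, "cases (counts follow the cohort marginals):")
for treatment, count in mix.most_common():
    print(f"  {treatment:24s} {count}")
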