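"""Generate a synthetic problem-list corpus and look at its surface forms.

Each item is a <=50-character German-like diagnosis string drawn from one of
12 hidden 3-digit ICD-10 topics; half of the items keep their code visible,
the other half are masked but remember their generating topic as truth.
"""

from problist import SynthConfig, generate

synthetic = generate(SynthConfig(n_patients=2, items_per_patient=(8, 8), seed=4))

print(f"{'item':9} {'visible':8} {'truth':6} description")
for item in synthetic.corpus:
    truth = synthetic.truth[item.item_id]
    visible = item.code.category3 if item.code else "-"
    print(f"{item.item_id:9} {visible:8} {truth.true_code:6} {item.description}")

masked = sum(t.was_masked for t in synthetic.truth.values())
print(f"\n{len(synthetic.corpus)} items, {masked} with masked codes.")
print("A '-' in the visible column is an uncoded entry the pipeline will try")
print("to post-code from its cluster neighbors.")
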