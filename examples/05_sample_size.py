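"""Chernoff-bound sample size for a representative linguistic sample.

n >= (3 / eps^2) * ln(2 / delta) text snippets guarantee that observed
pattern proportions are within eps of the population value with confidence
1 - delta, independently of the pool size.
"""

from problist import estimate_sample_size

for eps, delta in [(0.05, 0.05), (0.1, 0.05), (0.05, 0.01)]:
    n = estimate_sample_size(eps, delta)
    print(f"accuracy ±{eps:4}  confidence {1 - delta:.0%}  ->  n >= {n}")

print()
print("At ±5% accuracy and 95% confidence, 4427 distinct coded snippets")
print("suffice to capture the corpus' linguistic fingerprint.")
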