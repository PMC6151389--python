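"""Derive the full metric suite from pooled confusion counts.

Takes the pooled true/false positive/negative counts of a whole-panel
activity model (70 inhibitors x 379 kinases, activity = Kd < 10 uM) and
prints sensitivity, selectivity, accuracy, Matthews correlation, predictive
values, and the Fisher comparison against a coin-flip predictor.
"""

from kinsel import ConfusionCounts, fisher_vs_random, metrics

counts = ConfusionCounts(tp=3765, fp=2944, tn=17048, fn=2773)
report = metrics(counts)

print(f"pairs scored: {counts.total}  (actives {counts.actives}, "
      f"inactives {counts.inactives})")
for name, value in report.as_percent_row().items():
    print(f"  {name:>3s} = {value}")

p, table = fisher_vs_random(counts)
print(f"correct calls: {counts.tp + counts.tn}")
print(f"Fisher exact p vs 50% coin-flip model: {p:.3g}")
print()
print("ACC/SEN/SEL are percentages; MCC is a balanced correlation in [-1, 1]")
print("that stays informative when actives are rare, which is why it is the")
print("preferred single number for ranking cutoff choices.")
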