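"""Metric arithmetic on the bundled reference confusion matrices.

Recomputes headline accuracies and the accuracy improvements that the
local-averaging augmentation delivers, straight from the stored count
matrices — no training involved.
"""

import harspec as h

best = [("or-200", 0.003), ("uci-or", 0.0002), ("uci-la1", 0.003)]
for variant, rate in best:
    cm = h.get_matrix(variant, rate)
    print(f"{variant} @ lr {rate}: accuracy "
          f"{h.accuracy_from_cm(cm):.2f}% on {cm.total} test samples")

print()
for rate in (0.01, 0.015, 0.006):
    d = h.accuracy_delta(h.get_matrix("la1-100", rate),
                         h.get_matrix("or-100", rate))
    print(f"100-feature OR+LA1 vs OR @ lr {rate}: {d:+.2f} points")
d = h.accuracy_delta(h.get_matrix("uci-la1", 0.003), h.get_matrix("uci-or", 0.003))
print(f"UCI OR+LA1 vs OR @ lr 0.003: {d:+.2f} points")

# At the higher learning rates the unaugmented 100-feature runs collapse
# to a single predicted class; appending local averages restores balanced
# learning, which is where the +32-point improvements come from.
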