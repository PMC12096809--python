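"""Single-trial spike-pattern classification and the selectivity index.

For a dAC-like unit, single-trial PSTHs (1-ms bins, Gaussian-smoothed)
are assigned to the call category of the nearest template by Euclidean
distance, over 10,000 resamples.  The diagonal of the confusion matrix is
the probability of correct category assignment; SI summarizes how
selective the unit's best row is.  The 2-ms integration window exploits
fine temporal structure, the 200-ms window only rate-like information.
"""

import numpy as np

import batvoc as bv

library = bv.make_call_library(seed=1)
categories = {c.call_id: c.category for c in library}
protocol = bv.TrialProtocol(50, 450, 20, seed=5)

profile = bv.distinct_pattern_template()
data = {c.call_id: bv.simulate_call_response(profile, c, protocol) for c in library}
window = bv.preference_result(data, categories).window

for w_ms in (2.0, 200.0):
    cm = bv.confusion_matrix(data, categories, level="category",
                             integration_window_ms=w_ms, n_resamples=10_000,
                             seed=5, window=window)
    best_p, si, best = bv.unit_selectivity(cm)
    print(f"\n{w_ms:g}-ms integration window ({cm.labels}):")
    print(np.round(cm.probs, 3))
    print(f"best category '{best}': p(correct) = {best_p:.3f}, SI = {si:.3f}")

print("\nDiagonal entries near 1 mean each category's temporal spike pattern")
print("is reproducible and distinct; chance would be 1/3 per entry.")
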