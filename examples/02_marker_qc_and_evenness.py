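"""Marker quality statistics: dosage-class evenness and selection filters.

Computes the Shannon-Wiener evenness of dosage-class proportions for a few
markers (an even spread across the five tetraploid dosage classes means
more discriminatory power) and applies the three chip-selection criteria
to a posterior table.
"""

import numpy as np

from polyfp import chip_filter, compute_evenness

# dosage-class proportions P0..P4 of three markers with very different
# class balance
examples = {
    "skewed marker": (0.03, 0.13, 0.16, 0.09, 0.59),
    "balanced marker": (0.24, 0.19, 0.21, 0.19, 0.17),
    "uniform ideal": (0.2, 0.2, 0.2, 0.2, 0.2),
}
for name, props in examples.items():
    r = compute_evenness(props)
    print(f"{name}: H_S = {r.H_S:.3f} nats, evenness I = {r.I:.3f}")
print("evenness 1.0 = all five dosage classes equally occupied\n")

# chip filter: 100 samples, balanced classes, confident posteriors
rng = np.random.default_rng(0)
posteriors = np.full((100, 5), 0.00125)
for i in range(100):
    posteriors[i, i % 5] = 0.995
res = chip_filter(posteriors, marker_id="demo")
print(f"chip filter for 'demo': min class occupancy {res.min_class_proportion:.2f}, "
      f"confident fraction {res.frac_high_confidence:.2f}, "
      f"mean max posterior {res.mean_max_posterior:.3f}")
print(f"passes all three criteria: {res.passed}")
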