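"""Localise the sequence feature that drives expression.

Correlates window A/T content with expression over a grid of window sizes and
positions anchored at each construct's main polyadenylation site, recovering
the planted effect window, and calibrates the peak against a permutation
null.  Also shows the grouped positional G/C profile view of the same signal.
"""

import numpy as np

from utr3end import seqfeatures, simulate

constructs, truth = simulate.generate_construct_library(200, seed=4)

grid = seqfeatures.feature_expression_scan(constructs)
size, offset, r = grid.peak()
null = seqfeatures.scan_permutation_null(constructs, n_perm=500, seed=5)

print(f"planted window:   {truth.effect_width} bp at offset {truth.effect_center}")
print(f"grid peak:        {size} bp at offset {offset}, Pearson r = {r:.3f}")
print(f"null 95% band:    |r| <= {np.quantile(null, 0.95):.3f} "
      f"(observed peak is {'outside' if r > np.quantile(null, 0.95) else 'inside'})")

profiles = seqfeatures.grouped_gc_profile(constructs, span=range(-100, 1, 10))
in_window = [-60, -50, -40, -30]
for name in ("low", "high"):
    df = profiles[name]
    sel = df[df["offset"].isin(in_window)]["mean_gc"].mean()
    print(f"mean G/C in planted region, {name}-expression group: {sel:.3f}")

# High-expression constructs are A/T-rich (G/C-poor) just upstream of the
# polyA site; the grid pinpoints where and at what scale the signal lives.
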