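"""Quantify per-strain expression from plate-reader growth curves.

Simulates a plate of strains with known YFP production rates (logistic
growth, measurement noise, spike artefacts, background wells), then runs the
full processing pipeline — background subtraction, outlier masking, growth-
phase segmentation, production-per-cell — and compares against the truth.
"""

import warnings

import numpy as np

from utr3end import platereader, simulate

warnings.simplefilter("ignore")

production = {f"strain{i}": p for i, p in enumerate(np.linspace(0.5, 4.0, 8))}
samples, backgrounds, truth = simulate.simulate_plate_timecourses(
    production, noise_frac=0.01, spike_rate=0.01, seed=2
)

print(f"{'strain':<10}{'true P':>8}{'recovered':>11}{'rel err':>9}  window (h)")
for tc in samples:
    m = platereader.process_timecourse(tc, backgrounds)
    p_true = production[tc.strain_id]
    err = abs(m.production - p_true) / p_true
    t0, t1 = m.window
    print(f"{tc.strain_id:<10}{p_true:>8.3f}{m.production:>11.3f}{err:>8.1%}"
          f"   {t0 / 3600:.1f}-{t1 / 3600:.1f}")

# 'P' is the rate of fluorescence production per OD unit per second during
# exponential growth — the per-cell expression measure.  Recovery within a
# couple of percent despite noise and spikes shows the pipeline inverts the
# generative model.
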