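"""Extract transcriptional burst statistics from single-cell populations.

Under the gamma model of bursty expression, a population's YFP distribution
is Gamma(a, b): a = burst frequency (bursts per protein lifetime), b = burst
size (proteins per burst).  Burst frequency is estimated as 1/noise
(mean^2/variance) and burst size as the noise strength (variance/mean), after
gating out spores and scatter outliers.
"""

from utr3end import simulate, stats

print(f"{'a (true)':>9}{'b (true)':>9}{'freq est':>10}{'size est':>10}{'gated %':>9}")
for a, b in [(2, 100), (10, 100), (10, 500), (50, 50)]:
    pop, _ = simulate.simulate_cell_population(
        a, b, 50_000, extrinsic_cv=0.0, spore_frac=0.03, seed=a + b
    )
    gated, report = stats.gate_cells(pop)
    ns = stats.population_noise_stats(gated)
    removed = 100 * (1 - report.n_after / report.n_before)
    print(f"{a:>9}{b:>9}{ns.burst_frequency:>10.2f}{ns.burst_size:>10.1f}"
          f"{removed:>8.1f}%")

# Distinguishing the two parameters matters: promoter activation shifts burst
# frequency, while 3' end sequences shift burst size.  Varying b moves the
# mean with flat noise; varying a moves the mean with noise ~ 1/mean.
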