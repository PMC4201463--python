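"""Calibrated substitution rates from gene trees, end to end.

Simulates a 10-locus panel, infers each gene tree by exhaustive ML search,
averages patristic distances across the ingroup/outgroup root split, and
calibrates with the 15.9 Ma root age.  Compares recovered rates with the
planted truth.
"""

from lcnpipe import SimulationConfig, rate_recovery_run

config = SimulationConfig(seed=3, n_loci=10, locus_length_range=(2500, 2500))
run = rate_recovery_run(config)

print(f"{'locus':8s} {'true (e-9)':>10s} {'estimated (e-9)':>15s} "
      f"{'error':>7s}")
for _, row in run.table.iterrows():
    err = 100 * (row.est_rate / row.true_rate - 1)
    print(f"{row.locus_id:8s} {row.true_rate * 1e9:10.2f} "
          f"{row.est_rate * 1e9:15.2f} {err:+6.1f}%")

print("\nEach estimate is mean cross-root patristic distance / (2 x 15.9 Ma);")
print("per-locus errors reflect finite alignment length (2.5 kb).")
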