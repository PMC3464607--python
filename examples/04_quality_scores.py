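"""Quality scores: calibration and discrimination.

Calls a noisy tile, then checks that the posterior-derived error
probabilities mean what they say: bases predicted to fail 1% of the time
should actually fail about 1% of the time (calibration), and D(eps) shows
how many bases survive a quality cutoff while being correct.
"""

import numpy as np

import sbscall as sc
from sbscall.quality import calibration_table, discrimination_curve

params = sc.default_preset(L=76)
tile = sc.simulate_tile(n=300, L=76, params=params, seed=5)
res = sc.call_tile(tile.reads, params, N_p=800, seed=6)

rate, per_cycle = sc.error_rate([r.calls for r in res], tile.truths)
print(f"overall error rate {rate:.4f}; cycle 1 {per_cycle[0]:.4f}, "
      f"cycle 76 {per_cycle[-1]:.4f}")

print("\ncalibration (predicted vs empirical error probability per bin):")
tab = calibration_table(res, tile.truths)
for _, row in tab[tab.n > 0].iterrows():
    print(
        f"  [{row.bin_lo:8.4f}, {row.bin_hi:8.4f})  n={int(row.n):6d}  "
        f"predicted {row.mean_predicted:8.5f}  empirical {row.empirical:8.5f}"
    )

print("\ndiscrimination D(eps): fraction of bases correct AND confident")
for eps, d in discrimination_curve(res, tile.truths, np.array([1e-3, 1e-2, 1e-1])):
    print(f"  eps={eps:7.3f}  D={d:.3f}")
print("\nRows where 'empirical' tracks 'predicted' within a factor ~2 mean the")
print("phred scores written to FASTQ are trustworthy for downstream filtering.")
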