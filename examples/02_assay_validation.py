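"""Assay analytics: limit of blank, probit limit of detection, %CV,
standard curve and amplification efficiency.

The dilution series is generated from a known probit dose-response
(intercept -2, slope 2 on log10 concentration), so the analytic 95%
detection level, 10**((1.645+2)/2) ~ 66.4 CTC-equivalents/mL, is the
ground truth the fit should recover.
"""

import numpy as np

from dscout.quantify import lob, lod_probit, percent_cv, qpcr_efficiency, standard_curve
from dscout.simulate import simulate_dilution_series

blanks = [98, 102, 95, 110, 101, 99, 104, 97, 106, 100, 103, 96]
print(f"LOB of 12 blank replicates: {lob(blanks):.1f} copies (95th percentile rule)")

hits = simulate_dilution_series([20, 40, 60, 80, 120, 200], reps=2000,
                                detect_model=(-2.0, 2.0), seed=1)
res = lod_probit(hits)
print(f"probit LOD95: {res.lod:.1f} CTC-equivalents/mL (analytic 66.4)")

replicates = [512.0, 498.0, 505.0, 520.0, 491.0]
print(f"replicate %CV: {percent_cv(replicates):.2f}%")

cells = np.array([0, 10, 20, 50, 100], dtype=float)
copies = 9.8 * cells + 4.0 + np.random.default_rng(1).normal(0, 5, cells.size)
sc = standard_curve(cells, copies)
print(f"standard curve: slope {sc.slope:.2f} copies/cell, r^2 {sc.r2:.4f}")

concs = [1.0, 10.0, 100.0, 1000.0]
cts = [33.1, 29.8, 26.4, 23.1]
print(f"amplification efficiency: {qpcr_efficiency(cts, concs):.1f}%")
# Good assays show r^2 > 0.98 on the standard curve and efficiency > 90%.
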