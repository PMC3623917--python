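#!/usr/bin/env python
"""Run the multi-scale roughness analysis over the simulated ensemble.

Reads the trajectories written by 01_simulate.py and computes, per time
scale tau in {1, 10, 100, 1000} x delta and window exponents m = 5, 6:
windowed Pearson r between E_p and E_p-w, the window sigmas, smoothing /
roughening probabilities and quadrant occupancy.  Tables land under
results/analysis/.
"""

import logging
from pathlib import Path

from pesrough import AnalysisConfig, InputSpec, TimescaleGrid, run

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

paths = sorted(str(p) for p in Path("scratch/trajectories").glob("traj*.tsv"))
if not paths:
    raise SystemExit("no trajectories found; run analysis/01_simulate.py first")

cfg = AnalysisConfig(
    input=InputSpec(paths=paths, dialect="plain3col", sampling_interval=1.0),
    scales=TimescaleGrid((1.0, 10.0, 100.0, 1000.0), 1.0),
    exponents=(5, 6),
    max_windows=3000,
    output_dir="results/analysis",
)
report = run(cfg)

for m, rows in sorted(report.summaries.items()):
    print(f"\n== m = {m} (n = {2**m} points per window) ==")
    print(f"{'tau':>6} {'mean_r':>8} {'sig_p':>7} {'sig_pw':>7} "
          f"{'sig_tot':>7} {'p_smooth':>8}")
    for s in rows:
        print(f"{s.tau:>6g} {s.mean_r:>8.3f} {s.mean_sigma_p:>7.3f} "
              f"{s.mean_sigma_pw:>7.3f} {s.mean_sigma_tot:>7.3f} "
              f"{s.p_smooth:>8.3f}")

rows = report.summaries[6]
print("\nFindings:")
print(f"- mean r strengthens from {rows[0].mean_r:.3f} at tau=1 to "
      f"{rows[-1].mean_r:.3f} at tau=1000: the water term compensates more "
      "strongly on slower time scales.")
print(f"- all sigmas grow with tau; sigma_tot/sigma_pw falls from "
      f"{rows[0].mean_sigma_tot / rows[0].mean_sigma_pw:.2f} to "
      f"{rows[-1].mean_sigma_tot / rows[-1].mean_sigma_pw:.2f}: the total "
      "starts above both components and ends between sigma_p and sigma_pw.")
print(f"- smoothing probability drops from {rows[0].p_smooth:.3f} to "
      f"{rows[-1].p_smooth:.3f}: water roughens the landscape almost "
      "everywhere at coarse scales, despite the stronger anticorrelation.")
print("\nNext: python analysis/03_compare_exponents.py")
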