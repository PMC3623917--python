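#!/usr/bin/env python
"""Render the overview and quadrant figures for the analysed ensemble.

Re-runs the analysis of 02_analyze.py with plotting enabled; figures land
next to the tables under results/analysis/m5/ and m6/ (PNG, advisory only —
the TSV/JSON tables are the surface of record).
"""

from pathlib import Path

from pesrough import AnalysisConfig, InputSpec, TimescaleGrid, run

paths = sorted(str(p) for p in Path("scratch/trajectories").glob("traj*.tsv"))
if not paths:
    raise SystemExit("no trajectories found; run analysis/01_simulate.py first")

cfg = AnalysisConfig(
    input=InputSpec(paths=paths, dialect="plain3col", sampling_interval=1.0),
    scales=TimescaleGrid((1.0, 10.0, 100.0, 1000.0), 1.0),
    exponents=(5, 6),
    max_windows=3000,
    output_dir="results/analysis",
    make_plots=True,
)
report = run(cfg)
for m in sorted(report.summaries):
    print(f"figures for m={m} under {report.output_dir}/m{m}/")
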