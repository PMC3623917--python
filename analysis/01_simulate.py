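#!/usr/bin/env python
"""Generate the synthetic trajectory ensemble for the downstream analysis.

Simulates six replicate trajectories of the two-component coupled-OU model
(fast weakly coupled component + slow water-dominated anticorrelated
component) and writes them as plain3col text under scratch/trajectories/.
These stand in for an MD ensemble's protein self energy / protein-water
interaction energy series; see docs/methods.md for what they do and do not
emulate.
"""

from pathlib import Path

from pesrough import write_series
from pesrough.synthetic import simulate, slaving_demo_model

N_REPLICATES = 6
N_STEPS = 200_000

out = Path("scratch/trajectories")
out.mkdir(parents=True, exist_ok=True)
for k in range(N_REPLICATES):
    model = slaving_demo_model(n_steps=N_STEPS, seed=k)
    series = simulate(model)
    path = out / f"traj{k:02d}.tsv"
    write_series(series, path)
    print(f"wrote {path}: {len(series)} frames, "
          f"stationary Var(E_p)={model.var_p:.3f}, "
          f"Var(E_pw)={model.var_pw:.3f}, Cov={model.cov_p_pw:.3f}")
print("\nNext: python analysis/02_analyze.py")
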