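# Methods

## The statistic

For one trajectory, the solvated-protein potential energy is decomposed
per frame into the protein self energy E_p and the protein–water
interaction energy E_p–w (kcal/mol), with E_tot = E_p + E_p–w derived, never
stored. At a time scale τ (an integer multiple of the sampling interval δ),
a window is n = 2^m frames spaced s = τ/δ frames apart, spanning (n−1)τ of
simulated time. Per window the package computes:

- population standard deviations σ_p, σ_p–w, σ_tot of the three energy
  terms (⟨E²⟩ − ⟨E⟩² form, divide by n);
- the Pearson correlation r between E_p and E_p–w over the same n points
  (population moments; undefined — an explicit flag — if either window is
  constant);
- Δσ = σ_tot − σ_p and the quadrant of (Δσ, r).

The sample identity σ_tot² = σ_p² + σ_p–w² + 2 r σ_p σ_p–w holds exactly in
population form; it is asserted on every window at 1e−9 relative tolerance
and a violation aborts the run. The same algebra makes quadrant II (Δσ < 0
with r ≥ 0 and σ_p–w > 0) impossible; a window classified there raises
rather than being silently re-binned. A divide-by-(n−1) option exists but is
off by default: with it, r uses the same ddof so the identity still holds.

Axis orientation of the quadrant plane is fixed as (x = Δσ, y = r). Only
this orientation makes quadrant II the impossible region while keeping the
common slaving case — anticorrelated water that nevertheless roughens
(r < 0, Δσ > 0) — in quadrant IV.

Numerics: moments are computed two-pass (centred). This is algebraically
identical to ⟨E²⟩ − ⟨E⟩² but does not lose digits when energies carry large
baselines (MD energies are O(10³) kcal/mol with O(10) fluctuations, where
the one-pass form would cancel catastrophically). Variances are clipped at 0
against round-off; r is clipped into [−1, 1].

## Window placement

Per scale, admissible start frames in a trajectory of L frames are
0 … L−1−(n−1)s (A = L−(n−1)s of them). The window budget (default
max_windows = 1000 per scale — an analysis choice, there is no canonical
value) is split across trajectories by largest-remainder proportional
allocation on A_t (exact integer arithmetic; ties broken toward earlier
trajectories), and W windows within a trajectory start at round(i·A/W),
i = 0…W−1, duplicates dropped. Placement is deterministic; "uniformly
distributed" is read as even spacing, not random draws, for
reproducibility. Windows may overlap — at fine scales even coverage
requires it — and never span trajectory boundaries. A seeded random
placement mode exists for sensitivity checks. Scales no trajectory can host
are skipped with a logged notice rather than failing the run, so short
series still exercise the full pipeline.

Default window exponents are m = 5 and 6 (32- and 64-point windows),
reported side by side: larger windows at scale τ start to mix in the
neighbouring (coarser) scale, smaller ones make r noisy. The
`compare_exponents` table quantifies how little the choice matters.

## Aggregation

Per scale: mean r over defined-r windows; mean σ over all windows;
p_smooth = P(σ_tot < σ_p) strict, p_rough its complement (ties σ_tot = σ_p
count as roughening); quadrant percentages over defined-r windows (so
quadrant III fraction equals p_smooth restricted to defined-r windows);
equal-width histograms (default 50 bins, an analysis choice) spanning
[min, max] per statistic, right edge inclusive. Undefined-r windows are
excluded from r aggregates and quadrant tallies but kept in σ aggregates
and p_smooth/p_rough, which remain well defined without r. Windows are
pooled across trajectories. Both the all-window and defined-r window counts
are reported so either averaging convention can be reconstructed.

## The synthetic generator

Hydrated-protein energy fluctuations are hierarchical: vibrations at
femtoseconds, side-chain and backbone rotations from picoseconds up,
substate exchange at nanoseconds and beyond. The generator emulates this
with a mixture of Ornstein–Uhlenbeck (OU) components. Component k holds a
relaxation time θ_k (strictly increasing across components), amplitudes
A_k (into E_p) and B_k (into E_p–w), and a cross-correlation ρ_k carried by
a shared latent process:

    E_p   = μ_p + Σ_k A_k X_k
    E_p–w = μ_w + Σ_k B_k (ρ_k X_k + √(1−ρ_k²) Y_k)

with X_k, Y_k independent unit-variance stationary OU processes. The update
is the exact discretisation X(t+δ) = e^(−δ/θ) X(t) + √(1−e^(−2δ/θ)) ξ with
X(0) stationary, so there is no burn-in and the closed forms

    Var(E_p) = Σ A_k²,  Var(E_p–w) = Σ B_k²,  Cov = Σ ρ_k A_k B_k

hold from t = 0. A second closed form, the exact expectation of the
population window variance of an OU component at any (n, stride),
E[s²] = v·(1 − n⁻² Σ_{ij} e^(−|i−j|·stride/θ)), serves as the oracle for
the windowed σ estimates. Time units are abstract; only τ/δ and θ/δ enter
the analysis. Simulation is seeded and bit-reproducible.

What the generator emulates: coupled two-channel fluctuations with a
hierarchy of relaxation times, water-dominated amplitude (B ≫ A possible)
and tunable (typically negative) cross-correlation. What it does not:
non-Gaussian tails, aging/non-stationarity, discrete substate jumps, or any
force-field realism — energies are in abstract kcal/mol-scale units with
zero baseline by default. Passing tests on this generator validates the
*statistics pipeline*, not any claim about a specific protein.

### Default demonstration model

`slaving_demo_model` fixes the study conditions used by the analysis
drivers and the acceptance script: a fast, weakly coupled component
(θ = 5δ, A = 1.0, B = 0.4, ρ = −0.1) plus a slow, water-dominated,
strongly anticorrelated one (θ = 2000δ, A = 0.8, B = 2.4, ρ = −0.8);
six replicate trajectories of 2×10⁵ frames. The fast component's small
|ρ| encodes that fast vibrational noise in the two channels is nearly
independent; the slow component's B = 3A and ρ = −0.8 encode solvent
dominance with energetic compensation during substate exchange. These
values were chosen once, from the closed forms, to place the σ-ordering
transition (σ_tot above both components at fine scales, between σ_p and
σ_p–w at coarse scales) inside the analysed decade grid τ/δ ∈ {1, 10, 100,
1000}, and are not tuned thereafter.

## Known limitations and numerical caveats

- Short windows on processes much slower than the window span (τ·(n−1) ≪ θ)
  behave like Brownian paths; the window Pearson r is then biased toward 0
  (for ρ = −0.6, n = 64, span/θ ≈ 0.06 the mean window r converges to
  ≈ −0.55, not the i.i.d.-bias value ρ(1−(1−ρ²)/(2n)) ≈ −0.597). This is a
  property of the statistic itself, inherited by anything that aggregates
  windowed correlations across scales; mean r(τ) curves should be read as
  the windowed statistic, not as an unbiased estimate of an underlying ρ.
- Overlapping windows are statistically dependent; quoted Monte-Carlo
  standard errors in the tests therefore come from replicate independent
  trajectories (batch means over seeds), never from treating windows as
  independent.
- Problem sizes in the test suite and acceptance script (2×10⁵-frame
  series, ≤ 3000 windows per scale, ≤ 10 replicate seeds) were chosen so
  each statistical assertion carries a standard error several times smaller
  than its tolerance band.
- The NAMD-log reader sums user-declared ETITLE columns; it does not decide
  which force-field terms belong to E_p versus E_p–w (whether, e.g.,
  protein–ion terms join E_p is the user's call via the column mapping).
- No free-energy, entropy or barrier-height estimates are attempted: σ per
  scale is used as a roughness proxy, adopted, not derived.
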