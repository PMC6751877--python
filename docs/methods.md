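# Methods

## Models

All three circuits are deterministic mass-action/Hill ODE models with
concentrations in nM and time in hours.

**Repressilator** — six states (mRNA + protein per gene). Each mRNA is
produced at α/(1 + (R/Kd)ⁿ) + α₀ under repression by the upstream protein R,
degraded at δ_m; proteins are translated at β·m and degraded at δ_p.

**AC-DC circuit** — same six-state scaffold; the mX promoter is repressed by
both Z (Kd_a) and Y (Kd_b) — additive Hill terms in one denominator — while
X ⊣ Y (Kd_c) and Y ⊣ Z (Kd_d). The X/Y mutual repression forms a toggle
switch, the ring a repressilator; the same topology oscillates or latches
depending on kinetics. The extracellular signaling input of the original
circuit is outside scope; only the two kinetic modes (oscillation,
bistability) are analyzed.

**D flip-flop (master-slave)** — four protein states a, a_c (master) and q,
q_c (slave), driven by a square clock CLK and a data input d. Master
promoters respond to d and CLK with a competitive (Ω₁ = 0) or independent
(Ω₁ = 1) two-input Hill denominator — independence adds the cross term
(d/Kd)ⁿ(CLK/Kd)ⁿ; slave promoters implement an AND of the master output and
CLK. Degradation is either Michaelian shared-protease,
δ·E/(K_M + P) + δ_dil with P the total protein load (Ω₂ = 0), or linear δ
(Ω₂ = 1). In counter mode the input is wired d = q_c, which toggles the
output every clock cycle — a 1-bit counter at half the clock frequency.

Parameter bounds (the feasible box Θᵖ) follow physiological ranges:
transcription/translation 10⁻² – 50 h⁻¹, protein production 10⁻¹ – 50 h⁻¹,
protein degradation 10⁻³ – 50 h⁻¹, mRNA degradation 10⁻¹ – 100 h⁻¹,
dissociation and Michaelis constants 10⁻² – 250 nM, protease pool
10 – 1000 nM, Hill coefficient 1 – 5. The dilution rate (0.6 h⁻¹) and
reaction volume (V_R·N_A = 1 nM⁻¹) are fixed constants, excluded from
search and from all volume bookkeeping; flip-flop variants with linear
degradation drop K_M and E from the free parameters (p = 8 vs. 10).

## Numerics

Integration uses LSODA (adaptive, stiff-capable) at rtol 10⁻⁶ / atol 10⁻⁹
nM, sampled on a uniform output grid (default 0.05 h). Hill nonlinearities
with n up to 5 can be stiff. The flip-flop is integrated piecewise between
clock transitions with CLK held constant per segment, so the solver never
steps across a discontinuity. Output states are clipped at zero to remove
sub-tolerance negative excursions. Solver failures mark a candidate
non-viable; they never abort a search. Halving the tolerances moves the
measured period/amplitude of the repressilator benchmark by < 0.5%, and an
independent Radau integration of the same right-hand side agrees to within
solver tolerance (both under test).

Default evaluation horizons: 48 h (repressilator, AC-DC — the window of
every benchmark simulation), four clock periods = 96 h (flip-flop). The CLK defaults to a square wave, period 24 h,
duty 0.5, amplitude 100 nM; the amplitude is a configuration knob because
only the period is fixed by the benchmark.

## Costs and viability

A point is viable iff E(θ) clears its threshold. Readouts: protein X
(repressilator, AC-DC oscillation), X and Y (AC-DC bistability), q
(flip-flop).

**Harmonic MSE** (strict): E = Σᵢ(ĥᵢ − hᵢ)² over the first n harmonics
(default 10) of the mean-removed rectangular-window FFT, at the bins
nearest multiples of 1/T_ideal. The ideal sine is sampled on the same grid
so leakage bias cancels. Magnitudes are normalized so a pure sine of
amplitude A reports A. Viability: √(E/n) ≤ tol — "deviates on (rms) average
by at most tol nM per harmonic", the only sum-of-squares reading with nM
units. Study settings: repressilator scenario 1 A = 300 nM, T = 12 h,
tol = 10; AC-DC oscillation A = 200 nM, T = 12 h, tol = 15; flip-flop
A = 50 nM, T = 48 h, tol = 10. The rms reading is deliberate: a
mean-absolute reading would let a completely flat signal pass whenever the
ideal amplitude is below n·tol (5 nM average deviation for the 50 nM
flip-flop ideal), hollowing out the criterion. The cost is phase-invariant
(magnitudes only). Under these conventions the strict repressilator
criterion (scenario 1) is extremely selective: the benchmark parameter set
itself deviates by ≥ 20 nM rms per harmonic (its waveform carries a 60 nM
second harmonic), and the GA converges to a broad rms ≈ 52 basin without
reaching the viability boundary at any tested population, so the
scenario-1 region is empty to within search resolution in this
implementation.

**Peak prominence** (loose): local maxima of the magnitude spectrum (first
50 harmonic bins, prominence ≥ 1% of the spectral maximum) enter
E = −(1/P)Σσᵢ − Σᵢ≥₂(γᵢ − γᵢ₋₁), σᵢ the standard deviation of the 3-bin
window centered on peak i. The difference term telescopes to γ_P − γ₁.
Peak magnitudes enter **sorted ascending**, so the telescoped term equals
−(γ_max − γ_min) and one dominant prominent peak scores strongly negative.
Frequency-ordering was rejected on substance: with a dominant fundamental it
makes E positive, so no signal inside the 200–400 nM amplitude window could
ever reach the −200 threshold and the scenario-2 region would be empty,
contradicting the observed nonempty region ~20× larger than scenario 1.
Viability: E < E₀ (−200) and leading harmonic within the amplitude window.

**Time-domain MSE** (bistability): mean squared deviation of X and Y from
their target levels (high → 400 nM, low → 0 nM) under two swapped initial
conditions, evaluated after discarding the first half of the window so the
relaxation from the initial state does not dominate; viable iff rms ≤ 4 nM
in both scenarios. The discard fraction is a documented knob (default 0.5
for this cost, 0 for the spectral costs).

**Period/amplitude readout.** `measure_oscillation` reports the leading
harmonic of the full-window rectangular FFT: the period as the inverse of
its frequency, the amplitude as its magnitude ("the size of the leading
harmonic"). On the 48 h benchmark windows this reads 12.01 h / 283 nM for
the repressilator benchmark set (true inter-peak period 11.18 h; the
printed figure values 12 h / 300 nM are reproduced to bin resolution for
the period, while no standard estimator — rectangular or Hann FFT,
exact-period fundamental (342 nM), half peak-to-trough (349 nM) — lands
within 5% of the printed amplitude, which appears figure-rounded).
Peak-based diagnostics (inter-peak interval, half peak-to-trough) are
reported alongside.

## Search machinery

**GA** (defaults: population 5000, 10 generations, seeded RNG): uniform
initialization in the feasible box (linear scale; the multiplicative
mutation already takes relative steps), per-coordinate mutation ×U(0.8, 1.2)
with probability 0.75, two-point crossover with probability 1 per pair,
tournament selection of N individuals with k = N/10 drawn without
replacement, no elitism. Out-of-bounds children are clipped to the box.
All viable individuals from all generations are unioned (exact-duplicate
rows removed). A run with zero viable individuals raises a distinct
"no viable seed" outcome. The bistable AC-DC mode is a thin shell in 9
dimensions (the high steady level β·α/(δ_m·δ_p) must sit within ~1% of
400 nM while Kd_d stays ≲ 1 nM); seeding it reliably needs the full
population of 5000 — at population 500 the GA reproducibly stalls at
rms ≈ 4.03–4.1 nM against the 4 nM threshold without ever crossing.

**Local sampling** (defaults: N = 10⁵/iteration, 10 iterations, λ: 4 → 2
linearly): proposals mean + (z·λ·sdev)@components from the PCA of the
accumulated viable set; out-of-bounds proposals are discarded before
evaluation. New viable points are unioned with the set (accumulation
stabilizes the PCA; counts never shrink within a region). Convergence is
the Frobenius norm of the change in principal components after matching
rows by maximal |inner product| (Hungarian assignment) and sign alignment —
principal directions are defined up to sign and, at equal variance, up to
relabeling. Clustering triggers: (1) iteration budget exhausted, (2) this
iteration's viable yield fell 10× below the previous one (the root's
"previous" count is the GA harvest size), (3) the components jumped by more
than C₀ = 0.2·√p (the threshold scales with dimension; the value is a
package default — none is fixed by the study). The root region may split
at most once; children are never re-split and get a fresh iteration budget.
Clustering and the gap statistic operate on coordinates standardized by the
feasible-box span so nM- and h⁻¹-scaled axes weigh equally; K-means uses 10
restarts. The gap statistic draws 20 uniform reference sets over the
PCA-aligned bounding box (rotation-invariant) and picks the smallest k with
G(k) ≥ G(k+1) − s_{k+1} (reference spread inflated by √(1 + 1/n_ref)); a
bare argmax of G overestimates k on unimodal center-dense clouds, the
overestimation also reported in the original study. Multi-mode runs
evaluate each candidate against every cost until one accepts and tag it by
the accepting cost; after a split each region keeps the evaluator of its
majority tag.

**Volume**: the bounding box spans the min/max projections of a region's
viable points on its PCA basis, with no inflation margin (a margin knob
exists). Uniform samples in box coordinates are mapped back; samples
outside the feasible box count as non-viable without evaluation. Reported
per region: absolute volume (|ν|/|S|)·Vol(B), relative volume divided by
Vol(Θᵖ) over free parameters, and the achieved CLT confidence radius. The
printed sample-size bound coefficient at β = 0.95 is
|Φ⁻¹(0.025)|/2 ≈ 0.98 (the inverse-CDF argument is (1−β)/2; a (β−1)/2
argument would be outside the function's domain). Per-region volumes are
reported separately; sums over regions ignore potential overlap and are
used only for ratio comparisons.

**Stochastic validation**: the direct Gillespie method on propensities
obtained by evaluating each ODE production/degradation term at integer
copy numbers (one production and one degradation channel per term; 12
reactions for each circuit). The flip-flop clock enters as a
piecewise-constant time-varying propensity; jumps never cross a clock edge
(the waiting time is redrawn there), which is exact for piecewise-constant
rates. Ensemble summaries (default 100 runs): oscillatory — half the mean
peak-to-trough excursion and the mean inter-peak interval after a 1 h
moving-average smooth; bistable — |mean(high) − mean(low)| over the final
third. One amplitude convention is used everywhere.

## Desk-scale budgets

The test suite reproduces the study's qualitative results at reduced
budgets chosen once: evaluation horizon 48 h (96 h flip-flop) at 0.1 h
output steps; GA population 5000 × 10 generations where a mode is hard to
seed (AC-DC bistability), 300–1000 otherwise;
local sampling N = 1500–5000 over 4–5 iterations; 1500–5000 volume samples
per region. At these budgets volume ratios are order-of-magnitude
estimates: regions are less fully explored than at N = 10⁵ × 10 iterations,
so relative volumes are systematically smaller than full-budget values and
only their orderings and rough magnitudes are meaningful.

## What the synthetic fixtures do and do not show

Unit fixtures (Gaussian blobs, uniform boxes, disjoint-box and
inscribed-sphere oracles) have analytic ground truth for cluster counts,
containment and volumes; they validate the clustering, exploration and
Monte-Carlo machinery in isolation from ODE dynamics. They are convex and
axis-aligned (up to rotation), so they do not probe curved or filamentous
viable sets; the circuit benchmarks cover that partially. All generators
and search stages are seeded; fixed seeds make every pipeline bit
reproducible.

## Known limitations

- Viable-set shape claims rest on PCA boxes: strongly curved regions
  inflate Vol(B) and lower the hit fraction (cost, not bias).
- The gap statistic assumes a uniform null over the PCA box; heavy-tailed
  viable clouds can still mislead it (cluster cap 2 and the split-once rule
  bound the damage).
- SSA validation at reaction-volume scale 1 nM⁻¹ means hundreds of
  molecules; mean-field agreement is verified at system-size scalings 1 and
  10 (scale 100 is computationally out of desk range).
- Printed benchmark amplitudes (300 nM repressilator, 200 nM AC-DC) are
  reproduced only to ~6–7% by any standard estimator; see the readout note
  above.
- The flip-flop clock amplitude, duty and data-input wiring are free
  choices (only the 24 h period is fixed by the benchmark); they shift the
  viable-volume balance between functional-form variants. Under this
  package's defaults the competitive-binding/linear-degradation variant
  carries a large viable region of genuine 48 h counters, so robustness
  rankings across flip-flop variants should be read as conditional on the
  clock model.
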