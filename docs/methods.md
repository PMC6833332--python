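# Methods

## Model structure and assumptions

The model describes a closed, well-mixed culture transitioning from
exponential growth to replicative senescence. Its state is the number of
cells (in arbitrary units; only proportions are ever compared with data) in
N proliferative doubling-age classes P₀ … P_{N−1} and four terminal-ish
pools: growth-arrested G, apoptotic A, senescent S and dead D. Assumptions:

* **Deterministic, population-level dynamics.** Transitions are first-order
  rates; no stochastic single-cell effects, no spatial structure, no
  explicit SASP signalling mechanism (its presumed effect — arrest and
  senescence rates rising with age — is folded into the rate ladders).
* **Linear age dependence.** The four transition rates out of Pᵢ (division,
  jump to senescence, growth arrest, apoptosis) are linear in the doubling
  age i, parameterised by their endpoints at i = 0 and i = N−1 and
  interpolated over i/(N−1). This is the model's key structural assumption:
  it gives 8 rate parameters instead of 4N.
* **Mitosis factor 2.** A division removes the mother from Pᵢ and adds two
  daughters to Pᵢ₊₁; division out of the oldest class P_{N−1} adds two
  cells to S. All non-division transitions move cells one-for-one. Hence
  the grand total (D included) grows exactly at Σᵢ m_{PᵢPᵢ₊₁} Pᵢ, which the
  suite checks as a conservation property.
* **Irreversibility.** S is absorbing; growth arrest never reverts to
  proliferation (G feeds only S at the scalar rate m_GS); apoptotic cells
  clear into D at m_AD. G → A transitions are excluded. Dead cells detach
  and are invisible to every readout, so the live total TP = ΣP + G + A + S
  excludes D — without this, m_AD would have no observable effect.
* **Seed condition.** Unless overridden, simulations start with TP(0) = 1
  entirely in P₀: the first sampled passage is treated as a uniformly young
  founder population.

The system is linear and time-invariant, x′ = M x with M lower triangular,
hence non-stiff (eigenvalues are the negated exit rates, all of magnitude
≲ 0.04 h⁻¹ at realistic values).

The model has 13 tunable quantities — the 8 ladder endpoints, m_GS, m_AD,
and the three staining fractions below — plus the structural constant N,
which is configurable but not fitted.

## Marker mapping

The assays report the percentage of cells staining positive. Mapping, with
all channels fractions of TP and reported on the 0–100 scale:

| readout | composition |
| --- | --- |
| PD | log₂ TP(t)/TP(0) |
| SA-β-Gal | S |
| TUNEL | A |
| Ki-67 | ΣP + G_Ki67 · G |
| γH2AX | S + A + P_γH2AX · ΣP + G_γH2AX · G |

γH2AX includes *all* senescent and apoptotic cells; only the proliferative
and growth-arrested contributions carry free fractions (P_γH2AX, G_γH2AX ∈
[0,1], and G_Ki67 for Ki-67). Consequently γH2AX ≥ SA-β-Gal + TUNEL
pointwise, a property test. The observed ~30% γH2AX positivity of young
cultures is *not* hard-coded into P_γH2AX: at early times small G/S/A
pools also contribute, so the fitted fraction settles below the raw
percentage.

## Parameters

| parameter | meaning | units | reference value |
| --- | --- | --- | --- |
| mP0P1, mPN1PN | division rate at age 0 / N−1 | h⁻¹ | 0.0259, 0.0063 |
| mP0S, mPN1S | jump-to-senescence endpoints | h⁻¹ | 0.0026, 0.0053 |
| mP0G, mPN1G | growth-arrest endpoints | h⁻¹ | 0.0018, 0.0037 |
| mP0A, mPN1A | apoptosis endpoints | h⁻¹ | 0.0018, 0.0016 |
| mGS | growth-arrested → senescent | h⁻¹ | 0.0007 |
| mAD | apoptotic → dead | h⁻¹ | 0.0010 |
| PgH2AX, GKi67, GgH2AX | staining fractions | — | 0.2385, 0.9979, 0.8237 |
| N | division limit | — | 50 |

Division slows with age while senescence and arrest accelerate — the
biological picture of telomere attrition and accumulating damage. With the
reference set the simulated culture plateaus after ~2500 h; the
growth-arrested fraction G/TP passes through an interior maximum at
~1836 h (computed by `scripts/acceptance.py`), a consequence of the G → S
drain: with m_GS = 0 the fraction is monotone and no peak exists. The
senescent fraction reaches 85% of the live population at ~3374 h, and at
5000 h essentially only S and G cells remain.

## Integration

Default solver: adaptive explicit Runge–Kutta (SciPy RK45), rtol 1e-8,
atol 1e-10, dense output for root finding (threshold crossings). Because
the system is LTI, a matrix-exponential propagator (`method="expm"`) gives
machine-exact states on coarse grids at ~1 ms per evaluation; the fitting
loop uses it throughout. The suite cross-checks the two paths against each
other, against a fixed-step classical RK4 oracle at h = 0.01 h over
5000 h (< 1e-5 relative), and against closed forms (N = 1 collapse,
pure-exponential cascade).

## Cost function

Range-normalised weighted MSE: per marker, residuals are divided by that
marker's observed range (max − min over all its records) before squaring;
per-marker means over records are summed with weights (default 1). This
makes PD (span ~17 doublings) and the percentage channels commensurate and
makes "percent increase in error" statistics scale-free. Replicates enter
as individual records, so the cost is invariant to record order and to
duplicating every replicate.

PD alignment: a culture sampled mid-life reports cumulative doublings
(first sample ≈ PD 5) while the model's PD starts at 0. Default
`subtract-first` subtracts the mean observed PD at the earliest sampled
time; `free-offset` profiles out an additive constant analytically;
`none` compares raw values. Under `subtract-first` the offset anchor is
the earliest time *present in the dataset being fitted* — reduced designs
that remove the earliest passages therefore pay a genuine (and intended)
alignment penalty when scored against the full data.

## Optimisation

Search space: the 10 rates log-uniform in [1e-5, 1e-1] h⁻¹ (the reference
values span 7e-4 to 2.6e-2; the log scale equalises sensitivity), the 3
fractions uniform in [0,1]; everything is optimised on a normalised
13-gene unit genome.

GA defaults: population 200, 300 generations, tournament selection (size
3), uniform crossover p = 0.7, per-gene Gaussian mutation (σ = 10% of the
gene range, p = 0.15), elitism 2, seeded RNG (bit-reproducible). A warm
start individual can be injected, which the design/holdout/N-sweep refits
use to keep desk-scale runtimes; a cold start is the default otherwise.

Refinement: L-BFGS-B on the genome with 3-point finite-difference
gradients, bounds [0,1] per gene, up to 500 iterations, gtol 1e-8; the top
GA candidates are each polished and the best kept. The projected-gradient
norm at termination is reported as the local-minimum check; a refinement
that fails to improve returns its start flagged with a warning.

On noise-free synthetic data this pipeline at a *reduced* budget
(population 60, 60 generations) recovers all 13 generating parameters to
~4 significant digits with final cost ~1e-12 — the suite asserts cost
< 1e-4 of the marker variance and marker-trajectory overlay within 0.5
percentage points.

## Synthetic data

The generator reproduces the study design the model targets: 16 passages
(numbered 5–20) at 160 h spacing (0–2400 h — per-passage culture times are
not individually specified anywhere, so uniform spacing reproducing the
~2400–2500 h span is used and is configurable), all five markers in
triplicate (240 records, 80 per-passage marker series), additive Gaussian
replicate noise truncated to [0,100] (percent) or [0,∞) (PD). Default
noise: σ = 3 percentage points for the stains — plausible counting noise
for ≥300 cells per field — and 0.2 doublings for PD; these are conventions,
not estimates of any particular assay's variance. PD is emitted with a +5
offset so the fitting layer's subtract-first alignment is exercised.

What passing tests on these data do **not** show about real cultures: the
generator draws from the model itself, so structural misfit (cell-cycle
phase composition, freeze–thaw perturbations, density effects, non-linear
age dependence of rates, correlated or non-Gaussian assay noise) is outside
its reach. Recovery results certify the estimation machinery, not the
biological adequacy of the model.

## Design and sensitivity analyses

`design_strategy_error` refits on a reduced design and scores the refit on
the **full** dataset, reporting 100·(cost_reduced_refit −
cost_full_fit)/cost_full_fit — the error measures information lost, not
goodness-of-fit to the points kept. Strategies: drop the k earliest or
latest passages, skip with stride k (retain the first passage and then
every (k+1)-th: stride 2 keeps 6 of 16 passages, 30 of 80 measurements),
or drop a centred block of k passages. On the default noisy dataset,
dropping the late passages is markedly worse than regular skipping at
matched points retained.

`sensitivity_grid` / `sensitivity_scan` evaluate the cost over one ladder's
(first, last) endpoint pair (default 41×41, log-spaced over [¼×, 4×] the
optimum; the diagonal is the flat, age-independent ladder) or over one
scalar parameter (default 101 points), holding everything else fixed.
Simulation failures at extreme rates become NaN cells, not crashes.

Numerical guards: percent-increase statistics divide by
max(baseline cost, 1e-6 × marker variance) — on noiseless self-consistent
data the baseline is numerically zero and an unguarded ratio would amplify
1e-12-scale optimiser round-off into arbitrary percentages. Results also
carry the raw cost surfaces, which are what the noiseless-truth tests
compare. The growth-arrest peak locator sharpens the grid argmax with a
three-point quadratic fit and signals "no peak" when the maximum sits on
the window boundary; the time-to-threshold routine bisects on the dense
solver output.

## Problem sizes in the test suite

The suite runs the full study design (16 passages × 5 markers ×
triplicates, N = 50) but reduced optimiser budgets: GA population 60 with
40–60 generations for fits, pure-refinement refits inside holdout and
noiseless design loops, 9–21-point sensitivity grids. These choices keep
the whole suite at a few minutes on one CPU while leaving the asserted
margins (often several orders of magnitude) intact.

## Known limitations

* The supplement-level equations of the original formulation are
  reconstructed from the stated transition rules; the contract implemented
  here (factor-2 mitosis, one-for-one jumps, G → S and A → D scalar flows,
  D excluded from TP) is normative for this package.
* Printed reference rates carry 1–2 significant figures; landmark times
  computed from them inherit that uncertainty (the G/TP peak sits on a
  broad plateau — the fraction stays within 5% of its maximum for roughly
  1500–2160 h).
* No uncertainty quantification beyond holdout and sensitivity surfaces
  (no posterior/MCMC); no cell-cycle phase structure; no reversal of
  growth arrest; no G → A flow; percentage truncation makes extreme-noise
  settings biased near the 0/100 rails (negligible at the default σ = 3
  away from the rails, as tested).
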