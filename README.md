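# replisen

Population dynamics of a cell culture's transition to replicative
senescence.

Continuously passaged primary cells (the canonical system is human dermal
fibroblasts) stop dividing after a finite number of population doublings.
The culture is never a single cell type along the way: proliferating,
growth-arrested, apoptotic and senescent cells coexist, and the standard
assays — population doublings (PD), SA-β-Gal, Ki-67, γH2AX, TUNEL — each
report overlapping mixtures of those states rather than senescence alone.
`replisen` implements an age-structured compartment model that turns joint
marker time courses into an explicit description of the proportion of cells
in each state over the whole replicative life span, for experimentalists
quantifying senescence and for modellers studying fitting and
experimental-design questions on this system.

## The model

Proliferative cells are split by *doubling age* i (mitoses completed) into
subpopulations P₀ … P_{N−1}, with N = 50 a Hayflick-like division limit.
Each age class divides or jumps into the growth-arrested (G), apoptotic (A)
or senescent (S) pools, with all four rates linear in doubling age
("rate ladders" m_{PᵢX}). Division feeds the next age class with the
mitosis factor 2; division out of P_{N−1} lands in S. Two scalar rates
complete the flow: G → S at m_GS and A → D (a dead pool, invisible to the
assays) at m_AD:

    dP₀/dt = −(m_{P₀P₁} + m_{P₀S} + m_{P₀G} + m_{P₀A}) P₀
    dPᵢ/dt = 2 m_{Pᵢ₋₁Pᵢ} Pᵢ₋₁ − (m_{PᵢPᵢ₊₁} + m_{PᵢS} + m_{PᵢG} + m_{PᵢA}) Pᵢ
    dS/dt  = 2 m_{P_{N−1}P_N} P_{N−1} + Σᵢ m_{PᵢS} Pᵢ + m_GS G
    dG/dt  = Σᵢ m_{PᵢG} Pᵢ − m_GS G
    dA/dt  = Σᵢ m_{PᵢA} Pᵢ − m_AD A
    dD/dt  = m_AD A

The live total is TP = ΣP + G + A + S and PD(t) = log₂ TP(t)/TP(0). The
five readouts are constant mixtures of the live pools: SA-β-Gal = S/TP,
TUNEL = A/TP, Ki-67 = (ΣP + G_Ki67·G)/TP, γH2AX = (S + A + P_γH2AX·ΣP +
G_γH2AX·G)/TP. The 13 tunable quantities (8 ladder endpoints, m_GS, m_AD,
3 staining fractions) are estimated by a genetic algorithm over
log-scaled rates followed by box-constrained quasi-Newton refinement,
minimising a range-normalised mean squared error across all markers and
replicates. A packaged reference parameter set ships with the library.

## Worked example

Generate a synthetic triplicate experiment (16 passages, p5-p20, ~2400 h)
from the reference parameters, then re-estimate the parameters from it:

```python
import replisen as rs

params, mparams = rs.reference_parameters()
dataset = rs.generate_dataset(params, mparams, rs.DesignSpec(seed=42))

model = rs.SenescenceMarkerModel(dataset)
fit = model.fit(seed=7, ga_config=rs.GAConfig(population_size=60, generations=40))
print(fit.summary())
```

```
Senescence marker model fit
==============================================
records                                    240
age classes (N)                             50
cost (range-norm. MSE)               0.0250736
GA generations                              40
refine iterations                          493
gradient norm                         1.29e-07
seed                                         7
----------------------------------------------
parameter             estimate  units
----------------------------------------------
mP0P1                0.0270659  h^-1
mPN1PN              0.00778036  h^-1
mP0S                0.00280927  h^-1
mPN1S               0.00539282  h^-1
mP0G                 0.0034157  h^-1
mPN1G               0.00257987  h^-1
mP0A                0.00163505  h^-1
mPN1A                0.0020592  h^-1
mGS                0.000183993  h^-1
mAD                  0.0016751  h^-1
PgH2AX                0.206997  fraction
GKi67                 0.950247  fraction
GgH2AX                0.871068  fraction
==============================================
```

The cost (0.025) is the noise floor of the simulated triplicates; the
division-ladder endpoints (0.0271 → 0.0078 h⁻¹ against a generating truth
of 0.0259 → 0.0063 h⁻¹) recover the slowing of the cell cycle with
doubling age, and the gradient norm confirms the refinement terminated at
a local minimum. On noise-free data the same pipeline returns the
generating parameters to four significant digits.

Landmarks of the reference model from the command line:

```bash
$ replisen peak
growth-arrest fraction peaks at 1835.9 h
$ replisen t2sen --threshold 0.85
senescent fraction reaches 85% at 3374.2 h
```

Everything else hangs off the same objects: `fit.predict()` returns the
five marker trajectories, `fit.holdout()` measures refit stability under
record removal, `rs.design_strategy_error` scores sparse sampling designs
(drop-first / drop-last / skip / drop-middle-block), and
`rs.sensitivity_grid` / `rs.sensitivity_scan` map the cost surface around
an optimum. The `replisen` CLI exposes `simulate`, `fit`, `generate`,
`design`, `sensitivity`, `peak` and `t2sen` over CSV/JSON/YAML files.

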