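# Methods

This note documents the models, conventions and numerical choices behind
`glucoge`, in the order data flows through the package.

## Physiological preprocessing

**Meal absorption.** A meal of `CHO` grams eaten at time `t_m` contributes
a glucose rate of appearance

    Ra(t) = CHO · CHO_BIO · τ · exp(−τ / t_max,G) / t_max,G²,   τ = t − t_m ≥ 0

with population defaults `t_max,G = 50 min` (peak time) and
`CHO_BIO = 0.8` (bioavailable fraction; the kernel integrates to 1, so
quadrature recovers exactly `CHO_BIO·CHO`). Meals superpose linearly. The
kernel is truncated at `τ > 12·t_max,G`, where it is below ~7·10⁻⁵ of its
peak. Carbohydrate mass is kept in **grams** end to end, so Ra is on a
g/min scale; a `mass_factor` argument converts to the conventional mg/min.
Downstream, the evolved constants absorb any fixed scale, so the choice of
unit does not affect the forecaster.

**Insulin on board.** Deliveries `u(t)` (basal U/min plus boluses as
one-sample impulses, matching pump records) drive

    dC1/dt = u − K·C1,   dC2/dt = K·(C1 − C2),   IOB = C1 + C2

integrated by explicit forward Euler on the native 1-min grid
(`K·dt = 0.039 < 1`, so the scheme is stable). The closed-form impulse
response is `D·e^(−Kt)(1 + Kt)`; the discrete scheme converges to it at
first order in `dt` (verified in the tests by step-halving). The only
published (DIA, K) pair is (2 h, 0.039 /min); it is kept as a one-entry
lookup rather than a fitted mapping.

**Bolus calculator.** `I_bolus = CHO_est/CR + correction`. The printed form
of the correction, `(G_T − G_B)/CF`, *subtracts* insulin when glucose is
above target; the clinical convention is `(G_B − G_T)/CF`. The package
defaults to the clinical convention and keeps the printed form behind
`correction="as-printed"`. Negative totals clamp to zero (a pump cannot
withdraw insulin).

## Grammar and expression semantics

The shipped grammar (`data/glucose.bnf`, 13 rules) derives expressions

    pred(n) = (G-block op Ra-block op IOB-block) op Circadian

where each block is a **sum** of terms `preop(X[n − lag]/α) op δ` built by
the recursive `[X] → GetX(...)[X] | λ` rules, and the circadian block is
`A op cos(ωn + φ)` with `op ∈ {*, /}`. Conventions, where the grammar
excerpt left room:

- **Constants.** Each `Get*` call carries two `[Cte]` arguments — the
  divisor α, then the offset δ — both three-digit constants in
  [00.0, 99.9]. (The published grammar excerpt prints `Get*` with four
  arguments, but the accompanying expression semantics and worked example
  require per-term constants; the grammar here makes them explicit.)
- **Lag window.** `PrevIni` is the lag actually read; `PrevFin` is retained
  and the constraint `PrevIni < PrevFin` is enforced by *normalization*:
  a violating pair is reordered, and an equal pair widens by one grid step.
  Rejection was tried first and discarded — it invalidated ~46% of terms
  and crippled the evolutionary search without changing the phenotype
  space.
- **Pre-operators.** `sqrt|sin|log|pow|exp|cos`, chainable; a chain
  `f g` applies as `f(g(x))`. `pow` squares (it is unary in the grammar).
- **Empty blocks.** A λ block stands for the neutral element of the
  operator joining it (0 for `+`/`−`, 1 for `*`/`/`).
- **Circadian.** `GetCircadian(op, A, w, φ)`: the first constant is the
  amplitude (clipped to 28 mg/dl ≈ 20% of a 140 mg/dl representative mean,
  the grammar's stated day-to-day bound), the second the frequency in
  cycles/day (`ω = w·2π/288` rad per 5-min sample), the third the phase in
  radians. The assignment order is a convention of this package.
- **Protected arithmetic.** Division by zero → 1; `log` and `sqrt` act on
  magnitudes with `log(0) = 0`; `exp` arguments clip to [−50, 50]; `pow`
  results clip to ±10¹⁰; every intermediate clips to ±10¹⁰ with NaN → 0.
  Consequently any derivable expression is finite on finite inputs, and
  fitness values stay comparable.

Genotypes are variable-length strings of 8-bit codons. Mapping is the
standard leftmost GE derivation: at each choice point the production index
is `codon mod n_productions`; single-production rules consume no codon.
"Max wraps 2" is read as two *additional* passes over the codon string.
A derivation exceeding 4000 pending symbols is declared invalid (wrapped
genotypes can otherwise grow without bound). Expressions serialize to their
phenotype text, which parses back bit-exactly.

Signals are aligned by computing Ra and IOB on the 1-min event grid and
subsampling at the CGM timestamps, so all grammar lags count 5-min CGM
samples; lag 24 = 120 min of history, and the prediction horizon is 24
samples ahead of the evaluation index.

## Fitness and metrics

The training loss is the glucose-specific MSE, applied pointwise:

    gMSE = mean_t [ Pen(g_t, ĝ_t) · (g_t − ĝ_t)² ]

The printed penalty equation is typographically corrupted; this package
reconstructs it as two weighted products of C¹ smoothstep transitions
(`s(u) = 3u² − 2u³` clamped to [0, 1]):

    Pen(g, ĝ) = 1 + α_L · [1 − s((g − T_L)/β_L)] · s((ĝ − g)/γ_L)
                  + α_H · s((g − T_H)/β_H) · s(−(ĝ − g)/γ_H)

with α_L = 1.5, α_H = 1, β_L = 30, β_H = 100, γ_L = 10, γ_H = 20,
T_L = 85, T_H = 155 (mg/dl). Both error-axis factors vanish at zero error,
so exact forecasts are never penalized; Pen is continuous, bounded in
[1, 1 + α_L + α_H] = [1, 3.5], and satisfies the clinical ordering
Pen(50, 75) > Pen(175, 150). Because the two terms are exclusive in `g`,
the attained supremum is 1 + α_L = 2.5. The reconstruction is isolated in
`metrics.pen`, so an alternative reading changes one function.

Accuracy is reported as RMSE, MAD (mg/dl), MARD (%) and their
penalty-weighted versions (gRMSE = √mean(Pen·e²), etc. — the g-versions
dominate their plain counterparts since Pen ≥ 1). MAD is reported in
mg/dl, matching the tabulated results rather than the "%" in one formula
header. Clarke error-grid classification uses the canonical published
boundary inequalities with ties resolved toward the more benign zone (a
pair exactly 20% off is zone A); inputs clamp to the 400 mg/dl grid edge.

## Evolution

Generational loop with the published operator set and parameters:
population 50, 2000 generations, crossover 0.90, integer-flip mutation
0.005 per codon, elitism 2, tournament size 2, wrap budget 2. Reduced
budgets for tests and examples use the same operators. Implementation
choices:

- Initial genotypes are uniform random, 15–100 codons (configurable).
- Invalid mappings receive worst-marker fitness (`inf`) and still take part
  in selection, keeping the population size fixed without repair.
- Crossover draws an independent cut point in each parent, uniform over the
  parent's **expressed region** (the codons actually consumed during
  mapping) — effective crossover. Cutting uniformly over the whole string
  was tried first and discarded: with most material unexpressed, crossover
  was usually silent and the search stagnated at reduced budgets.
- Cut pairs that would produce an empty child are redrawn, preserving the
  total codon count.
- Piecewise training excludes off-segment timestamps from the loss sum
  entirely — mathematically equivalent to holding the model output constant
  there, and cheaper.
- Fitness is cached by codon string; mapping and evaluation dominate
  runtime. Expression evaluation is vectorized over all training
  timestamps.
- Forecasts are clipped to [1, 10⁶] mg/dl before the loss, keeping them in
  the metric domain.

## Synthetic virtual patients

The generator reproduces the *statistical structure* of the original
in-silico data without its proprietary physiology. Behavioral layer (the
stated scenario): three meals/day near 07:00/13:00/19:00 (±30 min uniform
jitter — an invented realism knob), Gaussian masses with means
50/60/63.5 g and 20% CV (floored at 10 g); carb-counting error
`(1 + ε), ε ~ N(0, 0.20)`; preprandial SMBG with 5% CV noise; boluses from
the clinical calculator; 20-g rescues every ≥ 20 min while SMBG < 60 mg/dl
(SMBG is re-checked every 20 min whenever true BG < 80 mg/dl — a
monitoring-behavior assumption); time-varying basal following circadian
insulin sensitivity of 20% amplitude.

Glucose dynamics are a deliberately minimal surrogate:

    dBG/dt = −S_G·(BG − G_endo) − k_I·c(t)·X2 + k_meal·Ra(t)
    dX1/dt = p2·(u − X1),  dX2/dt = p2·(X1 − X2)
    c(t)   = 1 + A·sin(2π(t − φ)/1440)

Defaults: S_G = 0.01 /min, G_endo = 180 mg/dl, k_I = 40 mg/dl per U,
k_meal = 5 mg/dl per g absorbed, p2 = 0.0125 /min, A = 0.20. The two-stage
insulin-action chain gives the sigmoidal onset of rapid analogs with peak
effect at 1/p2 = 80 min — deliberately *after* the 50-min meal-absorption
peak, which is what produces realistic postprandial excursions and
occasional late hypoglycemia. Total effects are timing-independent:
1 U lowers BG by k_I mg/dl, 1 g raises it by k_meal·CHO_BIO. The basal
profile is the circadian steady-state solution for an individual glycemic
set point (drawn per patient from U(110, 150) mg/dl with a lognormal
setting bias, σ = 0.08), which spreads cohort mean glucose the way real
cohorts spread. Interpatient draws further vary body scale, insulin
sensitivity, S_G, G_endo, p2, circadian phase, and therapy CR/CF (the
physiologic values with 10% setting error). BG is clamped to
[20, 600] mg/dl; integration is explicit Euler at 1 min.

The CGM is a first-order 10-min lag filter of plasma BG plus AR(1) noise
(ρ = 0.7, stationary SD 3 mg/dl), sampled every 5 min and floored at
39 mg/dl; 14 days yield exactly 4032 samples. What the surrogate does
*not* emulate: the reference simulator's multi-compartment physiology and
validated population, published sensor error models, exercise, illness.
Tests passing on this cohort therefore demonstrate that the pipeline is
correct and that evolved models beat naive baselines on data with realistic
structure — not clinical performance on real patients.

## Experiment protocol

14 consecutive days per patient: the first 10 train, the last 4 test. Days
tile into four 6-h segments — Nocturnal 01:00–06:59, Breakfast 07:00–12:59,
Lunch 13:00–18:59, Dinner 19:00–00:59 (wrapping midnight) — as half-open
windows on the 5-min grid. A forecast belongs to the segment owning its
*target* time, not the time it is made; history may cross segment
boundaries. The first 120 min of a record provide no training pairs
(insufficient lag history). An alternative postprandial scheme
(09:00–13:00, 15:00–19:00, 19:00–01:00) trains models that skip the first
2 h after breakfast and lunch; its third window is kept exactly as
tabulated in the source (6 h, not 4) even though that is inconsistent with
the skip-2-h description — the inconsistency is inherited, not introduced.
Reports mirror the 12-column tabulated layout (six metrics + five zones +
A+B) per segment for training and testing; with equal-width segments the
"24 hour" row is the arithmetic mean of the segment rows.

## Problem sizes and reproducibility

The full-scale run (100 patients × 4 segments × 2000 generations) is a
batch job; the shipped tests and examples use reduced budgets chosen as
this package's standard desk-scale conditions: 3–5 patients, population
30, 100–200 generations. Every stochastic component takes an explicit
seed; cohort members get child seeds from a master `SeedSequence`, and
per-segment evolution seeds derive deterministically from the run seed, so
simulations, training and serialized models reproduce bitwise.

## Known limitations

- The GE search with the published operator probabilities needs several
  hundred generations to pin down the three-digit term constants; at a
  100-generation desk budget it reliably recovers model *structure* but
  usually not exact constants. The acceptance suite documents this
  honestly rather than relaxing the published parameters.
- The penalty reconstruction fixes a smoothstep transition shape; only the
  ordering, bound and continuity properties — not the exact shape — are
  asserted.
- The worked-example expression from the source prints a lag (24) and a
  constant (909.1) outside the grammar's own grids; the derivability
  fixture maps them to the nearest grid values (22; 90.9).
- No exercise inputs, alarm logic, or real-sensor error models.
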