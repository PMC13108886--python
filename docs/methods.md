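# Methods

## The model

The package implements a seven-variable ODE description of the nutrient-gated
pheromone MAPK cascade of fission yeast. The dynamic quantities, in
integration order, are

| state | meaning | units |
|---|---|---|
| `Ste11` | master transcription factor for the mating programme | arbitrary |
| `Ste4_6` | lumped pheromone sensing unit (receptor/adaptor supply) | arbitrary |
| `aRas1` | active fraction of the GTPase Ras1 | fraction, ≤ 1 |
| `aCdc42` | active Cdc42 in CRIB-reporter signal units | signal, ≤ k19 |
| `ppByr1` | active (phosphorylated) fraction of the MAPKK Byr1 | fraction, ≤ 1 |
| `tSpk1` | total MAPK Spk1 in Western-blot signal units | signal |
| `ppSpk1` | dually phosphorylated Spk1 in blot signal units | signal |

Nitrogen status enters through a smooth depletion step

```
N(t) = (1/π) [ arctan((t − (100 + k24)) / k25) + π/2 ]
```

which rises from ~0 (rich medium) to ~1 (starved) around model time
`100 + k24` with steepness `k25`. Model time and experimental time are
distinct axes: integration always starts from the all-zero state at model
time 0, the window [0, 100] serves as a vegetative burn-in, and experimental
hour `h` (hours after the shift to starvation medium) maps to model time
`100 + h`.

The rate equations (see `pombesig/model.py` for the exact code) comprise
nutrient-driven Ste11 induction with a ppSpk1→Ste11 positive feedback,
Ste11-driven synthesis of the sensing unit and of total Spk1, and the
cascade Ste4/6 → Ras1 → {Cdc42, Byr1} → Spk1 with saturating activation
terms, nitrogen-dependent inhibition of the Cdc42 and Byr1 nodes, and
normalisation constants `k12` (blot signal per unit phosphorylated fraction
of Spk1) and `k19` (CRIB signal at full Cdc42 activation).

Three structural variants share this backbone:

* **Model A** — no negative feedback (the ppSpk1→Ste4/6 term is off); the
  nitrogen inhibition of Byr1 uses `k6`.
* **Model B** — adds the delayed negative feedback in which ppSpk1 enhances
  turnover of the sensing unit with strength `k6` (summarising Sxa2/Rgs1-type
  attenuation). Because `k6` now drives the feedback, the Byr1 nitrogen term
  uses its own constant `k26`.
* **Model C** — extends B with a Cdc42-dependent boost of Spk1
  phosphorylation (`k27`) and, only in `ras1.G17V` backgrounds, two
  ppSpk1-dependent attenuations of Ras1-downstream activation (`k28`, `k29`).

## Genotypes

Strains are declarative constraint lists (`GenotypeSpec`): *clamps* fix a
state variable to a constant — the variable is removed from the integrated
system entirely — and *rate scalings* multiply the Ras1-activation (`k7`)
and/or Byr1-activation (`k13`) constants. Clamps take precedence over
scalings touching the same node. The built-in registry:

| token | effect |
|---|---|
| `ras1.G17V` | clamp `aRas1 = k22` (constitutively active Ras1) |
| `byr1.DD` | clamp `ppByr1 = k23` (phosphomimetic MAPKK) |
| `scd1del` | clamp `aCdc42 = 0` |
| `ras1del` | clamp `aRas1 = 0` |
| `byr1del` | clamp `ppByr1 = 0` |
| `byr2del`, `ste4del` | `k13 × 0` |
| `ste6del` | `k7 × 0` |
| `gpa1del` | `k7 × 0`, `k13 × 0` |
| `h-` | `k7 × 0.01`, `k13 × 0.01`, clamp `Ste4_6 = 0.2` |
| `gpa1.QL` | restores `k7`/`k13` multipliers to 1 (provisional encoding) |

Compound names are whitespace- or `+`-separated tokens
(`"gpa1del ras1.G17V byr1.DD"`); unicode deltas and `_delta` suffixes are
accepted. The `gpa1.QL` encoding is an inference: a constitutively active
Gα should bypass the receptor-level attenuation of the heterothallic
background, so it undoes the scaling reductions while the low sensing-unit
clamp of `h-` stays.

The 20-strain prediction panel (`PREDICTION_PANEL`) contains every strain of
the epistasis experiments that is not one of the five training genotypes
(`WT`, `ras1.G17V`, `byr1.DD`, `ras1.G17V byr1.DD`, `scd1del`).

## Numerics

The right-hand side is compiled with numba and integrated with LSODA
(`scipy.integrate.odeint`), which switches automatically between stiff and
non-stiff methods. Clamped variables are substituted as constants before
compilation so the solver only sees the free subsystem. Default tolerances
are `rtol 1e-8 / atol 1e-10`; fitting loops use `1e-7 / 1e-9`
(`FIT_SOLVER`). A solve of the full 7-state system over 25 output hours
costs ~2 ms, which keeps the multi-thousand-solve acceptance sweeps and the
MCMC chains inside their time budgets. Integration failures raise
`SimulationError`; the likelihood maps them to `-inf`.

## Likelihood and fitting

Measurements are tidy records `(genotype, observable, hour, mean, sd, n)`.
The joint Gaussian log-likelihood is

```
log L = Σ_i [ −½ log(2π σ_i²) − (M_i − D_i)² / (2 σ_i²) ]
```

with `M` from simulation. `sd` is treated as a standard deviation; zero or
missing values are floored at 5% of the per-observable maximum mean so each
record contributes a proper density.

Fitting is two-stage, mirroring the printed protocol:

1. **`initial_fit`** — bounded nonlinear least squares (`scipy` trf) on the
   scaled residuals, run in log-parameter space inside the box
   `0.1 ≤ k ≤ 10`, with a seeded multi-start. Residuals are clipped at
   ±1e6 so near-divergent corners of the box stay finite for the optimiser.
2. **`mcmc_fit`** — Metropolis refinement with multiplicative proposals
   `k′ = k · exp(r)`, `r ~ Normal(0, 0.01²)` i.i.d. over the free parameters
   (joint update by default), 100,000 steps in production, keeping the
   highest-likelihood visit. An optional `jacobian_correction` flag enables
   the exact Metropolis–Hastings ratio for the multiplicative proposal; the
   default (off) matches the printed protocol, which uses the plain
   likelihood ratio. Optional `bounds` reject proposals outside the box.

## Synthetic ground truth

`pombesig/data/model_b_truth.json` is a Model B parameter point inside the
fitting box, found once by fitting hand-drawn target shapes with
`fit_pipeline` (bounded least squares plus a 20,000-step box-restricted
chain) and then frozen. Under it:

* wild-type ppSpk1 pulses with an interior peak at hour 6 and attenuates by
  ~45% by hour 24;
* `byr1.DD` is sustained (the clamp bypasses the feedback's entry point);
* `scd1del` peaks at ~54% of the wild-type peak;
* `gpa1del`, `byr1del`, `ste4del`, `byr2del` are flat at background;
* `gpa1del byr1.DD` is sustained (epistasis of the clamp over the null).

Mechanistically, the transient requires the sensing unit to overshoot: with
strong feedback (`k6` large) and an unsaturated downstream (small
`k13/k16`, `k20·ppByr1` comparable to `k21`), Ste4/6 accumulates during the
first hours, ppSpk1 rises after it with the `tSpk1` expression delay, and
the feedback then collapses the sensing unit to a lower steady state. If
the downstream saturates, the overshoot is compressed away and the response
is monotone — which is also why Model A (no feedback) produces no transient
anywhere in the box (acceptance criterion 3).

`generate_dataset` draws per-record replicates `M + Normal(0, σ²)` truncated
at zero, with `σ = max(rel_sd, sd_floor) · panel_max` per observable
(homoscedastic within an observable), and stores their mean and sample SD.

## Dynamics classification and the trace procedure

`classify_dynamics` labels a course *minimal* if its peak is below 5% of the
reference maximum, *transient* if the maximum is interior and the final
value has declined by ≥ 30% from it, and *sustained* otherwise. Both
thresholds are exposed (`ClassifierThresholds`).

`smooth_align_traces` reproduces the cortical CRIB-profile procedure:
centred rolling mean over ±5 samples (window truncated at the boundaries,
so output length equals input length), alignment of each smoothed trace so
its maximum sits at position 0 (ties resolved to the earliest index), and a
mean curve over the union of aligned supports with per-position SEM
(sample SD / √n over the covering traces; 0 where only one trace covers).

## Design decisions

* **k26 substitution (Models B/C)**: `k6` appears both in the feedback and
  in the Byr1 nitrogen term of the base model; reusing one constant for two
  unrelated roles would couple them, so B/C use `k26` for the nitrogen term.
* **All-zero initial state + 100 h burn-in**: initial conditions are not
  part of the parameter vector; the burn-in lets every genotype relax to its
  vegetative rest state before the nutrient step.
* **Clamps remove variables from the system** rather than zeroing their
  derivatives inside the solver, which keeps the integrated system
  non-stiff in the clamped direction and makes precedence over rate
  scalings structural.
* **State-bounds checks apply to free variables**: a clamped variable equals
  its clamp by construction, and a sampled `k22`/`k23` above 1 would
  trivially violate a ≤ 1 bound that the saturation structure only
  guarantees for integrated variables.
* **`sd` is a standard deviation** in the likelihood (not a variance); the
  5% SD floor makes zero-SD records usable.
* **Classifier thresholds** (5% minimal, 30% decline) are artifact choices
  exposed in configuration.
* **Scaled-down test protocol**: chains of 10,000 steps and least-squares
  budgets of tens of iterations; the production default remains 100,000.

## Limitations

* The equations use lumped, phenomenological saturation terms; parameters
  are effective constants per model-hour, not biochemical rate constants.
* The `gpa1.QL` encoding is provisional (see above).
* The likelihood assumes independent Gaussian errors with per-observable
  homoscedastic floors; replicate correlation structure is not modelled.
* The Metropolis sampler is used as a stochastic optimiser (best-of-chain),
  matching the original protocol; posterior summaries from a single
  un-corrected chain should be treated with care (enable
  `jacobian_correction` and `bounds` for proper sampling inside the box).
* The prediction-panel check is ordinal (class labels and an epistasis
  ladder), not numeric.
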