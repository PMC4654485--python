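# Methods

## Model structure and assumptions

The model is a deterministic, two-compartment (cytoplasm/nucleus) ODE system
for hypoxia-driven VEGF desuppression in endothelial cells: 47 species, 57
reactions, 91 kinetic parameters. Units are fixed package-wide: μM and
minutes. 47 of the 57 reactions are first- or second-order mass action; the
remainder are three Hill-type transcription steps, three enzyme-catalyzed
Michaelis–Menten steps (two Dicer processings, VHL-mediated degradation) and
four zero-order basal syntheses. A reversible binding or transport step is a
single reaction with forward and reverse rate constants (net flux =
forward − reverse), which is how the 57-reaction count is kept while every
association remains microscopically reversible.

Key mechanistic commitments:

- **Oxygen sensing.** PHD2/FIH assemble with Fe²⁺ and 2-OG into
  hydroxylation-competent complexes that load O₂ reversibly; only the
  O₂-loaded complexes hydroxylate cytoplasmic HIF-1α, and hydroxylated
  HIF-1α is removed by a saturable VHL-dependent step. PHD2, FIH, VHL,
  HIF-1β, Fe and 2-OG are conserved pools without turnover: PHD2 is assumed
  to be in excess, and HIF→PHD feedback is out of scope. The O₂-binding
  dissociation constant (~100 μM) places the graded response between 0.5%
  and 21% ambient O₂.
- **O₂ as a clamped boundary species.** Protocols set dissolved O₂ from the
  linear map 21% ≡ 209 μM and hold it constant; the cell does not deplete
  the reservoir. The clamp is a species flag and can be switched off.
- **HIF-1 complex formation.** A single reversible dimerization of nuclear
  HIF-1α with a small constitutive HIF-1β pool (2.5 nM free subunit,
  strong association) that also stands in for CBP/p300 recruitment.
  Partial saturation of this step compresses the difference between deep
  (1%) and moderate (2%) hypoxia, which the validation data require.
- **TTP negative feedback.** HIF-dependent TTP transcription; TTP
  destabilizes HIF-1α and VEGF mRNAs as a linear modifier on their decay
  (`k·[mRNA]·(1 + a·[TTP])`) rather than through explicit TTP:mRNA
  complexes. TTP self-destabilization is not part of the canonical model.
  TTP accumulation over hours terminates the HIF-1α overshoot; silencing
  TTP (siRNA, Kd 1 nM) prolongs it.
- **miR biogenesis.** pri-let-7 → pre-let-7 lumps Drosha processing and
  XPO-5 export into one step whose rate is multiplied by a saturable
  function of nuclear let-7:AGO1 (the positive auto-regulatory loop,
  resolved as a linear-times-saturating multiplier rather than a Hill
  activator). Dicer maturation is `kcat·[Dicer]·[pre]/(Km+[pre])`. RISC
  formation is one reversible AGO1·miR association; AGO-free miRs decay an
  order of magnitude faster than RISC-bound miRs, and AGO1 inside RISC is
  protected from degradation.
- **p-bodies.** let-7-RISC routes AGO1 and Dicer mRNAs, and miR-15a-RISC
  routes VEGF mRNA (through an explicit bound intermediate), into p-body
  pools that are translation-inaccessible, decay more slowly than the free
  mRNAs, and leak back at a small exit rate.
- **Lumping.** HIF-2α is represented within HIF-1α; miR-15a stands for the
  VEGF-targeting miR group; no explicit Drosha, XPO-5, Ran, CBP/p300 or
  GW182 species.
- **Perturbants are first-class species** (siRNAs and their duplexes, miR
  antagonists and their complexes, CoCl₂ and its two sequestration
  complexes) present at zero concentration in the canonical model. A
  treatment is therefore only an initial-condition bump at t = 0 of the
  test condition, applied on top of the normoxic pre-equilibrated state;
  zero-dose treatments are exact no-ops. CoCl₂ acts by sequestering the
  hydroxylation-competent PHD2/FIH complexes with a weak (≈25 μM Kd)
  reversible binding, so 200 μM CoCl₂ reproduces a hypoxia-mimetic ~2-fold
  HIF-1α and ~3-fold VEGF rise in normoxia rather than total anoxia.

## Parameter provenance

The supplementary reaction/parameter tables of the source study were not
available as machine-readable input, so the registry was reconstructed (see
`src/hifmir/data/calibration_provenance.json`): printed class medians anchor
the turnover classes (mRNA decay 1.2e-3 min⁻¹, miR decay 1e-4 min⁻¹, protein
decay 2.5e-4 min⁻¹, translation 3 min⁻¹ per mRNA, normoxic mRNA level
2.8e-5 μM, protein level 0.08 μM; priors span ±2 orders of magnitude around
these), and the remaining parameters were calibrated so the configuration
reproduces the published quantitative anchors: 3.5-fold intracellular VEGF
at 24 h/2% O₂, 2-fold VEGF at 8 h/1% O₂, an HIF-1α overshoot peaking in the
first half-day with subsequent decline, delayed AGO1 downregulation, a
free-VEGF-mRNA fraction that falls with O₂, ≥3-fold tumor-screen VEGF
suppression at 0.5–2% O₂ and >2-fold PAD-screen rescue. Those two VEGF folds
are therefore fitted-then-reproduced constraints, not blind predictions.
Where the calibration pulled a rate away from its class median (e.g. AGO1,
Dicer and miR-15a-RISC turnover at ~3–7e-3 min⁻¹, an order of magnitude
above the protein/miR medians), the faster turnover is what lets the
let-7→AGO1→miR-15a cascade relax within the 48-h window the data cover; the
values remain inside the ±2-order prior bounds. `kp21` is implemented as the
Hill half-saturation (μM) of HIF-driven pri-let-7 transcription; the PAD
disease mode raises it to 0.464 μM, which abolishes let-7 induction while
leaving everything else untouched.

## Protocols and readouts

Every virtual experiment pre-equilibrates the untreated model at 21% O₂ by
long stiff integration until max |dxᵢ/dt| / max(xᵢ, 1e-9) < 1e-8 min⁻¹
(steady states are memoized on a model content hash), then doses treatments,
sets the O₂ clamp, and integrates with BDF at rtol 1e-8 / atol 1e-12 μM,
storing output at ≥1-minute resolution. Total HIF-1α and total AGO1 sum free
plus all bound forms across both compartments; relative expression divides
by the t = 0 value. "Total VEGF produced" is the time integral of the
translation flux kt·[free VEGF mRNA] (trapezoidal on the stored grid) — a
production quantity independent of VEGF protein decay; the end-point protein
level is available separately. The transcriptional onset delay is an
operational metric: the first time a species reaches 5% of its 120-min net
rise.

## Sensitivity analysis

Trajectory sensitivities use the complex-step approximation: the parameter
is perturbed to p(1 + i·h) with h = 1e-20 and the derivative read from the
imaginary part of the complex BDF trajectory (the analytic Jacobian keeps
the implicit solver exact in the complex domain). Central differences
(relative step 1e-4) serve as the independent cross-check; if the complex
path fails the code falls back to central differences and records the method
in the report — never silently. Each sensitivity is non-dimensionalized as
(p/[A](t))·∂[A]/∂p with a 1e-12 μM floor on the denominator, its absolute
value integrated over the span (default 48 h at 2% O₂), and the integrals
normalized to shares summing to one; absolute values are taken so the shares
are a probability vector. Direct production/degradation rates of the readout
species can be excluded by flag. Parameter scans re-equilibrate: for each
multiplier the new normoxic steady state becomes t = 0 before the hypoxia
run, and traces are normalized to the new baseline.

## Calibration and synthetic fixtures

The objective is the unweighted sum of squared errors between normalized
simulation profiles and the datasets (1/sd² weighting optional); fitting
uses bounded trust-region least squares on log₁₀ parameters (the bounded
analogue of Levenberg–Marquardt) with optional log-uniform multistart
(default 10 starts, seeded). Only a declared free subset is fitted — fitting
all 91 parameters to a few normalized curves is non-identifiable. The
shipped round-trip demonstration stages the fit along the pathway: the
let-7-arm subset {Vm_let7, kp21, kf_let7_ago1} against AGO1 + let-7 traces,
then the transcription subset {Vm_vegf, K_vegf, Vm_ttp, K_ttp} against all
three traces (TTP parameters feed back into the AGO1 arm, so the second
stage keeps all datasets in the objective). Individual parameters are only
partially identifiable; the recoverable quantities are the readout
fold-changes, which return to within 10% (noise-free) and 15% (10% CV) of
the reference.

The fixture generator emulates quantified Western-blot densitometry:
simulate, sample n points over the span, multiply every point after the
t = 0 anchor by lognormal noise with exact coefficient of variation
(σ² = ln(1+cv²), mean-corrected so the noise is unbiased), re-anchor t = 0
to 1, attach sd = cv·value. It emulates multiplicative, independent
measurement error only — no batch effects, no background subtraction
artifacts, no correlated blotting errors — so passing round-trip tests shows
the estimation machinery is consistent, not that real Western-blot data
would constrain the model equally well.

## Therapy screens

A screen cell = (strategy, dose, O₂): pre-equilibrate untreated, dose at
t = 0, integrate 24 h, record total VEGF produced and its fold versus the
matched same-O₂ untreated control (control rows have fold 1; failed cells
are recorded as missing and the screen continues; the table is tidy/long).
Dose grids are "auto" by default, spanning sub-stoichiometric to saturating:
antagonists 1–10× the matched RISC pool, mimics 1–10× the matched mature-miR
pool, mRNA overexpression 10–150× the matched mRNA pool (the top dose
saturates the VEGF response), siRNA 1–10× the target mRNA pool. The actual
dose values of the published screens are not printed, so these grids are the
package's own choice. In PAD screens doses are matched to the healthy
model's pools (therapy designed against physiological targets) and folds are
computed against PAD controls.

In the calibrated model the strongest tumor strategy is AGO1 overexpression
(≈5-fold suppression at its saturating dose) with the let-7 antagonist close
behind (≈3-fold); the source study reports the antagonist as the stronger of
the two at its (unprinted) doses, so the ordering of these two strategies
should be treated as dose-convention-dependent. The robust, reproduced
orderings are: both dominate the miR-15a mimic by a wide margin (the mimic
is nearly inert because hypoxia depletes Dicer and AGO1, so mimic-derived
precursor is poorly processed and the mature product poorly protected),
adding Dicer on top of AGO1 overexpression changes the fold only marginally,
and in PAD the miR-15a antagonist far outperforms the let-7 mimic with the
combination dominating both. The PAD antagonist rescue is large (tens-fold)
because PAD controls hold VEGF mRNA almost fully repressed; the published
statement is the bound "more than two-fold", which this satisfies.

## Numerical choices and degenerate inputs

- Stiff BDF with analytic Jacobian assembled per rate-law kind; halving the
  tolerances moves reported readouts by <0.1%.
- Negative concentrations: values below −1e-9 μM abort with a solver error;
  small negative round-off is clipped to zero for reporting only.
- Hill coefficients ≥ 1 enforced; all rate constants strictly positive.
- Empty reaction lists, zero readouts at t = 0, spans beyond the stored
  time course, out-of-range O₂ percentages and unknown
  species/parameter/target ids raise typed errors
  (`hifmir.errors`).
- Steady-state pre-equilibration integrates in doubling chunks (10⁵ → 4×10⁶
  min) and raises with the residual if the cap (2×10⁷ min) is reached.

## Known limitations

- Ascorbate binding, nuclear HIF stabilization, ROS/succinate effects,
  HIF/PHD feedback, a distinct HIF-2α species, stochastic simulation and
  tissue-level angiogenesis are deliberately out of scope.
- Mature let-7 plateaus rather than gently declining late in hypoxia; the
  decline reported experimentally is reproduced only as a slowing of
  accumulation.
- All treatments are applied at t = 0 of the test condition; there is no
  mid-run dosing schedule.
- Total AGO1 declines to ≈0.83 by 24–48 h at 2% O₂ — the direction and
  delay match the quantified blots, but the published depth of the decline
  is larger; the screens' effect sizes rest on the free-AGO1 pool, which
  falls much further (≈0.4).
- The p-body pools are coarse reservoirs: no explicit GW182/decapping
  machinery, and the exit flux is a single first-order rate.
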