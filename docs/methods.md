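# Methods

## Circuit model

The Glenn pathway is modelled as a purely resistive 0D network: the SVC inlet
flow `Q_in(t)` passes a series resistor `r_svc` (the SVC and the pulmonary
artery junction folded into one element, so it loads both lungs equally), then
splits at the junction node into two branches. Each branch is a pathway-vessel
resistor (`r_lpa_vessel`, `r_rpa_vessel`) in series with an outlet resistor
(`r_lpa_outlet`, `r_rpa_outlet`) representing the distal pulmonary bed,
terminated by a constant distal pressure (`p_dist_l`, `p_dist_r`). Every
element obeys `ΔP = R·Q`. Compliance is deliberately absent, which makes the
circuit memoryless: the state at time t depends only on `Q_in(t)`, a single
cycle *is* the periodic solution, and the junction pressure has the closed
form

```
p_j = (Q_in + p_dist_l/R_Lt + p_dist_r/R_Rt) / (1/R_Lt + 1/R_Rt)
```

with `R_Lt`, `R_Rt` the branch totals. Omitting compliance is a modelling
choice, not an approximation of convenience: adding distal compliance
alongside resistance creates an identifiability problem (both shape the
pressure response), while the quantities being matched — cycle-averaged flows
and pressure — are insensitive to it in a rigid, purely resistive pathway.

**Assumptions.** Flow is bulk and one-dimensional per element; blood enters
only via the SVC (accessory flow sources are ignored); distal pressures are
constant over the cycle; respiratory modulation is absent; all quantities are
BSA-indexed so an indexed resistance (WU·m²) times an indexed flow (L/min/m²)
is a pressure (mmHg).

**Parameter placement.** Where the junction resistance sits is not
identifiable from per-lung PVR data; folding it into `r_svc` (upstream of the
split) preserves the per-lung PVR definition `(P̄_SVC − p_dist)/Q̄_branch`
used everywhere else. Proximal vessel resistors default to 0 — all resistance
in the outlets — with a Poiseuille helper (`8μL/(πr⁴)`, μ = 0.04 poise
default, converted to Wood units) available to set them from vessel geometry.
Because the model is linear, the *reported* per-lung PVR is invariant to how
a branch's total resistance is split between vessel and outlet; only the
decomposition table changes.

**Verification.** The closed-form solver is checked against an independent
modified-nodal-analysis solve (4 node pressures + 5 element currents,
assembled from Kirchhoff's current law and per-element pressure-flow
relations, solved generically) on randomized circuits; agreement is ~1e-14,
asserted at 1e-10. Mass conservation `Q_L + Q_R = Q_in` holds to 1e-12
relative at every timestep. Degenerate circuits (one zero-resistance branch)
pin the junction to that branch's distal pressure and warn; both branches at
zero resistance are rejected.

## Calibration

Two parameters are calibrated per patient: the outlet resistances. The cost is
the time-averaged squared branch-flow error, each term normalized by the
clinical cycle-mean of that branch's flow, plus the squared mean-SVC-pressure
error normalized by the clinical mean pressure. Two printed-form details are
implemented literally: the pressure term is constant over the cycle, so adding
it once equals carrying it under the time average (a unit test asserts the
equivalence); and the normalizers are the raw clinical means, which leaves the
flow and pressure terms in heterogeneous units — the weighting is part of the
method and is not re-normalized.

Minimization is Nelder-Mead with absolute tolerance 1e-4 applied to both the
simplex spread and the function-value spread, an evaluation budget of 2,000
(typical runs converge in ~70-150 evaluations), and a finite penalty of 1e6
for any candidate with a non-positive resistance (no simulation is run there).
A run that exhausts its budget returns its best point flagged unconverged; a
run stranded in the penalty region is an error. Every patient starts from the
same cohort-wide initial guess: the cohort mean of the direct per-lung PVR,
net of any configured proximal series resistance, floored at 0.1 WU·m²
((6.181, 5.292) WU·m² for the bundled cohort with zero proximal resistance).

The simulation backend is a callable `(r_lpa_outlet, r_rpa_outlet) →
SimulationResult`, so the same loop can drive the closed-form solver (default),
the nodal verification solver, or an external solver such as a 3D CFD runner.
The calibrator is an sklearn-style estimator (`GlennPVREstimator`) with
`get_params`/`set_params` and trailing-underscore fitted attributes.

## Synthetic patients

Real phase-contrast CMR waveforms for the cohort are not available, so
synthetic patients provide ground truth for accuracy claims. The inlet is a
raised sinusoid `mean·(1 + pulsatility·sin(2πt/l + phase))` on an
endpoint-exclusive uniform grid over [0, l), which averages exactly to its
mean. Defaults: cycle length 0.8 s (a plausible pediatric cycle; heart rates
are not part of the clinical table, so it is a scenario parameter), timestep
0.001 s, pulsatility 0.3. Observed branch flows are the ground-truth
simulation plus seeded zero-mean Gaussian noise with SD expressed as a
fraction of that branch's mean flow; the inlet is treated as exactly known,
matching its role as a Dirichlet boundary. Cohort scenarios draw outlet
resistances from U(2, 12) WU·m², distal pressures from U(3, 7) mmHg (equal
left/right) and inlet means from U(1.2, 3.2) L/min/m² — the ranges spanned by
the bundled cohort's computed PVRs, left-atrial pressures and SVC flows.

What this does and does not show: parameter recovery on these scenarios
demonstrates that the calibration loop finds the generating resistances of a
self-consistent resistive circuit, including under observation noise. It does
not exercise real waveform morphology, inter-modality inconsistency (clinical
SVC flow generally differs from the summed branch flows), or model mismatch
between a real pulmonary bed and a two-resistor branch — with clinical data
the calibration resolves such inconsistencies in the least-squares sense of
the cost, and the self-consistent stand-ins used by the CLI's `optimize`
subcommand (circuit set to the computed PVR, inlet mean set to the summed
branch flows) are labelled as stand-ins for exactly that reason.

## Statistics

Paired comparisons gate on Shapiro-Wilk normality of the differences at
α = 0.05: Gaussian-looking differences get a two-tailed paired t-test,
otherwise the Wilcoxon signed-rank test, and the branch taken is reported.
ICC is the two-way random-effects, absolute-agreement, single-measure
coefficient ICC(2,1) with the F-based 95% CI (computed via pingouin); on the
bundled cohort the CMR-vs-CATH pulmonary flow ICC is 0.208 [−0.15, 0.58],
which is what fixed the variant choice. Bland-Altman uses bias ± 1.96 sample
SD of the differences. Percent differences are per-pair relative to a stated
reference vector, then averaged — this convention (rather than
ratio-of-means) is what the comparison tables report. All SDs use the n−1
denominator.

## Numerical choices and edge cases

- Grids are uniform and endpoint-exclusive; `n = round(l/dt) ≥ 2`.
  Resampling is periodic linear interpolation (`np.interp` with a period),
  wrapping between the last sample and t = l.
- Waveform CSVs round-trip at 12 significant digits; the patient table
  round-trips exactly at printed precision.
- The bundled table prints flows to 2 decimals; statistics derived from it
  (e.g. the computed-PVR cohort mean 6.1807 WU·m²) therefore carry ~0.1%
  input-rounding uncertainty in their 3rd decimal.
- Zero branch flow makes the direct PVR undefined → domain error naming the
  branch; a negative transpulmonary gradient is returned with a warning.
- Problem sizes in the test suite and acceptance script: dt of 0.002-0.004 s
  for calibration studies (the cost is dominated by cycle averages, which a
  few hundred samples resolve to well below the 1e-4 optimizer tolerance),
  1,000 randomized circuits for solver equivalence, and 10-patient synthetic
  cohorts per noise condition.

## Known limitations

- Purely resistive: no wave propagation, no compliance, no inertance; only
  cycle-averaged quantities are meaningful outputs.
- Per-lung distal pressure is a single constant (left atrial pressure by
  default); regional heterogeneity within a lung is out of scope.
- The synthetic waveform family is a single-harmonic sinusoid; conclusions
  about waveform-shape sensitivity cannot be drawn from it.
- Fick-based cardiac output is consumed as data, never recomputed; the known
  CMR-vs-CATH flow discrepancy (ICC ≈ 0.21 on the bundled cohort) therefore
  propagates into any comparison against CATH total PVR.
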