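# Methods

## Model

Each solute is described by a variable-volume two-compartment model: a
plasmatic pool (`V1`, `C1`) that the dialyzer clears at a session-constant
clearance `K`, and an extraplasmatic pool (`V2`, `C2`) coupled to it by an
intercompartment clearance `K21`. Generation `G` enters the plasmatic pool.
The mass balances are

    V1·dC1/dt + C1·dV1/dt = G − K·C1 + K21·(C2 − C1)
    V2·dC2/dt + C2·dV2/dt =          − K21·(C2 − C1)

Assumptions:

* **Volume dynamics.** Net ultrafiltration `Q_UF` changes `Vtot = V1 + V2`
  linearly; the loss is partitioned over the pools in proportion to their
  volumes (instant vascular refill), so `V1/Vtot` is constant within a phase
  and the volumes have the closed form `Vi(t) = Vi(0)·(1 − Q_UF·t/Vtot(0))`.
  Only the concentrations, the removal integral `∫K·C1 dt` and the C1 area
  are integrated numerically.
* **Initial condition.** Both pools start a session at the measured
  predialysis plasma concentration.
* **Generation.** `G` is constant over the whole week, intradialytic phases
  included (switchable per phase via the `G` field of `PhaseSpec` and the
  `generation_during_session` flag of the fitting estimators). See
  "Reproduction accuracy" below for the consequences of this convention.
* **Not modelled.** Access/cardiopulmonary recirculation, in-dialyzer
  plasma-water partitioning, residual renal clearance (the calibration
  cohort was nearly anuric), binding-site competition.

A one-pool comparison model (single volume `Vtot`, same mass-balance
contract) is provided for misfit studies; on two-pool-generated data for a
strongly bound solute it overestimates concentrations in the first half of
the session and underestimates them in the second half, the classic
signature that motivates the two-pool description.

## Numerics

Phases are integrated with `scipy.integrate.solve_ivp` (LSODA,
`rtol 1e-8 / atol 1e-10`), which remains stable in the stiff `K21 → ∞`
limit used by the single-pool equivalence tests. Dense output is sampled on
a 1-min grid by default (10-min in the weekly iteration, where the scored
quantities come from integrated ODE states, not the grid). Mass conservation
`|ΔM − (G·T − removal)|/max(M(0),1) < 1e-6` is asserted in the test suite
for every phase type and parameter set, and fixed-step RK4 at `dt = 0.01`
min serves as an independent oracle (<0.1% discrepancy on all six reference
solutes). Prescriptions whose ultrafiltration would empty the distribution
volume raise `InfeasiblePrescriptionError` before integration.

## Calibration

`TwoCompartmentModel` estimates `(V1, V2, K21)` with
`scipy.optimize.least_squares` (trust-region reflective) on relative
residuals `(predicted/measured − 1)`; relative residuals make the loss
invariant to the concentration scale, so urea (g/L) and trace solutes
(mg/L) are fitted identically. Bounds: `V1 ≥` the anthropometric plasma
volume `BW/13·(1 − Hct)` (an active floor is reported, not hidden),
`K21 ∈ [0, 2000]` mL/min, and `Vtot ≤ 60` L via a smooth penalty. Because
the K21 likelihood is shallow when mixing is fast, the optimiser restarts
from a Latin-hypercube of initial points (default 8, seeded —
deterministic). Noiseless synthetic data are recovered to well under 1% for
all six reference parameter sets. Identifiability degrades monotonically
with measurement noise; at 5% multiplicative noise the median relative K21
error is roughly 20% for the strongly bound regime and worse (~25–30%) for
the fast-mixing urea regime, where the data carry little K21 information.

## Clearance conventions

* Urea clearance is blood-side, `K = (Q_B·C_in − (Q_B − Q_UF)·C_out)/C_in`,
  with blood flow (not plasma-water flow) in the denominator.
* Protein-bound solute clearance is dialysate-side,
  `K = Q_D·C_dialysate/C_in_total`.
* Both are computed at 30 and 120 min and averaged; a missing time point is
  an error, not an imputation.
* Hemoconcentration correction `F = TP_pre/TP_t` is applied to
  protein-bound plasma series before fitting, never to dialysate samples;
  clearance estimation uses raw measured concentrations.
* Generation rate defaults to the full-session dialysate mass divided by
  the 3120-min midweek cycle (two interdialytic days plus the session);
  the cycle length is a parameter.

## Weekly strategy simulation

Seven timeframes are encoded (name = sessions x hours_flow per week):
3x4h_300 (reference), 3x8h_150, 6x2h_300, 6x4h_150 at 216 L processed blood
per week; 3x8h_300, 6x4h_300, 6x8h_150 at 432 L. At 150 mL/min blood flow
the extraction ratio `K/300` is rescaled by 1.33 (urea) or 1.00
(protein-bound solutes), capped at 1. Conventions the underlying study left
open, fixed here once:

* thrice-weekly sessions on days 1/3/5, six-times-weekly on days 1–6 with
  day 7 off; the reported "midweek" session is the one preceded by the
  schedule's regular short gap (index `sessions_per_week // 2`);
* weekly fluid removal is fixed at 4.92 L (the measured 0.41 L/h over
  3 x 4 h), split evenly per session; each interdialytic gap linearly
  regains exactly the next session's ultrafiltrate, so volumes are periodic
  and every session starts at the predialysis volumes;
* steady state: the predialysis concentration of every like-positioned
  session changes by <1% between consecutive weeks (reached in ≤5 weeks for
  all reference cells; results change by <0.5% when iterated to 1e-5);
* TSR is scored on the first session of the new strategy starting from the
  reference steady state (first two sessions for six-times-weekly
  schedules); TAC1 is the weekly C1 area divided by 10080 min.

At steady state the simulated weekly removal equals `G·10080` within 0.4%
for every solute-strategy cell (asserted at 2% in the tests, reflecting the
1% stopping rule).

## Reproduction accuracy and known discrepancies

Driven by the published central parameter values, the simulator reproduces
the reference adequacy table to within ~12% on the urea, IS and PCS cells
(e.g. reference-strategy urea session removal 30.7 g vs 28.3 g reported;
steady-state predialysis urea 1.21 vs 1.13 g/L; IS removal over the first
two 6x8h_150 sessions 153 vs 149 mg; PCS reference TAC 32.2 vs
28.8 mg/L). Two systematic effects are worth knowing:

* The reported table is numerically more consistent with generation being
  paused during sessions (that convention reproduces the urea cells to
  ~1%); the package defaults to continuous generation, which keeps the
  weekly balance `removal = G·10080` exact and explains the +7–12% offsets.
* For solutes whose generation rate is summarised as a median with a wide
  right tail (hippuric acid, p-cresylglucuronide), steady-state
  concentrations scale linearly in `G`, and the reported adequacy values
  imply a cohort *mean* generation rate well above the printed median
  (≈0.24 vs 0.136 mg/min for hippuric acid). Simulations from the printed
  central values therefore undershoot those columns by ~35–40%; the package
  reports what the stated inputs produce rather than back-fitting `G`.

Similarly, the protein-binding correlations recomputed from the central
values are −0.976 (K), −0.956 (V1), −0.699 (K21; −0.958 without PCG) — the
PB–Vtot correlation recomputes to −0.71, not the −0.81 sometimes quoted
from the same central values, and the recomputed value is what the
`correlate` command prints.

## Synthetic data

The cohort generator draws per-patient parameters from the published
summary statistics: mean ± SD entries as truncated normals, median [IQR]
entries as log-normals matched by quantiles, independently across solutes
(within-patient cross-solute correlations are unreported). Constraints are
enforced by resampling (`V1 ≥` plasma-volume floor, `V1 < Vtot`). Sample
sheets mirror the study design — inlet samples at 0/15/30/60/120/240 min,
outlet and dialysate at 30/120 min, full-session dialysate collection —
with unit-mean multiplicative log-normal noise. Outlet and spot-dialysate
values are derived from the clearance identities and protein-bound inlet
series are hemoconcentrated through a synthetic total-protein course (one
third of the ultrafiltrate taken from plasma), so every estimator
round-trips exactly in the noiseless limit. The generator does not emulate
detection limits, chromatographic artifacts or inter-laboratory bias, so
passing recovery tests demonstrate correctness of the estimation machinery
under the model's own assumptions, not robustness to real measurement
pathologies.
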