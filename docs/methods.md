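# Methods

## Two-compartment nicotine pharmacokinetics

The model tracks drug amounts (μg) in a central pool (blood, plasma, CSF —
reported as one concentration; "plasma" and "CSF" predictions are synonyms
here) and a peripheral pool (fat, muscle, other poorly perfused tissue),
with first-order elimination from the central pool only. Concentration is
A_c/V_c in μg/l ≡ ng/ml.

Parameters and defaults (a 350-g rat):

| parameter | meaning | default | units |
|---|---|---|---|
| `vc_per_kg` | central volume of distribution | 5 | l/kg |
| `k_el` | elimination rate constant | 0.8 | h⁻¹ |
| `k_cp` | central→peripheral transfer | 1.5 | h⁻¹ |
| `k_pc` | peripheral→central transfer | 1.2 | h⁻¹ |
| `body_mass` | — | 0.35 | kg |
| `clearance` | configured systemic clearance | 1.4 | l/h |

The published parameter set prints the rate constants as bare numbers; we
interpret them as h⁻¹ because that makes k_el·V_c = 0.8 × 1.75 = 1.4 l/h,
numerically identical to the printed clearance, and yields a terminal
half-life ln2/λ₂ ≈ 2.3 h, physiologically plausible for rat nicotine.
Clearance is therefore treated as the *derived* quantity k_el·V_c — applied
once, not as a second loss term, since double-counting elimination would
halve the predicted steady state out of the plausible band.
`derive_clearance` warns if the configured and derived values disagree by
more than 1%. A sensitivity variant (`extra_loss_per_h`) adds an extra
first-order loss for users who prefer the other reading.

Dosing events default to instantaneous boluses: the 2-s pump infusion is
three orders of magnitude faster than the system time constants
(λ₁ = 3.2 h⁻¹, λ₂ = 0.3 h⁻¹), and the bolus-vs-pump peak difference at the
default parameters is below 0.5%. A zero-order 2-s infusion mode is
available. Event times are pump-onset times; onset vs completion is
immaterial at this timescale.

Numerics: LSODA (adaptive, stiff-capable) integrates each inter-event
segment at rtol 1e-8 / atol 1e-10; boluses are applied as state jumps so
no discontinuity is smeared. The output grid defaults to 1-s resolution
and grid points coinciding with an event report the post-bolus value, so
C(0⁺) = dose/V_c. The closed-form biexponential solution — an independent
eigenvalue computation — agrees with the solver to <1e-6 relative error;
mass balance (central + peripheral + eliminated = infused) and
superposition across events hold to solver tolerance. The rate-matrix
eigenvalues are real and distinct for any strictly positive parameters;
the degenerate-root guard exists only for pathological near-zero transfer
rates.

Exposure metrics use trapezoidal AUC on the output grid; AUC to infinity
for a single bolus equals dose/(k_el·V_c), which the trapezoid reproduces
to 0.1% on a long grid.

## Reconstructed session schedules

Raw infusion records are not available, so the two headline sessions are
reconstructed from their described structure: the 30 μg/kg/inf session as
10 loading infusions evenly spaced over minutes 0–18 followed by 12
maintenance infusions every 8 min from minute 26 to 114 (22 infusions,
loading-then-maintenance); the 1.5 μg/kg/inf session as back-loaded — 10
infusions over the first hour (endpoint-exclusive spacing, so minute 60
belongs to the late block) and 30 infusions evenly spaced over minutes
60–118. These reconstructions, not fitted to any output, produce a
maintenance-window average of ~35 ng/ml (band 30–50), troughs ≥ 30 ng/ml,
and a low-dose end-of-session concentration of ~4.8 ng/ml.

## Operant sessions and acquisition rules

Session logs use a documented CSV dialect (`# key=value` header block, then
`t_sec,kind` rows) rather than proprietary operant-chamber formats.
`validate_schedule_semantics` replays the fixed-ratio contingency: active
pokes within `timeout_s` (20 s) of an infusion are recorded but never
counted; an infusion is justified only by exactly `fr_value` counted pokes
since the last timeout expired. Violations are returned as data, not
exceptions.

Classifier conventions, chosen where the verbal rules are ambiguous:

* all printed inequalities are strict as printed (`<10`, `<2.0`); a window
  mean of exactly 11.1 is "maintained" (acquired); the ≥75% response drop
  is inclusive;
* the 75%-drop baseline is the mean of active responses over sessions 1–5
  (the only well-defined pre-window); a session in 6–10 triggers at
  active ≤ 25% of baseline;
* "consecutive" counts session order; weekend calendar gaps are ignored;
* ratio with zero inactive pokes is +∞ (passes); a session with zero pokes
  on both holes fails the ratio criterion for that session — a
  non-responding animal is not discriminating;
* the control-referenced cutoff uses the sample (n−1) SD over per-subject
  window means, making the "mean + 2 SD" reconstruction auditable.

Rules are checked in their stated order and the first trigger is recorded.

## Hill concentration–response fitting

The Hill function is a logistic in log concentration, and is fitted in that
parameterization (log EC50, log n, and log top when top is free): it is
overflow-safe for any slope and makes the fit scale-equivariant. Activation
fits fix the bottom at 0 and leave the asymptote free; inhibition fits fix
the top at 1 (baseline-normalized) and the floor at 0 unless overridden.
Multi-start (the half-max interpolate plus every tested dose) guards
against local minima; objective tolerances are 1e-12.

EC50 intervals use a case-resampling bootstrap over whole replicates
(oocytes/slices are the exchangeable unit, not single observations). The
plain 95% percentile interval measurably undercovers at small replicate
counts, so the default is Hesterberg's expanded percentile interval — the
same bootstrap distribution read at widened quantile levels
Φ(−t_{α/2,n−1}·√(n/(n−1))) — which restores near-nominal coverage
(95/100 in this package's coverage simulation at 8 replicates);
`method="percentile"` gives the unadjusted interval. Asymptotic intervals
were considered and rejected as less honest about the small-n replicate
structure.

## FSCV release/uptake kinetics

Between stimulus pulses the Michaelis–Menten decay has the exact implicit
solution Km·ln(C₀/C) + (C₀ − C) = Vmax·t, solved in closed form with the
principal Lambert-W branch (asymptotic expansion when the argument would
overflow, i.e. deep in the zero-order regime C ≫ Km). Traces are therefore
free of step-size error at any sampling rate; the default trace rate is
10 samples/s (the FSCV waveform-repetition convention) and a brute-force
explicit-Euler integration at dt = 1e-4 s is kept in the test suite as an
independent cross-check (agreement < 1e-3 μM).

Release is an instantaneous per-pulse increment (4-ms pulses ≪ trace
resolution). Km is fixed at 0.16 μM — a standard striatal dopamine-uptake
value — because Vmax and Km are poorly jointly identifiable from single
evoked transients; it is configurable. Fitting estimates (Vmax, [DA]p) in
log space by least squares against the full trace, multi-started over
Vmax ∈ {0.3, 1, 3} μM/s.

Electrode calibration is ordinary least squares from background-current
features to dopamine sensitivity (nA/μM); the default feature set is a
single regressor (peak background current) since no richer feature list is
established, but the interface accepts arbitrary feature columns and
rejects rank-deficient designs. Frequency-response curves report peak
release as percent of the single-pulse peak; intensity curves normalize to
their maximum.

## Synthetic data

The generators emulate the *structure* of the study's data, not its
animals; true inter-infusion distributions are unknown and no behavioral
parameter is fitted to the original cohorts.

* Sessions: loading infusions evenly spaced (with jitter) in an early
  window, then maintenance with log-normal inter-infusion intervals
  (heavy right tail matches post-infusion pausing); a per-day rate
  multiplier produces escalation (>1) or extinction (<1); inactive pokes
  are homogeneous Poisson; extra actives land inside timeouts. A minimum
  inter-infusion gap of timeout + FR-run length guarantees every generated
  log passes schedule validation.
* Scenario defaults were chosen once to land in the reported qualitative
  ranges: standard-dose acquirers 15–25 infusions/day with loading in the
  first ~20 min; low-dose acquirers ~13–17/day (above the 11.1 benchmark
  with margin); saline-like cohorts ~4–5/day (always below it);
  the escalating cohort rises from ~17/day toward ~35/day by day 17 while
  its controls stay under 5/day; saline substitution decays intake by 25%
  per day after the switch.
* Dose–response replicates add Gaussian noise (sd 0.05 by default) to
  exact Hill values, truncated at zero. Coverage simulations use 8
  replicates per dataset, a typical oocyte-experiment scale.
* FSCV datasets jitter slice parameters log-normally around group means
  and add Gaussian trace noise; the intensity series couples per-pulse
  release to voltage through a saturating Hill-shaped function (V₅₀ = 3 V),
  a generator convention the analysis layer never assumes.

What passing tests therefore show: the estimators recover known parameters
under the stated noise models, and the classifiers implement the printed
rules exactly. What they do not show: recovery under real-data pathologies
(electrode drift, pH transients, satiation within sessions, non-stationary
poke rates), none of which the generators model.

## Problem sizes

The default suite simulates 100-schedule PK property sweeps at 30-s grid
resolution, 200 dose–response datasets plus a 100-round × 1000-resample
bootstrap coverage study, and 100 noisy FSCV fit recoveries — sizes chosen
to give stable medians and coverage proportions while keeping a full run
in a few minutes on one core.

## Known limitations

Inter-animal variability in nicotine metabolism is not modeled (matching
the source model's stated limitation); no pharmacodynamic link from
predicted concentration back to poke rates; no brain-compartment or
metabolite kinetics; inhibition floors below 0 and two-site fits are out
of scope; the 75%-drop baseline convention and the exact-equality reading
of the 11.1 cutoff are documented choices where the verbal rules are
silent.
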