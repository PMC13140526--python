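# Methods

## Scope and model overview

The package simulates and analyses a two-period crossover in which
well-trained swimmers train at sea level for two 4-week blocks — one with
thrice-daily low-dose CO inhalation (INCO), one with ambient-air placebo
(AIR) — separated by a washout long enough to reset physiology to baseline.
Every stage a real dataset would pass through is implemented as an
estimator over raw observations; the synthetic cohort provides those
observations with known ground truth, so each estimator is validated as a
round trip and the statistical stage is validated by Monte-Carlo
calibration.

## Synthetic cohort (`colhtl.cohort`)

Baseline physiology is drawn per sex from distributions matched to a
trained swimming cohort: body mass F ~ N(75.8, 5.6) kg, M ~ N(85.9, 10.5)
kg; relative Hb_mass F ~ N(11.0, 0.8), M ~ N(12.6, 0.8) g/kg (screened to a
plausible 9–16 g/kg band); [Hb] F ~ N(150, 7), M ~ N(162, 7) g/L; HCT
F ~ N(0.44, 0.02), M ~ N(0.47, 0.02); muscle recovery constant
k ~ N(3.0, 0.5) min⁻¹; resting COHb ~ U(0.5, 1.5)% (non-smokers, <2%).
Ground-truth volumes derive from Hb_mass, [Hb] and HCT through the same
f-cell relations the analysis uses, so PV + RBCV = BV holds exactly at
generation.

**Dose–response.** The treated arm multiplies true Hb_mass by
1 + g·D/1000/100 + η, with g = 4%/1000 km·h, accumulated dose D (default
847.9 km·h, the CO block's equivalent; 1000 km·h in the dose-recovery
experiments), and between-subject response η ~ N(0, 1.2%). The linear form
keeps ground truth analytic; an exponential-saturation alternative
(calibrated to the same gain at 1000 km·h) is selectable. The response SD
of 1.2% is our reading of the reported 95% range of individual responses to
a standardized hypoxic dose (roughly 1–6% around a 3.5% median); it is a
package choice, not a measured quantity. Plasma volume drifts
treatment-independently with SD 120 mL per block, the scale of the PV
changes seen in crossover altitude blocks; red-cell volume tracks Hb_mass
(constant cell haemoglobin), and [Hb]/HCT are re-derived so the volume
identities stay exact. The washout resets period-2 baselines; a carryover
knob (default 0, justified by the ~6-month washout) exists to probe ANCOVA
robustness. Post-treatment states skip the relative-Hb_mass plausibility
screen, which is an input filter for baseline states.

**Measurement models.** A rebreathing test is simulated by inverting the
analysis mass balance: observed ΔCOHb = V_abs·100/(Hb_mass·(1+ε)·1.39) with
ε ~ N(0, TE%), so duplicate estimates reproduce the configured typical
error (default 2%) in expectation and the TE = 0 round trip is exact to
machine precision. [Hb] and HCT are passed through as triplicate instrument
means without extra noise; the noise-free volume round trip therefore holds
end to end. The NIRS trace realizes a per-measurement rate constant
k·(1+ε), ε ~ N(0, 18%), reflecting the reported repeat-measurement CV of
the technique; optional white %TSI noise is a separate knob. Within each
brief occlusion the simulated TSI falls linearly at the recovery-model
slope evaluated at the analysis fit-window midpoint — a deliberate
idealization that makes the noise-free slope/k round trip exact. Peak
lactate per trial is a·e^(b·v) plus truncated N(0, 0.5 mM) noise, with each
subject's curve anchored at their 4 mM threshold speed (~1.4 m/s) and
steepness b ~ N(11, 1) s/m, which puts maximal-trial peaks at ~12 mM.

**What the generator does not emulate:** day-to-day biological drift within
a block, analyser-specific bias between the 2-min and 6-min rebreathing
devices, reticulocyte/steroid dynamics (marker formulas are pure functions
over supplied panels), training-load physiology, and any COHb dependence of
the erythropoietic response beyond the accumulated-dose scalar. Passing
tests demonstrate internal consistency of the estimators and calibration of
the statistics at the study's n — not that real physiology follows these
distributions.

## Dosing and COHb kinetics (`colhtl.dosing`)

One-compartment elimination with a fixed resting half-life of 4.5 h (the
midpoint of the 4–5 h literature range; ventilation dependence is out of
scope). Boluses absorb instantaneously — the 30 s breath-hold is far below
the model's resolution — each raising COHb by V/(Hb_mass·1.34)·100 points.
The block's first bolus targets 15% COHb; the published expression for it
contains a "×10/100×25%" factor that evaluates to 2.5% and contradicts the
stated 15% target, so the default parameterizes the target fraction and the
literal expression is kept as an `as_printed` variant. Follow-up boluses
use the individual mL-per-point calibration and, as printed, subtract both
the current COHb and the resting baseline from the 10% target (so achieved
peaks sit about one baseline below target); an excess-only variant is
exposed, and neither reading is asserted as the protocol's intent. Negative
prescriptions floor at 0 mL. A 20% COHb safety ceiling (heavy-smoker
territory) flags, rather than aborts, the series. Simulated schedules give
a time-weighted mean COHb near 5% with post-bolus peaks of 9–16%, inside
the observed exposure interval.

## Hypoxic dose (`colhtl.hypoxic`)

km·h = altitude[m] × 0.001 × h. The CO-equivalence maps COHb excess above
the individual baseline (so resting COHb accrues nothing) to altitude by
matching VO₂max decrements: default 1% per % COHb against 7% per 1000 m.
The 1%/1% slope is a linear reading of exercise-CO studies and is exposed
as configuration — the equivalent-dose integral scales linearly with it.
Our trapezoidal integral over the simulated 28-day course gives ~370 km·h;
published CO-block equivalents computed with unstated integration
assumptions are substantially higher, so this number is reported alongside,
never asserted. The integral is additive over intervals and stable to grid
refinement (<0.1% between 0.05 h and finer grids).

## Rebreathing haematology (`colhtl.rebreathe`)

Hb_mass = V_abs·100/(ΔCOHb·c) with c = 1.39 mL/g, f-cell = 0.91; both are
configuration (the method papers' values, not measured here), enabling
sensitivity analysis. The 2-min and 6-min protocols share the formula and
differ only in the unabsorbed-CO accounting, which enters as one aggregate
input field (the exhaled/circuit decomposition lives in the method papers,
not here). QC: ΔCOHb ≤ 0.5 points rejects the test (guards the dilution
quotient; an engineering choice), triplicate CVs above 5% reject, and
unabsorbed ≥ administered is structurally invalid. Typical error follows
the SD-of-differences/√2 definition.

## NIRS oxidative capacity (`colhtl.nirs`)

Physiological normalization maps the prolonged-occlusion minimum (the
deflection point) to 0% and the reperfusion maximum to 100%; a trace whose
final 10 s of occlusion still slopes more than 0.05 %TSI/s has not
plateaued and is rejected. Occlusion windows come from protocol
annotations, not auto-detection. Slopes are fitted by least squares over a
sub-window that skips the first 0.5 s (cuff-inflation transient) and uses
the next 2.0 s — a package choice, configurable. Windows whose mean
oxygenation is ≤50% of the physiological range are flagged and excluded
from the recovery fit, mirroring the well-oxygenated-muscle protocol rule.
The recovery fit uses |slope| so k is positive, nonlinear least squares
with a log-linear seed plus fixed fallback starts, k bounded to
[0.1, 20] min⁻¹ (bound hits are flagged), and asymptotic-covariance CIs.
The default simulated protocol places 10 six-second occlusions over 2.5
minutes, densified early, which resolves k in the physiological 2–4 min⁻¹
range; the real protocol's occlusion timing is investigator-modulated, so
this is an explicit assumption.

## Markers and performance (`colhtl.markers`)

The OFF-score defaults to the linear form [Hb]×10 − 60×RET% for fidelity to
the source protocol; standard passport practice uses 60×√RET%, provided as
a variant (the two coincide at RET% = 1 and diverge hard above it — group
means cannot arbitrate between nonlinear transforms). [Hb] is stored in
g/L package-wide; `off_score` takes g/dL at its boundary so the ×10 is
explicit and a silent unit error is impossible. The lactate model is the
exponential (log-linear) two-parameter curve — monotone and standard in
swim testing; threshold speed is its closed-form inverse, with >5%
extrapolation beyond the sampled speed range warned and a non-increasing
fit rejected.

## Crossover statistics (`colhtl.stats`)

The default ANCOVA is post ~ intercept + β·pre + τ·treatment with no period
term, matching the described analysis; `period_term` and a subject-level
differencing variant (which eliminates subject intercepts and tests the
within-subject contrast) are options because how the original analysis
handled the pairing is unstated. Missing data are complete-case per
outcome, so n varies by outcome. No multiplicity correction is applied, as
in the source analysis. Degenerate paired tests (zero-variance
differences) return (0, 1) for all-zero changes and a flagged infinite-t
for constant nonzero changes. Calibration: under a zero-effect generator
at n = 8, the paired t and change-score ANOVA reject at 5% within the
binomial 95% interval over 2000 replicates, and the noise-free ANCOVA
recovers an injected additive effect exactly.

## Numerical and design choices

- One `numpy.random.Generator` threads through every stochastic call; no
  global state. Identical seeds give bit-identical cohorts and bundles.
- COHb schedules evaluate the piecewise-exponential closed form on a
  0.05 h grid; grid samples at dose times show the post-bolus peak.
- The within-subject pre/post correlation of real repeated measures is not
  reported anywhere we can verify; measurement errors pre and post are
  drawn independently (correlation enters only through the shared true
  state). This is flagged as unverifiable rather than tuned.
- Problem sizes in the test and acceptance experiments — 500 cohorts for
  the dose-recovery mean, 500 duplicate pairs for TE, 200 NIRS replicates,
  2000 statistical-calibration replicates — were chosen so Monte-Carlo
  standard errors sit well inside the tolerances being checked while the
  whole suite stays fast.

## Known limitations

- No myoglobin CO binding, exercise-modulated washout, or
  ventilation-dependent half-life; no STPD gas corrections.
- The CO-altitude equivalence slope is the dominant uncertainty in the
  equivalent-dose estimate and is left as configuration.
- Group-level statistics at n = 8 are fragile by nature; the package
  reports them faithfully rather than regularizing.
- Real-cohort quantities that depend on unavailable raw data (individual
  duplicate records, instrument panels, the original integration
  assumptions) are out of scope; structural properties and calibrations
  stand in for them in the test suite.
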