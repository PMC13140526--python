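# colhtl

Simulation and analysis pipeline for crossover studies of **chronic low-dose
carbon-monoxide (CO) inhalation as a surrogate altitude exposure** — the
"live-high, train-low" (LHTL) strategy implemented pharmacologically rather
than geographically. It is written for exercise physiologists and
anti-doping scientists who need to plan CO dosing protocols, account hypoxic
dose, process CO-rebreathing haematology and NIRS oxidative-capacity data,
and analyse small two-period crossover trials — with a synthetic-cohort
generator providing ground truth so every estimator in the chain is
testable without human data.

## What it computes

**CO-rebreathing haematology.** Total haemoglobin mass by CO dilution,

    Hb_mass [g] = V_CO,absorbed × 100 / (ΔCOHb × 1.39),

with 1.39 mL CO/g Hb the binding capacity, and intravascular volumes via the
f-cell ratio (whole-body/venous haematocrit, 0.91):
BV = Hb_mass/([Hb]·f_cell)·1000, RBCV = BV·HCT·f_cell, PV = BV − RBCV.
Duplicate reliability is the typical error, TE = SD(differences)/√2.

**CO dosing and kinetics.** An initial bolus V = Hb_mass × 1.34 ×
target/100 sized to raise carboxyhaemoglobin (COHb) to 15%, follow-up
boluses scaled by the subject's measured COHb-per-mL response toward a 10%
target, and a one-compartment washout COHb(t) = base + (COHb₀ − base)·2^(−t/4.5 h)
over a thrice-daily, 6-days/week schedule.

**Hypoxic dose.** Kilometre-hours, km·h = altitude[m] × 0.001 × hours, and a
CO-equivalent altitude obtained by matching VO₂max decrements (default 1%
per % COHb excess vs 7% per 1000 m), integrated over the COHb time course.

**Muscle oxidative capacity.** The muscle O₂-uptake recovery rate constant
*k* (min⁻¹): TSI down-slopes during brief arterial occlusions, normalized to
the physiological range (ischaemic plateau → 0%, reperfusion peak → 100%),
fitted as |slope|(t) = a + A·e^(−kt) after exercise.

**Markers and performance.** OFF-score = [Hb](g/dL)×10 − 60×RET% (√-variant
available), urinary specific-gravity correction
conc × 0.020/((SG + 0.002) − 1), and the swim speed at 2/4 mM blood lactate
from an exponential speed–lactate fit.

**Crossover statistics.** Per-subject change scores, within-block paired
t-tests, baseline-adjusted ANCOVA (post ~ pre + treatment) for the
INCO-vs-AIR effect, and change-score ANOVA, complete-case per outcome.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_dose_schedule.py
python analysis/03_hypoxic_dose.py
python analysis/04_measurements.py
python analysis/05_crossover_stats.py
```

The drivers write their tables under `results/`. A run with the default
configuration (seed 1) prints, among other lines:

```
true Hb_mass gain: INCO +2.91% ± 0.92, AIR +0.43% ± 1.01
initial bolus 182.1 mL (15% target); follow-ups 30.2-96.8 mL (10% target)
time-weighted mean COHb 4.9% (peak 16.0%, baseline 1.0%)
classic LHTH block, 2100 m for 504 h: 1058.4 km·h
outcome          effect(SE)           p_treat  p_time_INCO
hbmass_g             +34.48 (10.62)  0.006    0.004
rbcv_ml             +100.61 (31.78)  0.007    0.004
pv_ml                -57.62 (82.83)  0.499    0.836
k_min                 -0.30 (0.28)  0.290    0.933
treatment effects at p<0.05: hbmass_g, hbmass_rel, rbcv_ml
```

Read: at the default dose (~848 km·h) the treated arm truly gains ~3%
Hb_mass; after measurement noise the ANCOVA still detects the haemoglobin
and red-cell-volume effects (p < 0.01) while plasma volume, muscle oxidative
capacity and lactate-based performance show none — the qualitative pattern
expected of a blinded CO-LHTL block on top of ordinary training.

The same functionality is scriptable via the `colhtl` CLI
(`colhtl simulate | dose | rebreathe | nirs | markers | analyse | run`), e.g.

```bash
colhtl dose kmh --altitude 2100 --hours 504   # -> 1058.4 km·h
colhtl markers off-score --hb 15 --ret 1      # -> 90.0
```

## Layout

- `src/colhtl/` — the library: `cohort` (synthetic generator), `dosing`,
  `hypoxic`, `rebreathe`, `nirs`, `markers`, `stats`, `tableio`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — models, assumptions, parameter defaults, limitations.
- `tests/` — unit, property and end-to-end suites.
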