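# Methods

## Scope and model

`syntherm` analyzes the competition between two methanogenic
acetate-degradation routes in a defined three-member thermophilic
consortium grown in sealed serum vials (68 ml total, 20 ml medium,
55 °C, pH 7.0, 40 mM sodium acetate). The object of study is the
in-situ Gibbs free energy

ΔG = ΔG°′ + R·T·ln Q

of each of the three catabolic reactions (aceticlastic methanogenesis,
syntrophic acetate oxidation, hydrogenotrophic methanogenesis), its
dependence on the medium's inorganic-carbon load, and the resulting
feasibility of the syntrophic route.

### Activity conventions

Aqueous species enter Q in mol/L against a 1 M standard state; gases in
atm against 1 atm (interfaces accept Pa and convert with
1 atm = 101 325 Pa); water has activity 1; the proton follows the
primed (pH-7) convention with activity 10^(7−pH), so it contributes
nothing at pH 7. Activity coefficients are unity throughout —
concentrations are used as activities, the convention under which the
−20 kJ/mol feasibility heuristic is quoted in the anaerobic-microbiology
literature.

### Formation energies and ΔG°′

The shipped table (`syntherm/data/formation_energies.tsv`) carries
25 °C standard Gibbs energies of formation in the Thauer-style primed
convention (acetate⁻ −369.41, H₂O −237.18, CH₄(g) −50.75, HCO₃⁻
−586.85, H₂(g) 0, H⁺ −39.87 kJ/mol). Coefficient-weighted sums give
−31.0, +104.6 and −135.6 kJ/mol for the three reactions. No published
source states which compilation produced the reference values this
table reproduces; the table is an implementation choice, documented and
editable (TSV: species, phase, energies, formula for integer C/H/O/
charge balance checking).

ΔG°′ is used at its 25 °C value together with R·T·ln Q at the culture
temperature (328.15 K). This mixed convention is deliberate: it is what
the field's worked H₂-shift arithmetic implies (a shift of ν·R·T·ln(p′/p)
with T = 328 K reproduces the −25.1 → −19.7 kJ/mol example at
16.4 → 10 Pa exactly). A Gibbs–Helmholtz correction of ΔG°′ to culture
temperature, using the table's formation enthalpies under a constant-ΔH°
approximation, is available (`temperature_correction=True`) but off by
default.

### Feasibility threshold

Default −20 kJ per mol of reaction, the approximate minimum for
chemiosmotic energy conservation (≈⅓ of ATP hydrolysis under
physiological conditions at 3–4 H⁺ per ATP). It is configurable because
some anaerobes demonstrably operate closer to equilibrium.

### H₂ feasibility window

For a given culture state, `feasibility_window` returns
[h2_low, h2_high]: h2_low solves ΔG(hydrogenotrophic) = threshold (the
methanogen's draw-down floor), h2_high solves ΔG(acetate oxidation) =
threshold (the SAOB's ceiling). Both are closed-form exponential
inversions. Raising bicarbonate lowers the ceiling as [HCO₃⁻]^(−1/2)
(two HCO₃⁻ produced, four H₂) and the floor as [HCO₃⁻]^(−1/4) (one
HCO₃⁻ consumed), so the log-width shrinks by ¼·Δln[HCO₃⁻]: elevated
CO₂ *narrows* the window from the top even though both endpoints move
down. An empty window with the aceticlastic ΔG still below threshold is
the dominance-switch signature.

## Carbonate speciation

A sealed vial holds inorganic carbon as headspace CO₂ (ideal gas,
R = 0.082057 L·atm·mol⁻¹·K⁻¹ at vial temperature), dissolved CO₂
(Henry's law, k = 0.019 mol L⁻¹ atm⁻¹ at 55 °C) and bicarbonate
(first dissociation, K₁ = 4.47 × 10⁻⁷, pK₁ ≈ 6.35 — entered as a
config parameter so other compilations can be forced). At fixed pH all
pools are linear in the CO₂ partial pressure, so the carbon balance has
a direct solution; conservation is verified to 10⁻⁹ relative after the
fact and violations raise with diagnostics. Carbonate ion is neglected
(<0.5% at pH 7); pH is an input, not solved, because the media are
adjusted to 7.0 and drift <0.2 during growth; totals are reported in
mmol per liter of medium ([ΣCO₂]).

Under this explicit mass balance the three study media work out to
5.0, 52.8 and 124.1 mmol/L initial [ΣCO₂] (and 2.2 / 23.2 / 54.6 mM
initial HCO₃⁻). The nominal condition labels in common use for these
recipes (5.0 / 50.7 / 113.4 mmol/L, with much smaller quoted initial
bicarbonate) rest on an unstated calculation convention that could not
be reconstructed from the published constants; the labels are kept as
labels, and no quantitative claim in this package depends on them.

## Synthetic time-course generator

No raw per-day metabolite tables are available for these experiments,
so the pipeline is validated on simulated batches with exactly known
ground truth. The generator is phenomenological:

- **Acetate** follows a clamped logistic decay
  A(t) = A₀·(1 − f(t)), f a logistic in t normalized so f(0) = 0,
  with steepness 0.7 d⁻¹ and midpoints 3.2 / 3.6 / 4.0 d for the three
  conditions (a slight rate decrease with CO₂), giving >99% depletion
  at ~10–11 d on a 15-day, 1-sample-per-day grid.
- **Methane** accumulates mol-for-mol with consumed acetate
  (configurable yield ≤1) entirely in the headspace; CH₄ solubility is
  neglected. Headspace pressure follows from the vial geometry, so
  `stoichiometry_check` recovers exactly 1.0 on the noise-free twin.
- **Inorganic carbon**: each acetate consumed delivers its second
  carbon to the inorganic pool, which is re-speciated day by day at
  fixed pH; carbon closes to 10⁻⁹ relative by construction.
- **H₂** rises with a 0.5-day time constant to a quasi-steady plateau
  and decays logistically ~4.5 d after the consumption midpoint,
  emulating the rise–plateau–collapse of trace H₂ in a syntrophic
  batch.
- **Noise**: independent multiplicative lognormal factors (σ = 0.05 on
  the log scale) per analyte per day per replicate; triplicates by
  default; every draw flows from one explicit seed; pH is carried
  unperturbed. The noise-free twin is retained on every replicate.

### Calibration of the per-condition defaults

The H₂ plateaus (30 / 24 / 21 Pa, decreasing with CO₂) and the
staggered midpoints were fixed once, by desk thermodynamics, to make
the generator's world internally consistent with the mechanism it
emulates: between conditions the log-phase acetate-oxidation ΔG changes
by ≈ 2RT·Δln[HCO₃⁻] + 4RT·Δln p₍H₂₎, so an H₂ contrast much steeper
than ~0.7× per condition step would overwhelm the bicarbonate term and
invert the CO₂ effect, while the measured high-CO₂ H₂ level (~16 Pa at
day 5) anchors the low end. The staggered midpoints let biogenic CO₂
partially compress the between-condition bicarbonate ratio during
days 2–5, keeping the aceticlastic spread below 5 kJ/mol as observed
in real cultures. These are stand-in parameters for trajectory shapes,
never presented as measurements.

What passing tests on this generator do show: the pipeline's
arithmetic (speciation, Q assembly, aggregation, counterfactuals,
normalization) is correct, and the CO₂-driven thermodynamic squeeze on
the syntrophs emerges from the chemistry given realistic inputs. What
they do not show: that real cultures follow logistic kinetics, that
real noise is lognormal and uncorrelated, or that absolute simulated
ΔG levels match measured ones (measured values depend on unpublished
per-day concentrations, and the simulated SAOB ΔG sits above the
−20 kJ/mol line through log phase, unlike the borderline-feasible
measured values).

## Analysis choices

- **Log-phase window**: days 2–5, closed on both ends; configurable.
- **Replicate scatter**: sample SD (n−1); SD is reported as exactly 0
  when all pooled values are identical (guarding against float-sum
  artifacts in the noise-free case).
- **Missing data**: a replicate-day whose required analyte is zero or
  absent (e.g. H₂ at inoculation, where ln Q is undefined) is dropped
  from that day's statistics and recorded in the series' error log,
  never imputed.
- **Methanogenic rate**: least-squares slope over the steepest
  contiguous 3-point window of cumulative CH₄ per liter of medium — a
  windowed estimate robust at the handful of time points of a batch
  experiment; no growth-model fit is attempted.
- **Normalized quantities** (relative rates, relative abundances):
  ratio of replicate means to the reference condition ("5.0"), with SD
  propagated by the first-order delta method.
- **Determinism**: all randomness flows from one seed; per-condition
  generator seeds are derived arithmetically from it. Pipeline outputs
  carry a hash of the scientific parameters (runtime plumbing such as
  the output directory excluded), and the analysis stage always
  consumes the written CSV, so fresh and `--skip-simulate` reruns are
  byte-identical.

## Problem sizes

Default runs are intentionally small: 3 conditions × 3 replicates ×
16 daily samples, 1000-state random sweeps for the thermodynamic
identity checks, 20 seeded runs for abundance-recovery statistics.
These sizes make every check exact or statistically comfortable while
keeping the full suite in seconds.

## Known limitations

- Fixed-pH, two-species carbonate chemistry; no ionic-strength or
  activity-coefficient corrections, no pH trajectory.
- The mixed temperature convention (25 °C ΔG°′ with 328 K R·T·ln Q) is
  the field's, not strict thermodynamics; the optional Gibbs–Helmholtz
  mode shifts aceticlastic ΔG by a few kJ/mol.
- No kinetics: the generator cannot answer rate questions beyond the
  shapes it was given, and no hypothesis testing between conditions is
  provided.
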