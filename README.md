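# syntherm

Bioenergetics of methanogenic acetate degradation in closed-vial
consortia: why does elevated CO₂ suppress syntrophic acetate oxidation
but not aceticlastic methanogenesis?

In thermophilic methanogenic environments, acetate is converted to
methane by two competing routes carried by different organisms:

| route | reaction | ΔG°′ (kJ/mol) |
|---|---|---|
| aceticlastic (*Methanosaeta thermophila*) | CH₃COO⁻ + H₂O → CH₄ + HCO₃⁻ | −31.0 |
| acetate oxidation (*Thermacetogenium phaeum*, SAOB) | CH₃COO⁻ + 4 H₂O → 2 HCO₃⁻ + 4 H₂ + H⁺ | +104.6 |
| hydrogenotrophic (*Methanothermobacter thermautotrophicus*) | 4 H₂ + HCO₃⁻ + H⁺ → CH₄ + 3 H₂O | −135.6 |

The syntrophic route (rows 2+3) lives on a knife edge: the oxidation
step is endergonic at standard state and feasible only at very low H₂
partial pressure, while the hydrogenotroph cannot draw H₂ below its own
energetic floor. Both partners must clear roughly −20 kJ per mol of
reaction — the approximate minimum for microbial energy conservation —
so syntrophy operates only inside an H₂ *feasibility window*. Because
acetate oxidation produces 2 mol of inorganic carbon per mol of acetate,
raising the CO₂/bicarbonate content of the medium pushes its in-situ

ΔG = ΔG°′ + R·T·ln Q,  Q = [HCO₃⁻]²·p₍H₂₎⁴·10^(7−pH) / [CH₃COO⁻],

toward (and past) the −20 kJ/mol borderline and squeezes the window
shut, while the aceticlastic reaction — producing a single HCO₃⁻ — is
barely perturbed. The package quantifies this dominance-switch
mechanism.

## What's inside

- `syntherm.carbonate` — closed-vial carbonate speciation: partitions
  NaHCO₃ + headspace CO₂ across gas, dissolved CO₂ and bicarbonate via
  Henry's law (k = 0.019 mol L⁻¹ atm⁻¹ at 55 °C) and the first
  carbonic-acid dissociation (K₁ = 4.47 × 10⁻⁷) at fixed pH.
- `syntherm.thermo` — the three reactions with an editable
  formation-energy table (Thauer-convention, pH-7 primed), in-situ ΔG,
  H₂ counterfactual shifts, H₂ thresholds, feasibility windows.
- `syntherm.synthetic` — batch time-course and 16S-abundance generators
  with exactly known ground truth (noise-free twins, explicit seeds).
- `syntherm.analysis` — ΔG series with replicate mean/SD, log-phase
  (day 2–5) summaries, counterfactual reports, methanogenic rates,
  normalized abundances, stoichiometric closure checks.
- `syntherm.io` / `syntherm.cli` — tidy-CSV interchange, validated YAML
  run configs, and the `syntherm` command.

## Worked example

Run the full pipeline — simulate the three study media (5 / 35 mM
NaHCO₃ under 0 / 20 / 100% CO₂ headspace, 40 mM acetate, triplicate,
5% noise) and analyze them:

```bash
syntherm run --seed 1 --out-dir demo
```

`demo/logphase_summary.csv` then holds the day 2–5 pooled ΔG per
condition and reaction (kJ/mol):

```
 condition          reaction   mean   sd  n  exceeds_threshold
       5.0      aceticlastic -36.84 3.59 12              False
       5.0 acetate_oxidation   1.42 3.22 12               True
      50.7 acetate_oxidation   4.65 1.81 12               True
     113.4      aceticlastic -33.49 2.65 12              False
     113.4 acetate_oxidation   7.08 1.14 12               True
```

Reading it: the aceticlastic ΔG barely moves across the three media
(−36.8 → −33.5, a 3.3 kJ/mol drift), while the acetate-oxidation ΔG
climbs monotonically with inorganic carbon (+1.4 → +4.7 → +7.1) — the
elevated-CO₂ media thermodynamically penalize only the syntrophs.
`demo/counterfactual.csv` answers "what if H₂ dropped to 10 Pa?": even
then the high-CO₂ oxidation ΔG stays near the borderline (+0.7 kJ/mol)
whereas the low-CO₂ one falls to −6.0, so only the low-CO₂ culture
leaves its SAOB room to operate. (Condition labels are the nominal
initial total inorganic carbon, mmol per liter of medium.)

`syntherm run` also accepts `--config run.yaml` (unknown keys are
rejected; the resolved config and its hash are echoed to the output
directory). The defaults shown reproduce the three study conditions:

```yaml
seed: 1
out_dir: demo
vial:
  total_volume: 0.068      # L
  liquid_volume: 0.020     # L
  temperature: 328.15      # K (55 degC)
generator:
  initial_acetate: 0.040   # mol/L
  duration_days: 15.0
  sampling_interval_days: 1.0
  n_replicates: 3
  noise_rel_sd: 0.05
analysis:
  window: [2.0, 5.0]       # log-phase days, closed
  threshold: -20.0         # kJ/mol feasibility borderline
  reference_condition: "5.0"
  counterfactual_day: 5.0
  counterfactual_h2_pa: 10.0
```

Single steps are available too:

```bash
syntherm speciate                       # media speciation as CSV
syntherm simulate --condition 113.4 --seed 2 --out tc.csv
syntherm deltag tc.csv --reaction acetate_oxidation
syntherm analyze tc.csv --window 2:5 --threshold -20
```

## Limitations

The synthetic trajectories are shape-level stand-ins with plausible
parameters, not measurements, and carbonate speciation assumes fixed pH,
unit activity coefficients and no carbonate ion. See
`docs/methods.md` for the model, its assumptions and the calibration
rationale.
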