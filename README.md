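# hepaflux

Bioenergetic assessment of donor livers during normothermic machine
perfusion (NMP), for transplant researchers and respirometry labs working
with oxygraph (O2k-style) data.

During NMP a donor liver is kept metabolically active outside the body,
which makes its mitochondrial function measurable *before* transplantation.
`hepaflux` implements the full analysis chain for that assessment:

1. **Trace analysis** — chamber oxygen concentration recorded at 2 s
   intervals is converted to mass-specific respiration
   `J(t) = [-dC/dt·1000 - J°bg(C)] / ρ` (pmol O₂ s⁻¹ mg⁻¹ wet mass), and a
   steady-state plateau is detected after every titration of a
   Substrate-Uncoupler-Inhibitor Titration (SUIT) protocol, with QC flags
   and duplicate-chamber merging.
2. **Coupling control** — from the succinate-pathway coupling states
   L (LEAK), P (OXPHOS), Pc (OXPHOS + cytochrome c) and E (ET capacity,
   the maximum over stepwise CCCP titrations), the control efficiencies
   `1 − L/P` (ATP-production efficiency), `1 − P/Pc` (outer-membrane
   damage) and `1 − P/E` or `1 − Pc/E` (phosphorylation-system control)
   are derived, plus flux control ratios `FCR = J_pathway / J_ref` for
   substrate-pathway runs. Out-of-range values are flagged, never clipped.
3. **Adenylate energetics** — energy charge
   `(ATP + 0.5·ADP)/(ATP + ADP + AMP)` and the ATP:ADP ratio from biopsy
   nucleotide panels.
4. **Perfusate viability** — the transplantability rules (lactate
   clearance ≤ 2.5 mmol L⁻¹ by 2 h, stable pH 7.30–7.45 without repeated
   bicarbonate, AST/ALT/LDH ≤ 20,000 U L⁻¹) and per-time-point cohort
   summaries.
5. **Outcome model** — trapezoidal AUC of each biomarker over the first
   6 h of NMP, bidirectional stepwise-AIC model selection (with the
   marginality rule for product interactions), and an OLS fit of the
   L-GrAFT early-graft-function score reported with Type II ANOVA,
   standardized betas, confidence intervals and partial residuals.
6. **Synthetic data** — a generator for traces, livers and whole cohorts
   with known ground truth (clinical NMP datasets are rarely shareable),
   whose outcome link uses the *same* AUC routine as the analysis.

## Worked example

```python
import hepaflux as hf

# simulate a SUIT02 coupling-control run and analyse it back
params = hf.TraceSimParams(noise_sd=0.1, seed=11)
table = hf.evaluate_protocol(hf.simulate_trace(params), "SUIT02")
profile = hf.coupling_states(table)
panel = hf.efficiency_panel(profile, variant="A")
```

prints (via the obvious f-strings):

```
L = 8.22, P = 40.97, Pc = 43.38, E = 69.66  (pmol O2 s-1 mg-1)
P-L efficiency 1-L/P = 0.799
cyt-c efficiency 1-P/Pc = 0.056
E-P efficiency 1-P/E = 0.412 (variant A), 1-Pc/E = 0.377 (variant B)
```

The extracted states sit within a couple of percent of the simulation truth
(8.21, 40.49, 43.48, 70.33): a P-L efficiency near 0.8 means ~80% of OXPHOS
flux is coupled to phosphorylation, and a cytochrome-c efficiency near zero
means an intact outer mitochondrial membrane.

A cohort-level model, end to end:

```python
bundle = hf.simulate_cohort(hf.CohortSimParams(n_livers=60, seed=11))
design = hf.assemble_design(
    bundle.model_frame(),
    ["pl_eff_auc", "cytc_eff_auc", "leak_auc"],
    [("cytc_eff_auc", "leak_auc")],
    outcome="lgraft",
)
selected = hf.stepwise_aic(design, "lgraft")
fit = hf.fit_and_anova(design, selected, "lgraft")
```

```
selected terms: ['pl_eff_auc', 'cytc_eff_auc', 'leak_auc', 'cytc_eff_auc:leak_auc']
                 term       b    beta       F      p
           pl_eff_auc -2.9833 -0.2590  6.5367 0.0134
         cytc_eff_auc  1.2931  0.1600 50.1973 0.0000
             leak_auc -0.0535 -0.3335 39.4165 0.0000
cytc_eff_auc:leak_auc -0.1124 -0.8468 13.7052 0.0005
r2 = 0.67, adj r2 = 0.64, F(4, 55) = 27.67, p = 0.0000
```

All four planted AUC predictors are recovered with the generating signs:
higher ATP-production efficiency and lower LEAK/outer-membrane damage over
the first 6 h of perfusion predict a lower (better) outcome score.

The same stages are scriptable from the shell:

```bash
hepaflux simulate cohort --seed 3 --out cohort/
hepaflux viability assess --perfusate cohort/perfusate.csv --out decisions.jsonl
hepaflux model fit --biomarkers cohort/biomarkers.csv \
    --outcomes cohort/outcomes.csv --interaction cytc_eff,leak --report report/
```

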