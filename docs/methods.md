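# Methods

This note documents the models implemented in `hepaflux`, the defaults and
why they were chosen, the design decisions taken where the problem was
genuinely open, and what the synthetic cohorts do and do not establish about
real data.

## Respirometry trace model

The oxygraph signal is chamber O₂ concentration C(t) in µM sampled at a
fixed interval (default 2 s, emulating O2k recordings in a 2 mL chamber with
1 mg mL⁻¹ wet tissue mass). Respiration removes oxygen, so the mass-specific
flux is

    J(t) = [ −dC/dt · 1000 − J°bg(C) ] / ρ        [pmol O₂ s⁻¹ mg⁻¹]

with ρ the wet mass per chamber volume (mg mL⁻¹) and J°bg(C) = a + b·C an
instrumental background flux per mL. The background defaults to (a, b) =
(0, 0) — a freshly calibrated chamber — which keeps the toy cases
closed-form; the simulator can inject nonzero values to test the
subtraction.

**Derivative estimation.** dC/dt is the least-squares slope over a moving
window of ±`smoothing_halfwidth` samples (default 5, ≈ ±10 s). A windowed
regression was preferred over a finite difference because at 2 s sampling
sensor noise dominates a two-point difference; the window trades a small
support (edges flagged invalid) for a large variance reduction.

**Plateau detection.** After each titration event the search skips
`skip_after_event` (60 s) and slides a window of `window_length` (120 s)
sample by sample. A window qualifies when the fitted flux trend is within
`slope_tolerance` (1% of the flux per minute) and the coefficient of
variation within `cv_max` (5%); the step flux is the **median** of the
earliest qualifying window (robust and deterministic; earliest-window
tie-break). If no window qualifies before the next event or `max_wait`
(600 s) the step is flagged `no_plateau`; if the trace ends before a full
window fits, `short_window` (flux from the available tail). Flags are
reported, never silently repaired, and duplicate-chamber merging propagates
the worst flag and marks steps whose chambers disagree by more than 15%.

**Precision experiment design.** The recovery study behind
`hepaflux.experiments` targets 2% accuracy per state at σ = 1 µM white
sensor noise. The standard error of a regression slope over a window of
length W with n samples is σ·√(12/n)/W, so the achievable flux precision is
set by the window length — ~0.03 pmol s⁻¹ mg⁻¹ for a 4000 s window but only
~3.7 pmol for the default 120 s window. Per-step windows are therefore sized
to each state's flux (LEAK, the smallest flux, gets the longest window), the
smoothing halfwidth is raised to 150 samples, and the run starts
hyperoxygenated at 480 µM — standard practice for homogenate runs — so the
whole titration fits the chamber oxygen budget (~410 µM consumed). The `cv`
bound is relaxed to 0.12 in this configuration because the heavier smoothing
changes the pointwise noise scale the CV is measured on. Measured
empirically, all four states recover within 1% per run at σ = 1 µM.

## Coupling control

From a SUIT02-style run the states are L (LEAK: succinate + rotenone, no
ADP), P (saturating ADP), Pc (after exogenous cytochrome c) and E (maximal
uncoupled respiration). E is the **maximum** over the recorded CCCP steps, so
an overshoot past the uncoupler optimum never lowers the reported capacity.

Efficiencies: P-L control efficiency 1 − L/P; cytochrome-c control
efficiency 1 − P/Pc; E-P control efficiency in two variants, 1 − P/E
(variant A) and 1 − Pc/E (variant B). Both variants circulate in the
literature and they differ numerically (0.42 vs 0.38 at the default truth
values), so the panel always carries both and the caller selects which one
is reported as *the* E-P efficiency. For a profile ordered
0 ≤ L ≤ P ≤ Pc ≤ E every efficiency lies in [0, 1]; values outside that
range diagnose titration problems (L > P, E < P) and are **flagged, not
clipped** — clipping would hide exactly the failure the flag exists for.

Cohort summaries of efficiencies are summaries of per-liver ratios (mean or
median of the per-measurement efficiencies), not ratios of summary fluxes;
the two differ whenever fluxes vary between livers, which is one reason a
cohort-mean efficiency need not equal the formula applied to cohort-mean
fluxes.

For substrate-pathway runs the serial titration (F substrates → + N
substrates → + succinate = all substrates → rotenone isolates S) is
decomposed as F_P = J(F), N_P = J(FN) − J(F), S_P = J(S), with the
all-substrate step as the internal reference; FCRs are each pathway flux
over that reference.

## Adenylate energetics

Energy charge (ATP + 0.5·ADP)/(ATP + ADP + AMP) and ATP:ADP ratio, with
undefined cases (all-zero panel, zero ADP) raised as errors scalar-wise and
returned as NaN in the vectorized table helper. HPLC peak quantification and
standard-curve calibration are upstream of this package; panels enter as
concentrations.

## Perfusate viability

The decision rule is a conjunction of three criteria; `overall` is "accept"
exactly when all three hold. Two operationalizations were needed where the
prose rule is underspecified:

* "prompt" lactate clearance is read as ≤ 2.5 mmol L⁻¹ at ≤ 2 h of NMP
  (the deadline is configurable);
* "repeated" bicarbonate addition is read as ≥ 2 additions (plural),
  also configurable.

IL-6 has no accept/reject threshold anywhere in the rule set; it is
surfaced as a warning only. Trajectory summaries report median/IQR per
analyte at **observed** sampling times only — no interpolation.

## Outcome model

Each biomarker series is condensed to a trapezoidal AUC over a window,
default [0 h, 6 h] of NMP with the end-of-cold-storage biopsy assigned
t = 0. The early window was chosen because the predictive claim of the
study design concerns the first 6 h of perfusion; a full-NMP window and a
time-averaged variant (AUC divided by integrated duration) are available by
flag. The integral clips to the window, interpolating at the window edges
but never extrapolating beyond the first/last observation; fewer than two
observations inside the window give a missing value, and modelling is
complete-case with the exclusion count logged.

**Selection.** Bidirectional stepwise AIC from the intercept-only model.
AIC is the least-squares form n·log(RSS/n) + 2p with p counting
coefficients including the intercept. Marginality is enforced: a product
interaction may enter only while both parents are in, and a parent may not
leave while its interaction remains. Ties break lexicographically, making
selection deterministic. RSS is floored at 1e-10 of the total sum of
squares inside the AIC: below that level log-RSS differences between nested
numerically-perfect fits are floating-point noise, and the floor lets the
2p penalty pick the smallest perfect model. Greedy single-move search
provably equals exhaustive subset search only on well-conditioned problems;
the test suite verifies the equivalence on independent-predictor designs
with clearly in/out coefficients, which is the regime the claim is made
for.

**Inference.** The selected model is refit by OLS (statsmodels). Type II
sums of squares are computed by explicit nested refits — SS(term) =
RSS(model with every term not containing it) − RSS(that model + term) — so
main effects are tested excluding their interactions; the implementation is
cross-checked against `statsmodels.stats.anova_lm(typ=2)` in the tests.
Standardized betas are b·sd(x)/sd(y). The overall F reproduces the closed
form (r²/k)/((1−r²)/df_resid) exactly. Partial residuals are e + b·x per
term; regressing them on x returns exactly b, the property that makes the
partial-residual plot interpretable. The sum of Type II SS need not equal
the total SS in non-orthogonal designs; this is expected, not a defect.

## Synthetic cohorts

Per-liver truth is drawn once per liver: OXPHOS capacity and the pathway
fluxes are lognormal with medians 40.23 / 12.54 / 4.81 pmol s⁻¹ mg⁻¹ and
shape parameters matched to the published interquartile ranges (σ =
ln(q75/q25)/1.349 ≈ 0.33 / 0.38 / 0.59); positive, right-skewed draws are
what liver respirometry data look like. The efficiencies are beta with
means 0.8 (P-L), 0.06 (cyt-c) and 0.40 (E-P) and a common concentration 60,
and the remaining states follow deterministically (L = P(1−pl), Pc =
P/(1−cc), E = Pc/(1−ep)).

Longitudinally, each state flux follows a liver-specific **linear trend**
(slope ~ N(0, drift_sd), default 0.01 relative per hour) plus measurement
noise (CV 5%, the scale of duplicate-averaged oxygraph measurements);
per-time efficiencies are then derived through the coupling formulas, so
noiseless data reproduce the liver draw exactly at every stage
(self-consistency). The between-time-point correlation model is a
construct of this package — no published estimate of it exists — so
conclusions that depend on the temporal correlation structure (e.g. how
much the AUC gains over a single time point) are statements about the
generator, not about real livers. Sampling times default to 0, 1, 6, 12
and 20 h of NMP. Adenylate panels have ATP rising saturating-exponentially
after the start of perfusion; perfusates have fast-clearing lactate
(floor ~0.8 mmol L⁻¹, τ ≈ 0.45 h) for transplant-quality livers and slow,
incomplete clearance for poor ones, with monotone enzyme-release trends —
deliberately minimal monotone models, not perfusion pharmacokinetics.

**Outcome link.** The score is linear in the realized AUC terms — computed
by the analysis module's own `time_auc`, never a private copy — plus
Gaussian noise: signs (−, +, −, and − for the product interaction) follow
the published multivariate model. The published raw coefficient magnitudes
are mutually inconsistent with raw value·hour AUC scales (they would swamp
the printed outcome range), so the default magnitudes (−3.1, +2.5, −0.047,
−0.125) were fixed once by scaling each term to roughly unit contribution
given the generator's AUC spreads (measured once as sd ≈ 0.32, 0.40, 21
and 8 for the partialled interaction), with outcome noise sd 2.0 giving
R² ≈ 0.5 at the cohort level — the same order as reported for the clinical
model. Identical root seeds give bit-identical cohorts; per-liver streams
are spawned as SeedSequence(root, index), so any single liver can be
regenerated alone.

**What passing tests show.** Recovery of the planted predictors at n = 200
demonstrates the correctness and power of the pipeline under the
generator's assumptions (linear link, independent livers, Gaussian noise,
the drift model above). It does not establish that the clinical effect
sizes are re-estimable at n = 20, nor validate the linearity of the true
biology.

## Numerical choices and limitations

* Trace integration is explicit Euler at the sample interval; exact for
  piecewise-linear segments, and transient-phase error is irrelevant
  because plateaus are read ≥ many time constants after each event.
* Oxygen exhaustion during simulation raises an error naming the step
  rather than producing an unphysical trace.
* Problem sizes in the test suite (50-seed recovery runs, 100 synthetic
  cohorts of 200 livers, 100 random ANOVA designs) were chosen to give
  comfortable statistical margins for the properties asserted while keeping
  the suite quick to run.
* The package does not model bile chemistry, hemodynamics, histology
  scores or immune markers; the NMP-imaging viability score enters only as
  an optional numeric covariate. MEAF and EAD are accepted as alternative
  outcome columns but their internal scoring formulas are out of scope.
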