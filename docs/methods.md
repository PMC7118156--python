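# Methods

This note records the models, parameter choices and numerical conventions
behind `platescreen`, and what the simulation-based validation does and does
not demonstrate.

## Data model

A screen is a long-format table, one record per (plate, well, read time),
with well roles `treated`, `vehicle_control`, `background`,
`untreated_reference` and `excluded`. Plates are standard 96-well grids
(rows A–H, columns 1–12); the 36 perimeter wells are the evaporation-prone
"edge" set. PBS-filled perimeter wells are retained in files with
`role=excluded` rather than dropped, so the mitigation is auditable.
Validation enforces: finite nonnegative signals, at least one background
well per analysed plate, and a vehicle control at every treated DMSO level
(both sides rounded to 4 decimals before matching, absorbing dilution-series
floating-point arithmetic).

## Normalization

Viability is `100 × (treated − bg) / (ctrl − bg)` with background and
matched-control means pooled per plate; controls are plate-local because
storage and evaporation histories differ between plates. Values are not
clipped at [0, 100]: >100% starts are a diagnostic of bad controls and must
stay visible to QC. The GR transform uses background-corrected signals as
cell-count proxies; the t = 0 reference `x0` is pooled per experiment by
default (sister-plate reads at treatment time), switchable to screen-wide
pooling. Whether `x0` should be tracked per plate or per experiment is
genuinely open in practice; per-experiment is the default because the t = 0
read typically lives on one sister plate per experiment. Wells whose
corrected signal falls at or below background (possible for fully killed
wells under noise) are floored at 10⁻⁶ of the control signal so their GR
value stays finite near −1 rather than crashing the fit.

## Dose-response fitting

Viability curves use the 4-parameter log-logistic
`V(c) = bottom + (top − bottom)/(1 + (c/ec50)^hill)` fitted on log10
concentration to replicate-level points. Bounds: top ∈ [50, 150] (free top
exposes >100% starts), bottom ∈ [−10, 100], hill ∈ [0.1, 10], log10(ec50)
within the tested range ±2 decades. Optimization is SciPy's trust-region
least squares with 15 starts (5-point ec50 grid × hill ∈ {0.5, 1, 2}) and
1e-12 tolerances — reproducibility is preferred over speed at these problem
sizes. The model choice itself is a documented convention: plate-viability
studies rarely state their curve model, and the 4PL is the field default.

IC50 is *absolute* (crossing of 50% of matched control), inverted in closed
form; it is the typed sentinel `NOT_REACHED` when 50% lies outside
(bottom, top) or the crossing leaves the tested range. Averaging or ranking
code must confront the sentinel explicitly — it is never a large
placeholder number. The relative EC50 remains available inside the fit.
AUC is the trapezoid of mean viability/100 over log10(c) divided by the
log-range, so 1.0 means no effect regardless of grid; this makes AUC
unit-invariant and comparable across drugs.

GR curves use `GR(c) = GR_inf + (1 − GR_inf)/(1 + (c/GEC50)^h)` with
GR_inf bounded at the physical kill limit −1. A sigmoid is accepted over
the constant model only if the F-test on its 2 extra parameters has
p < 0.05 (the selection rule used by reference GR implementations);
otherwise the fit is flat and GR50 is NOT_REACHED. GRmax defaults to the
mean GR at the single top concentration — the quantity screens actually
report as efficacy, despite "max" naming; a `top_two` variant averages the
two highest doses. GR_AOC integrates measured mean points rather than the
fitted curve so it stays meaningful when the flat-fit fallback triggers.

## Quality control

Z = 1 − 3(σp + σn)/|μp − μn| on treated versus background absorbance;
CV = 100σ/μ; signal window in the replicate-corrected form
(|μmax − μmin| − 3(SEMmax + SEMmin))/SEMmax, with the uncorrected raw-SD
variant behind a switch since both circulate in HTS validation guidance and
they disagree near the cutoff. Cutoff comparisons are strict (Z > 0.4,
SW > 2, CV < 20%). Because the granularity of QC is not standardized, the
report emits all of: per-plate (replicates at the highest-mean-signal
concentration versus background — pooling across doses would fold the
dose-response itself into σp), per-concentration, and screen-pooled rows.

## Confounder statistics

Variance components are *separate* one-way ANOVAs per covariate with
η² = SS_between/SS_total; under confounding these shares need not sum
to 100%, which is documented rather than "fixed" — the per-covariate
convention matches how screening optimization grids are analysed.
Continuous covariates are treated as the discrete levels actually tested.
The edge-effect test is a two-sided Wilcoxon rank-sum of perimeter versus
interior signals (mid-rank ties; exact null for tie-free samples ≤ 20,
normal approximation with continuity correction otherwise; all-tied input
returns p = 1). Two-group comparisons run Shapiro–Wilk per sample and use
the t-test only when both samples pass (p > 0.05), falling back to rank-sum
— including for constant samples, where Shapiro–Wilk is undefined.
Benjamini–Hochberg adjustment is applied once per comparison table
(one family per report section).

## Growth kinetics

Td = 1/slope from OLS of log2(signal) on time. The exponential window trims
trailing reads while the last inter-read increment carries < 50% of the
window's average slope or window r² < 0.98 (minimum 3 reads; full range
with a warning if nothing qualifies). The trimming removes the plateau
bias but cannot fully linearize a logistic that bends early; the window
bounds are reported so users can see what was fitted.

## Simulator

The generator works backwards from the analysis definitions so recovery is
well posed: treated-well cell counts are produced by the exact inverse of
the GR transform evaluated at the truth curve, control wells get the DMSO
viability factor `1/(1 + (dmso/d50)^h)`, and signal = α·cells + β times a
Normal(1, cv) multiplier truncated at 0. Defaults and why:

| parameter | default | rationale |
|---|---|---|
| seeding | 7.5e3 cells/well | optimized-assay density |
| dose plan | 9 doses, 2-fold, triplicate, 3 experiments | standard screen layout |
| doubling times | 21–36 h | range of common breast-line panels |
| noise_cv | 0.05 | optimized assays show replicate CV < 5% |
| α, β | 1e-4 a.u./cell, 0.05 a.u. | puts signals at 0.75–6 a.u., ~10× background — the regime where Z ≈ 0.8–1 |
| edge_inflation | 0.10 | multiplicative perimeter signal inflation, signal-level (mechanism-agnostic) |
| dmso_d50, hill | 2%, 2 | ~6% viability dip at 1% DMSO, severe toxicity ≥ 5% |
| dmso at top dose | 0.5% | below the 1% toxicity threshold, scaled ∝ dose |
| evaporation | (1+r)^days on concentration | off by default; storage studies set r > 0 |

Endpoint plates place 27 treated + 27 matched-vehicle + 6 background wells
on the 60-well interior with a PBS `excluded` perimeter; a sister plate per
experiment carries the t = 0 reference wells. Randomness is counter-based
per (master seed, plate id, well index): same truth → bit-identical screen,
and adding plates never perturbs existing wells.

What the simulator does *not* emulate: mechanistic pharmacokinetics,
cell-cycle structure, within-well spatial gradients, reagent over-reduction
kinetics, or spatially correlated noise. Passing recovery tests therefore
shows the estimators invert the stated generative model at realistic noise;
it does not certify behavior under structured artifacts absent from that
model.

## Validation studies (what `scripts/acceptance.py` recomputes)

Problem sizes were chosen as the smallest that make the Monte-Carlo
medians stable: noise-free inversion on one screen; GR50 recovery over 100
seeded screens (truth GR50 = 10); η² share recovery over 100 orthogonal
designs (planned 50/40%); edge-test calibration on 1000 null and 200
inflated plates; doubling-time recovery over 4 × 25 growth courses;
a paired fresh-vs-stored IC50 contrast; and exact closed-form checks for
Z/SW/CV and BH against hand-worked values. Every number the script reports
is computed at run time from these simulations.
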