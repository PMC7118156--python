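"""Simulate a one-drug screen and compute potency/efficacy metrics.

Builds a 9-dose, 2-fold, triplicate bortezomib screen on a simulated HCC38
line (36 h doubling time), normalizes against matched DMSO controls, and
reports both conventional (IC50/Emax/AUC) and growth-rate-corrected
(GR50/GRmax/GR_AOC) metrics.
"""

from platescreen import (
    NOT_REACHED,
    CellLineTruth, DosePlan, GRCurveTruth, SimTruth,
    build_gr_series, build_series, fit_gr_curve, gr_result, potency,
    simulate_screen,
)

truth = SimTruth(
    cell_lines={"HCC38": CellLineTruth(doubling_time_h=36.0)},
    drugs={("HCC38", "bortezomib"): GRCurveTruth(gr_inf=-0.9, gec50=10.0, h_gr=2.0)},
    plan=DosePlan(top=1000.0, fold=2.0, n_doses=9, replicates=3, conc_unit="nM"),
    n_experiments=3,
    noise_cv=0.05,
    seed=1,
)
sim = simulate_screen(truth)
print(f"simulated {len(sim.screen.data)} well records "
      f"({truth.n_experiments} experiments, triplicate, 9 doses)")

vs = build_series(sim.screen, "HCC38", "bortezomib")
pot = potency(vs)
print(f"IC50  = {pot.ic50:.3g} nM   (dose where viability crosses 50% of control)"
      if pot.ic50 is not NOT_REACHED else "IC50 not reached in tested range")
print(f"Emax  = {pot.emax:.1f} %    (viability at the top dose)")
print(f"AUC   = {pot.auc:.3f}      (area under viability curve; 1 = no effect)")

gs = build_gr_series(sim.screen, "HCC38", "bortezomib")
res = gr_result(gs, fit_gr_curve(gs))
print(f"GR50  = {res.gr50:.3g} nM   (dose where GR crosses 0.5; "
      "division-rate corrected potency)")
print(f"GRmax = {res.gr_max:.2f}    (GR at top dose; < 0 means net cell kill)")
print(f"GR_AOC = {res.gr_aoc:.2f}   (area over GR curve; 0 = inert, 2 = kill everywhere)")
print("GR50 < IC50: the growth-rate metric flags cytotoxicity at lower dose "
      "because it does not reward slow control growth.")
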