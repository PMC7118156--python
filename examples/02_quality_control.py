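"""Assay quality control: Z-factor, signal window, CV, and the edge effect.

A well-optimized resazurin assay should sit at Z > 0.75, SW > 10, CV < 5%
(pass cutoffs are Z > 0.4, SW > 2, CV < 20%). The edge-effect check compares
perimeter- against interior-well signals with a Wilcoxon rank-sum test on a
plate seeded uniformly with untreated cells.
"""

from platescreen import edge_effect_test, qc_report, simulate_screen, simulate_uniform_plate
from examples_common import default_truth

sim = simulate_screen(default_truth(seed=2))
rep = qc_report(sim.screen)
plate_rows = rep.table[rep.table["condition"] == "plate"]
for _, r in plate_rows.iterrows():
    print(f"{r['plate_id']}: Z = {r['z']:.2f}, SW = {r['sw']:.1f}, "
          f"CV = {r['cv']:.1f}%  -> pass = {bool(r[['pass_z','pass_sw','pass_cv']].all())}")
print(f"all QC rows pass: {rep.all_pass()}")

for e in (0.0, 0.10):
    plate = simulate_uniform_plate(noise_cv=0.02, edge_inflation=e, seed=3)
    res = edge_effect_test(plate)
    label = "no inflation" if e == 0 else f"{e:.0%} perimeter inflation"
    print(f"edge test, {label}: p = {res.p:.3g} ({res.stars})")
print("a significant edge test says perimeter wells read hotter than the "
      "interior - the layout should exclude them (PBS-filled).")
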