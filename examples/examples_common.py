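"""Shared default simulation truth for the example scripts."""

from platescreen import CellLineTruth, DosePlan, GRCurveTruth, SimTruth


def default_truth(seed: int = 0, **overrides) -> SimTruth:
    kwargs = dict(
        cell_lines={"HCC38": CellLineTruth(doubling_time_h=36.0)},
        drugs={("HCC38", "bortezomib"): GRCurveTruth(gr_inf=-0.9, gec50=10.0,
                                                     h_gr=2.0)},
        plan=DosePlan(top=1000.0, fold=2.0, n_doses=9, replicates=3,
                      conc_unit="nM"),
        n_experiments=1,
        noise_cv=0.05,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimTruth(**kwargs)
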