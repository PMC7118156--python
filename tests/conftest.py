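import numpy as np
import pytest

from platescreen import (
    CellLineTruth,
    DosePlan,
    GRCurveTruth,
    SimTruth,
    simulate_screen,
)


def make_truth(**overrides) -> SimTruth:
    """One cell line, one drug, one experiment: the small default screen."""
    kwargs = dict(
        cell_lines={"HCC38": CellLineTruth(doubling_time_h=36.0)},
        drugs={("HCC38", "bortezomib"): GRCurveTruth(gr_inf=-0.9, gec50=10.0, h_gr=2.0)},
        plan=DosePlan(top=1000.0, fold=2.0, n_doses=9, replicates=3, conc_unit="nM"),
        n_experiments=1,
        noise_cv=0.05,
        edge_inflation=0.10,
        seed=0,
    )
    kwargs.update(overrides)
    return SimTruth(**kwargs)


@pytest.fixture
def noise_free_sim():
    return simulate_screen(make_truth(noise_cv=0.0, edge_inflation=0.0))


@pytest.fixture
def noisy_sim():
    return simulate_screen(make_truth(seed=7))


@pytest.fixture
def exact_gr_curve():
    """Evaluate the default truth GR curve at arbitrary concentrations."""
    return GRCurveTruth(gr_inf=-0.9, gec50=10.0, h_gr=2.0)


def four_pl(c, top, bottom, ec50, hill):
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)
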