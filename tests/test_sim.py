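import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from platescreen import (
    dilution_series,
    dmso_viability_factor,
    effective_concentration,
    gr_forward,
    gr_value,
    grow,
    simulate_screen,
    simulate_uniform_plate,
)
from platescreen.errors import DomainError, ValidationError
from platescreen.sim import SimTruth, CellLineTruth, GRCurveTruth, DosePlan

from conftest import make_truth


class TestDilutionSeries:
    def test_nine_point_twofold_from_1024(self):
        got = dilution_series(1024.0, 2.0, 9)
        np.testing.assert_allclose(got, [1024, 512, 256, 128, 64, 32, 16, 8, 4])

    def test_single_dose(self):
        np.testing.assert_allclose(dilution_series(5.0, 2.0, 1), [5.0])

    def test_tenfold(self):
        np.testing.assert_allclose(dilution_series(100.0, 10.0, 3), [100, 10, 1])

    @pytest.mark.parametrize("top,fold,n", [(0, 2, 3), (-1, 2, 3), (10, 1, 3),
                                            (10, 2, 0)])
    def test_invalid_arguments(self, top, fold, n):
        with pytest.raises(DomainError):
            dilution_series(top, fold, n)


class TestGrow:
    def test_one_doubling(self):
        assert grow(7500, 24, 24) == pytest.approx(15000)

    def test_time_zero_identity(self):
        assert grow(7500, 26, 0) == 7500

    def test_direct_evaluation(self):
        assert grow(7500, 26, 72) == pytest.approx(7500 * 2 ** (72 / 26))

    def test_capacity_caps_growth_monotonically(self):
        t = np.linspace(0, 240, 40)
        n = np.array([grow(7500, 24, ti, capacity=1e5) for ti in t])
        assert np.all(np.diff(n) >= 0)
        assert n[-1] <= 1e5
        # early growth tracks the exponential
        assert grow(7500, 24, 6, capacity=1e6) == pytest.approx(
            grow(7500, 24, 6), rel=0.01)


class TestGRForward:
    def test_cytostasis_fixed_point(self):
        assert gr_forward(100, 400, 0.0) == pytest.approx(100)

    def test_no_effect_fixed_point(self):
        assert gr_forward(100, 400, 1.0) == pytest.approx(400)

    def test_hand_evaluation(self):
        # x = 100 * 2^(log2(0.5) * 2) = 25
        assert gr_forward(100, 400, -0.5) == pytest.approx(25)

    def test_complete_kill_is_out_of_domain(self):
        with pytest.raises(DomainError):
            gr_forward(100, 400, -1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(gr=st.floats(-0.999, 1.0), ratio=st.floats(1.1, 30.0),
           x0=st.floats(10.0, 1e5))
    def test_round_trip_with_gr_value(self, gr, ratio, x0):
        x = gr_forward(x0, x0 * ratio, gr)
        assert gr_value(x, x0, x0 * ratio) == pytest.approx(gr, abs=1e-12)


class TestConfounders:
    def test_dmso_factor_anchors(self):
        assert dmso_viability_factor(0, 2, 2) == 1.0
        assert dmso_viability_factor(2, 2, 2) == pytest.approx(0.5)
        assert dmso_viability_factor(4, 2, 2) == pytest.approx(0.2)

    def test_dmso_factor_strictly_decreasing(self):
        xs = np.linspace(0, 10, 30)
        ys = [dmso_viability_factor(x, 2, 2) for x in xs]
        assert np.all(np.diff(ys) < 0)

    def test_effective_concentration(self):
        assert effective_concentration(10, 0, 5) == 10
        assert effective_concentration(10, 0.1, 2) == pytest.approx(12.1)


class TestSimulateScreen:
    def test_same_seed_is_bit_identical(self):
        a = simulate_screen(make_truth(seed=11)).screen.data
        b = simulate_screen(make_truth(seed=11)).screen.data
        assert a.equals(b)

    def test_different_seed_differs(self):
        a = simulate_screen(make_truth(seed=11)).screen.data
        b = simulate_screen(make_truth(seed=12)).screen.data
        assert not a["signal"].equals(b["signal"])

    def test_adding_cell_line_does_not_perturb_existing_wells(self):
        base = simulate_screen(make_truth(seed=3)).screen.data
        extra = make_truth(seed=3)
        extra.cell_lines["MCF7"] = CellLineTruth(doubling_time_h=26.0)
        extra.drugs[("MCF7", "bortezomib")] = GRCurveTruth(-0.4, 30.0, 1.5)
        both = simulate_screen(extra).screen.data
        key = ["plate_id", "well", "read_time_h"]
        merged = base.merge(both, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(base)
        np.testing.assert_array_equal(merged["signal_a"], merged["signal_b"])

    def test_noise_free_edge_inflation_ratio(self):
        plate = simulate_uniform_plate(noise_cv=0.0, edge_inflation=0.1, seed=0)
        df = plate.wells
        edge = df["row"].isin(["A", "H"]) | df["col"].isin([1, 12])
        ratio = df.loc[edge, "signal"].mean() / df.loc[~edge, "signal"].mean()
        assert ratio == pytest.approx(1.1, abs=1e-12)

    def test_invalid_truth_lists_offending_fields(self):
        with pytest.raises(ValidationError, match="gec50"):
            SimTruth(
                cell_lines={"CL": CellLineTruth(26.0)},
                drugs={("CL", "d"): GRCurveTruth(-0.5, -1.0, 1.0)},
            ).validate()

    def test_log_signal_is_linear_in_time_without_capacity(self):
        # noise-free daily reads: log2(signal - beta) vs t has slope 1/Td
        from platescreen import simulate_growth_course

        t, s = simulate_growth_course(26.0, n_days=5, replicates=1, noise_cv=0.0)
        slope = np.polyfit(t, np.log2(s), 1)[0]
        assert 1.0 / slope == pytest.approx(26.0, rel=1e-9)


class TestTruthSerialization:
    def test_yaml_round_trip(self, tmp_path):
        from platescreen.sim import write_simulated, read_truth

        truth = make_truth(seed=9)
        sim = simulate_screen(truth)
        write_simulated(sim, tmp_path / "s.csv", tmp_path / "t.yaml")
        back = read_truth(tmp_path / "t.yaml")
        assert back == truth
        # regenerating from the stored truth is bit-identical
        assert simulate_screen(back).screen.data.equals(sim.screen.data)
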