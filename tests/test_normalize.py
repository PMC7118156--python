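import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from platescreen import (
    build_gr_series,
    build_series,
    gr_value,
    percent_viability,
    simulate_screen,
)
from platescreen.errors import DegenerateControlError, NoGrowthError
from platescreen.io import matched_control_mean
from platescreen.wells import WellRole

from conftest import make_truth


class TestPercentViability:
    def test_quoted_formula_midpoint(self):
        assert percent_viability(0.60, 1.10, 0.10) == pytest.approx(50.0)

    def test_control_identity(self):
        assert percent_viability(1.10, 1.10, 0.10) == pytest.approx(100.0)

    def test_full_kill_identity(self):
        assert percent_viability(0.10, 1.10, 0.10) == pytest.approx(0.0)

    def test_values_above_100_are_not_clipped(self):
        assert percent_viability(1.5, 1.0, 0.0) == pytest.approx(150.0)

    def test_degenerate_control_rejected(self):
        with pytest.raises(DegenerateControlError):
            percent_viability(0.5, 0.1, 0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gain=st.floats(0.1, 50.0), offset=st.floats(0.0, 5.0),
           t=st.floats(0.05, 2.0), c=st.floats(1.0, 3.0), b=st.floats(0.0, 0.5))
    def test_affine_invariance(self, gain, offset, t, c, b):
        base = percent_viability(t, c, b)
        scaled = percent_viability(gain * t + offset, gain * c + offset,
                                   gain * b + offset)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestGRValue:
    def test_untreated_identity(self):
        assert gr_value(400, 100, 400) == pytest.approx(1.0)

    def test_cytostatic_identity(self):
        assert gr_value(100, 100, 400) == pytest.approx(0.0)

    def test_hand_evaluation(self):
        assert gr_value(25, 100, 400) == pytest.approx(-0.5)

    def test_negative_iff_below_t0(self):
        assert gr_value(99, 100, 400) < 0
        assert gr_value(101, 100, 400) > 0

    def test_no_growth_error(self):
        with pytest.raises(NoGrowthError):
            gr_value(50, 100, 100)


class TestBuildSeries:
    def test_no_effect_truth_gives_100_percent(self):
        truth = make_truth(noise_cv=0.0)
        truth.drugs[("HCC38", "bortezomib")].gr_inf = 1.0  # GR == 1 everywhere
        # a GR==1 curve is flat at 1: every dose behaves like its control
        sim = simulate_screen(truth)
        vs = build_series(sim.screen, "HCC38", "bortezomib")
        np.testing.assert_allclose(vs.means, 100.0, atol=1e-9)

    def test_replicate_count_pools_experiments(self):
        sim = simulate_screen(make_truth(n_experiments=3))
        vs = build_series(sim.screen, "HCC38", "bortezomib")
        assert all(p.n == 9 for p in vs.points)  # 3 experiments x triplicate

    def test_vehicle_wells_against_themselves_average_100(self):
        sim = simulate_screen(make_truth(seed=21))
        for plate in sim.screen.plates():
            df = plate.wells
            veh = df[df["role"] == WellRole.VEHICLE_CONTROL.value]
            if veh.empty:
                continue
            bg = plate.background_mean()
            for dmso, grp in veh.groupby("dmso_pct"):
                ctrl = matched_control_mean(float(dmso), plate)
                vals = [percent_viability(s, ctrl, bg) for s in grp["signal"]]
                assert np.mean(vals) == pytest.approx(100.0, abs=1e-9)

    def test_hand_normalization_of_one_plate_matches(self):
        sim = simulate_screen(make_truth(seed=13))
        screen = sim.screen
        vs = build_series(screen, "HCC38", "bortezomib")
        # brute-force oracle: normalize every treated well by hand
        per_conc = {}
        for plate in screen.plates():
            df = plate.wells
            tr = df[df["role"] == "treated"]
            if tr.empty:
                continue
            bg = df[df["role"] == "background"]["signal"].mean()
            for _, r in tr.iterrows():
                veh = df[(df["role"] == "vehicle_control")
                         & (np.round(df["dmso_pct"], 4) == round(r["dmso_pct"], 4))]
                v = 100 * (r["signal"] - bg) / (veh["signal"].mean() - bg)
                per_conc.setdefault(r["conc"], []).append(v)
        for p in vs.points:
            np.testing.assert_allclose(sorted(p.values),
                                       sorted(per_conc[p.concentration]),
                                       rtol=1e-12)

    def test_missing_condition_raises_lookup_error(self):
        sim = simulate_screen(make_truth())
        with pytest.raises(KeyError):
            build_series(sim.screen, "HCC38", "no-such-drug")

    def test_sem_is_sample_sd_over_sqrt_n(self):
        sim = simulate_screen(make_truth(seed=2))
        vs = build_series(sim.screen, "HCC38", "bortezomib")
        p = vs.points[0]
        assert p.sem == pytest.approx(np.std(p.values, ddof=1) / np.sqrt(p.n))


class TestBuildGRSeries:
    def test_noise_free_recovery_is_exact(self, noise_free_sim, exact_gr_curve):
        gs = build_gr_series(noise_free_sim.screen, "HCC38", "bortezomib")
        for p in gs.points:
            assert p.mean == pytest.approx(exact_gr_curve(p.concentration),
                                           abs=1e-9)

    def test_x0_scope_screen_matches_single_experiment(self, noise_free_sim):
        a = build_gr_series(noise_free_sim.screen, "HCC38", "bortezomib",
                            x0_scope="experiment")
        b = build_gr_series(noise_free_sim.screen, "HCC38", "bortezomib",
                            x0_scope="screen")
        np.testing.assert_allclose(a.means, b.means, rtol=1e-12)
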