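import numpy as np
import pandas as pd
import pytest

from platescreen import (
    adaptive_compare,
    bh_adjust,
    compare_groups,
    edge_effect_test,
    eta_squared,
    simulate_uniform_plate,
    stars,
    variance_table,
)
from platescreen.errors import DomainError, InsufficientDataError
from platescreen.sim import simulate_variance_dataset


def brute_force_eta(values, groups):
    y = np.asarray(values, float)
    g = np.asarray(groups)
    grand = y.mean()
    ssb = sum(len(y[g == lab]) * (y[g == lab].mean() - grand) ** 2
              for lab in set(groups))
    sst = sum((v - grand) ** 2 for v in y)
    return ssb, sst


class TestEtaSquared:
    def test_two_group_fixture_brute_force(self):
        vr = eta_squared([1, 2, 3, 4, 5, 6], ["A", "A", "A", "B", "B", "B"])
        assert vr.ss_between == pytest.approx(13.5)
        assert vr.ss_total == pytest.approx(17.5)
        assert vr.eta_sq == pytest.approx(13.5 / 17.5)  # 0.7714...
        assert vr.p < 0.05 or vr.p >= 0  # defined

    def test_perfect_separation(self):
        vr = eta_squared([0, 0, 1, 1], ["A", "A", "B", "B"])
        assert vr.eta_sq == pytest.approx(1.0)
        assert vr.p == 0.0

    def test_equal_group_means_gives_zero(self):
        vr = eta_squared([1, 3, 1, 3], ["A", "B", "B", "A"])
        assert vr.eta_sq == pytest.approx(0.0)

    @pytest.mark.parametrize("vals,groups", [
        ([1.0, 2.0], ["A", "A"]),
        ([1.0, 2.0, 3.0], ["A", "B", "C"]),
    ])
    def test_degenerate_designs_rejected(self, vals, groups):
        with pytest.raises(InsufficientDataError):
            eta_squared(vals, groups)

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = rng.normal(size=30)
            g = rng.choice(list("ABC"), size=30)
            if len(set(g)) < 2:
                continue
            vr = eta_squared(y, g)
            ssb, sst = brute_force_eta(y, g)
            assert vr.ss_between == pytest.approx(ssb)
            assert vr.ss_total == pytest.approx(sst)


class TestVarianceTable:
    def test_dominant_factor_ranks_first_and_significant(self):
        df = simulate_variance_dataset({"dose": 0.7, "noise_factor": 0.0},
                                       levels=3, replicates=15, seed=1)
        vt = variance_table(df, ["dose", "noise_factor"])
        assert vt.iloc[0]["covariate"] == "dose"
        assert vt.iloc[0]["p"] < 0.05

    def test_planned_shares_recovered_on_orthogonal_design(self):
        med = {"drug": [], "dose": [], "cell_line": []}
        for seed in range(30):
            df = simulate_variance_dataset(
                {"drug": 0.5, "dose": 0.4, "cell_line": 0.054},
                levels=3, replicates=20, seed=seed)
            vt = variance_table(df, list(med))
            for _, r in vt.iterrows():
                med[r["covariate"]].append(r["eta_sq_pct"])
        assert np.median(med["drug"]) == pytest.approx(50.0, abs=3.0)
        assert np.median(med["dose"]) == pytest.approx(40.0, abs=3.0)
        assert np.median(med["cell_line"]) == pytest.approx(5.4, abs=3.0)

    def test_pure_noise_covariate_rarely_significant(self):
        below = 0
        for seed in range(40):
            df = simulate_variance_dataset({"real": 0.3, "null": 0.0},
                                           levels=3, replicates=10, seed=seed)
            vt = variance_table(df, ["real", "null"])
            p_null = float(vt.loc[vt["covariate"] == "null", "p"].iloc[0])
            below += p_null > 0.05
        assert below >= 0.9 * 40 * 0.9  # not significant in >= ~90% of seeds

    def test_constant_covariate_skipped(self):
        df = pd.DataFrame({"viability_pct": [1.0, 2.0, 3.0, 4.0],
                           "fixed": ["x", "x", "x", "x"],
                           "varies": ["a", "a", "b", "b"]})
        vt = variance_table(df, ["fixed", "varies"])
        assert list(vt["covariate"]) == ["varies"]


class TestEdgeEffectTest:
    def test_identical_signals_not_significant(self):
        plate = simulate_uniform_plate(noise_cv=0.0, edge_inflation=0.0, seed=0)
        res = edge_effect_test(plate)
        assert res.p == 1.0

    def test_detects_ten_percent_inflation(self):
        plate = simulate_uniform_plate(noise_cv=0.02, edge_inflation=0.10, seed=1)
        assert edge_effect_test(plate).p < 0.05

    def test_null_rejection_rate_near_alpha(self):
        rej = sum(
            edge_effect_test(simulate_uniform_plate(noise_cv=0.02, seed=s)).p < 0.05
            for s in range(200)
        )
        assert 0.01 <= rej / 200 <= 0.09

    def test_accepts_raw_arrays(self):
        rng = np.random.default_rng(3)
        res = edge_effect_test((rng.normal(1.1, 0.02, 36), rng.normal(1.0, 0.02, 60)))
        assert res.method == "wilcoxon"
        assert res.p < 0.05

    def test_too_few_wells_rejected(self):
        with pytest.raises(InsufficientDataError):
            edge_effect_test((np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0])))


class TestAdaptiveCompare:
    def test_normal_samples_use_t_test(self):
        rng = np.random.default_rng(0)
        res = adaptive_compare(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        assert res.method == "t_test"

    def test_skewed_samples_use_wilcoxon(self):
        rng = np.random.default_rng(1)
        res = adaptive_compare(rng.lognormal(0, 2.0, 30), rng.lognormal(0, 2.0, 30))
        assert res.method == "wilcoxon"

    def test_equal_mean_normals_rarely_significant(self):
        rng = np.random.default_rng(2)
        sig = sum(
            adaptive_compare(rng.normal(0, 1, 20), rng.normal(0, 1, 20)).p < 0.05
            for _ in range(100)
        )
        assert sig <= 12

    def test_constant_input_falls_back_with_warning(self):
        res = adaptive_compare([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.method == "wilcoxon"
        assert res.warning is not None
        assert res.p == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            adaptive_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.001, 0.9]), [0.002, 0.9])

    def test_adjusted_at_least_raw_and_order_preserved(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=20)
        q = bh_adjust(p)
        assert np.all(q >= p)
        assert np.all(q <= 1.0)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.02, "*"),
        (0.01, "**"), (0.001, "***"), (0.0001, "****"), (1e-6, "****"),
    ])
    def test_threshold_mapping(self, p, expected):
        assert stars(p) == expected


class TestCompareGroups:
    def test_pairwise_table_one_bh_family(self):
        rng = np.random.default_rng(5)
        samples = {
            "a": rng.normal(0, 1, 12),
            "b": rng.normal(0, 1, 12),
            "c": rng.normal(3, 1, 12),
        }
        df = compare_groups(samples)
        assert len(df) == 3
        np.testing.assert_allclose(df["p_adj"], bh_adjust(df["p"].to_numpy()))
        sig = df[(df["group_a"] == "a") & (df["group_b"] == "c")]
        assert sig["stars"].iloc[0] != "ns"
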