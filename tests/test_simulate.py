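"""Monte Carlo trip-dose engine: additivity, coverage, stopping, comparisons."""

import numpy as np
import pandas as pd
import pytest

from tripdose import (
    SimulationConfig,
    StageTimeModel,
    TripCatalog,
    TripTypeModel,
    compare_scenarios,
    fit_stage_kde,
    run_replication,
    run_simulation,
    trip_dose,
)
from tripdose.simulate import SimulationResult

RATES = {
    "feeder": {"pm25": 1.0, "ebc": 0.5, "co": 0.05},
    "bus": {"pm25": 0.8, "ebc": 0.4, "co": 0.04},
    "BRT": {"pm25": 0.6, "ebc": 0.3, "co": 0.03},
}


def _point_model(mean, trip="T", idx=1, mode="feeder"):
    return StageTimeModel(trip, idx, mode, np.full(5, float(mean)), 0.0)


def _point_catalog():
    return TripCatalog(
        [TripTypeModel("T", ("feeder", "bus"), 1.0,
                       [_point_model(30), _point_model(40, idx=2, mode="bus")])]
    )


def _stochastic_catalog(seed=42):
    rng = np.random.default_rng(seed)
    s1 = rng.lognormal(np.log(40), 0.35, 120)
    s2 = rng.lognormal(np.log(70), 0.30, 120)
    m1 = fit_stage_kde(s1, "T1", 1, "feeder")
    m2 = fit_stage_kde(s2, "T1", 2, "bus")
    return TripCatalog([
        TripTypeModel("T1", ("feeder", "bus"), 0.6, [m1, m2]),
        TripTypeModel("T2", ("feeder", "bus"), 0.4, [m2, m1]),
    ])


class TestTripDose:
    def test_two_stage_hand_arithmetic(self):
        d = trip_dose({"feeder": {"pm25": 1.0, "ebc": 0, "co": 0},
                       "bus": {"pm25": 0.8, "ebc": 0, "co": 0}},
                      ["feeder", "bus"], [30.0, 40.0])
        assert d["pm25"] == pytest.approx(62.0)

    def test_single_stage(self):
        d = trip_dose(RATES, ["bus"], [25.0])
        assert d["pm25"] == pytest.approx(0.8 * 25.0)

    def test_zero_duration_contributes_nothing(self):
        base = trip_dose(RATES, ["feeder"], [30.0])
        padded = trip_dose(RATES, ["feeder", "bus"], [30.0, 0.0])
        assert padded == pytest.approx(base)

    def test_additivity_of_concatenation(self):
        whole = trip_dose(RATES, ["feeder", "BRT", "bus"], [20.0, 35.0, 15.0])
        part1 = trip_dose(RATES, ["feeder", "BRT"], [20.0, 35.0])
        part2 = trip_dose(RATES, ["bus"], [15.0])
        for p in whole:
            assert whole[p] == pytest.approx(part1[p] + part2[p])

    def test_errors(self):
        with pytest.raises(ValueError, match="tram"):
            trip_dose(RATES, ["tram"], [10.0])
        with pytest.raises(ValueError):
            trip_dose(RATES, ["feeder", "bus"], [10.0])


class TestRunReplication:
    def test_degenerate_equals_trip_dose(self, rng):
        rep = run_replication(_point_catalog(), RATES, 500, rng)
        expected = trip_dose(RATES, ["feeder", "bus"], [30.0, 40.0])
        got = rep.set_index("pollutant")["mean_dose"]
        for p, v in expected.items():
            assert got[p] == pytest.approx(v, rel=1e-12)

    def test_assignment_counts_binomial_bound(self):
        cat = TripCatalog([
            TripTypeModel("A", ("feeder", "bus"), 0.5,
                          [_point_model(30, "A"), _point_model(40, "A", 2, "bus")]),
            TripTypeModel("B", ("feeder", "bus"), 0.5,
                          [_point_model(10, "B"), _point_model(20, "B", 2, "bus")]),
        ])
        rep = run_replication(cat, RATES, 10_000, np.random.default_rng(0))
        n_a = rep.loc[rep["trip_type"] == "A", "n_commuters"].iloc[0]
        se = np.sqrt(10_000 * 0.25)
        assert abs(n_a - 5000) < 3 * se

    def test_seeded_reproducibility(self):
        cat = _stochastic_catalog()
        a = run_replication(cat, RATES, 300, np.random.default_rng(9))
        b = run_replication(cat, RATES, 300, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_unassigned_type_missing_not_zero(self):
        cat = TripCatalog([
            TripTypeModel("A", ("feeder", "bus"), 1.0 - 1e-9,
                          [_point_model(30, "A"), _point_model(40, "A", 2, "bus")]),
            TripTypeModel("B", ("feeder", "bus"), 1e-9,
                          [_point_model(10, "B"), _point_model(20, "B", 2, "bus")]),
        ])
        rep = run_replication(cat, RATES, 50, np.random.default_rng(1))
        assert "B" not in set(rep["trip_type"])


class TestRunSimulation:
    def test_degenerate_zero_width_exact_mean(self):
        cfg = SimulationConfig(n_commuters=200, min_replications=5,
                               max_replications=10, precision=0.05, seed=3)
        res = run_simulation(_point_catalog(), RATES, cfg)
        expected = trip_dose(RATES, ["feeder", "bus"], [30.0, 40.0])
        assert res.n_replications == 5
        for _, row in res.estimates.iterrows():
            assert row["ci_low"] == row["mean"] == row["ci_high"]
            assert row["mean"] == pytest.approx(expected[row["pollutant"]], rel=1e-12)

    def test_ci_coverage_calibration(self):
        """Nominal 95 % CIs contain the analytic expected dose in 93-97 % of
        100 seeded runs (both trip types, PM2.5)."""
        cat = _stochastic_catalog()
        mu = {
            ("T1", "pm25"): sum(r * m.mean() for r, m in
                                zip((1.0, 0.8), cat["T1"].stages)),
            ("T2", "pm25"): sum(r * m.mean() for r, m in
                                zip((1.0, 0.8), cat["T2"].stages)),
        }
        hits = total = 0
        for seed in range(100):
            cfg = SimulationConfig(n_commuters=200, min_replications=30,
                                   max_replications=30, precision=1.0, seed=seed)
            est = run_simulation(cat, RATES, cfg).estimates.set_index(
                ["trip_type", "pollutant"])
            for key, m in mu.items():
                total += 1
                hits += est.loc[key, "ci_low"] <= m <= est.loc[key, "ci_high"]
        assert 0.93 <= hits / total <= 0.97

    def test_tighter_precision_needs_more_replications(self):
        """Halving the precision target at least doubles the replication
        count (seed-averaged) while neither run hits the cap."""
        cat = _stochastic_catalog()
        mean_reps = {}
        for prec in (0.008, 0.004):
            reps = []
            for seed in range(5):
                cfg = SimulationConfig(n_commuters=50, min_replications=10,
                                       max_replications=5000, precision=prec, seed=seed)
                res = run_simulation(cat, RATES, cfg)
                assert res.converged
                reps.append(res.n_replications)
            mean_reps[prec] = np.mean(reps)
        assert mean_reps[0.004] >= 2 * mean_reps[0.008]

    def test_non_convergence_flagged(self):
        cat = _stochastic_catalog()
        cfg = SimulationConfig(n_commuters=20, min_replications=5,
                               max_replications=6, precision=1e-4, seed=0)
        with pytest.warns(UserWarning, match="precision"):
            res = run_simulation(cat, RATES, cfg)
        assert not res.converged
        assert not res.estimates["converged"].any()

    def test_bitwise_determinism(self):
        cat = _stochastic_catalog()
        cfg = SimulationConfig(n_commuters=100, min_replications=10,
                               max_replications=20, precision=0.05, seed=17)
        a = run_simulation(cat, RATES, cfg)
        b = run_simulation(cat, RATES, cfg)
        pd.testing.assert_frame_equal(a.estimates, b.estimates)
        assert a.audit == b.audit

    def test_two_stage_below_three_stage(self):
        """Adding a third stage with positive dose rate increases the dose."""
        cat = TripCatalog([
            TripTypeModel("two", ("feeder", "BRT"), 0.5,
                          [_point_model(30, "two"), _point_model(40, "two", 2, "BRT")]),
            TripTypeModel("three", ("feeder", "BRT", "bus"), 0.5,
                          [_point_model(30, "three"), _point_model(40, "three", 2, "BRT"),
                           _point_model(15, "three", 3, "bus")]),
        ])
        cfg = SimulationConfig(n_commuters=500, min_replications=10,
                               max_replications=20, precision=0.05, seed=2)
        est = run_simulation(cat, RATES, cfg).estimates.set_index(
            ["trip_type", "pollutant"])
        for p in ("pm25", "ebc", "co"):
            assert est.loc[("two", p), "mean"] < est.loc[("three", p), "mean"]


def _result_from_means(means_by_type, n_reps=30, jitter=0.2, seed=0):
    """Build a SimulationResult whose replication means average exactly to
    the requested values (symmetric jitter around each mean)."""
    rng = np.random.default_rng(seed)
    rep_means = {}
    for (trip, pol), m in means_by_type.items():
        noise = jitter * rng.standard_normal(n_reps // 2)
        vals = m + np.concatenate([noise, -noise])
        rep_means[(trip, pol)] = vals
    return SimulationResult(estimates=pd.DataFrame(), replication_means=rep_means,
                            n_replications=n_reps, converged=True,
                            config=SimulationConfig(seed=seed))


class TestCompareScenarios:
    def test_printed_mode_substitution_differences(self):
        """Feeder-Bus vs Cable car-Bus replicate sets centred on the reported
        per-trip means give differences of 26.4 µg (PM2.5) and 13.6 µg (eBC)."""
        a = _result_from_means({("Feeder - Bus", "pm25"): 103.7,
                                ("Feeder - Bus", "ebc"): 54.3,
                                ("Feeder - Bus", "co"): 4.6})
        b = _result_from_means({("Cable car - Bus", "pm25"): 77.3,
                                ("Cable car - Bus", "ebc"): 40.7,
                                ("Cable car - Bus", "co"): 3.6}, seed=1)
        out = compare_scenarios(a, b, [("Feeder - Bus", "Cable car - Bus")]).set_index("pollutant")
        assert out.loc["pm25", "difference"] == pytest.approx(26.4, abs=1e-9)
        assert out.loc["ebc", "difference"] == pytest.approx(13.6, abs=1e-9)
        assert out.loc["pm25", "p_value"] < 0.001

    def test_identical_replicates_null(self):
        a = _result_from_means({("T", "pm25"): 10.0, ("T", "ebc"): 5.0, ("T", "co"): 1.0})
        out = compare_scenarios(a, a, [("T", "T")]).set_index("pollutant")
        assert out.loc["pm25", "difference"] == 0.0
        assert out.loc["pm25", "t_statistic"] == 0.0
        assert out.loc["pm25", "p_value"] == 1.0

    def test_unpaired_type_rejected(self):
        a = _result_from_means({("T", "pm25"): 10.0, ("T", "ebc"): 5.0, ("T", "co"): 1.0})
        with pytest.raises(ValueError, match="other"):
            compare_scenarios(a, a, [("T", "other")])
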