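"""Sensor pipeline: corrections, k fit, synchronization, segmentation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tripdose import (
    ExposureSeries,
    FieldRegistry,
    RegistryEvent,
    SegmentSpec,
    SessionScenario,
    correct_photometer,
    fit_loading_k,
    generate_dual_ebc,
    generate_session,
    percent_reduction,
    process_session,
    segment_by_registry,
    summarize_modes,
    synchronize,
    virkkula_correct,
)
from tripdose.sensors import DegenerateStreamError


class TestPhotometerCorrection:
    @pytest.mark.parametrize(
        "raw, factor, zero, expected",
        [
            (100.0, 0.63, 0.0, 63.0),
            (100.0, 1.0, 0.0, 100.0),
            (50.0, 0.58, 2.0, 27.84),
        ],
    )
    def test_examples(self, raw, factor, zero, expected):
        out = correct_photometer(np.array([raw]), factor, zero)
        assert out[0] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            correct_photometer(np.ones(3), 0.0)


class TestVirkkula:
    @pytest.mark.parametrize(
        "bc, atn, k, expected",
        [(10.0, 50.0, 0.005, 12.5), (10.0, 0.0, 0.005, 10.0), (10.0, 50.0, 0.0, 10.0)],
    )
    def test_examples(self, bc, atn, k, expected):
        out = virkkula_correct(np.array([bc]), np.array([atn]), k)
        assert out[0] == pytest.approx(expected, rel=1e-12)

    @given(
        bc=st.floats(0, 100, allow_nan=False),
        atn=st.floats(0, 200, allow_nan=False),
        k=st.floats(0, 0.05, allow_nan=False),
    )
    def test_monotone_inflation(self, bc, atn, k):
        """Corrected eBC never falls below raw; equal exactly when k*ATN = 0."""
        out = virkkula_correct(np.array([bc]), np.array([atn]), k)[0]
        assert out >= bc
        if k * atn == 0:
            assert out == bc

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            virkkula_correct(np.ones(3), np.ones(4), 0.005)


def _dual_pair(k_true, cv, seed=1, duration=10_000):
    scn = SessionScenario(
        segments=[
            SegmentSpec("bus", duration, 87.0, 28.2, 5.0, 300.0),
            SegmentSpec("pedestrian", duration, 40.0, 10.0, 1.0, 2500.0),
        ],
        noise_cv={"ebc": cv},
        k_true=k_true,
        seed=seed,
    )
    return generate_dual_ebc(scn)


class TestLoadingFactorFit:
    @pytest.mark.parametrize("k_true", [0.001, 0.005, 0.01])
    def test_noiseless_recovery(self, k_true):
        a, b, _ = _dual_pair(k_true, cv=0.0)
        fit = fit_loading_k(a, b)
        assert abs(fit.k - k_true) / k_true <= 1e-6
        assert not fit.degenerate

    def test_noisy_recovery_matches_grid_oracle(self):
        """cv=0.05, n=2000: the bounded fit agrees with an exhaustive grid
        search and lands within 20 % of the generating k."""
        a, b, _ = _dual_pair(0.005, cv=0.05, seed=2)
        assert len(a) == 2000
        fit = fit_loading_k(a, b)

        grid = np.linspace(0.0, 0.02, 2001)
        bc_a, atn_a = a["bc_nc"].to_numpy(), a["atn"].to_numpy()
        bc_b, atn_b = b["bc_nc"].to_numpy(), b["atn"].to_numpy()
        sse = [np.mean((bc_a * (1 + k * atn_a) - bc_b * (1 + k * atn_b)) ** 2) for k in grid]
        k_grid = grid[int(np.argmin(sse))]

        assert abs(fit.k - k_grid) <= 1e-5  # grid step
        assert abs(fit.k - 0.005) / 0.005 <= 0.20

    def test_identical_streams_degenerate(self):
        a, _, _ = _dual_pair(0.005, cv=0.0)
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_loading_k(a, a.copy())
        assert fit.k == 0.0
        assert fit.degenerate

    def test_insufficient_overlap(self):
        a, b, _ = _dual_pair(0.005, cv=0.0)
        with pytest.raises(ValueError, match="overlap"):
            fit_loading_k(a.head(50), b.head(50))

    def test_zero_streams_rejected(self):
        z = pd.DataFrame({"bc_nc": np.zeros(500), "atn": np.zeros(500)})
        with pytest.raises(DegenerateStreamError):
            fit_loading_k(z, z.copy())


def _session_with_lags(lag_s):
    scn = SessionScenario(
        segments=[
            SegmentSpec("pedestrian", 1500, 40.0, 10.0, 1.0, 2500.0),
            SegmentSpec("feeder", 1500, 87.0, 28.2, 5.0, 300.0),
            SegmentSpec("station", 1000, 60.0, 15.0, 2.0, 800.0),
            SegmentSpec("bus", 1500, 90.0, 30.0, 6.0, 300.0),
        ],
        noise_cv=0.05,
        k_true=0.005,
        lag_s=lag_s,
        seed=4,
    )
    return generate_session(scn)


class TestSynchronize:
    @pytest.mark.parametrize("shift", list(range(-12, 13)))
    def test_recovers_injected_shift(self, shift):
        """Exhaustive lag sweep: every integer offset in ±12 samples comes back."""
        bundle = _session_with_lags({"ebc": shift * 10.0})
        sync = synchronize(bundle.streams, max_lag_s=120.0)
        assert sync.lags_samples["ebc"] == shift
        assert sync.lags_s["ebc"] == shift * 10.0

    def test_identical_streams_zero_lag(self):
        bundle = _session_with_lags({})
        sync = synchronize(bundle.streams, max_lag_s=120.0)
        assert all(l == 0 for l in sync.lags_samples.values())
        assert not sync.unsynchronizable

    def test_white_noise_flagged_unsynchronizable(self, rng):
        n = 600
        t = np.arange(n) * 10.0
        streams = {
            "pm": pd.DataFrame({"t_s": t, "pm25_raw": rng.normal(size=n)}),
            "co": pd.DataFrame({"t_s": t, "co_ppm": rng.normal(size=n)}),
        }
        with pytest.warns(UserWarning, match="unsynchronizable"):
            sync = synchronize(streams, max_lag_s=120.0)
        assert sync.lags_samples["co"] == 0
        assert "co" in sync.unsynchronizable

    def test_too_short_rejected(self):
        t = np.arange(20) * 10.0
        streams = {
            "pm": pd.DataFrame({"t_s": t, "pm25_raw": np.sin(t)}),
            "co": pd.DataFrame({"t_s": t, "co_ppm": np.sin(t)}),
        }
        with pytest.raises(ValueError, match="short"):
            synchronize(streams, max_lag_s=120.0)


def _flat_series(n=180, period=10.0):
    df = pd.DataFrame(
        {
            "t_s": np.arange(n) * period,
            "pm25": np.full(n, 10.0),
            "ebc": np.full(n, 2.0),
            "co": np.full(n, 1.0),
            "atn": np.zeros(n),
            "counts": np.full(n, 100.0),
        }
    )
    return ExposureSeries(df, period_s=period)


class TestSegmentation:
    def test_interval_arithmetic(self):
        """0s pedestrian / 600s feeder / 1800s end -> 60 + 120 samples."""
        series = _flat_series(n=180)
        reg = FieldRegistry(
            [
                RegistryEvent(0.0, "start", "pedestrian"),
                RegistryEvent(600.0, "board", "feeder"),
                RegistryEvent(1800.0, "end", None),
            ]
        )
        labeled = segment_by_registry(series, reg)
        counts = labeled["mode"].value_counts()
        assert counts["pedestrian"] == 60
        assert counts["feeder"] == 120
        assert len(labeled) == len(series)  # conservation

    def test_single_event_whole_series(self):
        series = _flat_series()
        labeled = segment_by_registry(
            series, FieldRegistry([RegistryEvent(0.0, "start", "bus")])
        )
        assert (labeled["mode"] == "bus").all()

    def test_boundary_sample_belongs_to_later_segment(self):
        series = _flat_series(n=12)
        reg = FieldRegistry(
            [RegistryEvent(0.0, "s", "pedestrian"), RegistryEvent(50.0, "b", "bus")]
        )
        labeled = segment_by_registry(series, reg)
        assert labeled.loc[labeled["t_s"] == 50.0, "mode"].iloc[0] == "bus"

    def test_event_outside_span_rejected(self):
        series = _flat_series(n=12)
        reg = FieldRegistry(
            [RegistryEvent(0.0, "s", "pedestrian"), RegistryEvent(10_000.0, "b", "bus")]
        )
        with pytest.raises(ValueError, match="outside"):
            segment_by_registry(series, reg)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            FieldRegistry([RegistryEvent(0.0, "s", "bus"), RegistryEvent(0.0, "b", "feeder")])


class TestSummaries:
    def test_constant_segment(self):
        labeled = pd.DataFrame(
            {"mode": "feeder", "pm25": 87.0, "ebc": 1.0, "co": 1.0}, index=range(30)
        )
        s = summarize_modes(labeled, campaign="baseline")
        row = s[(s["mode"] == "feeder") & (s["pollutant"] == "pm25")].iloc[0]
        assert row["mean"] == row["median"] == 87.0

    def test_linear_interpolation_quartiles(self):
        labeled = pd.DataFrame(
            {"mode": "bus", "pm25": [1.0, 2.0, 3.0, 4.0], "ebc": 1.0, "co": 1.0}
        )
        row = summarize_modes(labeled, "baseline").set_index("pollutant").loc["pm25"]
        assert row["mean"] == 2.5
        assert row["median"] == 2.5
        assert row["q1"] == 1.75
        assert row["q3"] == 3.25

    def test_pooling_equals_concatenation(self, rng):
        a = pd.DataFrame({"mode": "bus", "pm25": rng.normal(50, 5, 40), "ebc": 1.0, "co": 1.0})
        b = pd.DataFrame({"mode": "bus", "pm25": rng.normal(60, 5, 25), "ebc": 1.0, "co": 1.0})
        merged = summarize_modes(pd.concat([a, b], ignore_index=True), "x")
        direct = summarize_modes(
            pd.DataFrame({"mode": "bus", "pm25": np.concatenate([a["pm25"], b["pm25"]]),
                          "ebc": 1.0, "co": 1.0}), "x")
        pd.testing.assert_frame_equal(merged, direct)

    def test_quartile_ordering(self, rng):
        labeled = pd.DataFrame(
            {"mode": "bus", "pm25": rng.lognormal(3, 1, 200), "ebc": 1.0, "co": 1.0}
        )
        row = summarize_modes(labeled, "x").set_index("pollutant").loc["pm25"]
        assert row["q1"] <= row["median"] <= row["q3"]


class TestPercentReduction:
    def test_printed_worked_examples(self):
        """Cable-car means vs in-bus means give the reported reductions."""
        assert percent_reduction(28.2, 5.2) == pytest.approx(81.6, abs=0.05)
        assert percent_reduction(87.0, 32.6) == pytest.approx(62.5, abs=0.05)

    def test_identity_and_errors(self):
        assert percent_reduction(10.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)


class TestFullPipelineRoundTrip:
    def test_zero_noise_recovers_true_means(self):
        """Sync + corrections + segmentation reproduce segment truth to 1e-6."""
        scn = SessionScenario(
            segments=[
                SegmentSpec("pedestrian", 1200, 40.0, 10.0, 1.0, 2500.0),
                SegmentSpec("feeder", 1500, 87.0, 28.2, 5.0, 300.0),
                SegmentSpec("cable car", 900, 32.6, 5.2, 1.0, 300.0),
            ],
            noise_cv=0.0,
            k_true=0.005,
            photometric_factor_true=0.63,
            lag_s={"ebc": 30.0, "co": -20.0},
            seed=11,
        )
        bundle = generate_session(scn)
        _, labeled, sync = process_session(
            bundle.streams, bundle.registry, pm_factor=0.63, k=0.005
        )
        assert sync.lags_samples["ebc"] == 3
        assert sync.lags_samples["co"] == -2
        summaries = summarize_modes(labeled, "x").set_index(["mode", "pollutant"])
        for seg in scn.segments:
            for pol, truth in (("pm25", seg.pm25), ("ebc", seg.ebc), ("co", seg.co)):
                got = summaries.loc[(seg.mode, pol), "mean"]
                assert got == pytest.approx(truth, rel=1e-6)
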