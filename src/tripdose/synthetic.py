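"""Synthetic instrument sessions and travel surveys with known ground truth.

The generator emulates the data a portable-monitor campaign produces — a
photometric PM2.5 channel with a device-specific scale factor, an
aethalometer eBC channel attenuated by filter loading with a known factor k,
a CO channel quantized to its 1 ppm resolution, accelerometer counts, and
per-instrument clock offsets — plus the two survey tables a travel-behavior
study collects: a small stage-level survey (minutes per stage of each
multimodal trip) and a large total-time survey (total minutes per trip).

Every recoverable parameter (segment means, k, the photometric factor, the
clock lags, stage-time means, trip-type shares) is returned in a ground-truth
record so the processing pipeline can be validated by round trip.

Noise is multiplicative lognormal per channel (concentrations are positive
and right-skewed), with unit mean so that segment means are preserved. ATN
grows in proportion to the cumulative eBC mass drawn through the filter —
the filter only accumulates — which makes k identifiable from a pair of
devices sampling the same air at different flow rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sensors import MODES, FieldRegistry, RegistryEvent, STREAM_FILES

CHANNELS = ("pm25", "ebc", "co", "counts")

DEFAULT_START = pd.Timestamp("2018-10-01T07:00:00")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentSpec:
    """True conditions in one microenvironment segment."""

    mode: str
    duration_s: float
    pm25: float  # µg/m³
    ebc: float  # µg/m³
    co: float  # ppm
    counts_per_min: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if min(self.pm25, self.ebc, self.co, self.counts_per_min) < 0:
            raise ValueError("segment levels must be nonnegative")


@dataclass
class SessionScenario:
    """Everything needed to generate one monitoring session.

    ``noise_cv`` is the fractional coefficient of variation, either one value
    for all channels or per channel. ``lag_s`` holds per-instrument clock
    offsets (seconds; positive = the instrument's record is delayed).
    ``atn_per_ug_min`` converts cumulative collected eBC (µg·min/m³) into
    attenuation units and stands in for the flow-rate dependence of filter
    loading.
    """

    segments: Sequence[SegmentSpec]
    noise_cv: float | Mapping[str, float] = 0.0
    k_true: float = 0.005
    photometric_factor_true: float = 0.63
    zero_offset_true: float = 0.0
    lag_s: Mapping[str, float] = field(default_factory=dict)
    atn_per_ug_min: float = 0.02
    sample_period_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("scenario needs at least one segment")
        for cv in self.cv_by_channel().values():
            if not 0 <= cv < 1:
                raise ValueError("noise_cv must lie in [0, 1)")
        if self.k_true < 0 or self.photometric_factor_true <= 0:
            raise ValueError("k_true must be >= 0 and the photometric factor positive")
        if self.sample_period_s <= 0:
            raise ValueError("sample_period_s must be positive")

    def cv_by_channel(self) -> dict[str, float]:
        if isinstance(self.noise_cv, Mapping):
            return {ch: float(self.noise_cv.get(ch, 0.0)) for ch in CHANNELS}
        return {ch: float(self.noise_cv) for ch in CHANNELS}

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)


@dataclass(frozen=True)
class TripTypeSpec:
    """One multimodal trip type: ordered mode sequence and commuter share."""

    name: str
    modes: tuple[str, ...]
    share: float

    def __post_init__(self) -> None:
        if not 2 <= len(self.modes) <= 3:
            raise ValueError("trip types must have 2 or 3 stages")
        if self.share < 0:
            raise ValueError("share must be nonnegative")


@dataclass(frozen=True)
class StageDist:
    """Named stage-time distribution (minutes).

    Families: ``lognormal`` (parametrized by mean and cv) and ``point``.
    """

    family: str
    mean: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "point"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.mean <= 0 or self.cv < 0:
            raise ValueError("stage times must be strictly positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point" or self.cv == 0:
            return np.full(size, self.mean)
        sigma = np.sqrt(np.log1p(self.cv**2))
        mu = np.log(self.mean) - sigma**2 / 2
        return rng.lognormal(mu, sigma, size)


@dataclass
class SurveyScenario:
    """Generative model for the stage-level and total-time survey tables."""

    trip_types: Sequence[TripTypeSpec]
    stage_time_dists: Mapping[str, Sequence[StageDist]]
    total_time_targets: Mapping[str, float]
    n_respondents_stage: int = 400
    n_respondents_total: int = 2000
    #: the stage-level survey is purposive: every trip type of interest gets
    #: at least this many respondents regardless of its population share
    min_stage_respondents: int = 30
    total_time_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        shares = sum(t.share for t in self.trip_types)
        if abs(shares - 1.0) > 1e-9:
            raise ValueError(f"trip-type shares must sum to 1 (got {shares})")
        if self.n_respondents_stage <= 0 or self.n_respondents_total <= 0:
            raise ValueError("respondent counts must be positive")
        for t in self.trip_types:
            dists = self.stage_time_dists.get(t.name)
            if dists is None or len(dists) != len(t.modes):
                raise ValueError(f"trip type {t.name!r} needs one stage distribution per mode")
            if t.name not in self.total_time_targets:
                raise ValueError(f"trip type {t.name!r} needs a total-time target")


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------


@dataclass
class SessionBundle:
    """Raw instrument streams + registry + ground truth for one session."""

    streams: dict[str, pd.DataFrame]
    registry: FieldRegistry
    truth: dict


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-(sigma**2) / 2, sigma, n))


def _shift(arr: np.ndarray, lag_samples: int) -> np.ndarray:
    """Delay a recorded stream by an integer number of samples (edge-clamped)."""
    idx = np.clip(np.arange(len(arr)) - lag_samples, 0, len(arr) - 1)
    return arr[idx]


def _true_channels(scenario: SessionScenario) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    p = scenario.sample_period_s
    lengths = [int(round(s.duration_s / p)) for s in scenario.segments]
    if any(l < 1 for l in lengths):
        raise ValueError("every segment must span at least one sample")
    n = sum(lengths)
    t = np.arange(n) * p
    true = {
        "pm25": np.repeat([s.pm25 for s in scenario.segments], lengths),
        "ebc": np.repeat([s.ebc for s in scenario.segments], lengths),
        "co": np.repeat([s.co for s in scenario.segments], lengths),
        "counts": np.repeat([s.counts_per_min for s in scenario.segments], lengths),
    }
    boundaries = np.concatenate([[0], np.cumsum(lengths)]) * p
    return t, true, boundaries


def _atn_trajectory(bc: np.ndarray, period_s: float, atn_per_ug_min: float) -> np.ndarray:
    """ATN from cumulative collected eBC mass; starts at 0, nondecreasing."""
    dt_min = period_s / 60.0
    deposited = np.concatenate([[0.0], np.cumsum(np.clip(bc, 0, None) * dt_min)[:-1]])
    return atn_per_ug_min * deposited


def generate_session(scenario: SessionScenario, with_gps: bool = False) -> SessionBundle:
    """Generate raw instrument streams, field registry, and ground truth.

    The raw photometer channel is true PM2.5 divided by the photometric
    factor (plus the HEPA zero offset); the raw eBC channel is the noisy true
    series attenuated by ``1/(1 + k*ATN)`` with ATN logged alongside; CO is
    quantized to 1 ppm; every stream is delayed by its instrument's clock
    offset.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    streams_rng = {ch: np.random.default_rng(s) for ch, s in
                   zip(CHANNELS, np.random.SeedSequence(scenario.seed).spawn(len(CHANNELS)))}
    t, true, boundaries = _true_channels(scenario)
    n = len(t)
    p = scenario.sample_period_s
    cv = scenario.cv_by_channel()

    noisy = {ch: true[ch] * _unit_mean_lognormal(streams_rng[ch], cv[ch], n) for ch in CHANNELS}

    lagk = {inst: int(round(scenario.lag_s.get(inst, 0.0) / p)) for inst in STREAM_FILES}

    pm_raw = noisy["pm25"] / scenario.photometric_factor_true + scenario.zero_offset_true
    atn = _atn_trajectory(noisy["ebc"], p, scenario.atn_per_ug_min)
    bc_nc = noisy["ebc"] / (1.0 + scenario.k_true * atn)
    co_ppm = np.clip(np.round(noisy["co"]), 0, None)
    counts = noisy["counts"] * (p / 60.0)

    streams = {
        "pm": pd.DataFrame({"t_s": t, "pm25_raw": _shift(pm_raw, lagk["pm"])}),
        "ebc": pd.DataFrame(
            {"t_s": t, "bc_nc": _shift(bc_nc, lagk["ebc"]), "atn": _shift(atn, lagk["ebc"])}
        ),
        "co": pd.DataFrame({"t_s": t, "co_ppm": _shift(co_ppm, lagk["co"])}),
        "acc": pd.DataFrame({"t_s": t, "counts": _shift(counts, lagk["acc"])}),
    }
    if with_gps:
        # straight-line synthetic track, 5 m/s pedestrian-scale drift
        lat = 4.57 + 4.5e-7 * t + 1e-6 * rng.standard_normal(n)
        lon = -74.16 + 4.5e-7 * t + 1e-6 * rng.standard_normal(n)
        ele = 2600 + 0.02 * t
        streams["gps"] = pd.DataFrame({"t_s": t, "lat": lat, "lon": lon, "ele": ele})

    events = [
        RegistryEvent(float(b), "board", seg.mode)
        for b, seg in zip(boundaries[:-1], scenario.segments)
    ]
    events.append(RegistryEvent(float(boundaries[-1]), "end", None))
    registry = FieldRegistry(events)

    truth = {
        "seed": scenario.seed,
        "k_true": scenario.k_true,
        "photometric_factor_true": scenario.photometric_factor_true,
        "zero_offset_true": scenario.zero_offset_true,
        "lag_s": {inst: lagk[inst] * p for inst in lagk},
        "sample_period_s": p,
        "segments": [asdict(s) for s in scenario.segments],
    }
    return SessionBundle(streams=streams, registry=registry, truth=truth)


def generate_dual_ebc(
    scenario: SessionScenario,
    atn_rates: tuple[float, float] = (0.02, 0.05),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two co-located aethalometers at different flow rates over the same air.

    Different flow rates load the filters at different speeds, so the two
    devices trace different ATN trajectories over one true eBC series; this
    contrast identifies the loading factor k. Device noise is independent.
    """
    t, true, _ = _true_channels(scenario)
    n = len(t)
    p = scenario.sample_period_s
    cv = scenario.cv_by_channel()["ebc"]
    seqs = np.random.SeedSequence(scenario.seed).spawn(2)
    frames = []
    for rate, seq in zip(atn_rates, seqs):
        rng = np.random.default_rng(seq)
        noisy = true["ebc"] * _unit_mean_lognormal(rng, cv, n)
        atn = _atn_trajectory(noisy, p, rate)
        bc_nc = noisy / (1.0 + scenario.k_true * atn)
        frames.append(pd.DataFrame({"t_s": t, "bc_nc": bc_nc, "atn": atn}))
    truth = {"k_true": scenario.k_true, "atn_rates": list(atn_rates), "seed": scenario.seed}
    return frames[0], frames[1], truth


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------


def generate_surveys(scenario: SurveyScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the stage-level and total-time survey tables.

    Stage rows: (trip_id, trip_type, stage_order, mode, minutes). The small
    stage survey is allocated proportionally to shares but with a per-type
    respondent floor (purposive oversampling of rare trips), so every trip
    type of interest supports a density fit. Total rows: (trip_type,
    minutes), lognormal around each type's target mean so that empirical
    means approach the targets. Reproducible from the scenario seed.
    """
    seq_stage, seq_total = np.random.SeedSequence(scenario.seed).spawn(2)
    rng_s = np.random.default_rng(seq_stage)
    rng_t = np.random.default_rng(seq_total)
    names = [t.name for t in scenario.trip_types]
    shares = np.array([t.share for t in scenario.trip_types])

    rows = []
    trip_id = 0
    for tt in scenario.trip_types:
        n_k = max(int(round(tt.share * scenario.n_respondents_stage)),
                  scenario.min_stage_respondents)
        dists = scenario.stage_time_dists[tt.name]
        drawn = [dist.sample(rng_s, n_k) for dist in dists]
        for i in range(n_k):
            for order, (mode, col) in enumerate(zip(tt.modes, drawn), start=1):
                rows.append((trip_id, tt.name, order, mode, float(col[i])))
            trip_id += 1
    stage_df = pd.DataFrame(rows, columns=["trip_id", "trip_type", "stage_order", "mode", "minutes"])

    picks = rng_t.choice(len(names), size=scenario.n_respondents_total, p=shares)
    totals = []
    for k in picks:
        name = names[k]
        dist = StageDist("lognormal" if scenario.total_time_cv > 0 else "point",
                         scenario.total_time_targets[name], scenario.total_time_cv)
        totals.append((name, float(dist.sample(rng_t, 1)[0])))
    total_df = pd.DataFrame(totals, columns=["trip_type", "minutes"])
    return stage_df, total_df


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_gpx(path: str | Path, t_s, lat, lon, ele, start: pd.Timestamp = DEFAULT_START) -> None:
    """Minimal GPX 1.1 track for a synthetic GPS trace."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<gpx version="1.1" creator="tripdose" xmlns="http://www.topografix.com/GPX/1/1">',
        "<trk><trkseg>",
    ]
    for ti, la, lo, el in zip(t_s, lat, lon, ele):
        stamp = (start + pd.to_timedelta(float(ti), unit="s")).isoformat()
        lines.append(
            f'<trkpt lat="{la:.7f}" lon="{lo:.7f}"><ele>{el:.1f}</ele>'
            f"<time>{stamp}</time></trkpt>"
        )
    lines += ["</trkseg></trk>", "</gpx>"]
    Path(path).write_text("\n".join(lines))


def write_session(bundle: SessionBundle, out_dir: str | Path, start: pd.Timestamp = DEFAULT_START) -> Path:
    """Write one session as tidy CSVs (ISO-8601 timestamps) + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.streams.items():
        if name == "gps":
            write_gpx(out / "track.gpx", df["t_s"], df["lat"], df["lon"], df["ele"], start)
            fname = "gps.csv"
        else:
            fname = STREAM_FILES[name]
        w = df.copy()
        w.insert(0, "timestamp", start + pd.to_timedelta(w.pop("t_s"), unit="s"))
        w.to_csv(out / fname, index=False)
    bundle.registry.to_frame(start=start).to_csv(out / "registry.csv", index=False)
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2))
    return out
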