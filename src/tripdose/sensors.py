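"""Raw portable-monitor streams -> synchronized, corrected exposure series.

The processing chain mirrors a typical personal-monitoring campaign with a
photometric PM2.5 sensor, a filter-based micro-aethalometer (equivalent black
carbon, eBC), an electrochemical CO cell, and a hip-worn accelerometer, all
resampled to a common 10 s time base:

1. bin-average every raw stream onto the common grid;
2. estimate per-instrument clock offsets by lag correlation against a
   reference channel and shift the streams onto one clock;
3. apply the photometric correction factor (and optional HEPA zero offset)
   to PM2.5 and the filter-loading correction ``BC_c = BC_nc * (1 + k*ATN)``
   to eBC;
4. cut the series into transport-microenvironment segments using the field
   registry of boarding/alighting events and summarize exposure per mode.

Negative instantaneous eBC readings (ordinary micro-aethalometer noise) are
retained by default so that segment means stay unbiased; a floor can be
configured where a downstream consumer requires nonnegative values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

#: Closed set of transport microenvironments.
MODES = ("BRT", "feeder", "bus", "informal", "pedestrian", "cable car", "station")

#: Pollutant channels carried by an ExposureSeries.
POLLUTANTS = ("pm25", "ebc", "co")

#: Default channel used for lag correlation, per stream name.
SYNC_CHANNELS = {"pm": "pm25_raw", "ebc": "bc_nc", "co": "co_ppm", "acc": "counts"}

DEFAULT_PERIOD_S = 10.0


class DegenerateStreamError(ValueError):
    """Raised when a stream carries no usable signal for the requested fit."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistryEvent:
    """One field-registry entry: at ``t_s`` the commuter enters ``mode``."""

    t_s: float
    label: str
    mode: str | None  # None marks the end-of-session sentinel


@dataclass
class FieldRegistry:
    """Ordered mode-change events partitioning a session into segments."""

    events: list[RegistryEvent]

    def __post_init__(self) -> None:
        times = [e.t_s for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("registry timestamps must be strictly increasing")
        for e in self.events:
            if e.mode is not None and e.mode not in MODES:
                raise ValueError(f"unknown mode {e.mode!r}; expected one of {MODES}")

    @property
    def mode_events(self) -> list[RegistryEvent]:
        return [e for e in self.events if e.mode is not None]

    def to_frame(self, start: pd.Timestamp | None = None) -> pd.DataFrame:
        rows = [(e.t_s, e.label, "" if e.mode is None else e.mode) for e in self.events]
        df = pd.DataFrame(rows, columns=["t_s", "event", "mode"])
        if start is not None:
            df.insert(0, "timestamp", start + pd.to_timedelta(df.pop("t_s"), unit="s"))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, start: pd.Timestamp | None = None) -> "FieldRegistry":
        if "t_s" in df.columns:
            t = df["t_s"].to_numpy(float)
        else:
            ts = pd.to_datetime(df["timestamp"])
            if start is None:
                start = ts.iloc[0]
            t = (ts - start).dt.total_seconds().to_numpy()
        events = []
        for ti, label, mode in zip(t, df["event"], df["mode"]):
            mode = None if (pd.isna(mode) or mode == "") else str(mode)
            events.append(RegistryEvent(float(ti), str(label), mode))
        return cls(events)


@dataclass
class ExposureSeries:
    """Synchronized multi-channel series on a uniform grid (10 s default).

    Columns: ``t_s`` (seconds from session start), corrected ``pm25`` and
    ``ebc`` (µg/m³), ``co`` (ppm), ``atn`` (filter attenuation), ``counts``
    (accelerometer counts per epoch), optionally ``lat``/``lon``/``ele``.
    """

    df: pd.DataFrame
    period_s: float = DEFAULT_PERIOD_S
    floor: float | None = None

    def __post_init__(self) -> None:
        t = self.df["t_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError("series needs at least two samples")
        steps = np.diff(t)
        if not np.allclose(steps, self.period_s, rtol=0, atol=1e-6):
            raise ValueError("timestamps must be strictly increasing and uniform")
        if "atn" in self.df and np.any(np.diff(self.df["atn"].to_numpy(float)) < -1e-9):
            raise ValueError("ATN must be nondecreasing within a session")
        if self.floor is not None:
            for ch in POLLUTANTS:
                if ch in self.df:
                    self.df[ch] = self.df[ch].clip(lower=self.floor)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t_s(self) -> np.ndarray:
        return self.df["t_s"].to_numpy(float)


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------


def correct_photometer(raw, factor: float, zero_offset: float = 0.0) -> np.ndarray:
    """Apply a device-specific photometric scale factor to raw PM2.5.

    The HEPA zero offset is subtracted first, then the multiplicative
    gravimetric calibration factor is applied.
    """
    if factor <= 0:
        raise ValueError("photometric factor must be positive")
    return (np.asarray(raw, dtype=float) - zero_offset) * factor


def virkkula_correct(bc_nc, atn, k: float) -> np.ndarray:
    """Filter-loading correction ``BC_c = BC_nc * (1 + k*ATN)``.

    As absorbing particles accumulate on the aethalometer filter spot the
    optical sensitivity drops; the correction inflates the raw reading in
    proportion to the logged attenuation ATN.
    """
    bc_nc = np.asarray(bc_nc, dtype=float)
    atn = np.asarray(atn, dtype=float)
    if bc_nc.shape != atn.shape:
        raise ValueError("bc_nc and atn must have the same length")
    if k < 0:
        raise ValueError("loading factor k must be nonnegative")
    if np.any(atn < -1e-12):
        raise ValueError("ATN must be nonnegative")
    return bc_nc * (1.0 + k * atn)


@dataclass(frozen=True)
class KFit:
    """Result of the dual-device loading-factor fit."""

    k: float
    objective: float
    n_overlap: int
    degenerate: bool = False


def fit_loading_k(
    stream_a: pd.DataFrame,
    stream_b: pd.DataFrame,
    k_max: float = 0.1,
    min_overlap: int = 100,
) -> KFit:
    """Estimate the loading factor k from two co-located aethalometers.

    The devices run at different flow rates, so their filters load at
    different speeds and trace different ATN trajectories over the same
    aerosol. Both lose sensitivity; k is the value that minimizes the sum of
    squared differences between the two loading-corrected series over the
    overlap, constrained to k >= 0 (bounded 1-D minimization).

    Each stream must carry ``bc_nc`` and ``atn`` columns on a common grid.
    """
    n = min(len(stream_a), len(stream_b))
    if n < min_overlap:
        raise ValueError(f"need >= {min_overlap} overlapping samples, got {n}")
    a = stream_a.iloc[:n]
    b = stream_b.iloc[:n]
    bc_a, atn_a = a["bc_nc"].to_numpy(float), a["atn"].to_numpy(float)
    bc_b, atn_b = b["bc_nc"].to_numpy(float), b["atn"].to_numpy(float)
    scale = float(np.mean(bc_a**2) + np.mean(bc_b**2))
    if scale <= 0:
        raise DegenerateStreamError("constant-zero streams; k is unidentifiable")

    def objective(k: float) -> float:
        resid = bc_a * (1.0 + k * atn_a) - bc_b * (1.0 + k * atn_b)
        return float(np.mean(resid**2))

    # the objective is quadratic in k; a flat quadratic term means the two
    # ATN trajectories carry no contrast and k is unidentifiable
    d1 = bc_a * atn_a - bc_b * atn_b
    curvature = float(np.mean(d1**2))
    if curvature <= 1e-12 * scale * max(np.max(atn_a), np.max(atn_b), 1.0) ** 2:
        warnings.warn("objective flat in k (identical ATN trajectories); returning 0")
        return KFit(k=0.0, objective=objective(0.0), n_overlap=n, degenerate=True)

    res = minimize_scalar(
        objective, bounds=(0.0, k_max), method="bounded",
        options={"xatol": 1e-12},
    )
    return KFit(k=float(res.x), objective=float(res.fun), n_overlap=n)


# ---------------------------------------------------------------------------
# resampling & synchronization
# ---------------------------------------------------------------------------


def resample_to_grid(
    df: pd.DataFrame, period_s: float = DEFAULT_PERIOD_S, min_valid_frac: float = 0.5
) -> pd.DataFrame:
    """Bin-average a raw stream onto a uniform grid.

    Bins start at t=0 of the stream's own clock. A bin is reported missing
    (NaN) when fewer than ``min_valid_frac`` of its expected samples are
    present.
    """
    t = df["t_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("stream too short to resample")
    native = float(np.median(np.diff(t)))
    expected = max(1, int(round(period_s / native)))
    idx = np.floor(t / period_s).astype(int)
    out = df.drop(columns=["t_s"]).groupby(idx).mean()
    counts = pd.Series(1, index=idx).groupby(level=0).size()
    out[counts < min_valid_frac * expected] = np.nan
    full = np.arange(idx.min(), idx.max() + 1)
    out = out.reindex(full)
    out.insert(0, "t_s", full * period_s)
    return out.reset_index(drop=True)


def _lag_correlation(ref: np.ndarray, sig: np.ndarray, max_lag: int) -> tuple[int, float]:
    """Return (lag, peak |normalized correlation|) maximizing |corr(ref[i], sig[i+lag])|.

    The magnitude is used because physically co-driven channels can be
    anti-correlated (e.g. accelerometer counts peak while walking, when
    concentrations are lowest); the lag information is the same.
    """
    best_lag, best_corr = 0, -np.inf
    for s in range(-max_lag, max_lag + 1):
        if s >= 0:
            r, g = ref[: len(ref) - s or None], sig[s:]
        else:
            r, g = ref[-s:], sig[: len(sig) + s]
        m = min(len(r), len(g))
        r, g = r[:m], g[:m]
        ok = np.isfinite(r) & np.isfinite(g)
        if ok.sum() < 3:
            continue
        r, g = r[ok], g[ok]
        sr, sg = r.std(), g.std()
        if sr == 0 or sg == 0:
            continue
        c = abs(float(np.mean((r - r.mean()) * (g - g.mean())) / (sr * sg)))
        if c > best_corr:
            best_lag, best_corr = s, c
    if not np.isfinite(best_corr):
        best_corr = 0.0
    return best_lag, best_corr


@dataclass
class SyncResult:
    """Lags (samples and seconds) per stream plus the merged aligned frame."""

    lags_samples: dict[str, int]
    lags_s: dict[str, float]
    peak_corr: dict[str, float]
    unsynchronizable: list[str]
    aligned: pd.DataFrame
    period_s: float


def synchronize(
    streams: Mapping[str, pd.DataFrame],
    reference: str = "pm",
    channels: Mapping[str, str] | None = None,
    max_lag_s: float = 120.0,
    period_s: float = DEFAULT_PERIOD_S,
    min_corr: float = 0.2,
) -> SyncResult:
    """Lag-correlation alignment of instrument streams onto one clock.

    Every stream is first bin-averaged onto the common grid; the lag of each
    stream against the reference channel is the argmax of the normalized
    cross-correlation over +/- ``max_lag_s``. Streams whose correlation peak
    falls below ``min_corr`` are flagged unsynchronizable and kept at zero
    lag. Shifted streams are merged and trimmed to the jointly valid span.
    """
    if reference not in streams:
        raise ValueError(f"reference stream {reference!r} missing")
    channels = dict(SYNC_CHANNELS) | dict(channels or {})
    max_lag = int(round(max_lag_s / period_s))

    grids = {name: resample_to_grid(df, period_s) for name, df in streams.items()}
    nmin = min(len(g) for g in grids.values())
    if nmin < 10 * max(max_lag, 1):
        raise ValueError("streams too short for the requested maximum lag")

    ref = grids[reference][channels[reference]].to_numpy(float)
    lags: dict[str, int] = {}
    peaks: dict[str, float] = {}
    bad: list[str] = []
    for name, g in grids.items():
        if name == reference:
            lags[name], peaks[name] = 0, 1.0
            continue
        sig = g[channels[name]].to_numpy(float)
        lag, peak = _lag_correlation(ref, sig, max_lag)
        peaks[name] = peak
        if peak < min_corr:
            warnings.warn(f"stream {name!r} unsynchronizable (peak corr {peak:.2f}); keeping lag 0")
            bad.append(name)
            lags[name] = 0
        else:
            lags[name] = lag

    # aligned sample i of stream s is its raw sample i + lag_s
    starts, stops = [], []
    for name, g in grids.items():
        starts.append(max(0, -lags[name]))
        stops.append(len(g) - 1 - lags[name])
    lo, hi = max(starts), min(stops)
    if hi <= lo:
        raise ValueError("no common span after shifting")
    pieces = {"t_s": np.arange(lo, hi + 1) * period_s}
    for name, g in grids.items():
        block = g.iloc[lo + lags[name] : hi + 1 + lags[name]].reset_index(drop=True)
        for col in block.columns:
            if col != "t_s":
                pieces[col] = block[col].to_numpy()
    aligned = pd.DataFrame(pieces)
    return SyncResult(
        lags_samples=lags,
        lags_s={k: v * period_s for k, v in lags.items()},
        peak_corr=peaks,
        unsynchronizable=bad,
        aligned=aligned,
        period_s=period_s,
    )


# ---------------------------------------------------------------------------
# series assembly, segmentation, summaries
# ---------------------------------------------------------------------------


def build_exposure_series(
    aligned: pd.DataFrame,
    pm_factor: float,
    k: float,
    zero_offset: float = 0.0,
    period_s: float = DEFAULT_PERIOD_S,
    floor: float | None = None,
) -> ExposureSeries:
    """Apply all corrections to a synchronized frame of raw channels."""
    df = pd.DataFrame({"t_s": aligned["t_s"].to_numpy(float)})
    df["pm25"] = correct_photometer(aligned["pm25_raw"], pm_factor, zero_offset)
    df["ebc"] = virkkula_correct(aligned["bc_nc"], aligned["atn"], k)
    df["atn"] = aligned["atn"].to_numpy(float)
    df["co"] = aligned["co_ppm"].to_numpy(float)
    df["counts"] = aligned["counts"].to_numpy(float)
    for opt in ("lat", "lon", "ele"):
        if opt in aligned:
            df[opt] = aligned[opt].to_numpy(float)
    return ExposureSeries(df, period_s=period_s, floor=floor)


def segment_by_registry(series: ExposureSeries, registry: FieldRegistry) -> pd.DataFrame:
    """Label every sample with its transport mode.

    Segments are half-open ``[start, end)``: a sample exactly on an event
    timestamp belongs to the later segment. Events dated before the series
    start simply define the mode active at the start; a *mode* event after
    the series end is an error, while an end-of-session sentinel past the end
    (common after synchronization trims the series) just caps it. Returns the
    series frame with a ``mode`` column.
    """
    t = series.t_s
    events = registry.mode_events
    if not events:
        raise ValueError("registry has no mode events")
    end_t = t[-1] + series.period_s
    sentinel = [e for e in registry.events if e.mode is None]
    if sentinel:
        end_t = min(end_t, sentinel[-1].t_s)
    for e in events:
        if e.t_s > t[-1] + series.period_s + 1e-9:
            raise ValueError(f"registry event at t={e.t_s}s lies outside the series span")
    ev_t = np.array([e.t_s for e in events])
    if t[0] < ev_t[0] - 1e-9:
        raise ValueError("series starts before the first registry event")
    idx = np.searchsorted(ev_t, t, side="right") - 1
    labeled = series.df.copy()
    labeled["mode"] = [events[i].mode for i in idx]
    labeled = labeled[labeled["t_s"] < end_t - 1e-9].reset_index(drop=True)
    return labeled


def summarize_modes(
    labeled: pd.DataFrame,
    campaign: str,
    pollutants: Sequence[str] = POLLUTANTS,
) -> pd.DataFrame:
    """Per mode x pollutant: n, mean, median, Q1, Q3 over pooled samples.

    Quartiles use linear interpolation (the type-7 convention), matching the
    usual box-summary presentation of microenvironment concentrations.
    """
    rows = []
    for mode, grp in labeled.groupby("mode", sort=False):
        for ch in pollutants:
            x = grp[ch].dropna().to_numpy(float)
            if x.size == 0:
                raise ValueError(f"mode {mode!r} has no samples for {ch}")
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            rows.append(
                {
                    "mode": mode,
                    "campaign": campaign,
                    "pollutant": ch,
                    "n": int(x.size),
                    "mean": float(np.mean(x)),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                }
            )
    return pd.DataFrame(rows)


def percent_reduction(reference_mean: float, comparison_mean: float) -> float:
    """``100 * (1 - comparison/reference)``: how much lower the comparison is."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (1.0 - comparison_mean / reference_mean)


# ---------------------------------------------------------------------------
# session-level I/O and orchestration
# ---------------------------------------------------------------------------

STREAM_FILES = {"pm": "pm.csv", "ebc": "ebc.csv", "co": "co.csv", "acc": "acc.csv"}


def read_session(session_dir: str | Path) -> tuple[dict[str, pd.DataFrame], FieldRegistry]:
    """Read the instrument CSVs and field registry written for one session."""
    session_dir = Path(session_dir)
    streams: dict[str, pd.DataFrame] = {}
    start: pd.Timestamp | None = None
    for name, fname in STREAM_FILES.items():
        path = session_dir / fname
        if not path.exists():
            continue
        df = pd.read_csv(path)
        if "timestamp" in df.columns:
            ts = pd.to_datetime(df.pop("timestamp"))
            if start is None:
                start = ts.iloc[0]
            df.insert(0, "t_s", (ts - start).dt.total_seconds())
        streams[name] = df
    reg_df = pd.read_csv(session_dir / "registry.csv")
    registry = FieldRegistry.from_frame(reg_df, start=start)
    return streams, registry


def process_session(
    streams: Mapping[str, pd.DataFrame],
    registry: FieldRegistry,
    pm_factor: float,
    k: float,
    zero_offset: float = 0.0,
    max_lag_s: float = 120.0,
    period_s: float = DEFAULT_PERIOD_S,
    floor: float | None = None,
) -> tuple[ExposureSeries, pd.DataFrame, SyncResult]:
    """Full single-session chain: sync, correct, segment.

    Returns the corrected series, the mode-labeled frame, and the sync report.
    """
    sync = synchronize(streams, max_lag_s=max_lag_s, period_s=period_s)
    series = build_exposure_series(
        sync.aligned, pm_factor=pm_factor, k=k, zero_offset=zero_offset,
        period_s=period_s, floor=floor,
    )
    labeled = segment_by_registry(series, registry)
    return series, labeled, sync
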