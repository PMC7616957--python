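"""Monte Carlo engine for inhaled dose per multimodal commute trip.

One replication is a synthetic commuting day: N commuters are each assigned
a trip type according to the commuter shares, draw a travel time for every
stage from that trip's harmonized stage-time models, and accumulate

    D_kj = sum over stages i of  D_ij * dt_i

for each pollutant j (dose rate times minutes in the mode). Replications
repeat until the across-replication 95 % confidence interval (Student t on
replication means, which are i.i.d. by construction) is narrower than the
requested relative half-width for every trip-type x pollutant cell, subject
to minimum and maximum replication counts. Scenario comparisons (e.g. a
cable-car first stage replacing a feeder-bus first stage) are Welch t tests
on the replication means of the paired trip types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sensors import POLLUTANTS
from .stats import two_sample_t, star_annotate
from .travel import TripCatalog

DOSE_PER_TRIP_UNITS = {"pm25": "ug/trip", "ebc": "ug/trip", "co": "mg/trip"}


@dataclass(frozen=True)
class SimulationConfig:
    """Replication schedule and stopping rule."""

    n_commuters: int = 10_000
    ci_level: float = 0.95
    precision: float = 0.05  # target relative CI half-width
    min_replications: int = 30
    max_replications: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        if not 2 <= self.min_replications <= self.max_replications:
            raise ValueError("need 2 <= min_replications <= max_replications")
        if self.n_commuters < 1:
            raise ValueError("n_commuters must be positive")


@dataclass(frozen=True)
class TripDoseEstimate:
    """Across-replication summary for one trip type and pollutant."""

    trip_type: str
    pollutant: str
    mean: float
    ci_low: float
    ci_high: float
    median: float
    q1: float
    q3: float
    n_replications: int
    units: str
    converged: bool = True


def trip_dose(
    dose_rates: Mapping[str, Mapping[str, float]],
    mode_sequence: Sequence[str],
    stage_times_min: Sequence[float],
) -> dict[str, float]:
    """Inhaled dose of one trip: sum over stages of dose rate x minutes."""
    if len(mode_sequence) != len(stage_times_min):
        raise ValueError("one stage time per mode required")
    out = {p: 0.0 for p in POLLUTANTS}
    for mode, minutes in zip(mode_sequence, stage_times_min):
        if minutes < 0:
            raise ValueError("stage times must be nonnegative")
        if mode not in dose_rates:
            raise ValueError(f"no dose profile for mode {mode!r}")
        for p in POLLUTANTS:
            out[p] += dose_rates[mode][p] * minutes
    return out


def run_replication(
    catalog: TripCatalog,
    dose_rates: Mapping[str, Mapping[str, float]],
    n_commuters: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One synthetic day: assign commuters, sample times, average doses.

    Returns rows (trip_type, pollutant, mean_dose, n_commuters). Trip types
    that received zero commuters in this day are absent from the frame (never
    reported as zero dose).
    """
    shares = np.array([t.share for t in catalog.trip_types])
    counts = rng.multinomial(n_commuters, shares)
    rows = []
    for t, n_k in zip(catalog.trip_types, counts):
        if n_k == 0:
            continue
        times = t.sample_stage_times(rng, int(n_k))  # (n_k, n_stages) minutes
        rates = np.array([[dose_rates[m][p] for p in POLLUTANTS] for m in t.modes])
        doses = times @ rates  # (n_k, n_pollutants)
        for j, p in enumerate(POLLUTANTS):
            rows.append((t.name, p, float(doses[:, j].mean()), int(n_k)))
    return pd.DataFrame(rows, columns=["trip_type", "pollutant", "mean_dose", "n_commuters"])


@dataclass
class SimulationResult:
    """Estimates plus the per-replication means they were computed from."""

    estimates: pd.DataFrame
    replication_means: dict[tuple[str, str], np.ndarray]
    n_replications: int
    converged: bool
    config: SimulationConfig
    audit: dict = field(default_factory=dict)


def _cell_ci(values: np.ndarray, ci_level: float) -> tuple[float, float, float]:
    m = float(values.mean())
    r = len(values)
    if r < 2:
        return m, m, m
    sem = values.std(ddof=1) / np.sqrt(r)
    if sem == 0:
        return m, m, m
    tcrit = sps.t.ppf(0.5 + ci_level / 2, r - 1)
    return m, m - tcrit * sem, m + tcrit * sem


def run_simulation(
    catalog: TripCatalog,
    dose_rates: Mapping[str, Mapping[str, float]],
    config: SimulationConfig,
) -> SimulationResult:
    """Replicate synthetic days until every cell's CI meets the precision target."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    acc: dict[tuple[str, str], list[float]] = {}
    n_reps = 0
    converged = False
    while n_reps < config.max_replications:
        rep = run_replication(catalog, dose_rates, config.n_commuters, rng)
        n_reps += 1
        for _, row in rep.iterrows():
            acc.setdefault((row["trip_type"], row["pollutant"]), []).append(row["mean_dose"])
        if n_reps < config.min_replications:
            continue
        ok = True
        for key, vals in acc.items():
            v = np.asarray(vals)
            if len(v) < config.min_replications:
                ok = False
                break
            m, lo, hi = _cell_ci(v, config.ci_level)
            half = (hi - lo) / 2
            rel = half / abs(m) if m != 0 else (0.0 if half == 0 else np.inf)
            if rel > config.precision:
                ok = False
                break
        if ok:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"simulation did not reach the precision target within "
            f"{config.max_replications} replications"
        )

    rows = []
    rep_means: dict[tuple[str, str], np.ndarray] = {}
    for t in catalog.trip_types:
        for p in POLLUTANTS:
            key = (t.name, p)
            if key not in acc:
                continue
            v = np.asarray(acc[key])
            rep_means[key] = v
            m, lo, hi = _cell_ci(v, config.ci_level)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                TripDoseEstimate(
                    t.name, p, m, lo, hi, float(med), float(q1), float(q3),
                    len(v), DOSE_PER_TRIP_UNITS[p], converged,
                ).__dict__
            )
    estimates = pd.DataFrame(rows)
    audit = {
        "seed": config.seed,
        "n_replications": n_reps,
        "n_commuters": config.n_commuters,
        "converged": converged,
        "ci_level": config.ci_level,
        "precision": config.precision,
    }
    return SimulationResult(estimates, rep_means, n_reps, converged, config, audit)


def compare_scenarios(
    result_a: SimulationResult,
    result_b: SimulationResult,
    pairing: Sequence[tuple[str, str]],
    label_a: str = "a",
    label_b: str = "b",
) -> pd.DataFrame:
    """Paired trip-type comparisons on replication means.

    For each declared pair (trip type in scenario a, trip type in scenario b)
    and pollutant: mean difference (a - b), percent change relative to a, and
    a Welch t test across replication means.
    """
    rows = []
    for name_a, name_b in pairing:
        for p in POLLUTANTS:
            key_a, key_b = (name_a, p), (name_b, p)
            if key_a not in result_a.replication_means:
                raise ValueError(f"trip type {name_a!r} ({p}) absent from scenario {label_a}")
            if key_b not in result_b.replication_means:
                raise ValueError(f"trip type {name_b!r} ({p}) absent from scenario {label_b}")
            va = result_a.replication_means[key_a]
            vb = result_b.replication_means[key_b]
            res = two_sample_t(va, vb)
            mean_a, mean_b = float(va.mean()), float(vb.mean())
            rows.append(
                {
                    f"trip_{label_a}": name_a,
                    f"trip_{label_b}": name_b,
                    "pollutant": p,
                    f"mean_{label_a}": mean_a,
                    f"mean_{label_b}": mean_b,
                    "difference": mean_a - mean_b,
                    "percent_change": 100.0 * (mean_a - mean_b) / mean_a if mean_a else np.nan,
                    "t_statistic": res.statistic,
                    "p_value": res.pvalue,
                    "stars": res.stars,
                    "units": DOSE_PER_TRIP_UNITS[p],
                }
            )
    return pd.DataFrame(rows)
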