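"""Accelerometry -> inhalation rate -> inhaled-dose rate per microenvironment.

The inhaled dose per unit time of pollutant j in microenvironment i is the
product of the mean exposure concentration C_ij and the inhalation rate IR_i
for the activity level typical of that mode:

    D_ij = C_ij * IR_i        [µg/min; CO in mg/min after unit conversion]

Activity is proxied by accelerometer counts, mapped linearly to metabolic
equivalents (METs) and then proportionally to ventilation. The published
evidence is that counts correlate well with both METs and ventilation rate;
the linear coefficients used here are configurable defaults, not measured
constants, and are pinned in the test suite so any change is deliberate.

CO is measured in ppm but dosed in mg; the ideal-gas conversion defaults to
25 °C / 101.325 kPa. At high-altitude sites (Bogotá: ~74.7 kPa) the same ppm
reading corresponds to ~26 % less mass per m³ — set the pressure accordingly
when absolute CO doses matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sensors import POLLUTANTS

M_CO_G_PER_MOL = 28.01
R_KPA_L = 8.314462618  # kPa·L/(mol·K)

#: default counts/min -> METs linear map (intercept, slope)
DEFAULT_METS_COEFFS = (1.439, 0.000795)
#: resting ventilation, m³/min
DEFAULT_RESTING_IR = 0.0083

DOSE_UNITS = {"pm25": "ug/min", "ebc": "ug/min", "co": "mg/min"}
CONC_UNITS = {"pm25": "ug/m3", "ebc": "ug/m3", "co": "mg/m3"}


def counts_to_mets(counts_per_min, a: float = DEFAULT_METS_COEFFS[0],
                   b: float = DEFAULT_METS_COEFFS[1]) -> np.ndarray | float:
    """Linear counts->METs map, floored at 1 MET (sedentary)."""
    x = np.asarray(counts_per_min, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    mets = np.maximum(a + b * x, 1.0)
    return float(mets) if np.isscalar(counts_per_min) else mets


def mets_to_ir(mets, resting_ir: float = DEFAULT_RESTING_IR) -> np.ndarray | float:
    """Ventilation proportional to METs: IR = METs * resting IR (m³/min)."""
    if resting_ir <= 0:
        raise ValueError("resting inhalation rate must be positive")
    m = np.asarray(mets, dtype=float)
    if np.any(m < 1):
        raise ValueError("METs below 1 are not physical for this model")
    ir = m * resting_ir
    return float(ir) if np.isscalar(mets) else ir


def co_ppm_to_mgm3(ppm, temperature_c: float = 25.0, pressure_kpa: float = 101.325):
    """ppm CO -> mg/m³ via the ideal gas law (M_CO = 28.01 g/mol)."""
    if not (-60 < temperature_c < 60) or not (20 < pressure_kpa < 120):
        raise ValueError("nonphysical temperature or pressure")
    x = np.asarray(ppm, dtype=float)
    if np.any(x < 0):
        raise ValueError("ppm must be nonnegative")
    vm_l = R_KPA_L * (temperature_c + 273.15) / pressure_kpa  # L/mol
    out = x * M_CO_G_PER_MOL / vm_l
    return float(out) if np.isscalar(ppm) else out


def dose_rate(concentration: float, ir: float) -> float:
    """Dose per minute: concentration (mass/m³) times inhalation (m³/min)."""
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if ir <= 0:
        raise ValueError("inhalation rate must be positive")
    return concentration * ir


@dataclass(frozen=True)
class ModeDoseProfile:
    """Dose rate of one pollutant in one microenvironment."""

    mode: str
    pollutant: str
    concentration: float
    conc_units: str
    ir_m3_min: float
    dose_rate: float
    dose_units: str
    source: str = "measured"  # or "external"

    def __post_init__(self) -> None:
        if self.conc_units == "ppm":
            raise ValueError("convert CO from ppm to mg/m3 before building a dose profile")
        if self.conc_units != CONC_UNITS[self.pollutant]:
            raise ValueError(
                f"{self.pollutant} expects {CONC_UNITS[self.pollutant]}, got {self.conc_units}"
            )
        if abs(self.dose_rate - self.concentration * self.ir_m3_min) > 1e-9 * max(1.0, abs(self.dose_rate)):
            raise ValueError("dose_rate must equal concentration * IR")
        if min(self.concentration, self.ir_m3_min, self.dose_rate) < 0:
            raise ValueError("profile values must be nonnegative")


def mode_inhalation_rates(
    labeled: pd.DataFrame,
    period_s: float,
    mets_coeffs: tuple[float, float] = DEFAULT_METS_COEFFS,
    resting_ir: float = DEFAULT_RESTING_IR,
) -> dict[str, float]:
    """Mean inhalation rate per mode from per-epoch accelerometer counts.

    IR is averaged over each mode's samples because activity differs between
    walking and riding; that mean is the IR_i entering every dose rate for
    the mode.
    """
    out: dict[str, float] = {}
    for mode, grp in labeled.groupby("mode", sort=False):
        cpm = grp["counts"].dropna().to_numpy(float) * (60.0 / period_s)
        mets = counts_to_mets(cpm, *mets_coeffs)
        out[mode] = float(np.mean(mets_to_ir(mets, resting_ir)))
    return out


def build_dose_profiles(
    mode_summaries: pd.DataFrame,
    ir_by_mode: Mapping[str, float],
    required_modes: Sequence[str],
    external_profiles: Mapping[str, Mapping[str, float]] | None = None,
    co_temperature_c: float = 25.0,
    co_pressure_kpa: float = 101.325,
) -> pd.DataFrame:
    """One ModeDoseProfile per required mode x pollutant.

    Measured modes take their concentrations from ``mode_summaries`` (CO means
    in ppm are converted to mg/m³ here) and their IR from ``ir_by_mode``.
    Modes without measurements (typically BRT, whose cabins were characterized
    in an earlier campaign) must appear in ``external_profiles`` as
    ``{mode: {"pm25": C, "ebc": C, "co_mgm3": C, "ir": IR}}`` and pass through
    flagged as external. A required mode with neither is an error.
    """
    external_profiles = external_profiles or {}
    measured = set(mode_summaries["mode"].unique())
    profiles: list[ModeDoseProfile] = []
    for mode in required_modes:
        if mode in measured:
            ir = ir_by_mode.get(mode)
            if ir is None:
                raise ValueError(f"no inhalation rate for measured mode {mode!r}")
            sub = mode_summaries[mode_summaries["mode"] == mode].set_index("pollutant")
            for pol in POLLUTANTS:
                if pol not in sub.index:
                    raise ValueError(f"mode {mode!r} lacks a {pol} summary")
                c = float(sub.loc[pol, "mean"])
                if pol == "co":
                    c = co_ppm_to_mgm3(c, co_temperature_c, co_pressure_kpa)
                profiles.append(
                    ModeDoseProfile(mode, pol, c, CONC_UNITS[pol], ir,
                                    dose_rate(c, ir), DOSE_UNITS[pol])
                )
        elif mode in external_profiles:
            ext = external_profiles[mode]
            ir = float(ext["ir"])
            conc = {"pm25": float(ext["pm25"]), "ebc": float(ext["ebc"]),
                    "co": float(ext["co_mgm3"])}
            for pol in POLLUTANTS:
                profiles.append(
                    ModeDoseProfile(mode, pol, conc[pol], CONC_UNITS[pol], ir,
                                    dose_rate(conc[pol], ir), DOSE_UNITS[pol],
                                    source="external")
                )
        else:
            raise ValueError(
                f"mode {mode!r} has neither measured summaries nor an external profile"
            )
    return profiles_to_frame(profiles)


def profiles_to_frame(profiles: Sequence[ModeDoseProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in profiles])


def rates_by_mode(profiles: pd.DataFrame) -> dict[str, dict[str, float]]:
    """{mode: {pollutant: dose rate}} view consumed by the trip simulator."""
    out: dict[str, dict[str, float]] = {}
    for _, row in profiles.iterrows():
        out.setdefault(row["mode"], {})[row["pollutant"]] = float(row["dose_rate"])
    return out
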