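"""Preprocessing of batch-digester gas logs into specific methane yield curves.

A BMP (biochemical methane potential) assay logs incremental gas volumes per
channel at meter conditions.  This module normalizes those volumes to STP
(273.15 K, 101.325 kPa), weights them by the measured CH4 fraction, subtracts
the endogenous production of the inoculum (measured on blank channels, scaled
by inoculum volatile solids), and expresses the result as cumulative mL CH4
per gram of substrate volatile solids.  It also derives per-day / per-interval
production series, the T50/T90/T95 timing statistics, and the assay
termination day under the "three consecutive days below 1% of the running
total" rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STP_TEMPERATURE_K = 273.15
STP_PRESSURE_KPA = 101.325

#: standard column names used throughout this module
GAS_LOG_COLUMNS = (
    "channel_id",
    "time_h",
    "volume_increment_ml",
    "temperature_k",
    "pressure_kpa",
    "ch4_fraction",
)


@dataclass
class ChannelMeta:
    """Loading metadata for one digester channel.

    ``substrate_vs`` and ``inoculum_vs`` are grams of volatile solids loaded;
    blank (inoculum-only) channels have ``substrate_vs == 0``.
    """

    channel_id: str
    group_label: str
    substrate_vs: float
    inoculum_vs: float
    is_blank: bool = False
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.substrate_vs < 0:
            raise ValueError("substrate_vs must be >= 0")
        if self.inoculum_vs <= 0:
            raise ValueError("inoculum_vs must be > 0")
        if self.is_blank and self.substrate_vs != 0:
            raise ValueError("blank channels must have substrate_vs == 0")


@dataclass
class YieldCurve:
    """Cumulative gas curve: ``times`` in days (ascending, from 0),
    ``cumulative`` non-decreasing, in mL per gram of the reference VS."""

    times: np.ndarray
    cumulative: np.ndarray
    basis: str = "methane"  # or "total_gas"
    flagged: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.times.shape != self.cumulative.shape:
            raise ValueError("times and cumulative must have the same length")
        if self.times.size == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.basis not in ("methane", "total_gas"):
            raise ValueError(f"unknown basis {self.basis!r}")

    @property
    def final(self) -> float:
        return float(self.cumulative[-1])

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the cumulative curve (flat extrapolation)."""
        return np.interp(t, self.times, self.cumulative)


@dataclass
class TimingStats:
    t50: float | None = None
    t90: float | None = None
    t95: float | None = None
    end_day: float | None = None
    fraction_days: dict = field(default_factory=dict)


def normalize_to_stp(volume_ml, temperature_k, pressure_kpa):
    """Convert a gas volume at meter conditions to STP (273.15 K, 101.325 kPa).

    Ideal-gas correction: V_stp = V * (273.15 / T) * (P / 101.325).
    Accepts scalars or arrays; volume must be non-negative and T, P positive.
    """
    volume_ml = np.asarray(volume_ml, dtype=float)
    temperature_k = np.asarray(temperature_k, dtype=float)
    pressure_kpa = np.asarray(pressure_kpa, dtype=float)
    if np.any(temperature_k <= 0):
        raise ValueError("temperature must be > 0 K")
    if np.any(pressure_kpa <= 0):
        raise ValueError("pressure must be > 0 kPa")
    if np.any(volume_ml < 0):
        raise ValueError("volume must be >= 0")
    out = volume_ml * (STP_TEMPERATURE_K / temperature_k) * (pressure_kpa / STP_PRESSURE_KPA)
    return out if out.ndim else float(out)


def _validate_channel_log(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values("time_h").reset_index(drop=True)
    t = df["time_h"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing within a channel")
    if np.any(df["volume_increment_ml"].to_numpy(float) < 0):
        raise ValueError("volume increments must be >= 0")
    if "ch4_fraction" in df and df["ch4_fraction"].notna().any():
        f = df["ch4_fraction"].dropna().to_numpy(float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("ch4_fraction must lie in [0, 1]")
    return df


def cumulative_stp_curve(records: pd.DataFrame, basis: str = "methane") -> YieldCurve:
    """Cumulative STP gas volume (mL, absolute) for a single channel.

    With ``basis='methane'`` each increment is weighted by its CH4 fraction;
    a missing fraction is an error on that basis.  The returned curve is
    anchored at (0, 0).
    """
    df = _validate_channel_log(records)
    v = normalize_to_stp(
        df["volume_increment_ml"].to_numpy(float),
        df["temperature_k"].to_numpy(float),
        df["pressure_kpa"].to_numpy(float),
    )
    if basis == "methane":
        if "ch4_fraction" not in df or df["ch4_fraction"].isna().any():
            raise ValueError("basis='methane' requires a CH4 fraction on every record")
        v = v * df["ch4_fraction"].to_numpy(float)
    t_days = df["time_h"].to_numpy(float) / 24.0
    times = np.concatenate([[0.0], t_days]) if t_days[0] > 0 else t_days
    cum = np.cumsum(v)
    cum = np.concatenate([[0.0], cum]) if t_days[0] > 0 else cum
    return YieldCurve(times=times, cumulative=cum, basis=basis)


def blank_curve_per_g_inoculum(
    blank_records: Sequence[pd.DataFrame],
    blank_metas: Sequence[ChannelMeta],
    basis: str = "methane",
) -> YieldCurve:
    """Mean blank (inoculum-only) curve expressed per gram of inoculum VS.

    Replicate blanks are averaged on the union time grid after scaling each
    channel by its own inoculum VS.
    """
    if len(blank_records) != len(blank_metas) or not blank_records:
        raise ValueError("need one metadata entry per blank channel")
    curves = []
    for rec, meta in zip(blank_records, blank_metas):
        if not meta.is_blank:
            raise ValueError(f"channel {meta.channel_id} is not a blank")
        c = cumulative_stp_curve(rec, basis=basis)
        curves.append(YieldCurve(c.times, c.cumulative / meta.inoculum_vs, basis=basis))
    grid = np.unique(np.concatenate([c.times for c in curves]))
    mean = np.mean([c.at(grid) for c in curves], axis=0)
    return YieldCurve(times=grid, cumulative=np.maximum.accumulate(mean), basis=basis)


def specific_methane_curve(
    records: pd.DataFrame,
    meta: ChannelMeta,
    blank_curve: YieldCurve,
    basis: str = "methane",
) -> YieldCurve:
    """Blank-corrected specific yield curve (mL per g substrate VS).

    The test channel's cumulative STP curve minus the blank curve (per g
    inoculum VS) scaled by this channel's inoculum VS, divided by substrate
    VS.  Negative blank-corrected values are clamped and the output is made
    monotone by a running maximum; a blank exceeding the test at the final
    time flags the curve and logs a warning.
    """
    if meta.substrate_vs <= 0:
        raise ValueError("specific curve requires substrate_vs > 0")
    test = cumulative_stp_curve(records, basis=basis)
    raw = (test.cumulative - blank_curve.at(test.times) * meta.inoculum_vs) / meta.substrate_vs
    flagged = False
    if raw[-1] < 0:
        flagged = True
        msg = (
            f"channel {meta.channel_id}: blank production exceeds test production "
            f"at the final time ({raw[-1]:.3g} mL/g VS)"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    corrected = np.maximum.accumulate(np.clip(raw, 0.0, None))
    return YieldCurve(times=test.times, cumulative=corrected, basis=basis, flagged=flagged)


def daily_and_hourly_production(curve: YieldCurve) -> dict[str, pd.DataFrame]:
    """First-difference production series from a cumulative curve.

    Daily bins are anchored at t=0: day d covers elapsed hours (24(d-1), 24d],
    so the assay's first calendar day is day 1.  Hourly (native-interval)
    production is the first difference over the log's own time grid.  Both
    series telescope: they sum exactly to the final cumulative value minus
    the value at t=0 (zero for measured curves).
    """
    last_day = int(np.ceil(curve.times[-1] - 1e-12))
    day_edges = np.arange(0, last_day + 1, dtype=float)
    cum_at_edges = curve.at(day_edges)
    cum_at_edges[-1] = curve.final  # flat extrapolation must not lose the tail
    daily = pd.DataFrame(
        {"day": day_edges[1:].astype(int), "production": np.diff(cum_at_edges)}
    )
    hourly = pd.DataFrame(
        {
            "time_days": curve.times[1:],
            "production": np.diff(curve.cumulative),
        }
    )
    return {"daily": daily, "hourly": hourly}


def timing_stats(
    curve: YieldCurve,
    fractions: Sequence[float] = (0.5, 0.9, 0.95),
    end_day: float | None = None,
) -> TimingStats:
    """Earliest whole day at which the curve reaches each fraction of its final value.

    T_f is the smallest whole day d with cumulative(d) >= f * cumulative(final),
    evaluated on the measured curve (not a fitted asymptote).  Fraction 1.0
    returns the last whole day.
    """
    if curve.final <= 0:
        raise ValueError("timing statistics undefined for an all-zero curve")
    last_day = int(np.ceil(curve.times[-1] - 1e-12))
    days = np.arange(1, last_day + 1, dtype=float)
    cum = curve.at(days)
    cum[-1] = curve.final
    out: dict[float, float] = {}
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        if f == 1.0:
            out[f] = float(last_day)
            continue
        idx = np.nonzero(cum >= f * curve.final - 1e-12 * abs(curve.final))[0]
        out[f] = float(days[idx[0]]) if idx.size else float(last_day)
    stats = TimingStats(fraction_days=out, end_day=end_day)
    stats.t50 = out.get(0.5)
    stats.t90 = out.get(0.9)
    stats.t95 = out.get(0.95)
    return stats


def detect_termination(
    daily: Sequence[float], window: int = 3, threshold: float = 0.01
) -> int | None:
    """Assay termination day under the consecutive-low-production rule.

    Returns the (1-based) day ending the first run of ``window`` consecutive
    days whose production is each below ``threshold`` times the running
    cumulative total (inclusive of that day); None if never satisfied.
    """
    daily = np.asarray(daily, dtype=float)
    if np.any(daily < 0):
        raise ValueError("daily production must be non-negative")
    running = np.cumsum(daily)
    low = daily < threshold * running
    streak = 0
    for i, is_low in enumerate(low):
        streak = streak + 1 if is_low else 0
        if streak >= window:
            return i + 1
    return None


def group_mean_curves(
    curves: Sequence[YieldCurve], labels: Sequence[str]
) -> pd.DataFrame:
    """Tidy replicate mean +/- sd table of specific curves per group label."""
    rows = []
    by_group: dict[str, list[YieldCurve]] = {}
    for c, lab in zip(curves, labels):
        by_group.setdefault(lab, []).append(c)
    for lab, cs in by_group.items():
        grid = np.unique(np.concatenate([c.times for c in cs]))
        mat = np.array([c.at(grid) for c in cs])
        rows.append(
            pd.DataFrame(
                {
                    "group": lab,
                    "time_days": grid,
                    "mean": mat.mean(axis=0),
                    "sd": mat.std(axis=0, ddof=1) if len(cs) > 1 else 0.0,
                    "n": len(cs),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
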