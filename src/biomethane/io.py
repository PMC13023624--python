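"""Readers and writers for the delimiter-separated table dialects the
pipeline consumes: gas logs, channel metadata, substrate characterization,
substrate-concentration series and formula-assignment exports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gas_preprocess import GAS_LOG_COLUMNS, ChannelMeta
from .stoichiometry import ElementalComposition

DEFAULT_GAS_COLUMNS = {name: name for name in GAS_LOG_COLUMNS}


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    # sep=None lets pandas sniff commas/tabs/semicolons
    return pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")


def read_gas_log(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a gas log with a header row into the standard column layout.

    ``column_map`` maps standard names (channel_id, time_h, ...) to the file's
    own column names.  The time column may hold elapsed hours or ISO
    datetimes; datetimes are converted to elapsed hours from the earliest
    record of each channel.
    """
    column_map = {**DEFAULT_GAS_COLUMNS, **(column_map or {})}
    raw = _read_table(path, delimiter)
    missing = [v for k, v in column_map.items() if k != "ch4_fraction" and v not in raw.columns]
    if missing:
        raise ValueError(f"gas log {path} lacks required columns: {missing}")
    df = pd.DataFrame({std: raw[col] for std, col in column_map.items() if col in raw.columns})
    if not np.issubdtype(df["time_h"].dtype, np.number):
        ts = pd.to_datetime(df["time_h"])
        df["time_h"] = df.groupby(df["channel_id"])["time_h"].transform(
            lambda s: (pd.to_datetime(s) - pd.to_datetime(s).min()).dt.total_seconds() / 3600.0
        )
        del ts
    return df


def read_channel_meta(path: str | Path, delimiter: str | None = None) -> list[ChannelMeta]:
    df = _read_table(path, delimiter)
    metas = []
    for _, row in df.iterrows():
        metas.append(
            ChannelMeta(
                channel_id=str(row["channel_id"]),
                group_label=str(row["group_label"]),
                substrate_vs=float(row["substrate_vs"]),
                inoculum_vs=float(row["inoculum_vs"]),
                is_blank=bool(row.get("is_blank", False)),
                replicate_index=int(row.get("replicate_index", 0)),
            )
        )
    return metas


def read_characterization(path: str | Path, delimiter: str | None = None) -> dict[str, ElementalComposition]:
    """Substrate/inoculum characterization table -> elemental compositions.

    Expected columns: substrate, c_pct, h_pct, o_pct, n_pct, optional
    vs_fraction (VS/TS on dry basis).
    """
    df = _read_table(path, delimiter)
    out = {}
    for _, row in df.iterrows():
        out[str(row["substrate"])] = ElementalComposition(
            c_pct=float(row["c_pct"]), h_pct=float(row["h_pct"]),
            o_pct=float(row["o_pct"]), n_pct=float(row.get("n_pct", 0.0)),
            vs_fraction=float(row["vs_fraction"]) if "vs_fraction" in df.columns and pd.notna(row.get("vs_fraction")) else None,
        )
    return out


def read_substrate_series(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    df = _read_table(path, delimiter)
    need = {"time_days", "concentration_g_l"}
    if not need.issubset(df.columns):
        raise ValueError(f"substrate series {path} must have columns {sorted(need)}")
    return df


def read_formula_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Formula-assignment export: either a ``formula`` string column or
    per-element count columns c/h/o/n/s, plus relative_intensity."""
    df = _read_table(path, delimiter)
    if "formula" not in df.columns and not {"c", "h"}.issubset(df.columns):
        raise ValueError("formula table needs a 'formula' column or c/h/o/n/s counts")
    return df


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False)
    return path
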