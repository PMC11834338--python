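"""Reading and writing the pipeline's delimited-table formats.

Long-format CSV conventions:

* value series:   ``timestamp_utc,<value column>`` (ISO-8601 timestamps)
* spectral series: ``timestamp_utc,wavelength_nm,intensity``
* emergence:      ``strain,replicate,cycle,day,count``
* diel grids:     a matrix with clock minutes as the index and
                  day-in-cycle as columns
"""

from __future__ import annotations

import pandas as pd

from .radiometry import DielGrid

__all__ = [
    "read_series",
    "write_series",
    "read_spectral",
    "write_spectral",
    "read_emergence",
    "write_emergence",
    "write_grid",
    "read_grid",
]


def read_series(path, value_column: str | None = None) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["timestamp_utc"])
    col = value_column or df.columns[1]
    return pd.Series(
        df[col].to_numpy(), index=pd.DatetimeIndex(df["timestamp_utc"]),
        name=col,
    )


def write_series(series: pd.Series, path) -> None:
    pd.DataFrame(
        {
            "timestamp_utc": series.index,
            series.name or "value": series.to_numpy(),
        }
    ).to_csv(path, index=False)


def read_spectral(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp_utc"])
    wide = df.pivot(
        index="timestamp_utc", columns="wavelength_nm", values="intensity"
    )
    wide.columns = [float(c) for c in wide.columns]
    return wide.sort_index()


def write_spectral(spectral: pd.DataFrame, path) -> None:
    long = spectral.stack().rename("intensity").reset_index()
    long.columns = ["timestamp_utc", "wavelength_nm", "intensity"]
    long.to_csv(path, index=False)


def read_emergence(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"strain", "replicate", "cycle", "day", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"emergence table missing columns: {sorted(missing)}")
    return df


def write_emergence(emergence: pd.DataFrame, path) -> None:
    emergence.to_csv(path, index=False)


def write_grid(grid: DielGrid, path) -> None:
    grid.values.to_csv(path)


def read_grid(path, period_days: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = [int(c) for c in df.columns]
    df.index = [int(i) for i in df.index]
    df.index.name = "clock"
    df.columns.name = "day"
    return df
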