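"""Reading and writing series files, and run configuration.

Series are delimited text (CSV or TSV), either a single value column or a
time column followed by a value column.  Comment lines starting with ``#``
are tolerated.  When a time column is present the sampling interval is
inferred from it and uniform spacing is enforced; otherwise ``dt`` must be
supplied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .estimators import EstimatorSpec
from .series import TimeSeries

__all__ = ["read_series", "write_series", "RunConfig"]

#: relative tolerance on time-grid uniformity
_DT_RTOL = 1e-6


def read_series(
    path,
    value_col: Optional[int] = None,
    time_col: Optional[int] = None,
    dt: Optional[float] = None,
) -> TimeSeries:
    """Read a time series from a delimited text file.

    With two or more columns and no explicit column spec, the first column
    is taken as time and the second as the value.  With a single column,
    ``dt`` is required.
    """
    path = Path(path)
    first_data = next(
        (
            ln
            for ln in path.read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ),
        "",
    )
    if "," in first_data:
        sep = ","
    elif "\t" in first_data:
        sep = "\t"
    else:
        sep = r"\s+"
    try:
        df = pd.read_csv(
            path, sep=sep, engine="python", comment="#", header=None,
            skip_blank_lines=True,
        )
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    # a non-numeric first row is a header
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 data rows")

    ncol = df.shape[1]
    if value_col is None and time_col is None:
        if ncol == 1:
            value_col = 0
        else:
            time_col, value_col = 0, 1
    elif value_col is None:
        raise ValueError("time_col given without value_col")

    def _column(i: int) -> np.ndarray:
        raw = df.iloc[:, i]
        try:
            # exact strtod round-trip (pd.to_numeric can be 1 ulp off)
            col = raw.astype(float).to_numpy()
        except (ValueError, TypeError):
            col = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(col))[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric or non-finite entry in column {i}, "
                f"data row {bad[0] + 1}"
            )
        return col

    values = _column(value_col)
    if time_col is not None:
        times = _column(time_col)
        diffs = np.diff(times)
        dt_inferred = float(np.median(diffs))
        if dt_inferred <= 0:
            raise ValueError(f"{path}: time column is not strictly increasing")
        if np.any(np.abs(diffs - dt_inferred) > _DT_RTOL * dt_inferred):
            raise ValueError(f"{path}: time grid is not uniform")
        if dt is not None and abs(dt - dt_inferred) > _DT_RTOL * dt_inferred:
            raise ValueError(
                f"{path}: supplied dt={dt} conflicts with inferred dt={dt_inferred}"
            )
        return TimeSeries(values, dt=dt_inferred, t0=float(times[0]))
    if dt is None:
        raise ValueError(
            f"{path}: no time column found; a sampling interval (dt) is required"
        )
    return TimeSeries(values, dt=float(dt), t0=0.0)


def write_series(series: TimeSeries, path) -> Path:
    """Write a series as two-column CSV (time, value) at full precision."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([series.times, series.values]),
        delimiter=",",
        header="time,value",
        comments="",
        fmt="%.17g",
    )
    return path


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one analysis run."""

    method: str = "window"
    window_size: Optional[Union[int, str]] = "sqrt"
    mode: str = "min_mse"
    exclude_fraction: float = 0.10
    stride: int = 1
    seed: Optional[int] = None
    n_boot: int = 10_000
    variant: str = "standard"
    variant_params: dict = field(default_factory=dict)
    input_path: Optional[str] = None
    output_path: Optional[str] = None
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        self.spec()  # validates method/window_size combination
        if self.mode not in ("min_mse", "llm", "max_ess"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.exclude_fraction < 1.0:
            raise ValueError("exclude_fraction must lie in [0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def spec(self) -> EstimatorSpec:
        ws = self.window_size if self.method == "window" else None
        return EstimatorSpec(self.method, ws)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from YAML or JSON (decided by content, not suffix)."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        return cls.from_dict(data)
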