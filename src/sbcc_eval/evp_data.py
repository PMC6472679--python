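"""Containers and CSV I/O for site measurement time series.

The evaluation framework consumes three record kinds:

* depth-resolved current-speed grids (ADCP style, nominal 10-min means),
  held in :class:`VelocityField`;
* sea-state summary records (significant wave height ``H``, period ``T``),
  held in :class:`WaveRecord`;
* dissolved-oxygen concentration series, held in :class:`DOSeries`.

Vertical coordinate convention: heights are metres *above the seabed*
(the ADCP bin convention — the first bin of a bottom-mounted profiler sits
a metre or so off the bed).  Wave kinematics use ``z`` measured downward
from the still-water surface; the conversion ``z = height − water_depth``
is centralised in :meth:`VelocityField.z_below_surface` so the sign
convention lives in exactly one place.

Missing samples are explicit NaN marks, never silent zeros.  File format
is plain CSV with ``#``-prefixed metadata comment lines; timestamps are
ISO-8601 and treated as UTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EXTERNAL = "external"
INTERNAL = "internal"
_PROVENANCES = (EXTERNAL, INTERNAL)

_FLOAT_FMT = "%.10g"


class ValidationError(ValueError):
    """A record violates one of the data-model invariants."""


def _as_utc_naive(times) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(times))
    if idx.tz is not None:
        idx = idx.tz_convert("UTC").tz_localize(None)
    return idx


def _check_times(times: pd.DatetimeIndex, what: str = "time") -> None:
    if len(times) < 2:
        return
    if times.has_duplicates:
        bad = times[times.duplicated()][0]
        raise ValidationError(f"duplicate {what}stamp {bad.isoformat()}")
    if not times.is_monotonic_increasing:
        steps = np.diff(times.asi8)
        bad = times[int(np.flatnonzero(steps < 0)[0]) + 1]
        raise ValidationError(f"non-monotonic {what} at {bad.isoformat()}")


@dataclass
class VelocityField:
    """Time × height grid of flow-speed magnitude.

    Parameters
    ----------
    times : array-like of datetimes
        Sample timestamps (UTC, nominally uniform cadence).
    heights : array-like of float
        Heights above the seabed in metres, strictly increasing.
    speed : 2-D array, shape (len(times), len(heights))
        Flow-speed magnitude in m/s; NaN marks a missing sample.
    cadence : float
        Nominal sampling interval in seconds (10-min means by default
        upstream, but any positive cadence is accepted).
    provenance : {"external", "internal"}
        Whether the field is an external profile (EVP, as measured) or an
        internal profile (IVP, after the container transfer function).
    water_depth_ref : float, optional
        Reference water depth in metres, needed to convert heights above
        the seabed into depths below the surface.
    """

    times: pd.DatetimeIndex
    heights: np.ndarray
    speed: np.ndarray
    cadence: float = 600.0
    provenance: str = EXTERNAL
    water_depth_ref: float | None = None

    def __post_init__(self) -> None:
        self.times = _as_utc_naive(self.times)
        self.heights = np.asarray(self.heights, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.cadence = float(self.cadence)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        _check_times(self.times)
        if self.heights.ndim != 1 or len(self.heights) == 0:
            raise ValidationError("heights must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValidationError("heights must be finite")
        if len(self.heights) > 1 and not np.all(np.diff(self.heights) > 0):
            i = int(np.flatnonzero(np.diff(self.heights) <= 0)[0]) + 1
            raise ValidationError(f"heights not strictly increasing at index {i}")
        if self.speed.shape != (len(self.times), len(self.heights)):
            raise ValidationError(
                f"speed shape {self.speed.shape} does not match "
                f"{len(self.times)} times x {len(self.heights)} heights"
            )
        bad = ~(np.isnan(self.speed) | (np.isfinite(self.speed) & (self.speed >= 0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            when = self.times[i].isoformat() if len(self.times) else "?"
            raise ValidationError(
                f"invalid speed at row {i} ({when}), height {self.heights[j]:g} m: "
                f"{self.speed[i, j]!r} (speeds must be finite and >= 0, NaN = missing)"
            )
        if self.cadence <= 0:
            raise ValidationError("cadence must be positive")
        if self.provenance not in _PROVENANCES:
            raise ValidationError(f"provenance must be one of {_PROVENANCES}")
        if self.water_depth_ref is not None and self.water_depth_ref <= 0:
            raise ValidationError("water_depth_ref must be positive")

    # ------------------------------------------------------------------
    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.speed).sum())

    def z_below_surface(self) -> np.ndarray:
        """Heights converted to z measured downward from the surface (z <= 0)."""
        if self.water_depth_ref is None:
            raise ValidationError("water_depth_ref required to convert to z below surface")
        return self.heights - self.water_depth_ref

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.speed, index=self.times, columns=self.heights)

    def to_xarray(self):
        import xarray as xr

        return xr.DataArray(
            self.speed,
            coords={"time": self.times, "height": self.heights},
            dims=("time", "height"),
            name="speed",
            attrs={
                "units": "m s-1",
                "provenance": self.provenance,
                "cadence_s": self.cadence,
                **(
                    {"water_depth_ref_m": self.water_depth_ref}
                    if self.water_depth_ref is not None
                    else {}
                ),
            },
        )


# ----------------------------------------------------------------------
# Wave and DO records


@dataclass(frozen=True)
class WaveRecord:
    """One sea state: significant wave height H (m) and period T (s)."""

    timestamp: pd.Timestamp
    H: float
    T: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))
        object.__setattr__(self, "H", float(self.H))
        object.__setattr__(self, "T", float(self.T))
        if not (np.isfinite(self.H) and self.H > 0):
            raise ValidationError(f"wave height must be > 0, got {self.H!r}")
        if not (np.isfinite(self.T) and self.T > 0):
            raise ValidationError(f"wave period must be > 0, got {self.T!r}")


@dataclass
class DOSeries:
    """Dissolved-oxygen concentration series (mg/L), optional temperature (degC)."""

    times: pd.DatetimeIndex
    concentration: np.ndarray
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = _as_utc_naive(self.times)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_times(self.times)
        if self.concentration.shape != (len(self.times),):
            raise ValidationError("concentration length does not match times")
        bad = ~(
            np.isnan(self.concentration)
            | (np.isfinite(self.concentration) & (self.concentration > 0))
        )
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"DO concentration must be > 0; offending row {i} "
                f"({self.times[i].isoformat()}): {self.concentration[i]!r}"
            )
        if self.temperature is not None and self.temperature.shape != (len(self.times),):
            raise ValidationError("temperature length does not match times")


# ----------------------------------------------------------------------
# CSV I/O

def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_velocity_field(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> VelocityField:
    """Read a velocity field from CSV.

    Two layouts are understood:

    * wide (default): a time column followed by one column per height bin,
      column names being the heights in metres;
    * long: columns (time, height, speed), selected by passing a
      ``dialect`` that maps the logical names ``time``/``height``/``speed``
      to the file's column names.

    Unparseable speed cells become explicit missing marks (NaN).
    Non-monotonic or duplicate timestamps are hard errors naming the
    offending timestamp.
    """
    path = Path(path)
    dialect = dict(dialect or {})
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    time_col = dialect.get("time", "time")
    if time_col not in df.columns:
        raise ValidationError(f"no time column {time_col!r} in {path.name}")

    if "height" in dialect and "speed" in dialect:
        hcol, scol = dialect["height"], dialect["speed"]
        long = pd.DataFrame(
            {
                "time": pd.to_datetime(df[time_col]),
                "height": pd.to_numeric(df[hcol]),
                "speed": pd.to_numeric(df[scol], errors="coerce"),
            }
        )
        if long.duplicated(["time", "height"]).any():
            bad = long[long.duplicated(["time", "height"])].iloc[0]
            raise ValidationError(f"duplicate timestamp {bad['time'].isoformat()}")
        wide = long.pivot(index="time", columns="height", values="speed")
        times = pd.DatetimeIndex(wide.index)
        heights = np.asarray(wide.columns, dtype=float)
        speed = wide.to_numpy(dtype=float)
    else:
        times = pd.to_datetime(df[time_col])
        heights = np.array([float(c) for c in df.columns if c != time_col])
        speed = np.column_stack(
            [
                pd.to_numeric(df[c], errors="coerce").to_numpy()
                for c in df.columns
                if c != time_col
            ]
        ) if len(df) else np.empty((0, len(heights)))

    times = _as_utc_naive(times)
    _check_times(times)

    cadence = float(meta.get("cadence", "nan"))
    if not np.isfinite(cadence):
        diffs = np.diff(times.asi8) / 1e9
        cadence = float(np.median(diffs)) if len(diffs) else 600.0
    wdr = meta.get("water_depth_ref")
    return VelocityField(
        times=times,
        heights=heights,
        speed=speed,
        cadence=cadence,
        provenance=meta.get("provenance", EXTERNAL),
        water_depth_ref=float(wdr) if wdr is not None else None,
    )


def write_velocity_field(field: VelocityField, path: str | Path) -> None:
    """Write a velocity field as wide CSV readable by :func:`read_velocity_field`.

    Missing marks are serialised as empty cells; provenance, cadence and
    the reference water depth go into ``#`` metadata comment lines.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# sbcc-eval velocity field v1\n")
        fh.write(f"# provenance: {field.provenance}\n")
        fh.write(f"# cadence: {field.cadence:.10g}\n")
        if field.water_depth_ref is not None:
            fh.write(f"# water_depth_ref: {field.water_depth_ref:.10g}\n")
        fh.write("time," + ",".join(_FLOAT_FMT % h for h in field.heights) + "\n")
        for t, row in zip(field.times, field.speed):
            cells = ["" if np.isnan(v) else _FLOAT_FMT % v for v in row]
            fh.write(t.isoformat() + "," + ",".join(cells) + "\n")


def read_wave_records(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[WaveRecord]:
    dialect = dict(dialect or {})
    df = pd.read_csv(Path(path), comment="#")
    tcol = dialect.get("time", "time")
    hcol = dialect.get("H", "H")
    pcol = dialect.get("T", "T")
    for col in (tcol, hcol, pcol):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r} in wave record file")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(WaveRecord(row[tcol], row[hcol], row[pcol]))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    _check_times(pd.DatetimeIndex([r.timestamp for r in records]))
    return records


def write_wave_records(records: Sequence[WaveRecord], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("time,H,T\n")
        for r in records:
            fh.write(f"{r.timestamp.isoformat()},{_FLOAT_FMT % r.H},{_FLOAT_FMT % r.T}\n")


def read_do_series(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> DOSeries:
    dialect = dict(dialect or {})
    df = pd.read_csv(Path(path), comment="#")
    tcol = dialect.get("time", "time")
    ccol = dialect.get("concentration", "concentration")
    if tcol not in df.columns or ccol not in df.columns:
        raise ValidationError("DO file needs time and concentration columns")
    temp_col = dialect.get("temperature", "temperature")
    temperature = (
        pd.to_numeric(df[temp_col], errors="coerce").to_numpy()
        if temp_col in df.columns
        else None
    )
    return DOSeries(
        times=pd.to_datetime(df[tcol]),
        concentration=pd.to_numeric(df[ccol], errors="coerce").to_numpy(),
        temperature=temperature,
    )


def write_do_series(series: DOSeries, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        cols = "time,concentration" + (",temperature" if series.temperature is not None else "")
        fh.write(cols + "\n")
        for i, t in enumerate(series.times):
            row = [t.isoformat(), _FLOAT_FMT % series.concentration[i]]
            if series.temperature is not None:
                v = series.temperature[i]
                row.append("" if np.isnan(v) else _FLOAT_FMT % v)
            fh.write(",".join(row) + "\n")
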