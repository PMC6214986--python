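"""Hourly monitoring series: ingestion, diurnal adjustment, station geometry.

Hourly concentration series ``c(t(d, h))`` are stored on a gap-free calendar
hour index with missing observations kept as NaN.  The diurnal (24-hour)
cycle is removed by dividing every value by the across-day average at the
same hour of day, giving a dimensionless series ``x`` whose per-hour-of-day
day-mean is exactly 1.  Station geometry uses great-circle distances on a
spherical Earth (R = 6371 km).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateHourError,
    FormatError,
    IntegrityError,
    ValidationError,
)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "HourlySeries",
    "AdjustedSeries",
    "StationRegistry",
    "DistanceMatrix",
    "read_hourly_csv",
    "write_hourly_csv",
    "diurnal_adjust",
    "haversine_km",
    "interstation_distances",
    "EARTH_RADIUS_KM",
]


@dataclass
class HourlySeries:
    """One station/pollutant hourly concentration series.

    ``values`` is a pandas Series on a consecutive hourly DatetimeIndex;
    missing hours are NaN.  All present values must be non-negative.
    """

    station_id: str
    pollutant: str
    values: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v.index, pd.DatetimeIndex):
            raise ValidationError("values must be indexed by timestamps")
        if len(v) > 1:
            deltas = np.diff(v.index.view("i8"))
            if not np.all(deltas == 3_600_000_000_000):
                raise ValidationError(
                    "index must be consecutive calendar hours with no gaps"
                )
        present = v.dropna()
        if (present < 0).any():
            raise ValidationError("concentrations must be non-negative")

    @property
    def start(self) -> pd.Timestamp:
        return self.values.index[0]

    def __len__(self) -> int:
        return len(self.values)


class AdjustedSeries(HourlySeries):
    """Diurnally adjusted, dimensionless series x(t(d, h))."""


@dataclass
class StationRegistry:
    """Monitoring-station registry: label, code, longitude, latitude."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"label", "code", "longitude", "latitude"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"registry missing columns: {sorted(missing)}")
        if self.table["label"].duplicated().any():
            raise IntegrityError("station labels must be unique")
        lat = self.table["latitude"]
        lon = self.table["longitude"]
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude out of [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValidationError("longitude out of [-180, 180]")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "StationRegistry":
        return cls(pd.read_csv(path))

    @classmethod
    def beijing(cls) -> "StationRegistry":
        """The 12 national monitoring stations in Beijing (packaged fixture)."""
        ref = importlib.resources.files("riacd.data") / "stations_beijing.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)

    @property
    def labels(self) -> list:
        return list(self.table["label"])

    def coords(self, label) -> tuple[float, float]:
        row = self.table.loc[self.table["label"] == label].iloc[0]
        return float(row["longitude"]), float(row["latitude"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DistanceMatrix:
    """Pairwise great-circle distances (km) and nearest-neighbour orderings."""

    distances: pd.DataFrame
    neighbours: dict = field(default_factory=dict)

    def distance(self, i, j) -> float:
        return float(self.distances.loc[i, j])

    def nearest(self, i, rank: int = 1):
        """The rank-th nearest neighbour of station ``i`` (rank 1 = nearest)."""
        return self.neighbours[i][rank - 1]

    def to_csv(self, path) -> None:
        self.distances.to_csv(path)


def read_hourly_csv(path, schema: dict | None = None) -> dict:
    """Read an hourly CSV into ``{(station, pollutant): HourlySeries}``.

    Expected columns: station, pollutant, timestamp (ISO-8601 hourly), value;
    ``schema`` remaps nonstandard column names.  Calendar-hour gaps within
    each series are filled with NaN; duplicate (station, pollutant, hour)
    rows raise :class:`IntegrityError`.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    if df.empty:
        return {}
    required = {"station", "pollutant", "timestamp", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamp: {exc}") from exc
    if df.duplicated(subset=["station", "pollutant", "timestamp"]).any():
        raise IntegrityError("duplicate (station, pollutant, hour) rows")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if (vals.dropna() < 0).any():
        raise ValidationError("negative concentration value")
    df["value"] = vals
    df["station"] = df["station"].astype(str)
    df["pollutant"] = df["pollutant"].astype(str)

    out: dict = {}
    for (station, pollutant), grp in df.groupby(["station", "pollutant"], sort=True):
        grp = grp.sort_values("timestamp")
        idx = pd.date_range(grp["timestamp"].iloc[0], grp["timestamp"].iloc[-1], freq="h")
        series = grp.set_index("timestamp")["value"].reindex(idx)
        out[(station, pollutant)] = HourlySeries(str(station), str(pollutant), series)
    return out


def write_hourly_csv(series: dict | list, path) -> None:
    """Write HourlySeries back to the standard CSV schema (NaN → empty)."""
    items = series.values() if isinstance(series, dict) else series
    frames = []
    for hs in items:
        frames.append(
            pd.DataFrame(
                {
                    "station": hs.station_id,
                    "pollutant": hs.pollutant,
                    "timestamp": hs.values.index.strftime("%Y-%m-%dT%H:%M:%S"),
                    "value": hs.values.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def diurnal_adjust(c: HourlySeries) -> AdjustedSeries:
    """Remove the intraday cycle: divide by the across-day mean at each hour.

    x(t(d, h)) = c(t(d, h)) / mean over days d of c(t(d, h)), the mean taken
    over days with a present value at hour h.  Missing hours stay missing.
    """
    v = c.values
    hours = v.index.hour
    hour_means = v.groupby(hours).transform("mean")
    present_hours = np.unique(hours[v.notna()])
    means_by_hour = v.groupby(hours).mean()
    zero = [h for h in present_hours if means_by_hour.loc[h] == 0.0]
    if zero:
        raise DegenerateHourError(
            f"hour(s) of day with zero across-day average: {zero}"
        )
    x = v / hour_means
    return AdjustedSeries(c.station_id, c.pollutant, x)


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def interstation_distances(reg: StationRegistry) -> DistanceMatrix:
    """Distance matrix (km) and per-station neighbour orderings.

    Neighbours are sorted by ascending distance; ties broken by ascending
    station label for determinism.
    """
    if len(reg) < 2:
        raise ValidationError("need at least 2 stations")
    labels = reg.labels
    n = len(labels)
    lon = reg.table["longitude"].to_numpy(float)
    lat = reg.table["latitude"].to_numpy(float)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(lon[i], lat[i], lon[j], lat[j])
            mat[i, j] = mat[j, i] = d
    df = pd.DataFrame(mat, index=labels, columns=labels)
    neighbours = {}
    for i, li in enumerate(labels):
        others = [(mat[i, j], labels[j]) for j in range(n) if j != i]
        others.sort(key=lambda t: (t[0], t[1]))
        neighbours[li] = [lab for _, lab in others]
    return DistanceMatrix(df, neighbours)
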