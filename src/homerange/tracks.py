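"""Relocation data model: tracks, readers/writers, regularization, grouping.

A :class:`Track` is the time-ordered sequence of relocations of one sampling
instance (one animal in one period): planar coordinates in meters in a
projected CRS, timezone-aware timestamps (stored UTC), and an optional per-fix
HDOP (horizontal dilution of precision) used by the GPS-error model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import projection
from .errors import CRSError, SchemaError, TimestampParseError

__all__ = [
    "Track",
    "GroupedTracks",
    "make_track",
    "resample_track",
    "group_tracks",
    "floor_week",
    "read_tracks",
    "write_tracks",
    "track_to_geojson",
]

_WEEKDAYS = {
    "monday": 0,
    "tuesday": 1,
    "wednesday": 2,
    "thursday": 3,
    "friday": 4,
    "saturday": 5,
    "sunday": 6,
}


@dataclass
class Track:
    """Time-ordered relocations of one sampling instance.

    Parameters
    ----------
    x, y : ndarray of float
        Planar coordinates in meters (projected CRS).
    t : pandas.DatetimeIndex
        Timezone-aware fix times; stored in UTC; strictly increasing.
    id : str
        Label of the sampling instance (animal id, possibly animal-week).
    crs : int
        EPSG code of the coordinate system of ``x, y``.
    hdop : ndarray of float, optional
        Per-fix horizontal dilution of precision (positive).
    extra : pandas.DataFrame, optional
        Additional per-fix attributes, aligned with the fixes.
    """

    x: np.ndarray
    y: np.ndarray
    t: pd.DatetimeIndex
    id: str = "track"
    crs: int | None = None
    hdop: np.ndarray | None = None
    extra: pd.DataFrame | None = None
    is_geographic: bool = field(default=False)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        t = pd.DatetimeIndex(self.t)
        if t.tz is None:
            t = t.tz_localize("UTC")
        else:
            t = t.tz_convert("UTC")
        if not (len(self.x) == len(self.y) == len(t)):
            raise SchemaError("x, y and t must have equal length")
        if self.hdop is not None:
            self.hdop = np.asarray(self.hdop, dtype=float)
            if len(self.hdop) != len(t):
                raise SchemaError("hdop must have the same length as the fixes")
            with np.errstate(invalid="ignore"):
                bad = np.isinf(self.hdop) | (self.hdop <= 0)
            if bad.any():  # NaN allowed: missing per-fix quality, treated as 1
                raise SchemaError("hdop values must be positive (NaN = missing)")
        if len(t) and (np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y))):
            raise SchemaError("coordinates must be finite")

        order = np.argsort(t.values, kind="stable")
        self._reorder(order)
        t = pd.DatetimeIndex(t.values[order], tz="UTC")

        dup = t.duplicated(keep="first")
        if dup.any():
            warnings.warn(
                f"track {self.id!r}: dropped {int(dup.sum())} duplicate-timestamp fixes",
                stacklevel=2,
            )
            keep = ~dup
            self._reorder(np.flatnonzero(keep))
            t = t[keep]
        self.t = t

        if self.crs is not None and projection.is_geographic(self.crs):
            self.is_geographic = True
            warnings.warn(
                f"track {self.id!r} uses geographic EPSG:{self.crs}; "
                "reproject before calling any estimator",
                stacklevel=2,
            )

    def _reorder(self, idx):
        self.x = self.x[idx]
        self.y = self.y[idx]
        if self.hdop is not None:
            self.hdop = self.hdop[idx]
        if self.extra is not None:
            self.extra = self.extra.iloc[idx].reset_index(drop=True)

    def __len__(self):
        return len(self.t)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def seconds(self) -> np.ndarray:
        """Fix times as seconds since the first fix."""
        if not len(self.t):
            return np.empty(0)
        return (self.t - self.t[0]).total_seconds().to_numpy()

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.id, "x": self.x, "y": self.y, "t": self.t})
        if self.hdop is not None:
            df["hdop"] = self.hdop
        if self.extra is not None:
            for c in self.extra.columns:
                df[c] = self.extra[c].to_numpy()
        return df

    def require_projected(self):
        if self.crs is None or self.is_geographic:
            raise CRSError(
                f"track {self.id!r} needs a projected CRS (got "
                f"{'EPSG:' + str(self.crs) if self.crs else 'none'}); reproject first"
            )


@dataclass
class GroupedTracks:
    """Mapping from grouping key-tuples to :class:`Track` objects."""

    keys: list[str]
    groups: dict[tuple, Track]

    def sizes(self) -> dict[tuple, int]:
        return {k: len(v) for k, v in self.groups.items()}

    def filter_min_size(self, min_n: int) -> "GroupedTracks":
        """Keep groups with at least ``min_n`` fixes."""
        return GroupedTracks(
            self.keys, {k: v for k, v in self.groups.items() if len(v) >= min_n}
        )

    def __len__(self):
        return len(self.groups)

    def items(self):
        return self.groups.items()


def make_track(
    table: pd.DataFrame,
    x_col: str = "x",
    y_col: str = "y",
    t_col: str = "t",
    crs: int | None = None,
    id: str | None = None,
    hdop_col: str | None = None,
    extra_cols: list[str] | None = None,
) -> Track:
    """Build a :class:`Track` from a columnar table.

    The table is sorted by time; extra columns are retained as per-fix
    attributes. Timestamps must be parseable; naive times are taken as UTC.
    """
    for col in [x_col, y_col, t_col] + list(extra_cols or []) + (
        [hdop_col] if hdop_col else []
    ):
        if col not in table.columns:
            raise SchemaError(f"column {col!r} not found in input table")
    try:
        t = pd.to_datetime(table[t_col], utc=True, format="mixed")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(table[t_col], utc=True, errors="coerce", format="mixed")
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise TimestampParseError(bad, table[t_col].iloc[bad]) from None
    if t.isna().any():
        bad = int(np.flatnonzero(t.isna().to_numpy())[0])
        raise TimestampParseError(bad, table[t_col].iloc[bad])

    extra = None
    if extra_cols:
        extra = table[list(extra_cols)].reset_index(drop=True)
    return Track(
        x=table[x_col].to_numpy(dtype=float),
        y=table[y_col].to_numpy(dtype=float),
        t=pd.DatetimeIndex(t),
        id=id if id is not None else "track",
        crs=crs,
        hdop=table[hdop_col].to_numpy(dtype=float) if hdop_col else None,
        extra=extra,
    )


def resample_track(track: Track, interval, tolerance) -> Track:
    """Regularize a track to at most one fix per interval window.

    Windows are anchored at the first fix's time floored to ``interval``.
    Within each window the retained fix is the first whose offset from the
    window anchor is at most ``tolerance``; windows without such a fix stay
    empty (gaps are never interpolated — every output fix exists in the input).
    """
    interval = pd.Timedelta(interval)
    tolerance = pd.Timedelta(tolerance)
    if interval <= pd.Timedelta(0):
        raise ValueError("interval must be positive")
    if tolerance < pd.Timedelta(0):
        raise ValueError("tolerance must be nonnegative")
    if len(track) == 0:
        return track

    iv = interval.total_seconds()
    t0 = track.t[0].timestamp()
    anchor0 = np.floor(t0 / iv) * iv
    secs = track.t.asi8 / 1e9  # POSIX seconds
    window = np.floor((secs - anchor0) / iv).astype(np.int64)
    offset = secs - (anchor0 + window * iv)
    ok = offset <= tolerance.total_seconds() + 1e-9

    keep = []
    seen = set()
    for i in np.flatnonzero(ok):
        w = window[i]
        if w not in seen:
            seen.add(w)
            keep.append(i)
    keep = np.asarray(keep, dtype=int)
    return Track(
        x=track.x[keep],
        y=track.y[keep],
        t=track.t[keep],
        id=track.id,
        crs=track.crs,
        hdop=track.hdop[keep] if track.hdop is not None else None,
        extra=track.extra.iloc[keep].reset_index(drop=True)
        if track.extra is not None
        else None,
    )


def floor_week(t, week_start: str = "monday"):
    """Largest week boundary (00:00 on ``week_start``) at or before ``t``.

    Accepts a single timestamp or a datetime Series/Index; operates in the
    timestamp's own timezone.
    """
    wd = _WEEKDAYS[str(week_start).lower()]
    if isinstance(t, (pd.Series, pd.DatetimeIndex)):
        tt = pd.DatetimeIndex(t) if not isinstance(t, pd.Series) else pd.DatetimeIndex(t.values).tz_localize(t.dt.tz) if t.dt.tz is None else pd.DatetimeIndex(t)
        days = (tt.dayofweek - wd) % 7
        floored = tt.normalize() - pd.to_timedelta(days, unit="D")
        return floored
    ts = pd.Timestamp(t)
    days = (ts.dayofweek - wd) % 7
    return ts.normalize() - pd.Timedelta(days=days)


def group_tracks(
    table: pd.DataFrame,
    by: list[str],
    crs: int | None = None,
    x_col: str = "x",
    y_col: str = "y",
    t_col: str = "t",
    hdop_col: str | None = None,
) -> GroupedTracks:
    """Split a relocation table into one :class:`Track` per distinct key-tuple.

    Mirrors the nest-then-map pattern: the grouping columns become the keys,
    the remaining relocation columns the per-group track.
    """
    for col in by:
        if col not in table.columns:
            raise SchemaError(f"grouping column {col!r} not found")
    if hdop_col is None and "hdop" in table.columns:
        hdop_col = "hdop"
    groups: dict[tuple, Track] = {}
    for key, sub in table.groupby(by, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key)
        groups[key] = make_track(
            sub.reset_index(drop=True),
            x_col=x_col,
            y_col=y_col,
            t_col=t_col,
            crs=crs,
            id=label,
            hdop_col=hdop_col,
        )
    return GroupedTracks(list(by), groups)


# ---------------------------------------------------------------------------
# readers / writers

_GENERIC_COLS = {"x", "y", "t", "id"}
_MOVEBANK_COLS = {
    "location-long",
    "location-lat",
    "timestamp",
    "individual-local-identifier",
}


def read_tracks(path, dialect: str = "generic_csv", crs: int | None = None) -> pd.DataFrame:
    """Read a relocation table from CSV.

    ``generic_csv`` expects columns ``x, y, t, id`` (optional ``hdop``) with
    projected coordinates in meters; ``crs`` records their EPSG code.
    ``movebank_csv`` expects ``location-long, location-lat, timestamp,
    individual-local-identifier`` (optional ``gps:dop``) and **requires** a
    target projected ``crs`` onto which the coordinates are projected.

    Returns a tidy DataFrame with columns ``id, x, y, t[, hdop]`` and the EPSG
    code stored in ``df.attrs["crs"]``.
    """
    if dialect == "generic_csv":
        df = pd.read_csv(path)
        missing = {"x", "y", "t", "id"} - set(df.columns)
        if missing:
            raise SchemaError(f"generic_csv missing columns: {sorted(missing)}")
        df["t"] = pd.to_datetime(df["t"], utc=True, format="mixed")
        out = df[["id", "x", "y", "t"] + (["hdop"] if "hdop" in df.columns else [])]
        out = out.copy()
        out.attrs["crs"] = crs
        return out
    if dialect == "movebank_csv":
        if crs is None:
            raise CRSError(
                "movebank_csv carries geographic coordinates; a target projected "
                "EPSG code is required (pass crs=...)"
            )
        df = pd.read_csv(path)
        missing = _MOVEBANK_COLS - set(df.columns)
        if missing:
            raise SchemaError(f"movebank_csv missing columns: {sorted(missing)}")
        x, y = projection.project(
            df["location-long"].to_numpy(float), df["location-lat"].to_numpy(float), crs
        )
        out = pd.DataFrame(
            {
                "id": df["individual-local-identifier"].astype(str),
                "x": x,
                "y": y,
                "t": pd.to_datetime(df["timestamp"], utc=True, format="mixed"),
            }
        )
        if "gps:dop" in df.columns:
            out["hdop"] = df["gps:dop"].to_numpy(float)
        out.attrs["crs"] = crs
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tracks(table, path, dialect: str = "generic_csv"):
    """Write a relocation table (or Track) to CSV in the given dialect.

    Coordinates are written with full precision so that a write→read
    round-trip preserves values.
    """
    if isinstance(table, Track):
        table = table.to_dataframe()
    df = table.copy()
    df["t"] = pd.DatetimeIndex(df["t"]).tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    if dialect == "generic_csv":
        cols = ["id", "x", "y", "t"] + (["hdop"] if "hdop" in df.columns else [])
        df[cols].to_csv(path, index=False, float_format="%.10f")
        return
    raise ValueError(f"unknown dialect {dialect!r} for writing (use generic_csv)")


def track_to_geojson(track: Track) -> dict:
    """Export a track as a GeoJSON FeatureCollection of points."""
    feats = []
    for i in range(len(track)):
        props = {"id": track.id, "t": track.t[i].isoformat()}
        if track.hdop is not None:
            props["hdop"] = float(track.hdop[i])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(track.x[i]), float(track.y[i])]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(obj: dict, path):
    with open(path, "w") as fh:
        json.dump(obj, fh)
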