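"""Windowing and feature engineering for per-minute sensor/context streams.

Raw input is a long-form table of per-minute records (person, timestamp,
channel, value) plus a sparse table of self-reported emotion words.  The
pipeline resamples everything onto a 5-minute grid with mixed-type
aggregation (mean for continuous, sum for binary, max for ordinal),
tracks missingness per cell, imputes with a large negative sentinel,
standardizes using training rows only, and appends engineered temporal and
spatial columns.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import geohash_cluster, haversine_dist

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "KINDS",
    "QUARANTINE",
    "FeatureSchema",
    "SensorTable",
    "WindowedDataset",
    "read_sensor_table",
    "write_sensor_table",
    "resample_5min",
    "impute_and_standardize",
    "temporal_features",
    "location_features",
]

#: The seven closed feature categories.
CATEGORIES = (
    "motion",
    "audio",
    "location",
    "phone_state",
    "environmental",
    "temporal",
    "contextual",
)
KINDS = ("continuous", "binary", "ordinal")

#: Internal holding category for channels with unrecognized provenance;
#: excluded from modeling.
QUARANTINE = "quarantine"

#: ExtraSensory-dialect column prefixes -> (category, kind).
ES_PREFIXES = {
    "raw_acc": ("motion", "continuous"),
    "proc_gyro": ("motion", "continuous"),
    "raw_magnet": ("motion", "continuous"),
    "watch_acceleration": ("motion", "continuous"),
    "watch_heading": ("motion", "continuous"),
    "audio_naive": ("audio", "continuous"),
    "audio_properties": ("audio", "continuous"),
    "location": ("location", "continuous"),
    "location_quick_features": ("location", "continuous"),
    "discrete": ("phone_state", "binary"),
    "lf_measurements": ("environmental", "continuous"),
    "label": ("contextual", "binary"),
}
_CATEGORY_TO_ES_PREFIX = {
    "motion": "raw_acc",
    "audio": "audio_naive",
    "location": "location",
    "phone_state": "discrete",
    "environmental": "lf_measurements",
    "contextual": "label",
}

#: Default imputation sentinel: a large negative number far outside any
#: standardized feature range.
DEFAULT_SENTINEL = -1000.0

GRID = pd.Timedelta(minutes=5)
WINDOWS_PER_DAY = 288  # 24 * 60 / 5


@dataclass
class FeatureSchema:
    """Maps each channel name to a (category, kind) pair.

    Categories are the closed set :data:`CATEGORIES` (plus the internal
    quarantine bucket); kinds decide the within-window aggregator.
    """

    channels: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (cat, kind) in self.channels.items():
            if cat not in CATEGORIES and cat != QUARANTINE:
                raise ValueError(f"channel {name!r}: unknown category {cat!r}")
            if kind not in KINDS:
                raise ValueError(f"channel {name!r}: unknown kind {kind!r}")

    def category(self, channel: str) -> str:
        return self.channels[channel][0]

    def kind(self, channel: str) -> str:
        return self.channels[channel][1]

    def in_category(self, category: str) -> list[str]:
        return [c for c, (cat, _) in self.channels.items() if cat == category]

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def add(self, channel: str, category: str, kind: str) -> None:
        self.channels[channel] = (category, kind)
        self.__post_init__()

    # ------------------------------------------------------------------
    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {c: {"category": cat, "kind": kind} for c, (cat, kind) in self.channels.items()},
            indent=1,
        ))

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        raw = json.loads(Path(path).read_text())
        return cls({c: (v["category"], v["kind"]) for c, v in raw.items()})

    # ------------------------------------------------------------------
    @classmethod
    def build(
        cls,
        n_motion: int = 138,
        n_audio: int = 28,
        n_location: int = 17,
        n_phone: int = 28,
        n_environment: int = 6,
        n_context: int = 51,
    ) -> "FeatureSchema":
        """Construct a generic schema with the given channel counts.

        Defaults match the channel counts of the smartphone/smartwatch
        feature set this pipeline targets (138 motion, 28 audio, 17
        location + raw latitude/longitude, 28 phone-state, 6
        environmental, 51 contextual).  Scale the counts down for fast
        experiments; the shape of the pipeline does not change.
        """
        ch: dict[str, tuple[str, str]] = {}
        ch["latitude"] = ("location", "continuous")
        ch["longitude"] = ("location", "continuous")
        for i in range(n_motion):
            ch[f"motion_{i:03d}"] = ("motion", "continuous")
        for i in range(n_audio):
            ch[f"audio_{i:03d}"] = ("audio", "continuous")
        for i in range(n_location):
            ch[f"loc_feat_{i:03d}"] = ("location", "continuous")
        for i in range(n_phone):
            ch[f"phone_{i:03d}"] = ("phone_state", "binary")
        for i in range(n_environment):
            ch[f"env_{i:03d}"] = ("environmental", "continuous")
        for i in range(n_context):
            ch[f"ctx_{i:03d}"] = ("contextual", "binary")
        return cls(ch)

    @classmethod
    def compact(cls) -> "FeatureSchema":
        """A small schema (36 channels) for fast experiments and tests."""
        return cls.build(8, 4, 3, 6, 2, 10)


@dataclass
class SensorTable:
    """Long-form per-minute records plus sparse emotion self-reports.

    ``records`` has columns (person, timestamp, channel, value);
    ``events`` has columns (person, timestamp, emotion) and may be empty.
    """

    records: pd.DataFrame
    schema: FeatureSchema
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["person", "timestamp", "emotion"])
    )

    def persons(self) -> list[str]:
        ps = set(self.records["person"]) | set(self.events["person"])
        return sorted(ps)


@dataclass
class WindowedDataset:
    """Feature matrix on the 5-minute grid with a per-cell missingness mask.

    ``X`` is indexed by (person, window_start); ``mask`` is the same shape,
    True where no record contributed to the cell.  ``categories`` maps each
    column (raw channels and engineered columns alike) to its category,
    ``kinds`` to its value kind.  ``n_records`` counts the raw records per
    window (0-5 for per-minute input).  After standardization, ``scaler_mean``
    and ``scaler_scale`` hold the training-fit parameters.
    """

    X: pd.DataFrame
    mask: pd.DataFrame
    categories: dict[str, str]
    kinds: dict[str, str]
    n_records: pd.Series
    scaler_mean: pd.Series | None = None
    scaler_scale: pd.Series | None = None
    sentinel: float | None = None

    def copy(self) -> "WindowedDataset":
        return WindowedDataset(
            self.X.copy(), self.mask.copy(), dict(self.categories),
            dict(self.kinds), self.n_records.copy(),
            None if self.scaler_mean is None else self.scaler_mean.copy(),
            None if self.scaler_scale is None else self.scaler_scale.copy(),
            self.sentinel,
        )

    @property
    def persons(self) -> pd.Index:
        return self.X.index.get_level_values("person")

    @property
    def window_start(self) -> pd.Index:
        return self.X.index.get_level_values("window_start")


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def write_sensor_table(table: SensorTable, path, dialect: str = "generic") -> None:
    """Write a sensor table to CSV in the named dialect.

    generic
        ``<path>`` long CSV (person,timestamp,channel,value), a
        ``<path stem>.schema.json`` sidecar, and a ``<path stem>.events.csv``
        emotion-report table.
    extrasensory
        One wide CSV per person named ``<stem>.<person>.features_labels.csv``
        with unix-second timestamps and prefixed column names
        (``raw_acc:...``, ``label:...``), plus the shared events CSV.
    """
    path = Path(path)
    events = table.events.copy()
    if dialect == "generic":
        rec = table.records.copy()
        rec["timestamp"] = pd.to_datetime(rec["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        rec.to_csv(path, index=False)
        table.schema.to_json(path.with_suffix(".schema.json"))
    elif dialect == "extrasensory":
        for person, sub in table.records.groupby("person", sort=True):
            wide = sub.pivot_table(
                index="timestamp", columns="channel", values="value", aggfunc="last"
            )
            wide = wide.reindex(columns=[c for c in table.schema.names if c in wide.columns])
            wide.columns = [
                f"{_CATEGORY_TO_ES_PREFIX[table.schema.category(c)]}:{c}"
                for c in wide.columns
            ]
            wide.insert(0, "timestamp", (wide.index.astype("int64") // 10**9))
            out = path.with_suffix(f".{person}.features_labels.csv")
            wide.to_csv(out, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    events["timestamp"] = pd.to_datetime(events["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    events.to_csv(path.with_suffix(".events.csv"), index=False)


def read_sensor_table(
    path,
    dialect: str = "generic",
    person: str | None = None,
    events_path=None,
) -> SensorTable:
    """Read a per-minute sensor table from CSV.

    For the generic dialect, the schema sidecar ``<stem>.schema.json``
    must sit next to the CSV.  For the ExtraSensory dialect, ``path`` is
    one per-user wide CSV; the person id defaults to the filename stem and
    column prefixes are mapped to categories (``raw_acc:``/``proc_gyro:``/
    ... -> motion, ``audio_naive:`` -> audio, ``location:`` -> location,
    ``discrete:`` -> phone_state, ``lf_measurements:`` -> environmental,
    ``label:`` -> contextual).  Channels with an unknown prefix are routed
    to the quarantine category with a warning and excluded from modeling.
    """
    path = Path(path)
    events = pd.DataFrame(columns=["person", "timestamp", "emotion"])
    ev_path = Path(events_path) if events_path else path.with_suffix(".events.csv")
    if ev_path.exists():
        events = pd.read_csv(ev_path)
        if len(events):
            events["timestamp"] = pd.to_datetime(events["timestamp"])

    if dialect == "generic":
        try:
            rec = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            rec = pd.DataFrame(columns=["person", "timestamp", "channel", "value"])
        schema_path = path.with_suffix(".schema.json")
        schema = FeatureSchema.from_json(schema_path) if schema_path.exists() else FeatureSchema()
        if len(rec):
            rec["timestamp"] = pd.to_datetime(rec["timestamp"])
        return SensorTable(rec, schema, events)

    if dialect != "extrasensory":
        raise ValueError(f"unknown dialect {dialect!r}")

    wide = pd.read_csv(path)
    if person is None:
        person = path.stem.split(".")[-2] if path.stem.endswith(".features_labels") else path.stem
        person = person.removesuffix(".features_labels")
    ts = pd.to_datetime(wide.pop("timestamp"), unit="s")
    schema = FeatureSchema()
    renames = {}
    for col in wide.columns:
        prefix, _, rest = col.partition(":")
        if not rest:
            prefix, rest = "", col
        if prefix in ES_PREFIXES:
            cat, kind = ES_PREFIXES[prefix]
        else:
            warnings.warn(
                f"unknown column prefix {prefix!r} for {col!r}; "
                "routing channel to quarantine (excluded from modeling)",
                stacklevel=2,
            )
            cat, kind = QUARANTINE, "continuous"
            rest = col
        renames[col] = rest
        schema.add(rest, cat, kind)
    wide = wide.rename(columns=renames)
    wide.insert(0, "timestamp", ts)
    long = wide.melt(id_vars="timestamp", var_name="channel", value_name="value")
    long = long.dropna(subset=["value"])
    long.insert(0, "person", person)
    long = long.sort_values(["timestamp", "channel"], kind="stable").reset_index(drop=True)
    return SensorTable(long, schema, events[events["person"] == person].reset_index(drop=True)
                       if len(events) else events)


# ----------------------------------------------------------------------
# Resampling
# ----------------------------------------------------------------------

_AGG_BY_KIND = {"continuous": "mean", "binary": "sum", "ordinal": "max"}


def resample_5min(table: SensorTable) -> WindowedDataset:
    """Aggregate per-minute records onto the 5-minute grid.

    Continuous channels are averaged, binary channels summed, ordinal
    channels maximized within each window.  The grid runs from midnight of
    each person's first day to midnight after their last record, so a
    complete day contributes exactly 288 windows; windows with no records
    are fully masked.
    """
    schema = table.schema
    channels = [c for c in schema.names if schema.category(c) != QUARANTINE]
    rec = table.records
    if len(rec) and not rec["timestamp"].is_monotonic_increasing:
        logger.info("record timestamps out of order; sorting")
        rec = rec.sort_values("timestamp", kind="stable")

    frames = []
    masks = []
    counts = []
    persons = sorted(set(rec["person"])) if len(rec) else []
    for person in persons:
        sub = rec[rec["person"] == person]
        win = sub["timestamp"].dt.floor("5min")
        start = sub["timestamp"].min().normalize()
        end = (sub["timestamp"].max().normalize() + pd.Timedelta(days=1))
        grid = pd.date_range(start, end - GRID, freq="5min")

        agg = pd.DataFrame(index=grid, columns=channels, dtype=float)
        for kind, aggfunc in _AGG_BY_KIND.items():
            cols = [c for c in channels if schema.kind(c) == kind]
            if not cols:
                continue
            part = sub[sub["channel"].isin(cols)].assign(window_start=win)
            if len(part):
                p = part.pivot_table(
                    index="window_start", columns="channel", values="value",
                    aggfunc=aggfunc, observed=True,
                )
                agg.loc[p.index, p.columns.intersection(cols)] = p[p.columns.intersection(cols)]
        n_rec = (
            sub.assign(window_start=win)
            .groupby("window_start")["timestamp"].nunique()
            .reindex(grid, fill_value=0)
        )
        mask = agg.isna()
        idx = pd.MultiIndex.from_product([[person], grid], names=["person", "window_start"])
        agg.index = idx
        mask.index = idx
        n_rec.index = idx
        frames.append(agg)
        masks.append(mask)
        counts.append(n_rec)

    if frames:
        X = pd.concat(frames)
        mask = pd.concat(masks)
        n_records = pd.concat(counts).astype(int)
    else:
        idx = pd.MultiIndex.from_arrays([[], []], names=["person", "window_start"])
        X = pd.DataFrame(index=idx, columns=channels, dtype=float)
        mask = pd.DataFrame(True, index=idx, columns=channels)
        n_records = pd.Series([], index=idx, dtype=int)

    categories = {c: schema.category(c) for c in channels}
    kinds = {c: schema.kind(c) for c in channels}
    return WindowedDataset(X, mask, categories, kinds, n_records)


# ----------------------------------------------------------------------
# Imputation and standardization
# ----------------------------------------------------------------------

def impute_and_standardize(
    w: WindowedDataset,
    train_rows: np.ndarray | pd.Series,
    sentinel: float = DEFAULT_SENTINEL,
    sentinel_before_scaling: bool = False,
) -> WindowedDataset:
    """Standardize to training mean/unit variance and fill missing cells.

    Default mode fits the per-column mean and standard deviation on the
    *observed* training cells, applies them to observed cells everywhere,
    then fills masked cells with ``sentinel``.  With
    ``sentinel_before_scaling=True`` the sentinel is written first and the
    statistics are fit on all training rows, sentinel included (the order
    some pipelines use; it lets the sentinel dominate the statistics).
    Zero-variance columns get scale 1 so standardization is a no-op there.
    """
    train_rows = np.asarray(train_rows)
    if train_rows.dtype == bool:
        if not train_rows.any():
            raise ValueError("train_rows selects no rows")
    elif len(train_rows) == 0:
        raise ValueError("train_rows selects no rows")

    out = w.copy()
    X = out.X
    vals = X.to_numpy(dtype=float, copy=True)
    miss = out.mask.to_numpy(dtype=bool)

    rows = _row_indexer(train_rows, len(X))
    if sentinel_before_scaling:
        # strict order: sentinel first, statistics fit over everything
        vals[miss] = sentinel
        train = vals[rows]
        mean = np.nanmean(train, axis=0)
        std = np.nanstd(train, axis=0, ddof=0)
    else:
        train = vals[rows].copy()
        train[miss[rows]] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mean = np.nanmean(train, axis=0)
            std = np.nanstd(train, axis=0, ddof=0)
    fully_missing = np.isnan(mean)
    mean[fully_missing] = 0.0
    std[fully_missing] = 1.0
    zero_var = std == 0
    if zero_var.any():
        logger.info("zero-variance columns scaled by 1: %s",
                    list(X.columns[zero_var]))
        std[zero_var] = 1.0

    vals = (vals - mean) / std
    if not sentinel_before_scaling:
        vals[miss] = sentinel
    out.X = pd.DataFrame(vals, index=X.index, columns=X.columns)
    out.scaler_mean = pd.Series(mean, index=X.columns)
    out.scaler_scale = pd.Series(std, index=X.columns)
    out.sentinel = sentinel
    return out


def _row_indexer(train_rows: np.ndarray, n: int):
    if train_rows.dtype == bool:
        if len(train_rows) != n:
            raise ValueError("boolean train_rows length mismatch")
        return train_rows
    return np.asarray(train_rows, dtype=int)


# ----------------------------------------------------------------------
# Engineered features
# ----------------------------------------------------------------------

TEMPORAL_COLUMNS = (
    "minute_of_hour",
    "minute_of_day",
    "hour_of_day",
    "day_of_week",
    "time_diff_minutes",
)


def temporal_features(w: WindowedDataset) -> WindowedDataset:
    """Append the five temporal columns derived from the window start time.

    minute-of-hour, minute-of-day, hour-of-day, day-of-week (Monday=0) and
    the time difference in minutes since the person's previous non-empty
    window (0 for a person's first window).  The four calendar columns are
    ordinal; the time difference is continuous.  Temporal columns are never
    masked: the clock is always observed.
    """
    out = w.copy()
    ts = out.X.index.get_level_values("window_start")
    persons = out.X.index.get_level_values("person")
    out.X["minute_of_hour"] = ts.minute
    out.X["minute_of_day"] = ts.hour * 60 + ts.minute
    out.X["hour_of_day"] = ts.hour
    out.X["day_of_week"] = ts.dayofweek

    empty = out.n_records.to_numpy() == 0
    tdiff = np.zeros(len(out.X))
    minutes = (ts.asi8 // 60_000_000_000).astype(np.int64)
    pvals = persons.to_numpy()
    last_seen: dict[str, int] = {}
    for i in range(len(out.X)):
        p = pvals[i]
        if p in last_seen:
            tdiff[i] = minutes[i] - last_seen[p]
        if not empty[i]:
            last_seen[p] = minutes[i]
    out.X["time_diff_minutes"] = tdiff

    for col in TEMPORAL_COLUMNS:
        out.mask[col] = False
        out.categories[col] = "temporal"
        out.kinds[col] = "continuous" if col == "time_diff_minutes" else "ordinal"
    return out


LOCATION_COLUMNS = ("cl_latitude", "cl_longitude", "geo_dist")


def location_features(
    w: WindowedDataset,
    lat_col: str = "latitude",
    lon_col: str = "longitude",
    precision: int = 8,
) -> WindowedDataset:
    """Append geohash-clustered coordinates and travelled distance.

    ``cl_latitude``/``cl_longitude`` snap each observed coordinate pair to
    the centre of its precision-8 geohash cell; ``geo_dist`` is the
    haversine distance in metres from the person's previous observed
    position (0 at the first observed position).  All three are masked
    where the raw coordinates are.
    """
    out = w.copy()
    if lat_col not in out.X.columns or lon_col not in out.X.columns:
        raise ValueError(f"columns {lat_col!r}/{lon_col!r} not present")
    lat = out.X[lat_col].to_numpy()
    lon = out.X[lon_col].to_numpy()
    obs = ~(out.mask[lat_col].to_numpy() | out.mask[lon_col].to_numpy())
    cl_lat = np.full(len(lat), np.nan)
    cl_lon = np.full(len(lat), np.nan)
    dist = np.full(len(lat), np.nan)
    persons = out.X.index.get_level_values("person").to_numpy()
    prev_pos: dict[str, tuple[float, float]] = {}
    for i in range(len(lat)):
        if not obs[i]:
            continue
        cl_lat[i], cl_lon[i] = geohash_cluster(lat[i], lon[i], precision)
        p = persons[i]
        if p in prev_pos:
            dist[i] = haversine_dist(prev_pos[p], (lat[i], lon[i]))
        else:
            dist[i] = 0.0
        prev_pos[p] = (lat[i], lon[i])

    out.X["cl_latitude"] = cl_lat
    out.X["cl_longitude"] = cl_lon
    out.X["geo_dist"] = dist
    for col in LOCATION_COLUMNS:
        out.mask[col] = ~obs
        out.categories[col] = "location"
        out.kinds[col] = "continuous"
    return out
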