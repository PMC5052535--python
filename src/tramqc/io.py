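"""Reading, validating and writing per-cell tracking tables.

Image-analysis packages (Harmony, CellProfiler, Imaris, ...) export tracking
results as delimited text with one row per (cell, time point).  This module
assembles those rows into :class:`Track` / :class:`TrackSet` containers on a
uniform 0-based integer time grid, applies the first filtering step
(incomplete-track removal) and derives ratio features such as the
nuclear-to-cytoplasmic mean-intensity ratio.

The canonical on-disk representation is the *generic long format*: columns
``cell_id, time, x_um, y_um`` followed by one column per feature.  Other
dialects are described by a :class:`DialectSpec` column mapping, which can be
loaded from a YAML file so users can adapt to their software version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, TrackIntegrityError, TrackTableFormatError

__all__ = [
    "Track",
    "TrackSet",
    "DialectSpec",
    "DIALECTS",
    "read_track_table",
    "write_track_table",
    "split_complete",
    "SplitResult",
    "derive_ratio_feature",
    "filtering_report",
]


@dataclass(frozen=True)
class Track:
    """One cell's uniformly sampled time series of position and features.

    Parameters
    ----------
    cell_id:
        Opaque identifier, unique within a :class:`TrackSet`.
    times:
        Strictly increasing 0-based integer time indices on the experiment
        grid; real time is ``times * dt_minutes`` (held by the TrackSet).
    x, y:
        Positions in micrometres, finite everywhere.
    features:
        Mapping feature name -> series (same length as ``times``).  Feature
        values may be NaN ("flagged missing"); positions may not.
    """

    cell_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    features: Mapping[str, np.ndarray] = field(default_factory=dict)
    field_id: str | None = None
    well_id: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if times.ndim != 1 or len(times) == 0:
            raise TrackIntegrityError(f"track {self.cell_id!r}: empty time axis")
        if np.any(np.diff(times) <= 0):
            raise TrackIntegrityError(
                f"track {self.cell_id!r}: times must be strictly increasing"
            )
        if len(x) != len(times) or len(y) != len(times):
            raise TrackIntegrityError(
                f"track {self.cell_id!r}: position/time length mismatch"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrackIntegrityError(f"track {self.cell_id!r}: non-finite position")
        feats = {k: np.asarray(v, dtype=float) for k, v in self.features.items()}
        for name, series in feats.items():
            if len(series) != len(times):
                raise TrackIntegrityError(
                    f"track {self.cell_id!r}: feature {name!r} length mismatch"
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "features", feats)

    def __len__(self) -> int:
        return len(self.times)

    def is_complete(self, t_expected: int) -> bool:
        """True iff the track has a measurement at every grid point."""
        return len(self.times) == t_expected and self.times[0] == 0 and (
            self.times[-1] == t_expected - 1
        )

    def has_finite(self, feature_names: Iterable[str]) -> bool:
        """True iff every named feature is finite at every time point."""
        return all(
            name in self.features and bool(np.all(np.isfinite(self.features[name])))
            for name in feature_names
        )


@dataclass
class TrackSet:
    """A cohort of tracks sharing one time grid and acquisition metadata.

    ``t_expected`` is the full experiment length; a member track is
    *complete* iff it has all ``t_expected`` points.  ``metadata`` carries
    free-form condition labels (cell line, treatment, ...).
    """

    tracks: list[Track]
    dt_minutes: float = 1.0
    t_expected: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt_minutes <= 0:
            raise ConfigurationError("dt_minutes must be > 0")
        ids = [tr.cell_id for tr in self.tracks]
        if len(set(ids)) != len(ids):
            raise TrackIntegrityError("duplicate cell ids in TrackSet")

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def cell_ids(self) -> list[str]:
        return [tr.cell_id for tr in self.tracks]

    def get(self, cell_id: str) -> Track:
        for tr in self.tracks:
            if tr.cell_id == cell_id:
                return tr
        raise KeyError(cell_id)

    def complete_tracks(self) -> list[Track]:
        if self.t_expected is None:
            raise ConfigurationError("t_expected is not set on this TrackSet")
        return [tr for tr in self.tracks if tr.is_complete(self.t_expected)]

    def subset(self, cell_ids: Iterable[str]) -> "TrackSet":
        wanted = set(cell_ids)
        return TrackSet(
            tracks=[tr for tr in self.tracks if tr.cell_id in wanted],
            dt_minutes=self.dt_minutes,
            t_expected=self.t_expected,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class DialectSpec:
    """Column mapping describing one software's export schema.

    ``columns`` must map at least the keys ``cell_id``, ``time``, ``x`` and
    ``y`` to column names; the optional keys ``well`` and ``field`` map
    grouping identifiers.  ``feature_columns`` maps output feature names to
    source columns; ``None`` means "every remaining numeric column is a
    feature, named by its column header".
    """

    name: str
    columns: Mapping[str, str]
    feature_columns: Mapping[str, str] | None = None
    delimiter: str = ","
    decimal: str = "."

    def __post_init__(self) -> None:
        missing = {"cell_id", "time", "x", "y"} - set(self.columns)
        if missing:
            raise ConfigurationError(
                f"dialect {self.name!r} mapping lacks {sorted(missing)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            name=raw.get("name", Path(path).stem),
            columns=raw["columns"],
            feature_columns=raw.get("feature_columns"),
            delimiter=raw.get("delimiter", ","),
            decimal=raw.get("decimal", "."),
        )


# Default mappings for common export schemas.  Export headers vary with
# software version, so these are starting points meant to be overridden via
# DialectSpec.from_yaml when they do not match a given export.
DIALECTS: dict[str, DialectSpec] = {
    "generic": DialectSpec(
        name="generic",
        columns={"cell_id": "cell_id", "time": "time", "x": "x_um", "y": "y_um"},
    ),
    "harmony": DialectSpec(
        name="harmony",
        columns={
            "cell_id": "Object No",
            "time": "Timepoint",
            "x": "Position X [um]",
            "y": "Position Y [um]",
            "well": "Well",
            "field": "Field",
        },
        delimiter="\t",
    ),
    "cellprofiler": DialectSpec(
        name="cellprofiler",
        columns={
            "cell_id": "TrackObjects_Label",
            "time": "ImageNumber",
            "x": "Location_Center_X",
            "y": "Location_Center_Y",
        },
    ),
    "imaris": DialectSpec(
        name="imaris",
        columns={
            "cell_id": "TrackID",
            "time": "Time",
            "x": "Position X",
            "y": "Position Y",
        },
    ),
}


def _resolve_dialect(dialect: DialectSpec | str) -> DialectSpec:
    if isinstance(dialect, DialectSpec):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        ) from None


def read_track_table(
    path: str | Path,
    dialect: DialectSpec | str = "generic",
    *,
    dt_minutes: float = 1.0,
    t_expected: int | None = None,
    metadata: Mapping | None = None,
) -> TrackSet:
    """Read a delimited track table into a :class:`TrackSet`.

    Rows are grouped by cell id and sorted by time; the observed time values
    (which may be frame numbers or real times) are re-indexed to 0-based
    integers on the experiment grid.  Duplicate (cell, time) rows and
    non-numeric positions are rejected.

    ``t_expected`` defaults to the number of distinct time values in the
    table.  Reading is invariant to row order.
    """
    dialect = _resolve_dialect(dialect)
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        float_precision="round_trip",
    )

    for key in ("cell_id", "time", "x", "y"):
        col = dialect.columns[key]
        if col not in df.columns:
            raise TrackTableFormatError(
                f"mapped column {col!r} (for {key!r}) not found in {path}"
            )

    cid_col = dialect.columns["cell_id"]
    t_col = dialect.columns["time"]
    dup = df.duplicated(subset=[cid_col, t_col])
    if dup.any():
        first = df.loc[dup, [cid_col, t_col]].iloc[0]
        raise TrackIntegrityError(
            f"duplicate (cell, time) row: cell={first[cid_col]!r} "
            f"time={first[t_col]!r}"
        )

    for key in ("x", "y"):
        col = dialect.columns[key]
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrackTableFormatError(
                f"non-numeric position in column {col!r} at data row {row}"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise TrackTableFormatError(
                f"missing position in column {col!r} at data row {row}"
            )
        df[col] = vals

    # Re-index observed time values to 0-based integers on the grid.
    grid = np.sort(df[t_col].unique())
    index_of = {t: i for i, t in enumerate(grid)}
    df["_t"] = df[t_col].map(index_of)

    if dialect.feature_columns is not None:
        feat_map = dict(dialect.feature_columns)
        for name, col in feat_map.items():
            if col not in df.columns:
                raise TrackTableFormatError(
                    f"mapped feature column {col!r} (for {name!r}) not found"
                )
    else:
        reserved = {dialect.columns[k] for k in dialect.columns} | {"_t"}
        feat_map = {c: c for c in df.columns if c not in reserved}

    well_col = dialect.columns.get("well")
    field_col = dialect.columns.get("field")

    tracks = []
    for cid, grp in df.groupby(cid_col, sort=True):
        grp = grp.sort_values("_t")
        feats = {
            name: pd.to_numeric(grp[col], errors="coerce").to_numpy(dtype=float)
            for name, col in feat_map.items()
        }
        tracks.append(
            Track(
                cell_id=str(cid),
                times=grp["_t"].to_numpy(dtype=int),
                x=grp[dialect.columns["x"]].to_numpy(dtype=float),
                y=grp[dialect.columns["y"]].to_numpy(dtype=float),
                features=feats,
                well_id=str(grp[well_col].iloc[0]) if well_col else None,
                field_id=str(grp[field_col].iloc[0]) if field_col else None,
            )
        )

    return TrackSet(
        tracks=tracks,
        dt_minutes=dt_minutes,
        t_expected=t_expected if t_expected is not None else len(grid),
        metadata=dict(metadata or {}),
    )


def write_track_table(ts: TrackSet, path: str | Path) -> None:
    """Write a TrackSet in the generic long format (full float precision)."""
    feature_names = sorted({name for tr in ts for name in tr.features})
    rows = []
    for tr in ts:
        for j, t in enumerate(tr.times):
            row = {
                "cell_id": tr.cell_id,
                "time": int(t),
                "x_um": tr.x[j],
                "y_um": tr.y[j],
            }
            for name in feature_names:
                series = tr.features.get(name)
                row[name] = series[j] if series is not None else np.nan
            rows.append(row)
    # %.17g guarantees float64 round-trips exactly through text
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


@dataclass
class SplitResult:
    """Outcome of incomplete-track removal.

    Iterates as (complete, incomplete, summary) so it unpacks like a tuple.
    """

    complete: TrackSet
    incomplete: TrackSet
    summary: dict

    def __iter__(self):
        return iter((self.complete, self.incomplete, self.summary))


def split_complete(
    ts: TrackSet, *, require_features: Sequence[str] | None = None
) -> SplitResult:
    """Partition a TrackSet into complete and incomplete tracks.

    A track is complete iff it has a measurement at every one of the
    ``t_expected`` time points.  When ``require_features`` is given, tracks
    with a missing (NaN) value in any named feature are also routed to the
    incomplete set — downstream aberration scoring needs full series.

    The summary records counts and the incomplete fraction together with the
    set's condition metadata.
    """
    if ts.t_expected is None:
        raise ConfigurationError("t_expected must be set before splitting")
    complete, incomplete = [], []
    for tr in ts:
        ok = tr.is_complete(ts.t_expected)
        if ok and require_features is not None:
            ok = tr.has_finite(require_features)
        (complete if ok else incomplete).append(tr)
    mk = lambda trs: TrackSet(trs, ts.dt_minutes, ts.t_expected, dict(ts.metadata))
    n = len(ts)
    summary = {
        "n_total": n,
        "n_complete": len(complete),
        "n_incomplete": len(incomplete),
        "incomplete_fraction": (len(incomplete) / n) if n else 0.0,
        "condition": dict(ts.metadata),
    }
    return SplitResult(mk(complete), mk(incomplete), summary)


def derive_ratio_feature(
    ts: TrackSet,
    numerator: str,
    denominator: str,
    out: str,
    *,
    plausible_range: tuple[float, float] | None = None,
) -> TrackSet:
    """Add ``out = numerator / denominator`` pointwise to every track.

    A zero denominator flags the value missing (NaN) at that point.  The
    optional ``plausible_range`` gate additionally flags values outside
    ``(lo, hi)`` as missing — a QC range filter (off by default), not part of
    the aberration measure itself.
    """
    new_tracks = []
    for tr in ts:
        for name in (numerator, denominator):
            if name not in tr.features:
                raise KeyError(f"feature {name!r} absent on track {tr.cell_id!r}")
        num = tr.features[numerator]
        den = tr.features[denominator]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den == 0, np.nan, num / den)
        if plausible_range is not None:
            lo, hi = plausible_range
            ratio = np.where((ratio < lo) | (ratio > hi), np.nan, ratio)
        feats = dict(tr.features)
        feats[out] = ratio
        new_tracks.append(replace(tr, features=feats))
    return TrackSet(new_tracks, ts.dt_minutes, ts.t_expected, dict(ts.metadata))


def filtering_report(steps: Sequence[Mapping], path: str | Path | None = None) -> dict:
    """Assemble (and optionally write) a JSON report of filtering steps.

    ``steps`` is a sequence of summaries, e.g. from :func:`split_complete`
    and an aberration-threshold filter, in the order applied.
    """
    report = {"steps": [dict(s) for s in steps]}
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, default=float))
    return report
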