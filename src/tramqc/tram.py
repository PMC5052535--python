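"""The Tracking Aberration Measure (TrAM, τ).

Tracking failures in time-lapse microscopy — segmentation swaps, identity
exchanges, lost-and-reacquired objects — show up as sudden, unusually large
changes that hit several measured quantities at the same time point.  TrAM
scores each track by the single worst simultaneous deviation of its measured
time series from their smoothed baselines, in units of population-typical
frame-to-frame fluctuations:

    z_it  = |m_it − m̂_it| / s_i
    τ     = max_t [ (1/N) Σ_i z_it^p ]^(1/p)

where m̂ is a cubic regression-spline fit (default 5 knots), s_i is the
median absolute adjacent-frame difference of series i across the cohort, and
p = 0.5 by default.  Because p < 1 the aggregation is sub-additive: a given
total deviation scores highest when spread evenly across all series, making
τ sensitive to simultaneous jumps.  Well-tracked cells score τ of order 1;
larger values imply more aberrant tracks.  When (X, Y) positions are
included they enter as a single isotropic Euclidean term

    z_xy,t = sqrt( ((x_t − x̂_t)/s_xy)² + ((y_t − ŷ_t)/s_xy)² )

since the plain p-norm is anisotropic for p ≠ 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import ConfigurationError, TrackIntegrityError
from .io import Track, TrackSet

__all__ = [
    "TramParams",
    "ScaleTable",
    "TramResult",
    "FilterReport",
    "smooth_series",
    "fluctuation_scales",
    "tram_statistic",
    "compute_tram",
    "compute_tram_table",
    "tram_filter",
]


@dataclass(frozen=True)
class TramParams:
    """Parameters of the aberration measure.

    features:
        Names of the measured series entering τ (e.g. nuclear area and
        roundness).  Pick features that are not the assay's essential
        read-out, to avoid biasing it.
    p:
        Aggregation exponent in (0, 2]; p = 0.5 emphasizes simultaneous
        deviations across series.
    n_knots:
        Total knots of the cubic regression spline baseline; should reflect
        the credible temporal variability of the measurements.
    scale_quantile:
        Quantile of |adjacent differences| defining the fluctuation scale;
        the default median is robust to the few poorly tracked cells, a
        different quantile suits cohorts with more or fewer of them.
    use_euclidean_xy:
        Include (X, Y) as one isotropic Euclidean term.
    window:
        Optional half-open (start, end) time-index window; e.g. scoring only
        the first 30 points keeps the filter blind to late-occurring biology
        such as phototoxic shrinkage.
    """

    features: tuple[str, ...] = ()
    p: float = 0.5
    n_knots: int = 5
    scale_quantile: float = 0.5
    use_euclidean_xy: bool = True
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        if not (0 < self.p <= 2):
            raise ConfigurationError("p must be in (0, 2]")
        if self.n_knots < 3:
            raise ConfigurationError("n_knots must be >= 3")
        if not (0 < self.scale_quantile < 1):
            raise ConfigurationError("scale_quantile must be in (0, 1)")
        if not self.features and not self.use_euclidean_xy:
            raise ConfigurationError(
                "feature list empty and use_euclidean_xy false: nothing to score"
            )
        if self.window is not None:
            s, e = self.window
            if e - s < 4:
                raise ConfigurationError("window must span at least 4 points")

    def time_slice(self) -> slice:
        return slice(*self.window) if self.window is not None else slice(None)


@dataclass(frozen=True)
class ScaleTable:
    """Population fluctuation scales s_i (and s_xy), one condition.

    Scales are computed within a single condition (cell line × treatment)
    and must never be pooled across conditions: what counts as a typical
    fluctuation is population-specific.
    """

    features: Mapping[str, float]
    s_xy: float | None = None
    quantile: float = 0.5
    n_tracks: int = 0
    condition: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.features.items():
            if s < 0:
                raise ConfigurationError(f"negative scale for feature {name!r}")
        if self.s_xy is not None and self.s_xy < 0:
            raise ConfigurationError("negative s_xy")


@dataclass(frozen=True)
class TramResult:
    """Per-track aberration score.

    ``argmax_time`` is the grid index of the worst simultaneous fluctuation
    (smallest index on ties) and ``deviations`` the per-series normalized
    deviations z at that time point (key ``"xy"`` for the Euclidean term).
    """

    cell_id: str
    tau: float
    argmax_time: int
    deviations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


def _knot_vector(T: int, n_knots: int) -> tuple[float, ...]:
    t = np.arange(T, dtype=float)
    knots = np.quantile(t, np.linspace(0.0, 1.0, n_knots))
    full = np.r_[[knots[0]] * 3, knots, [knots[-1]] * 3]
    return tuple(full)


@lru_cache(maxsize=64)
def _hat_matrix(T: int, n_knots: int) -> np.ndarray:
    """Least-squares projection onto the cubic spline basis, cached per grid."""
    t = np.arange(T, dtype=float)
    full = np.asarray(_knot_vector(T, n_knots))
    B = BSpline.design_matrix(t, full, k=3).toarray()
    return B @ np.linalg.pinv(B)


def smooth_series(series: np.ndarray, n_knots: int = 5) -> np.ndarray:
    """Cubic regression-spline fit evaluated at the original time points.

    Knots sit at equally spaced quantiles of the time index.  For short
    series (T < n_knots + 2) the knot count is reduced to max(3, T − 2).
    Constants and exactly linear series are reproduced to numerical
    precision.
    """
    y = np.asarray(series, dtype=float)
    T = len(y)
    if T < 4:
        raise ValueError(f"series too short to smooth (T={T} < 4)")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    k = n_knots if T >= n_knots + 2 else max(3, T - 2)
    return _hat_matrix(T, k) @ y


def fluctuation_scales(ts: TrackSet, params: TramParams) -> ScaleTable:
    """Typical fluctuation scale of each series across the cohort.

    s_i is the ``scale_quantile`` (default median) of |m_{i,t+1,c} − m_{i,t,c}|
    pooled over all complete tracks c and adjacent time pairs t; s_xy is the
    same quantile of adjacent-frame Euclidean step lengths.  The median makes
    the scales insensitive to the large jumps of the few poorly tracked
    cells.  Scales are computed on the same time window τ will use, and —
    like τ itself — on drift-corrected positions.

    A population-constant feature (s_i = 0) carries no fluctuation scale; it
    is kept in the table but later dropped from τ with a warning.
    """
    w = params.time_slice()
    complete = ts.complete_tracks()
    for name in params.features:
        for tr in complete:
            if name not in tr.features:
                raise KeyError(f"feature {name!r} absent on track {tr.cell_id!r}")
    tracks = [tr for tr in complete if tr.has_finite(params.features)]
    if not tracks:
        raise ConfigurationError("no complete tracks with finite features")
    q = params.scale_quantile

    scales: dict[str, float] = {}
    for name in params.features:
        for tr in tracks:
            if name not in tr.features:
                raise KeyError(f"feature {name!r} absent on track {tr.cell_id!r}")
        diffs = np.concatenate(
            [np.abs(np.diff(tr.features[name][w])) for tr in tracks]
        )
        s = float(np.quantile(diffs, q))
        if s == 0.0:
            warnings.warn(
                f"feature {name!r} has zero fluctuation scale across the "
                "population; it will be dropped from the aberration measure",
                stacklevel=2,
            )
        scales[name] = s

    s_xy = None
    if params.use_euclidean_xy:
        steps = np.concatenate(
            [np.hypot(np.diff(tr.x[w]), np.diff(tr.y[w])) for tr in tracks]
        )
        s_xy = float(np.quantile(steps, q))
        if s_xy == 0.0:
            warnings.warn(
                "zero spatial fluctuation scale; the Euclidean XY term will "
                "be dropped from the aberration measure",
                stacklevel=2,
            )
    return ScaleTable(
        features=scales,
        s_xy=s_xy,
        quantile=q,
        n_tracks=len(tracks),
        condition=dict(ts.metadata),
    )


def tram_statistic(z: np.ndarray, p: float) -> tuple[float, int]:
    """Aggregate normalized deviations into (τ, argmax time index).

    ``z`` has shape (n_series, T) of non-negative normalized deviations.
    Per time point the mean-power aggregation [ (1/N) Σ z^p ]^(1/p) is taken,
    and τ is its maximum over time (first index on ties).  With z ≈ 1
    typical, τ ≈ 1 regardless of how many series are included.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] == 0:
        raise ValueError("z must be a (n_series, T) array with n_series >= 1")
    if np.any(z < 0):
        raise ValueError("deviations must be non-negative")
    per_time = np.mean(z**p, axis=0) ** (1.0 / p)
    idx = int(np.argmax(per_time))  # np.argmax returns the first maximum
    return float(per_time[idx]), idx


def compute_tram(track: Track, scales: ScaleTable, params: TramParams) -> TramResult:
    """Aberration score τ of one track.

    The track must be complete over the scoring window and the scales must
    come from the same condition.  Features with zero population scale are
    skipped (they carry no information about fluctuation size).
    """
    w = params.time_slice()
    terms: list[np.ndarray] = []
    names: list[str] = []
    for name in params.features:
        if name not in scales.features:
            raise ConfigurationError(f"no fluctuation scale for feature {name!r}")
        s = scales.features[name]
        if s == 0.0:
            continue
        m = track.features[name][w]
        z = np.abs(m - smooth_series(m, params.n_knots)) / s
        terms.append(z)
        names.append(name)
    if params.use_euclidean_xy and scales.s_xy:
        x, y = track.x[w], track.y[w]
        zx = (x - smooth_series(x, params.n_knots)) / scales.s_xy
        zy = (y - smooth_series(y, params.n_knots)) / scales.s_xy
        terms.append(np.hypot(zx, zy))
        names.append("xy")
    if not terms:
        raise ConfigurationError(
            "no usable series for TrAM (all scales zero or no terms configured)"
        )
    Z = np.vstack(terms)
    tau, local_idx = tram_statistic(Z, params.p)
    offset = params.window[0] if params.window is not None else 0
    return TramResult(
        cell_id=track.cell_id,
        tau=tau,
        argmax_time=offset + local_idx,
        deviations={name: float(Z[i, local_idx]) for i, name in enumerate(names)},
    )


def compute_tram_table(
    ts: TrackSet,
    params: TramParams,
    scales: ScaleTable | None = None,
) -> tuple[pd.DataFrame, ScaleTable]:
    """τ for every complete track of a cohort.

    Returns a table (cell_id, tau, argmax_time) and the scale table used
    (computed from the cohort itself unless supplied).
    """
    if scales is None:
        scales = fluctuation_scales(ts, params)
    rows = []
    for tr in ts.complete_tracks():
        if not tr.has_finite(params.features):
            continue
        res = compute_tram(tr, scales, params)
        rows.append(
            {"cell_id": res.cell_id, "tau": res.tau, "argmax_time": res.argmax_time}
        )
    return pd.DataFrame(rows, columns=["cell_id", "tau", "argmax_time"]), scales


@dataclass
class FilterReport:
    """Outcome of thresholding τ: tracks with τ > τ* are rejected."""

    tau_star: float
    kept_ids: list[str]
    rejected_ids: list[str]
    condition: dict = field(default_factory=dict)

    @property
    def rejected_fraction(self) -> float:
        n = len(self.kept_ids) + len(self.rejected_ids)
        return len(self.rejected_ids) / n if n else 0.0

    def summary(self) -> dict:
        return {
            "step": "tram_filter",
            "tau_star": self.tau_star,
            "n_kept": len(self.kept_ids),
            "n_rejected": len(self.rejected_ids),
            "rejected_fraction": self.rejected_fraction,
            "condition": dict(self.condition),
        }

    def to_json(self, path: str | Path) -> None:
        payload = self.summary()
        payload["kept_ids"] = list(self.kept_ids)
        payload["rejected_ids"] = list(self.rejected_ids)
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def tram_filter(
    ts: TrackSet,
    results: Mapping[str, TramResult] | pd.DataFrame,
    tau_star: float,
) -> FilterReport:
    """Reject every track whose τ exceeds the threshold τ*.

    ``results`` maps cell id -> :class:`TramResult`, or is a table with
    columns ``cell_id`` and ``tau``.  Every track in ``ts`` must have a
    result.
    """
    if isinstance(results, pd.DataFrame):
        taus = dict(zip(results["cell_id"].astype(str), results["tau"]))
    else:
        taus = {cid: res.tau for cid, res in results.items()}
    kept, rejected = [], []
    for tr in ts:
        if tr.cell_id not in taus:
            raise TrackIntegrityError(f"no TrAM result for track {tr.cell_id!r}")
        (rejected if taus[tr.cell_id] > tau_star else kept).append(tr.cell_id)
    return FilterReport(
        tau_star=float(tau_star),
        kept_ids=kept,
        rejected_ids=rejected,
        condition=dict(ts.metadata),
    )
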