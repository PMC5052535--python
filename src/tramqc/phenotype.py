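"""Post-filter phenotype evaluations.

Once incomplete and aberrant tracks are removed, the cleaned cohort supports
the downstream read-outs: per-cell mean speed on drift-corrected positions,
K-means clustering of feature time courses to surface subpopulations (e.g.
phototoxic nuclear shrinkage), mitosis detection from single-step nuclear
area increases, and threshold classification of responders (nuclear
translocation) or dead cells (caspase signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigurationError
from .io import Track, TrackSet

__all__ = [
    "SpeedRecord",
    "ClusterResult",
    "MitosisEvent",
    "mean_speed",
    "speed_table",
    "cluster_feature_trajectories",
    "detect_premitotic",
    "premitotic_rate",
    "classify_threshold_response",
    "compare_groups",
    "group_difference_model",
]


@dataclass(frozen=True)
class SpeedRecord:
    """Mean speed of one cell over an analysis window, μm/min."""

    cell_id: str
    speed_um_min: float
    n_steps: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.speed_um_min < 0:
            raise ValueError("speed must be >= 0")


def mean_speed(
    track: Track,
    dt_minutes: float,
    window: tuple[int, int] | None = None,
) -> SpeedRecord:
    """Mean frame-to-frame speed over a half-open index window.

    speed = mean over adjacent frames of Euclidean displacement / dt.
    Positions are assumed drift-corrected.  A window is used e.g. to skip
    the first frames affected by thermal shift.
    """
    start, end = window if window is not None else (0, len(track))
    if end - start < 2:
        raise ConfigurationError("speed window must span at least 2 frames")
    x, y = track.x[start:end], track.y[start:end]
    steps = np.hypot(np.diff(x), np.diff(y))
    return SpeedRecord(
        cell_id=track.cell_id,
        speed_um_min=float(steps.mean() / dt_minutes),
        n_steps=len(steps),
        window=(start, end),
    )


def speed_table(ts: TrackSet, window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Mean speed of every complete track, as a table."""
    recs = [mean_speed(tr, ts.dt_minutes, window) for tr in ts.complete_tracks()]
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in recs],
            "speed_um_min": [r.speed_um_min for r in recs],
            "n_steps": [r.n_steps for r in recs],
        }
    )


@dataclass
class ClusterResult:
    """K-means partition of feature time courses.

    ``stability`` is the mean pairwise adjusted Rand index between the
    assignments of ``n_runs`` random initializations; attend only to K
    values whose results are stable across runs.  The reported assignment
    comes from the run with the lowest within-cluster sum of squares.
    """

    k: int
    cell_ids: list[str]
    assignments: np.ndarray
    centers: np.ndarray
    stability: float
    inertia: float
    has_empty_cluster: bool = False

    def assignment_map(self) -> dict[str, int]:
        return dict(zip(self.cell_ids, (int(a) for a in self.assignments)))

    def cluster_fractions(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k) / len(self.assignments)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.assignments})


def cluster_feature_trajectories(
    ts: TrackSet,
    feature: str,
    k: int,
    n_runs: int = 10,
    seed: int = 0,
    *,
    normalize: bool = True,
) -> ClusterResult:
    """K-means clustering of one feature's time courses across the cohort.

    Trajectories are normalized to their first time-point value by default,
    so clusters reflect relative change (a nucleus shrinking to 40% of its
    starting area clusters together regardless of absolute size); set
    ``normalize=False`` to cluster raw values.  Uses complete tracks only —
    run incomplete-track removal and aberration filtering first.
    """
    if k < 2:
        raise ConfigurationError("K must be >= 2")
    tracks = [tr for tr in ts.complete_tracks() if tr.has_finite([feature])]
    if len(tracks) < k:
        raise ConfigurationError(f"need at least K={k} tracks, have {len(tracks)}")
    X = np.stack([tr.features[feature] for tr in tracks])
    if normalize:
        first = X[:, :1]
        if np.any(first == 0):
            raise ConfigurationError(
                "cannot normalize: zero feature value at the first time point"
            )
        X = X / first

    rng = np.random.default_rng(seed)
    labels_per_run, fits = [], []
    for _ in range(n_runs):
        km = KMeans(
            n_clusters=k,
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X)
        labels_per_run.append(km.labels_)
        fits.append(km)

    if n_runs > 1:
        pair_scores = [
            adjusted_rand_score(labels_per_run[i], labels_per_run[j])
            for i in range(n_runs)
            for j in range(i + 1, n_runs)
        ]
        stability = float(np.mean(pair_scores))
    else:
        stability = 1.0

    best = min(fits, key=lambda km: km.inertia_)
    counts = np.bincount(best.labels_, minlength=k)
    return ClusterResult(
        k=k,
        cell_ids=[tr.cell_id for tr in tracks],
        assignments=best.labels_.copy(),
        centers=best.cluster_centers_.copy(),
        stability=stability,
        inertia=float(best.inertia_),
        has_empty_cluster=bool((counts == 0).any()),
    )


@dataclass(frozen=True)
class MitosisEvent:
    """A single-step relative nuclear-area increase above threshold.

    ``time`` indexes the frame *before* the jump: an event at t means the
    step from t to t+1 exceeded the threshold.
    """

    cell_id: str
    time: int
    relative_change: float


def detect_premitotic(
    track: Track,
    area_feature: str = "area",
    threshold: float = 0.182,
) -> list[MitosisEvent]:
    """Detect candidate divisions from single-step nuclear area increases.

    An event fires at every t with (A_{t+1} − A_t)/A_t strictly greater than
    the threshold (increases only; the default 0.182 corresponds to an
    18.2% swell within one frame).  Detection depends only on relative
    changes, so it is invariant to rescaling the whole series.
    """
    a = np.asarray(track.features[area_feature], dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("area series must be positive and finite")
    rel = np.diff(a) / a[:-1]
    return [
        MitosisEvent(cell_id=track.cell_id, time=int(t), relative_change=float(r))
        for t, r in enumerate(rel)
        if r > threshold
    ]


def premitotic_rate(
    events_by_cell: Mapping[str, Sequence[MitosisEvent]],
    n_cells: int,
    hours_observed: float,
) -> float:
    """Fraction of the population entering mitosis per hour.

    Counts cells with at least one detected event, divided by
    (cells × hours observed).
    """
    if n_cells <= 0 or hours_observed <= 0:
        raise ValueError("n_cells and hours_observed must be positive")
    n_dividing = sum(1 for evs in events_by_cell.values() if len(evs) > 0)
    return n_dividing / (n_cells * hours_observed)


def classify_threshold_response(
    track: Track,
    feature: str,
    statistic: str = "change",
    threshold: float = 0.147,
) -> str:
    """Label a track "positive"/"negative" by thresholding a summary statistic.

    statistic:
        ``"change"`` — value at the last time point minus the first (e.g.
        nuclear/cytoplasmic intensity change for translocation responders);
        ``"max"`` — maximum over the time course (e.g. caspase
        signal-to-background: a cell dead at any point stays flagged).

    The comparison is strictly greater-than.
    """
    series = np.asarray(track.features[feature], dtype=float)
    if np.any(~np.isfinite(series)):
        raise ValueError(f"feature {feature!r} has missing values")
    if statistic == "change":
        value = series[-1] - series[0]
    elif statistic == "max":
        value = series.max()
    else:
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    return "positive" if value > threshold else "negative"


def compare_groups(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sided Welch t-test between two groups of per-cell values.

    Thin reporting wrapper (e.g. speeds of two cell lines); returns group
    means, SEMs, t and p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_a": float(a.mean()),
        "sem_a": float(stats.sem(a)),
        "mean_b": float(b.mean()),
        "sem_b": float(stats.sem(b)),
        "t": float(t),
        "p": float(p),
    }


def group_difference_model(values: Sequence[float], groups: Sequence) -> dict:
    """First-order linear model of a per-cell value on a two-level group.

    Thin wrapper over OLS; returns the group-difference estimate with its
    95% CI and p-value (e.g. translocation change, clonal vs polyclonal).
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ConfigurationError("group_difference_model needs exactly 2 groups")
    X = sm.add_constant((groups == levels[1]).astype(float))
    fit = sm.OLS(values, X).fit()
    lo, hi = fit.conf_int()[1]
    return {
        "difference": float(fit.params[1]),
        "ci95": (float(lo), float(hi)),
        "p": float(fit.pvalues[1]),
        "reference_level": levels[0],
        "comparison_level": levels[1],
    }
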