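"""Global plate-drift estimation and correction.

Well plates expand slightly during thermal equilibration, imprinting a common
translation on every tracked cell.  Assuming cells move randomly with no net
direction, the mean displacement of cells present at all time points
estimates the plate motion; subtracting it gives corrected positions used in
every downstream computation (speed, aberration scoring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DriftEstimationError
from .io import Track, TrackSet

__all__ = ["DriftPath", "estimate_global_drift", "apply_drift_correction"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriftPath:
    """Cumulative (dx, dy) plate displacement per time point, in μm.

    Displacement at time 0 is (0, 0) by construction; length equals the
    experiment grid length.
    """

    dx: np.ndarray
    dy: np.ndarray
    n_cells_used: int

    def __post_init__(self) -> None:
        dx = np.asarray(self.dx, dtype=float)
        dy = np.asarray(self.dy, dtype=float)
        if dx.shape != dy.shape or dx.ndim != 1:
            raise ValueError("dx and dy must be 1-D arrays of equal length")
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "dy", dy)

    def __len__(self) -> int:
        return len(self.dx)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time": np.arange(len(self)), "dx_um": self.dx, "dy_um": self.dy}
        ).to_csv(path, index=False)

    @classmethod
    def zero(cls, length: int) -> "DriftPath":
        return cls(np.zeros(length), np.zeros(length), n_cells_used=0)


def estimate_global_drift(ts: TrackSet, *, stat: str = "mean") -> DriftPath:
    """Estimate plate drift from the average motion of complete tracks.

    drift(t) = mean over complete tracks of (position_t − position_0),
    component-wise.  ``stat="median"`` substitutes the median for robustness
    against a few wildly mistracked cells.

    Only tracks present at every time point contribute; with none, a
    :class:`DriftEstimationError` is raised.
    """
    complete = ts.complete_tracks()
    if not complete:
        raise DriftEstimationError("no complete tracks to estimate drift from")
    X = np.stack([tr.x - tr.x[0] for tr in complete])  # (cells, T)
    Y = np.stack([tr.y - tr.y[0] for tr in complete])
    if stat == "mean":
        dx, dy = X.mean(axis=0), Y.mean(axis=0)
    elif stat == "median":
        dx, dy = np.median(X, axis=0), np.median(Y, axis=0)
    else:
        raise ValueError(f"unknown stat {stat!r}")

    # No guard exists for collectively migrating populations; flag when the
    # apparent drift is large relative to per-cell scatter.
    step = np.hypot(np.diff(dx), np.diff(dy))
    scatter = np.median(
        [np.median(np.hypot(np.diff(tr.x), np.diff(tr.y))) for tr in complete]
    )
    if scatter > 0 and np.any(step > scatter):
        log.warning(
            "estimated per-frame drift exceeds the median cell step; "
            "collective migration would be absorbed into the correction"
        )
    return DriftPath(dx=dx, dy=dy, n_cells_used=len(complete))


def apply_drift_correction(ts: TrackSet, drift: DriftPath) -> TrackSet:
    """Subtract the drift path from every track's positions.

    Incomplete tracks receive the same correction at the time points they
    possess — the drift is a property of the plate, not the cell.  All
    non-position features are preserved bit-exactly.
    """
    if ts.t_expected is not None and len(drift) != ts.t_expected:
        raise ValueError(
            f"drift length {len(drift)} does not match grid length {ts.t_expected}"
        )
    corrected: list[Track] = []
    for tr in ts:
        idx = tr.times
        if idx[-1] >= len(drift):
            raise ValueError(
                f"track {tr.cell_id!r} extends past the drift path length"
            )
        corrected.append(
            replace(tr, x=tr.x - drift.dx[idx], y=tr.y - drift.dy[idx])
        )
    return TrackSet(corrected, ts.dt_minutes, ts.t_expected, dict(ts.metadata))
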