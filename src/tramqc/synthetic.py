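"""Synthetic track cohorts with known ground truth.

Generates the statistical structure that time-lapse tracking exports exhibit:
random-walk motility on top of a global plate drift, smooth per-cell feature
dynamics with measurement noise, tracking-failure artifacts (simultaneous
additive jumps in several series and in position, modeling segmentation
swaps), debris tracks truncated to a sub-window (incomplete), and the
phenotype subpopulations used downstream — logistic translocation
responders, phototoxic nuclei shrinking over the second half of the course,
and pre-mitotic nuclear swelling with a single-step area jump at division.

One global seed drives a per-cell substream, so cohorts are bit-reproducible
and stable under reordering.  Presets mirror the four assay layouts this
kind of experiment uses (short motility, translocation, phototoxicity,
mitosis); see :class:`SimConfig` classmethods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io import Track, TrackSet

__all__ = ["FeatureSim", "ArtifactModel", "SimConfig", "GroundTruth", "simulate_trackset"]

# median |N(0, 2sigma^2)| / sigma: adjacent-difference fluctuation unit for
# white measurement noise of sd sigma
_DIFF_UNIT = np.sqrt(2.0) * 0.674489750196082
# median Rayleigh(sigma) / sigma: adjacent-frame step-length unit
_STEP_UNIT = np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class FeatureSim:
    """Generative model of one measured feature.

    The clean series is  baseline_c + trend_c(t) + noise, where baseline_c
    varies between cells (coefficient of variation ``baseline_cv``),
    trend_c is a smooth low-frequency excursion of random amplitude
    (sd ``trend_sd``) and the noise is white with sd ``noise_sd``.
    """

    baseline: float
    baseline_cv: float = 0.1
    trend_sd: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.trend_sd < 0 or self.baseline_cv < 0:
            raise ConfigurationError("feature model scales must be non-negative")


@dataclass(frozen=True)
class ArtifactModel:
    """Tracking-failure model: simultaneous additive jumps.

    ``prevalence`` is the probability a (non-debris) track is aberrant;
    ``jump_scale`` the jump magnitude in units of the typical adjacent-frame
    fluctuation of each affected series; ``n_features`` how many feature
    series are hit (None = all); the jump always also displaces the
    position, so at least two series move together.  The pulse lasts
    ``duration`` frames and then reverts — the measurement is wrong, not the
    cell.
    """

    prevalence: float = 0.17
    jump_scale: float = 10.0
    n_features: int | None = None
    duration: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ConfigurationError("artifact prevalence must be in [0, 1]")
        if self.jump_scale < 0:
            raise ConfigurationError("jump_scale must be >= 0")
        if self.duration < 1:
            raise ConfigurationError("duration must be >= 1")


def _default_features() -> dict[str, FeatureSim]:
    # Nuclear area (um^2) and roundness (dimensionless) of adherent cancer
    # cells at 20x: ~150 um^2 nuclei, near-round.
    return {
        "area": FeatureSim(baseline=150.0, baseline_cv=0.15, trend_sd=8.0, noise_sd=4.0),
        "roundness": FeatureSim(
            baseline=0.90, baseline_cv=0.03, trend_sd=0.02, noise_sd=0.015
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated cohort.

    Motility: isotropic Gaussian random-walk steps with per-component sd
    ``step_scale_um`` (0.32 μm at 1-min sampling gives a mean step length of
    ~0.40 μm/min, the speed range of the cancer lines this workflow
    targets), plus a constant per-frame plate drift.

    Subpopulations: fractions of responders (logistic nuclear/cytoplasmic
    intensity time course), phototoxic cells (area shrinking to
    ``terminal_area_fraction`` of baseline over the second half) and mitotic
    cells (gentle pre-division swelling ending in a single-step area jump of
    ``swell_fraction``); the remainder is stable (labeled "non-responder"
    when a translocation feature is simulated).
    """

    seed: int
    n_cells: int = 500
    n_timepoints: int = 25
    dt_minutes: float = 1.0
    step_scale_um: float = 0.32
    drift_per_frame_um: tuple[float, float] = (0.15, 0.10)
    field_size_um: float = 600.0
    features: Mapping[str, FeatureSim] = field(default_factory=_default_features)
    artifact: ArtifactModel = field(default_factory=ArtifactModel)
    debris_prob: float = 0.13
    # translocation subpopulation
    responder_fraction: float = 0.0
    translocation_feature: str = "nuc_cyto"
    translocation_baseline: float = 0.90
    translocation_amplitude: float = 0.60
    translocation_midpoint_min: float = 12.5
    translocation_rate_per_min: float = 0.5
    translocation_noise_sd: float = 0.02
    # phototoxic subpopulation
    phototoxic_fraction: float = 0.0
    terminal_area_fraction: float = 0.46
    # mitotic subpopulation
    mitotic_fraction: float = 0.0
    swell_fraction: float = 0.37

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ConfigurationError("n_timepoints must be >= 4")
        if self.dt_minutes <= 0 or self.step_scale_um <= 0:
            raise ConfigurationError("dt_minutes and step_scale_um must be positive")
        for name, frac in (
            ("debris_prob", self.debris_prob),
            ("responder_fraction", self.responder_fraction),
            ("phototoxic_fraction", self.phototoxic_fraction),
            ("mitotic_fraction", self.mitotic_fraction),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        total = self.responder_fraction + self.phototoxic_fraction + self.mitotic_fraction
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"subpopulation fractions sum to {total:.3f} > 1"
            )
        object.__setattr__(self, "features", dict(self.features))

    # ---- assay presets -------------------------------------------------

    @classmethod
    def motility(cls, seed: int, n_cells: int = 500, **kw) -> "SimConfig":
        """Short-term motility layout: 25 frames at 1-min increments."""
        return cls(seed=seed, n_cells=n_cells, n_timepoints=25, dt_minutes=1.0, **kw)

    @classmethod
    def translocation(cls, seed: int, n_cells: int = 500, **kw) -> "SimConfig":
        """Receptor-translocation layout: 31 frames at 1 min, mixed
        responders (57%) and non-responders, as in a polyclonal line."""
        kw.setdefault("responder_fraction", 0.57)
        return cls(seed=seed, n_cells=n_cells, n_timepoints=31, dt_minutes=1.0, **kw)

    @classmethod
    def phototoxicity(cls, seed: int, n_cells: int = 500, **kw) -> "SimConfig":
        """Extended imaging layout: 5 h at 5-min increments, 19% of nuclei
        shrinking below half their starting area."""
        kw.setdefault("phototoxic_fraction", 0.19)
        kw.setdefault("debris_prob", 0.31)
        return cls(seed=seed, n_cells=n_cells, n_timepoints=61, dt_minutes=5.0, **kw)

    @classmethod
    def mitosis(cls, seed: int, n_cells: int = 500, **kw) -> "SimConfig":
        """Proliferation layout: 20 h at 30-min increments; ~3% of cells
        divide per hour, swelling 37% in the step before division."""
        kw.setdefault("mitotic_fraction", 0.62)
        return cls(seed=seed, n_cells=n_cells, n_timepoints=40, dt_minutes=30.0, **kw)

    # ---- serialization -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "features" in raw:
            raw["features"] = {
                k: FeatureSim(**v) for k, v in raw["features"].items()
            }
        if "artifact" in raw:
            raw["artifact"] = ArtifactModel(**raw["artifact"])
        if "drift_per_frame_um" in raw:
            raw["drift_per_frame_um"] = tuple(raw["drift_per_frame_um"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["drift_per_frame_um"] = list(self.drift_per_frame_um)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class GroundTruth:
    """Per-cell labels consistent with the generated data by construction.

    track_quality in {good, aberrant, incomplete}; subpopulation in
    {stable, responder, non-responder, phototoxic, mitotic};
    artifact_times holds the frames at which jump pulses start.
    """

    track_quality: dict[str, str]
    subpopulation: dict[str, str]
    artifact_times: dict[str, tuple[int, ...]]

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(self.track_quality)
        return pd.DataFrame(
            {
                "cell_id": ids,
                "track_quality": [self.track_quality[i] for i in ids],
                "subpopulation": [self.subpopulation[i] for i in ids],
                "artifact_times": [
                    ";".join(map(str, self.artifact_times.get(i, ()))) for i in ids
                ],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, dtype={"cell_id": str}, keep_default_na=False)
        at = {}
        for cid, raw in zip(df["cell_id"], df["artifact_times"]):
            at[cid] = tuple(int(v) for v in str(raw).split(";") if v != "")
        return cls(
            track_quality=dict(zip(df["cell_id"], df["track_quality"])),
            subpopulation=dict(zip(df["cell_id"], df["subpopulation"])),
            artifact_times=at,
        )


def _smooth_trend(rng: np.random.Generator, T: int, sd: float) -> np.ndarray:
    """Low-frequency per-cell excursion: half a cycle over the course."""
    if sd == 0.0:
        return np.zeros(T)
    amp = rng.normal(0.0, sd)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    u = np.linspace(0.0, 1.0, T)
    return amp * np.sin(np.pi * u + phase)


def simulate_trackset(cfg: SimConfig) -> tuple[TrackSet, GroundTruth]:
    """Generate one cohort and its ground truth.

    Identical configs (same seed) give bit-identical output; every cell
    draws from its own random substream spawned from the global seed.
    """
    T = cfg.n_timepoints
    t_min = np.arange(T) * cfg.dt_minutes
    drift_x = np.arange(T) * cfg.drift_per_frame_um[0]
    drift_y = np.arange(T) * cfg.drift_per_frame_um[1]
    hour_frames = max(1, int(round(60.0 / cfg.dt_minutes)))

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_cells)
    tracks: list[Track] = []
    quality: dict[str, str] = {}
    subpop: dict[str, str] = {}
    artifact_times: dict[str, tuple[int, ...]] = {}
    has_transloc = cfg.responder_fraction > 0.0

    for c, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cid = f"c{c:05d}"

        # -- labels (fixed draw order keeps substreams reproducible) -----
        is_debris = rng.random() < cfg.debris_prob
        is_aberrant = (not is_debris) and (rng.random() < cfg.artifact.prevalence)
        u = rng.random()
        if u < cfg.responder_fraction:
            pop = "responder"
        elif u < cfg.responder_fraction + cfg.phototoxic_fraction:
            pop = "phototoxic"
        elif u < (
            cfg.responder_fraction + cfg.phototoxic_fraction + cfg.mitotic_fraction
        ):
            pop = "mitotic"
        else:
            pop = "non-responder" if has_transloc else "stable"

        # -- positions: drift + random walk ------------------------------
        x0 = rng.uniform(0.0, cfg.field_size_um)
        y0 = rng.uniform(0.0, cfg.field_size_um)
        steps = rng.normal(0.0, cfg.step_scale_um, size=(T - 1, 2))
        x = x0 + drift_x + np.concatenate(([0.0], np.cumsum(steps[:, 0])))
        y = y0 + drift_y + np.concatenate(([0.0], np.cumsum(steps[:, 1])))

        # -- features -----------------------------------------------------
        feats: dict[str, np.ndarray] = {}
        for name, fm in cfg.features.items():
            base = fm.baseline * (1.0 + fm.baseline_cv * rng.normal())
            series = base + _smooth_trend(rng, T, fm.trend_sd) + rng.normal(
                0.0, fm.noise_sd, size=T
            )
            feats[name] = series

        # subpopulation dynamics act multiplicatively on the area series
        if pop == "phototoxic" and "area" in feats:
            mult = np.ones(T)
            half = T // 2
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.linspace(0, 1, T - half)))
            mult[half:] = 1.0 + (cfg.terminal_area_fraction - 1.0) * ramp
            feats["area"] = feats["area"] * mult
        division_time = None
        if pop == "mitotic" and "area" in feats:
            division_time = int(rng.integers(max(2, hour_frames + 1), T))
            mult = np.ones(T)
            pre = np.arange(max(0, division_time - hour_frames), division_time)
            if len(pre):  # gentle swelling over the final pre-division hour
                mult[pre] = 1.0 + 0.08 * (pre - pre[0] + 1) / len(pre)
            mult[division_time:] = (1.0 + cfg.swell_fraction) * mult[
                division_time - 1
            ]
            feats["area"] = feats["area"] * mult

        if has_transloc:
            base = cfg.translocation_baseline + 0.05 * rng.normal()
            series = base + rng.normal(0.0, cfg.translocation_noise_sd, size=T)
            if pop == "responder":
                amp = max(0.2, cfg.translocation_amplitude + 0.15 * rng.normal())
                series = series + amp / (
                    1.0
                    + np.exp(
                        -cfg.translocation_rate_per_min
                        * (t_min - cfg.translocation_midpoint_min)
                    )
                )
            feats[cfg.translocation_feature] = series

        # -- tracking-failure pulse --------------------------------------
        if is_aberrant:
            t0 = int(rng.integers(1, max(2, T - cfg.artifact.duration)))
            sl = slice(t0, t0 + cfg.artifact.duration)
            names = list(cfg.features)
            if cfg.artifact.n_features is not None:
                k = min(cfg.artifact.n_features, len(names))
                names = list(rng.choice(names, size=k, replace=False))
            for name in names:
                unit = _DIFF_UNIT * cfg.features[name].noise_sd
                feats[name] = feats[name].copy()
                feats[name][sl] += rng.choice([-1.0, 1.0]) * cfg.artifact.jump_scale * unit
            theta = rng.uniform(0.0, 2.0 * np.pi)
            r = cfg.artifact.jump_scale * _STEP_UNIT * cfg.step_scale_um
            x = x.copy()
            y = y.copy()
            x[sl] += r * np.cos(theta)
            y[sl] += r * np.sin(theta)
            artifact_times[cid] = (t0,)
        else:
            artifact_times[cid] = ()

        # -- debris: truncate to a random sub-window ----------------------
        times = np.arange(T)
        if is_debris:
            L = int(rng.integers(4, T))  # < T, hence incomplete
            start = int(rng.integers(0, T - L + 1))
            keep = slice(start, start + L)
            times = times[keep]
            x, y = x[keep], y[keep]
            feats = {k: v[keep] for k, v in feats.items()}

        quality[cid] = (
            "incomplete" if is_debris else ("aberrant" if is_aberrant else "good")
        )
        subpop[cid] = pop
        tracks.append(Track(cell_id=cid, times=times, x=x, y=y, features=feats))

    ts = TrackSet(
        tracks=tracks,
        dt_minutes=cfg.dt_minutes,
        t_expected=T,
        metadata={"source": "tramqc.synthetic", "seed": cfg.seed},
    )
    return ts, GroundTruth(quality, subpop, artifact_times)
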