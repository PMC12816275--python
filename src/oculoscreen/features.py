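"""Per-trial oculomotor features in three families.

Saccadic (5): mean vectorial saccade velocity, mean vectorial amplitude,
inflection count (directional sign changes, horizontal plus vertical),
mean vectorial peak velocity, and the velocity-waveform indicator (OLS
slope relating per-saccade mean and peak velocity).

Fixation (3): mean fixation duration, fixation count, and the number of
regions of interest — data-driven single-linkage clusters of fixation
centroids that received concentrated attention (>= 2 member fixations).

Scanpath (3): Shannon entropy of the fixation distribution over a grid of
screen cells (gaze dispersion), scanpath length (summed centroid-to-
centroid distances), and scanpath area (convex hull of the centroids).

Features labelled deg/deg^2 can also be emitted in raw pixel units via
``units="px"``; missing features (e.g. no saccades in a trial) are NaN,
never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry, px_to_deg
from .event_detection import Fixation, OculomotorEvents, Saccade

__all__ = [
    "TrialFeatures",
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "saccade_summary",
    "velocity_waveform_indicator",
    "inflection_count",
    "fixation_summary",
    "roi_count",
    "shannon_entropy",
    "scanpath_length",
    "scanpath_area",
    "trial_features",
    "cohort_features",
]


@dataclass(frozen=True)
class TrialFeatures:
    mean_saccade_velocity: float
    mean_saccade_amplitude: float
    inflection_count: float
    mean_saccade_peak_velocity: float
    velocity_waveform_indicator: float
    mean_fixation_duration: float
    fixation_count: float
    roi_count: float
    shannon_entropy: float
    scanpath_length: float
    scanpath_area: float


FEATURE_NAMES = [f.name for f in dc_fields(TrialFeatures)]

FEATURE_FAMILIES = {
    "saccadic": ["mean_saccade_velocity", "mean_saccade_amplitude", "inflection_count",
                 "mean_saccade_peak_velocity", "velocity_waveform_indicator"],
    "fixation": ["mean_fixation_duration", "fixation_count", "roi_count"],
    "scanpath": ["shannon_entropy", "scanpath_length", "scanpath_area"],
}


def _centroids_px(fixations: list[Fixation]) -> np.ndarray:
    return np.array([[f.centroid_x, f.centroid_y] for f in fixations], dtype=float).reshape(-1, 2)


def _scale(geom: ScreenGeometry, units: str) -> float:
    """Small-displacement px->unit factor; exact conversions use px_to_deg."""
    if units == "px":
        return 1.0
    if units == "deg":
        return float(px_to_deg(1.0, 0.0, geom))
    raise ValueError(f"units must be 'deg' or 'px', got {units!r}")


def saccade_summary(events: OculomotorEvents, units: str = "deg",
                    geom: ScreenGeometry = DEFAULT_GEOMETRY) -> tuple[float, float, float]:
    """(mean velocity, mean amplitude, mean peak velocity) over all saccades."""
    sacc = events.saccades
    if not sacc:
        return (math.nan, math.nan, math.nan)
    if units == "deg":
        amps = [s.amplitude_deg for s in sacc]
        mean_v = [s.mean_velocity for s in sacc]
        peak_v = [s.peak_velocity for s in sacc]
    else:
        # pixel mode: velocities rescaled by the local px/deg factor
        f = 1.0 / _scale(geom, "deg")
        amps = [s.amplitude_px for s in sacc]
        mean_v = [s.mean_velocity * f for s in sacc]
        peak_v = [s.peak_velocity * f for s in sacc]
    return (float(np.mean(mean_v)), float(np.mean(amps)), float(np.mean(peak_v)))


def velocity_waveform_indicator(saccades: list[Saccade],
                                orientation: str = "mean_on_peak") -> float:
    """OLS slope between per-saccade mean and peak velocity.

    Default regresses mean velocity on peak velocity (slope < 1 for
    stereotyped velocity profiles); ``orientation="peak_on_mean"`` swaps
    the axes.  Requires >= 3 saccades and non-degenerate predictor
    variance.
    """
    if orientation not in ("mean_on_peak", "peak_on_mean"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if len(saccades) < 3:
        return math.nan
    mean_v = np.array([s.mean_velocity for s in saccades])
    peak_v = np.array([s.peak_velocity for s in saccades])
    x, y = (peak_v, mean_v) if orientation == "mean_on_peak" else (mean_v, peak_v)
    if np.var(x) == 0:
        return math.nan
    slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
    return float(slope)


def inflection_count(saccades: list[Saccade], jitter_floor_px: float = 1.0) -> int:
    """Directional changes across consecutive saccades (horizontal + vertical).

    A displacement component with magnitude at or below the jitter floor
    inherits the previous sign, so tracker noise does not flip directions.
    """
    if len(saccades) < 2:
        return 0
    count = 0
    for comp in ("dx", "dy"):
        prev_sign = 0
        for s in saccades:
            val = getattr(s, comp)
            sign = prev_sign if abs(val) <= jitter_floor_px else (1 if val > 0 else -1)
            if prev_sign != 0 and sign != 0 and sign != prev_sign:
                count += 1
            if sign != 0:
                prev_sign = sign
    return count


def fixation_summary(events: OculomotorEvents) -> tuple[float, int]:
    """(mean fixation duration ms, fixation count)."""
    fix = events.fixations
    if not fix:
        return (math.nan, 0)
    return (float(np.mean([f.duration for f in fix])), len(fix))


def roi_count(fixations: list[Fixation], link_radius_deg: float = 1.2,
              min_members: int = 2, geom: ScreenGeometry = DEFAULT_GEOMETRY) -> int:
    """Number of distinct regions receiving concentrated attention.

    Single-linkage clustering of fixation centroids with clusters cut at
    ``link_radius_deg``; only clusters with at least ``min_members``
    fixations count as concentrated attention.
    """
    pts = _centroids_px(fixations)
    if len(pts) == 0:
        return 0
    if len(pts) == 1:
        return int(min_members <= 1)
    deg = np.asarray(px_to_deg(pts[:, 0:1] - pts[:, 0:1].T,
                               pts[:, 1:2] - pts[:, 1:2].T, geom))
    # condensed distance matrix in degrees
    iu = np.triu_indices(len(pts), k=1)
    z = linkage(deg[iu], method="single")
    labels = fcluster(z, t=link_radius_deg, criterion="distance")
    _, counts = np.unique(labels, return_counts=True)
    return int(np.sum(counts >= min_members))


def shannon_entropy(fixations: list[Fixation], grid: tuple[int, int] = (8, 8),
                    geom: ScreenGeometry = DEFAULT_GEOMETRY,
                    bias_correction: str | None = "miller_madow") -> float:
    """Gaze-dispersion entropy (bits) of fixation counts over screen cells.

    The screen is partitioned into ``rows x cols`` equal cells and the
    Shannon entropy of the occupancy distribution is returned.  Higher
    values indicate more dispersed, irregular exploration.  The default
    Miller-Madow estimator adds the first-order small-sample correction
    ``(K - 1) / (2 n ln 2)`` (K = occupied cells), so trials with different
    fixation counts are compared on dispersion rather than sample size;
    ``bias_correction=None`` gives the plug-in estimate.
    """
    pts = _centroids_px(fixations)
    if len(pts) == 0:
        return math.nan
    rows, cols = grid
    r = np.clip((pts[:, 1] / geom.height_px * rows).astype(int), 0, rows - 1)
    c = np.clip((pts[:, 0] / geom.width_px * cols).astype(int), 0, cols - 1)
    _, counts = np.unique(r * cols + c, return_counts=True)
    n = counts.sum()
    p = counts / n
    h = float(-np.sum(p * np.log2(p)))
    if bias_correction == "miller_madow":
        h += (len(counts) - 1) / (2.0 * n * math.log(2.0))
    elif bias_correction is not None:
        raise ValueError(f"unknown bias_correction {bias_correction!r}")
    return h


def scanpath_length(fixations: list[Fixation], units: str = "deg",
                    geom: ScreenGeometry = DEFAULT_GEOMETRY) -> float:
    """Total centroid-to-centroid path length over the fixation sequence."""
    pts = _centroids_px(fixations)
    if len(pts) < 2:
        return 0.0
    d = np.diff(pts, axis=0)
    if units == "px":
        return float(np.hypot(d[:, 0], d[:, 1]).sum())
    return float(np.sum(px_to_deg(d[:, 0], d[:, 1], geom)))


def scanpath_area(fixations: list[Fixation], units: str = "deg",
                  geom: ScreenGeometry = DEFAULT_GEOMETRY) -> float:
    """Convex-hull area of the fixation centroids (deg^2 or px^2)."""
    pts = _centroids_px(fixations)
    if len(pts) < 3:
        return 0.0
    if units == "deg":
        # small-angle planar coordinates: px scaled by the per-pixel angle
        pts = pts * _scale(geom, "deg")
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0  # collinear / degenerate point set


def trial_features(
    events: OculomotorEvents,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    units: str = "deg",
    entropy_grid: tuple[int, int] = (8, 8),
    link_radius_deg: float = 1.2,
    roi_min_members: int = 2,
    vwi_orientation: str = "mean_on_peak",
    inflection_floor_px: float = 1.0,
) -> TrialFeatures:
    """All 11 features for one trial's events."""
    mean_v, mean_a, peak_v = saccade_summary(events, units, geom)
    mean_dur, n_fix = fixation_summary(events)
    return TrialFeatures(
        mean_saccade_velocity=mean_v,
        mean_saccade_amplitude=mean_a,
        inflection_count=float(inflection_count(events.saccades, inflection_floor_px)),
        mean_saccade_peak_velocity=peak_v,
        velocity_waveform_indicator=velocity_waveform_indicator(events.saccades, vwi_orientation),
        mean_fixation_duration=mean_dur,
        fixation_count=float(n_fix),
        roi_count=float(roi_count(events.fixations, link_radius_deg, roi_min_members, geom)),
        shannon_entropy=shannon_entropy(events.fixations, entropy_grid, geom),
        scanpath_length=scanpath_length(events.fixations, units, geom),
        scanpath_area=scanpath_area(events.fixations, units, geom),
    )


def cohort_features(events_by_trial: list[tuple[str, str, str, OculomotorEvents]],
                    geom: ScreenGeometry = DEFAULT_GEOMETRY,
                    **kwargs) -> pd.DataFrame:
    """Feature table: one row per (subject, trial) with the 11 feature columns.

    ``events_by_trial`` holds (subject_id, trial_id, stimulus_id, events).
    """
    rows = []
    for subject_id, trial_id, stimulus_id, events in events_by_trial:
        feats = trial_features(events, geom, **kwargs)
        row = {"subject_id": subject_id, "trial_id": trial_id, "stimulus_id": stimulus_id}
        row.update({name: getattr(feats, name) for name in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "trial_id", "stimulus_id",
                                       *FEATURE_NAMES])
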