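"""Scanpath-sequence alignment dissimilarity and similarity analyses.

Two scanpaths (time-ordered fixation sequences with positions in degrees
and durations in ms) are compared by global sequence alignment in the
scasim style: substituting fixation *i* for fixation *j* costs

    |d_i - d_j| * m**dist_ij  +  (d_i + d_j) * (1 - m**dist_ij)

where ``dist_ij`` is their spatial separation in degrees and ``m`` (the
modulation, default 0.83 per degree) controls how quickly spatially distant
fixations stop counting as matches; inserting or deleting a fixation costs
its duration.  Identical scanpaths align at zero cost, and the total cost
never exceeds the summed duration of both paths, so a normalised
dissimilarity ``d_norm = cost / (dur_a + dur_b)`` lies in [0, 1] and the
similarity transform ``s = 1 - d_norm`` lies in [0, 1] with 1 meaning
identical exploration.

Two study-level summaries are provided: intra-individual similarity (mean
over a subject's trial pairs — stability of an individual's exploration
style) and inter-individual similarity (mean over subject pairs of a group
viewing the same stimulus — group-level pattern consistency).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry, px_to_deg
from .event_detection import OculomotorEvents

__all__ = [
    "Scanpath",
    "scanpath_from_events",
    "scanpath_dissimilarity",
    "to_similarity",
    "pair_similarity",
    "intra_individual_similarity",
    "inter_individual_similarity",
]


@dataclass(frozen=True)
class Scanpath:
    """Fixation sequence: positions (deg), durations (ms)."""

    x: np.ndarray
    y: np.ndarray
    durations: np.ndarray
    subject_id: str = ""
    trial_id: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "durations", np.asarray(self.durations, dtype=float))
        if not (len(self.x) == len(self.y) == len(self.durations)):
            raise ValueError("x, y and durations must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("fixation durations must be positive")

    def __len__(self) -> int:
        return len(self.durations)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())


def scanpath_from_events(events: OculomotorEvents,
                         geom: ScreenGeometry = DEFAULT_GEOMETRY,
                         subject_id: str = "", trial_id: str = "",
                         stimulus_id: str = "") -> Scanpath:
    """Build a degree-coordinate scanpath from detected fixations."""
    fix = events.fixations
    scale = float(px_to_deg(1.0, 0.0, geom))
    return Scanpath(
        x=np.array([f.centroid_x for f in fix]) * scale,
        y=np.array([f.centroid_y for f in fix]) * scale,
        durations=np.array([max(f.duration, 1e-9) for f in fix]),
        subject_id=subject_id, trial_id=trial_id, stimulus_id=stimulus_id,
    )


def scanpath_dissimilarity(a: Scanpath, b: Scanpath,
                           modulation: float = 0.83,
                           normalize: bool = False) -> float:
    """Minimal duration-weighted alignment cost between two scanpaths.

    Non-negative, symmetric, and zero exactly for identical sequences.
    With ``normalize=True`` the cost is divided by the total duration of
    both scanpaths, giving a value in [0, 1].
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("scanpaths must be non-empty")
    if not (0 < modulation < 1):
        raise ValueError("modulation must lie in (0, 1)")
    da, db = a.durations, b.durations
    dist = np.hypot(a.x[:, None] - b.x[None, :], a.y[:, None] - b.y[None, :])
    mod = modulation ** dist
    sub = np.abs(da[:, None] - db[None, :]) * mod + (da[:, None] + db[None, :]) * (1 - mod)

    n, m = len(a), len(b)
    acc = np.empty((n + 1, m + 1))
    acc[0, 0] = 0.0
    acc[1:, 0] = np.cumsum(da)
    acc[0, 1:] = np.cumsum(db)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = min(
                acc[i - 1, j - 1] + sub[i - 1, j - 1],
                acc[i - 1, j] + da[i - 1],
                acc[i, j - 1] + db[j - 1],
            )
    cost = float(acc[n, m])
    if normalize:
        cost /= a.total_duration + b.total_duration
    return cost


def to_similarity(dissimilarity, method: str = "linear"):
    """Map normalised dissimilarities in [0, 1] to similarities in [0, 1].

    ``linear``: s = 1 - d.  ``exponential``: s = exp(-3 d) rescaled to hit 0
    at d = 1.  Both are strictly order-reversing.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if np.any(d < 0):
        raise ValueError("dissimilarities must be >= 0")
    if method == "linear":
        s = 1.0 - d
    elif method == "exponential":
        s = (np.exp(-3.0 * d) - np.exp(-3.0)) / (1.0 - np.exp(-3.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    s = np.clip(s, 0.0, 1.0)
    return s if s.ndim else float(s)


def pair_similarity(a: Scanpath, b: Scanpath, modulation: float = 0.83,
                    method: str = "linear") -> float:
    return float(to_similarity(
        scanpath_dissimilarity(a, b, modulation, normalize=True), method))


def intra_individual_similarity(scanpaths: list[Scanpath],
                                modulation: float = 0.83,
                                method: str = "linear") -> float:
    """Mean pairwise similarity across one subject's trials (NaN if < 2)."""
    paths = [p for p in scanpaths if len(p) > 0]
    if len(paths) < 2:
        return float("nan")
    sims = [pair_similarity(p, q, modulation, method)
            for p, q in combinations(paths, 2)]
    return float(np.mean(sims))


def inter_individual_similarity(scanpaths: list[Scanpath],
                                modulation: float = 0.83,
                                method: str = "linear") -> pd.Series:
    """Per-stimulus mean similarity over subject pairs of one group.

    Scanpaths are grouped by ``stimulus_id``; stimuli with fewer than two
    subjects are skipped.  Returns a Series indexed by stimulus (mean over
    stimuli = ``result.mean()``).
    """
    by_stim: dict[str, list[Scanpath]] = {}
    for p in scanpaths:
        if len(p) > 0:
            by_stim.setdefault(p.stimulus_id, []).append(p)
    out = {}
    for stim, paths in sorted(by_stim.items()):
        if len(paths) < 2:
            continue
        sims = [pair_similarity(p, q, modulation, method)
                for p, q in combinations(paths, 2)]
        out[stim] = float(np.mean(sims))
    return pd.Series(out, dtype=float)
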