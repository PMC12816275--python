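"""Gaze-stream container and cleaning rules.

Raw recordings arrive as one row per sample (timestamp, x, y, validity) at a
nominal 90 Hz.  Cleaning follows a fixed order:

1. blink removal — validity-0 runs whose duration falls inside a blink
   window (default 75-500 ms) are excised, together with a one-sample
   margin, and are never interpolated;
2. gap interpolation — remaining invalid runs strictly shorter than
   75 ms that are flanked by valid samples are filled linearly in x and y;
3. trial quality control — a trial is dropped when the fraction of samples
   still missing (invalid or blink-removed) exceeds 20%.

Blinks are exempt from filling because filled blink data would fabricate
gaze positions during eye closure; ordering blink removal first keeps the
two rules consistent.  Sample count and timestamps are never altered by any
step — only positions and flags change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GazeTrial", "QCResult", "interpolate_gaps", "remove_blinks", "qc_trial", "preprocess_trial"]


@dataclass
class GazeTrial:
    """One subject's raw sample stream for one stimulus.

    ``valid`` marks samples with a usable gaze position; ``removed`` marks
    samples excised as blink artifacts (a subset of the originally invalid
    samples plus a margin).  Usable samples are ``valid & ~removed``.
    """

    subject_id: str
    trial_id: str
    stimulus_id: str
    t: np.ndarray          # ms, strictly increasing
    x: np.ndarray          # px
    y: np.ndarray          # px
    valid: np.ndarray      # bool
    sampling_hz: float = 90.0
    removed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.removed is None:
            self.removed = np.zeros(self.t.shape, dtype=bool)
        else:
            self.removed = np.asarray(self.removed, dtype=bool)
        n = len(self.t)
        if not all(len(a) == n for a in (self.x, self.y, self.valid, self.removed)):
            raise ValueError("all sample arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"timestamps must be strictly increasing in trial {self.trial_id!r}")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_hz

    @property
    def usable(self) -> np.ndarray:
        return self.valid & ~self.removed

    @property
    def duration_ms(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.t[-1] - self.t[0]) + self.dt_ms

    def copy(self) -> "GazeTrial":
        return replace(
            self,
            t=self.t.copy(), x=self.x.copy(), y=self.y.copy(),
            valid=self.valid.copy(), removed=self.removed.copy(),
        )


@dataclass(frozen=True)
class QCResult:
    keep: bool
    missing_frac: float


def _invalid_runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop exclusive)."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        yield int(start), int(stop)


def _run_duration_ms(trial: GazeTrial, start: int, stop: int) -> float:
    """Gap duration: span between flanking samples minus one nominal interval.

    Measured between the last valid sample before the run and the first
    valid sample after it, which is robust to timestamp jitter.  Edge runs
    (no flanking sample) fall back to the timestamp span plus one interval.
    """
    if start > 0 and stop < trial.n_samples:
        return float(trial.t[stop] - trial.t[start - 1]) - trial.dt_ms
    return float(trial.t[stop - 1] - trial.t[start]) + trial.dt_ms


def remove_blinks(
    trial: GazeTrial,
    blink_min_ms: float = 75.0,
    blink_max_ms: float = 500.0,
    margin_samples: int = 1,
) -> GazeTrial:
    """Classify validity-0 runs as blinks by duration and excise them.

    A run whose duration lies in ``[blink_min_ms, blink_max_ms]`` is marked
    removed together with ``margin_samples`` adjacent samples on each side
    (the tracker typically reports distorted positions at lid closure and
    reopening).  Removed samples are excluded from interpolation and from
    event detection.
    """
    out = trial.copy()
    for start, stop in _invalid_runs(~out.valid):
        dur = _run_duration_ms(out, start, stop)
        if blink_min_ms <= dur <= blink_max_ms:
            lo = max(0, start - margin_samples)
            hi = min(out.n_samples, stop + margin_samples)
            out.removed[lo:hi] = True
            out.valid[lo:hi] = False
    return out


def interpolate_gaps(trial: GazeTrial, max_gap_ms: float = 75.0) -> GazeTrial:
    """Fill short missing runs by linear interpolation between flanking samples.

    Only maximal invalid runs strictly shorter than ``max_gap_ms`` that are
    flanked by valid samples on both sides and contain no blink-removed
    samples are filled.  Longer runs, edge runs and blink runs stay invalid.
    Idempotent: a second application is a no-op.
    """
    out = trial.copy()
    if not out.valid.any():
        warnings.warn(
            f"trial {out.trial_id!r} has no valid samples; returned unchanged",
            stacklevel=2,
        )
        return out
    for start, stop in _invalid_runs(~out.valid):
        if out.removed[start:stop].any():
            continue
        if start == 0 or stop == out.n_samples:
            continue
        if _run_duration_ms(out, start, stop) >= max_gap_ms:
            continue
        t0, t1 = out.t[start - 1], out.t[stop]
        frac = (out.t[start:stop] - t0) / (t1 - t0)
        out.x[start:stop] = out.x[start - 1] + frac * (out.x[stop] - out.x[start - 1])
        out.y[start:stop] = out.y[start - 1] + frac * (out.y[stop] - out.y[start - 1])
        out.valid[start:stop] = True
    return out


def qc_trial(trial: GazeTrial, max_missing_frac: float = 0.20) -> QCResult:
    """Keep/drop decision after cleaning.

    The missing fraction counts samples still invalid or blink-removed
    against the number of samples expected at the nominal rate over the
    recorded span; the trial is dropped only when the fraction is strictly
    greater than ``max_missing_frac``.
    """
    if trial.n_samples == 0:
        return QCResult(keep=False, missing_frac=1.0)
    n_expected = max(trial.n_samples, int(round(trial.duration_ms / trial.dt_ms)))
    n_missing = int(np.sum(~trial.usable)) + (n_expected - trial.n_samples)
    frac = n_missing / n_expected
    return QCResult(keep=frac <= max_missing_frac, missing_frac=float(frac))


def preprocess_trial(
    trial: GazeTrial,
    max_gap_ms: float = 75.0,
    blink_min_ms: float = 75.0,
    blink_max_ms: float = 500.0,
    blink_margin_samples: int = 1,
    max_missing_frac: float = 0.20,
) -> tuple[GazeTrial, QCResult]:
    """Full cleaning chain: blink removal -> gap interpolation -> QC."""
    cleaned = remove_blinks(trial, blink_min_ms, blink_max_ms, blink_margin_samples)
    cleaned = interpolate_gaps(cleaned, max_gap_ms)
    return cleaned, qc_trial(cleaned, max_missing_frac)
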