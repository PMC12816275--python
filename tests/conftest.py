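"""Shared fixtures: geometry, constructed trials, small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from oculoscreen import CohortSpec, GazeTrial, ScreenGeometry, simulate_cohort

DT = 1000.0 / 90.0  # nominal sample interval, ms


@pytest.fixture(scope="session")
def geom() -> ScreenGeometry:
    return ScreenGeometry()


def make_trial(x, y, valid=None, subject="s1", trial="t1", stimulus="stim1",
               hz: float = 90.0) -> GazeTrial:
    """Trial from explicit position arrays on a uniform 90 Hz clock."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeTrial(subject_id=subject, trial_id=trial, stimulus_id=stimulus,
                     t=np.arange(n) * (1000.0 / hz), x=x,
                     y=np.asarray(y, dtype=float), valid=np.asarray(valid, dtype=bool),
                     sampling_hz=hz)


def make_schedule_trial(schedule, geom: ScreenGeometry, hz: float = 90.0,
                        main_seq=(2.2, 21.0)) -> tuple[GazeTrial, list]:
    """Noise-free trial from an explicit fixation schedule.

    ``schedule`` = [((x, y), duration_ms), ...]; consecutive fixations are
    joined by linear position ramps whose duration follows the
    amplitude-duration main-sequence rule.  Returns the trial and the
    intended (x, y, onset, offset) per fixation, with epoch boundaries
    snapped to the sample clock so intended durations are exact.
    """
    from oculoscreen import px_to_deg

    dt = 1000.0 / hz
    xs, ys, intended = [], [], []
    clock = 0.0
    for idx, ((cx, cy), dur) in enumerate(schedule):
        n_fix = int(round(dur / dt))
        onset = clock
        xs.extend([cx] * n_fix)
        ys.extend([cy] * n_fix)
        clock += n_fix * dt
        intended.append((cx, cy, onset, clock - dt))
        if idx + 1 < len(schedule):
            nx, ny = schedule[idx + 1][0]
            amp = px_to_deg(nx - cx, ny - cy, geom)
            ramp_ms = main_seq[0] * amp + main_seq[1]
            n_ramp = max(1, int(round(ramp_ms / dt)))
            frac = (np.arange(1, n_ramp + 1)) / (n_ramp + 1)
            xs.extend(cx + frac * (nx - cx))
            ys.extend(cy + frac * (ny - cy))
            clock += n_ramp * dt
    return make_trial(xs, ys, hz=hz), intended


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with default effects (deterministic)."""
    spec = CohortSpec(n_subjects_per_group=(4, 4), n_trials=3, seed=42)
    return spec, simulate_cohort(spec)
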