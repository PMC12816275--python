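"""Synthetic free-viewing gaze generator for two cohorts.

No public gaze dataset accompanies the screening protocol this package
analyses, so cohort-level behaviour is emulated by simulation.  A trial is
an alternation of fixation epochs (position = fixation centre + isotropic
jitter, duration log-normal) and saccade epochs (minimum-jerk position ramp
between centres, duration from a main-sequence rule), sampled at a nominal
90 Hz over 10 s, with blink gaps and random sample loss injected on top.

Group differences are injected so that the impaired ("case") cohort shows
the directions reported for stroke free viewing — longer and fewer
fixations, smaller and slower saccades, shorter scanpaths, smaller explored
area, fewer attended regions — while gaze-dispersion entropy stays matched:

* the per-fixation spatial distribution — a mixture of facial anchor
  regions (eyes, nose, mouth) plus occasional wider excursions — is shared
  between groups, so the *set* of fixation locations in a trial is
  identically distributed up to the excursion extent factor and fixation
  count; fewer fixations mechanically yield fewer regions with
  concentrated (>= 2 fixations) attention and a smaller convex hull;
* the saccade-amplitude factor acts by ordering that set with a
  locality bias (nearest-remaining-first with some probability) instead of
  scaling positions, which shortens saccades and scanpaths without moving
  the spatial marginal;
* the fixation-duration and saccade-rate factors lengthen dwell times,
  which lowers the fixation count within the fixed trial duration.

Subject idiosyncrasy (a per-subject duration multiplier, spatial offset and
locality shift, constant across trials) makes a subject's scanpaths more
similar to each other than to other subjects', mirroring the observed
intra- vs inter-individual similarity structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry, px_to_deg
from .preprocessing import GazeTrial

__all__ = [
    "GroupEffects",
    "CohortSpec",
    "SubjectParams",
    "Cohort",
    "simulate_trial",
    "simulate_cohort",
    "GROUP_CONTROL",
    "GROUP_CASE",
]

GROUP_CONTROL = "control"
GROUP_CASE = "case"


@dataclass(frozen=True)
class GroupEffects:
    """Multiplicative shifts applied to the impaired group.

    Defaults are calibrated so the *detected* feature ratios approximate
    the reported group-mean ratios (case / control ~ 1.16 for fixation
    duration, ~0.86 for saccade amplitude): the dwell multiplier is set
    slightly below the target ratio because velocity-threshold detection
    merges some of the impaired group's small saccades, lengthening
    detected fixations; the saccade-rate and exploration-extent factors
    have no directly printed ratio and default to mild reductions.
    """

    fixation_duration: float = 1.07   # >1: longer dwells
    saccade_amplitude: float = 0.86   # <1: shorter saccades (via ordering locality)
    saccade_rate: float = 0.98        # <1: fewer saccades per second
    exploration_extent: float = 0.75  # <1: shorter far excursions from the face core

    def __post_init__(self) -> None:
        for name in ("fixation_duration", "saccade_amplitude", "saccade_rate", "exploration_extent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"group effect {name} must be > 0")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject random effects, constant across that subject's trials.

    The ``*_gain`` exponents form an impairment profile: for an impaired
    subject each group factor is applied as ``factor ** gain``, so one
    patient may be mostly dwell-affected and another mostly
    amplitude-affected — mimicking lesion heterogeneity.  Gains average 1
    and are inert for controls (1 ** gain = 1).
    """

    duration_mult: float = 1.0
    offset_x_px: float = 0.0
    offset_y_px: float = 0.0
    locality_shift: float = 0.0
    anchor_weights: tuple[float, ...] | None = None  # None -> spec defaults
    duration_gain: float = 1.0
    amplitude_gain: float = 1.0
    extent_gain: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for cohort simulation.

    ``n_subjects_per_group`` may be a single count or an
    ``(n_control, n_case)`` pair.  The trial schedule defaults (10 trials
    of 10 s at 90 Hz on a 1920x1080 screen at 70 cm) match the screening
    protocol; generator internals (spread, jitter, main-sequence
    constants) are exposed so degenerate schedules can be constructed for
    testing.
    """

    n_subjects_per_group: int | tuple[int, int] = 20
    n_trials: int = 10
    trial_duration_ms: float = 10_000.0
    sampling_hz: float = 90.0
    group_effects: GroupEffects = field(default_factory=GroupEffects)
    blink_rate_per_s: float = 0.25
    missing_frac: float = 0.02
    seed: int = 0

    # generator internals
    base_fixation_ms: float = 300.0       # control-group log-normal mean
    fixation_log_sd: float = 0.40
    jitter_px: float = 5.0                # isotropic within-fixation noise
    # facial anchor regions (px offsets from screen centre) and visit weights:
    # left eye, right eye, nose, mouth, brow, left cheek, right cheek
    anchor_points_px: tuple[tuple[float, float], ...] = (
        (-120.0, -90.0), (120.0, -90.0), (0.0, -10.0), (0.0, 140.0),
        (0.0, -160.0), (-170.0, 40.0), (170.0, 40.0))
    anchor_weights: tuple[float, ...] = (0.21, 0.19, 0.15, 0.13, 0.10, 0.11, 0.11)
    anchor_scatter_px: float = 25.0       # per-fixation scatter around an anchor
    wide_rate_per_trial: float = 4.0      # mean excursion fixations per trial (Poisson)
    wide_spread_px: tuple[float, float] = (280.0, 210.0)  # excursion SD (x, y)
    extent_tail_sd: float = 0.9           # radius (in SD units) beyond which the extent factor bites
    locality_gain: float = 1.9            # maps (1 - amplitude factor) -> ordering bias
    subject_duration_sd: float = 0.06     # log-scale SD of the per-subject duration RE
    subject_offset_sd_px: float = 80.0
    subject_locality_sd: float = 0.05
    subject_weight_conc: float = 60.0     # Dirichlet concentration of per-subject anchor weights
    case_heterogeneity_sd: float = 0.6    # log-SD of per-case-subject effect-expression gains
    blink_dur_ms: tuple[float, float] = (100.0, 300.0)
    main_seq_slope_ms_per_deg: float = 2.2
    main_seq_intercept_ms: float = 21.0
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        n = self.n_subjects_per_group
        counts = (n, n) if isinstance(n, int) else tuple(n)
        if len(counts) != 2 or any(int(c) <= 0 for c in counts):
            raise ValueError("n_subjects_per_group must be a positive count or pair")
        if self.n_trials <= 0 or self.trial_duration_ms <= 0 or self.sampling_hz <= 0:
            raise ValueError("counts, durations and rates must be positive")
        if not (0 <= self.missing_frac < 1):
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.blink_rate_per_s < 0:
            raise ValueError("blink_rate_per_s must be >= 0")
        if len(self.anchor_points_px) != len(self.anchor_weights):
            raise ValueError("anchor_points_px and anchor_weights must match in length")
        if any(w < 0 for w in self.anchor_weights) or sum(self.anchor_weights) <= 0:
            raise ValueError("anchor_weights must be non-negative and sum to > 0")

    @property
    def group_sizes(self) -> tuple[int, int]:
        n = self.n_subjects_per_group
        return (n, n) if isinstance(n, int) else (int(n[0]), int(n[1]))


@dataclass
class Cohort:
    """Simulated trials plus subject-to-group labels."""

    trials: list[GazeTrial]
    groups: dict[str, str]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.groups)

    def labels(self) -> np.ndarray:
        return np.array([self.groups[s] for s in self.subject_ids])


def _mean_fixation_ms(spec: CohortSpec, group: str, subject: SubjectParams) -> float:
    eff = spec.group_effects
    mean = spec.base_fixation_ms * subject.duration_mult
    if group == GROUP_CASE:
        mean *= (eff.fixation_duration / eff.saccade_rate) ** subject.duration_gain
    return mean


def _locality(spec: CohortSpec, group: str, subject: SubjectParams) -> float:
    base = 0.0
    if group == GROUP_CASE:
        amp = spec.group_effects.saccade_amplitude ** subject.amplitude_gain
        base = (1.0 - amp) * spec.locality_gain
    return float(np.clip(base + subject.locality_shift, 0.0, 1.0))


def _draw_centers(spec: CohortSpec, group: str, subject: SubjectParams,
                  n: int, rng: np.random.Generator) -> np.ndarray:
    """Fixation locations: facial-anchor mixture plus occasional excursions.

    The anchor mixture is identical for both groups (up to per-subject
    idiosyncrasy); only the excursion spread is scaled down for the
    impaired group via the exploration-extent factor.
    """
    cx, cy = spec.geometry.center_px
    cx += subject.offset_x_px
    cy += subject.offset_y_px
    weights = np.asarray(subject.anchor_weights if subject.anchor_weights is not None
                         else spec.anchor_weights, dtype=float)
    weights = weights / weights.sum()
    anchors = np.asarray(spec.anchor_points_px, dtype=float)

    which = rng.choice(len(anchors), size=n, p=weights)
    pts = anchors[which] + rng.standard_normal((n, 2)) * spec.anchor_scatter_px
    # excursions arrive at a fixed temporal rate (independent of how many
    # fixations a group makes), so the number of occupied off-face cells —
    # the main entropy driver — is matched between groups; the extent
    # factor contracts only radii beyond ``extent_tail_sd`` SDs, shrinking
    # the hull extremes while leaving the cell-occupancy mass distribution
    # essentially unchanged
    wx, wy = spec.wide_spread_px
    extent = (spec.group_effects.exploration_extent ** subject.extent_gain
              if group == GROUP_CASE else 1.0)
    n_wide = min(n, int(rng.poisson(spec.wide_rate_per_trial)))
    if n_wide:
        wide = rng.choice(n, size=n_wide, replace=False)
        z = rng.standard_normal((n_wide, 2))
        r = np.hypot(z[:, 0], z[:, 1])
        r0 = spec.extent_tail_sd
        with np.errstate(invalid="ignore"):
            shrink = np.where(r > r0, (r0 + (r - r0) * extent) / np.maximum(r, 1e-12), 1.0)
        pts[wide] = z * shrink[:, None] * (wx, wy)
    pts += (cx, cy)
    np.clip(pts[:, 0], 1.0, spec.geometry.width_px - 1.0, out=pts[:, 0])
    np.clip(pts[:, 1], 1.0, spec.geometry.height_px - 1.0, out=pts[:, 1])
    return pts


def _order_centers(pts: np.ndarray, locality: float, rng: np.random.Generator) -> np.ndarray:
    """Visit order over the fixation set: nearest-remaining with prob `locality`."""
    n = len(pts)
    remaining = list(range(n))
    current = remaining.pop(rng.integers(len(remaining)))
    order = [current]
    while remaining:
        if locality > 0 and rng.random() < locality:
            d2 = ((pts[remaining] - pts[current]) ** 2).sum(axis=1)
            idx = int(np.argmin(d2))
        else:
            idx = int(rng.integers(len(remaining)))
        current = remaining.pop(idx)
        order.append(current)
    return pts[order]


def _min_jerk(frac: np.ndarray) -> np.ndarray:
    return 10 * frac**3 - 15 * frac**4 + 6 * frac**5


def simulate_trial(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    subject: SubjectParams = SubjectParams(),
    subject_id: str = "s00",
    trial_id: str = "t00",
    stimulus_id: str = "stim00",
) -> GazeTrial:
    """Simulate one raw gaze trial for a subject of the given group."""
    if group not in (GROUP_CONTROL, GROUP_CASE):
        raise ValueError(f"unknown group {group!r}")
    mean_fix = _mean_fixation_ms(spec, group, subject)
    if mean_fix >= spec.trial_duration_ms:
        raise ValueError(
            f"impossible schedule: mean fixation duration {mean_fix:.0f} ms "
            f">= trial duration {spec.trial_duration_ms:.0f} ms"
        )
    dt = 1000.0 / spec.sampling_hz
    n_samples = int(round(spec.trial_duration_ms / dt))
    t = np.arange(n_samples) * dt

    # fixation schedule: draw generously, truncate at the trial end
    # draw barely more centres than the schedule will consume: the ordered
    # fixation set is truncated at the trial end, and a large surplus would
    # let the locality-biased ordering under-sample its tail
    typical_saccade_ms = spec.main_seq_slope_ms_per_deg * 4.0 + spec.main_seq_intercept_ms
    n_draw = int(math.ceil(spec.trial_duration_ms / (mean_fix + typical_saccade_ms))) + 3
    mu = math.log(mean_fix) - spec.fixation_log_sd**2 / 2.0
    durations = rng.lognormal(mu, spec.fixation_log_sd, size=n_draw)
    centers = _order_centers(
        _draw_centers(spec, group, subject, n_draw, rng),
        _locality(spec, group, subject),
        rng,
    )

    x = np.empty(n_samples)
    y = np.empty(n_samples)
    clock = 0.0
    i = 0
    k = 0  # fixation index
    while i < n_samples:
        # fixation epoch
        end = min(clock + durations[k], spec.trial_duration_ms)
        j = min(n_samples, int(math.ceil(end / dt - 1e-9)))
        if j > i:
            m = j - i
            x[i:j] = centers[k, 0] + rng.standard_normal(m) * spec.jitter_px
            y[i:j] = centers[k, 1] + rng.standard_normal(m) * spec.jitter_px
            i = j
        clock = end
        if clock >= spec.trial_duration_ms or k + 1 >= n_draw:
            if i < n_samples:  # pad any rounding remainder with the last fixation
                m = n_samples - i
                x[i:] = centers[k, 0] + rng.standard_normal(m) * spec.jitter_px
                y[i:] = centers[k, 1] + rng.standard_normal(m) * spec.jitter_px
                i = n_samples
            break
        # saccade epoch to the next centre (minimum-jerk ramp)
        amp_deg = px_to_deg(centers[k + 1, 0] - centers[k, 0],
                            centers[k + 1, 1] - centers[k, 1], spec.geometry)
        sacc_ms = spec.main_seq_slope_ms_per_deg * amp_deg + spec.main_seq_intercept_ms
        end = min(clock + sacc_ms, spec.trial_duration_ms)
        j = min(n_samples, int(math.ceil(end / dt - 1e-9)))
        if j > i:
            frac = np.clip((t[i:j] - clock) / sacc_ms, 0.0, 1.0)
            s = _min_jerk(frac)
            x[i:j] = centers[k, 0] + s * (centers[k + 1, 0] - centers[k, 0])
            y[i:j] = centers[k, 1] + s * (centers[k + 1, 1] - centers[k, 1])
            i = j
        clock = end
        k += 1

    valid = np.ones(n_samples, dtype=bool)
    # blinks: Poisson arrivals, uniform duration
    if spec.blink_rate_per_s > 0:
        clock_s = rng.exponential(1.0 / spec.blink_rate_per_s)
        while clock_s * 1000.0 < spec.trial_duration_ms:
            b0 = clock_s * 1000.0
            b1 = b0 + rng.uniform(*spec.blink_dur_ms)
            valid[(t >= b0) & (t < b1)] = False
            clock_s += rng.exponential(1.0 / spec.blink_rate_per_s)
    # additional isolated sample loss
    if spec.missing_frac > 0:
        valid &= rng.random(n_samples) >= spec.missing_frac

    return GazeTrial(
        subject_id=subject_id, trial_id=trial_id, stimulus_id=stimulus_id,
        t=t, x=x, y=y, valid=valid, sampling_hz=spec.sampling_hz,
    )


def _draw_subject(spec: CohortSpec, rng: np.random.Generator) -> SubjectParams:
    weights = np.asarray(spec.anchor_weights, dtype=float)
    weights = weights / weights.sum()
    subject_weights = tuple(rng.dirichlet(weights * spec.subject_weight_conc))
    het = spec.case_heterogeneity_sd
    gains = rng.lognormal(-het ** 2 / 2.0, het, size=3) if het > 0 else np.ones(3)
    return SubjectParams(
        duration_mult=float(rng.lognormal(0.0, spec.subject_duration_sd)),
        offset_x_px=float(rng.standard_normal() * spec.subject_offset_sd_px),
        offset_y_px=float(rng.standard_normal() * spec.subject_offset_sd_px),
        locality_shift=float(rng.standard_normal() * spec.subject_locality_sd),
        anchor_weights=subject_weights,
        duration_gain=float(gains[0]),
        amplitude_gain=float(gains[1]),
        extent_gain=float(gains[2]),
    )


def simulate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> Cohort:
    """Simulate both cohorts: every subject sees the same stimulus sequence.

    Reproducible: the same ``(spec, seed)`` yields bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_control, n_case = spec.group_sizes
    trials: list[GazeTrial] = []
    groups: dict[str, str] = {}
    for group, count, prefix in ((GROUP_CONTROL, n_control, "ctrl"),
                                 (GROUP_CASE, n_case, "case")):
        for s in range(count):
            subject_id = f"{prefix}{s + 1:02d}"
            groups[subject_id] = group
            subject = _draw_subject(spec, rng)
            for tr in range(spec.n_trials):
                trials.append(simulate_trial(
                    spec, group, rng, subject,
                    subject_id=subject_id,
                    trial_id=f"t{tr + 1:02d}",
                    stimulus_id=f"stim{tr + 1:02d}",
                ))
    return Cohort(trials=trials, groups=groups)
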