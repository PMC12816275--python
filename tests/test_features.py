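"""The 11 per-trial features against independent brute-force oracles."""

import math

import numpy as np
import pytest

from oculoscreen import (OculomotorEvents, ScreenGeometry, deg_to_px,
                         fixation_summary, inflection_count, px_to_deg,
                         roi_count, saccade_summary, scanpath_area,
                         scanpath_length, shannon_entropy, trial_features,
                         velocity_waveform_indicator)
from oculoscreen.event_detection import Fixation, Saccade

GEOM = ScreenGeometry()


def fix(x, y, dur=200.0, onset=0.0):
    return Fixation(onset=onset, offset=onset + dur, centroid_x=x, centroid_y=y)


def sacc(dx, dy, mean_v=100.0, peak_v=180.0):
    amp_px = math.hypot(dx, dy)
    return Saccade(onset=0, offset=30, dx=dx, dy=dy,
                   amplitude_deg=float(px_to_deg(dx, dy, GEOM)), amplitude_px=amp_px,
                   mean_velocity=mean_v, peak_velocity=peak_v)


def random_events(rng, n_fix=None, n_sacc=None) -> OculomotorEvents:
    n_fix = int(rng.integers(1, 12)) if n_fix is None else n_fix
    n_sacc = int(rng.integers(1, 10)) if n_sacc is None else n_sacc
    fixations = [fix(rng.uniform(50, 1870), rng.uniform(50, 1030),
                     dur=rng.uniform(60, 600)) for _ in range(n_fix)]
    saccades = []
    for _ in range(n_sacc):
        mean_v = rng.uniform(30, 300)
        saccades.append(sacc(rng.uniform(-400, 400), rng.uniform(-300, 300),
                             mean_v=mean_v, peak_v=mean_v * rng.uniform(1.0, 3.0)))
    return OculomotorEvents(fixations=fixations, saccades=saccades)


# --- saccade summaries -----------------------------------------------------

def test_saccade_summary_single():
    ev = OculomotorEvents(saccades=[sacc(100, 0, mean_v=100, peak_v=180)])
    ev.saccades[0] = Saccade(onset=0, offset=30, dx=100, dy=0, amplitude_deg=5.0,
                             amplitude_px=100, mean_velocity=100, peak_velocity=180)
    assert saccade_summary(ev) == (100.0, 5.0, 180.0)


def test_saccade_summary_hand_sum_oracle():
    rng = np.random.default_rng(1)
    ev = random_events(rng, n_fix=1, n_sacc=7)
    mean_v, mean_a, peak_v = saccade_summary(ev)
    assert mean_v == pytest.approx(sum(s.mean_velocity for s in ev.saccades) / 7, rel=1e-12)
    assert mean_a == pytest.approx(sum(s.amplitude_deg for s in ev.saccades) / 7, rel=1e-12)
    assert peak_v == pytest.approx(sum(s.peak_velocity for s in ev.saccades) / 7, rel=1e-12)


def test_saccade_summary_missing_when_no_saccades():
    out = saccade_summary(OculomotorEvents())
    assert all(math.isnan(v) for v in out)


# --- velocity waveform indicator ------------------------------------------

def test_vwi_exact_proportionality():
    saccades = [sacc(10, 0, mean_v=v, peak_v=v / 0.2) for v in (50, 90, 140, 200)]
    assert velocity_waveform_indicator(saccades) == pytest.approx(0.2, rel=1e-9)


def test_vwi_degenerate_predictor_missing():
    saccades = [sacc(10, 0, mean_v=v, peak_v=100.0) for v in (50, 60, 70)]
    assert math.isnan(velocity_waveform_indicator(saccades))
    assert math.isnan(velocity_waveform_indicator(saccades[:2]))


def test_vwi_normal_equations_oracle():
    rng = np.random.default_rng(2)
    saccades = [sacc(10, 0, mean_v=rng.uniform(40, 200), peak_v=rng.uniform(80, 500))
                for _ in range(5)]
    x = np.array([s.peak_velocity for s in saccades])
    y = np.array([s.mean_velocity for s in saccades])
    n = len(x)
    slope = (n * np.sum(x * y) - x.sum() * y.sum()) / (n * np.sum(x * x) - x.sum() ** 2)
    assert velocity_waveform_indicator(saccades) == pytest.approx(slope, rel=1e-9)
    slope_rev = (n * np.sum(x * y) - x.sum() * y.sum()) / (n * np.sum(y * y) - y.sum() ** 2)
    assert velocity_waveform_indicator(saccades, orientation="peak_on_mean") == \
        pytest.approx(slope_rev, rel=1e-9)


# --- inflection count ------------------------------------------------------

def oracle_inflections(displacements, floor=1.0):
    count = 0
    for axis in (0, 1):
        prev = 0
        for d in displacements:
            v = d[axis]
            s = prev if abs(v) <= floor else (1 if v > 0 else -1)
            if prev and s and s != prev:
                count += 1
            if s:
                prev = s
    return count


def test_inflection_monotone_zero():
    saccades = [sacc(50, 30) for _ in range(4)]
    assert inflection_count(saccades) == 0


def test_inflection_alternating_horizontal():
    disp = [(100, 10), (-100, 10), (100, 10), (-100, 10), (100, 10), (-100, 10)]
    saccades = [sacc(dx, dy) for dx, dy in disp]
    assert inflection_count(saccades) == 5  # 5 horizontal sign changes, 0 vertical


def test_inflection_single_saccade_zero():
    assert inflection_count([sacc(10, 10)]) == 0
    assert inflection_count([]) == 0


def test_inflection_jitter_floor_inherits_sign():
    # sub-pixel wiggle between two rightward moves is not a direction change
    saccades = [sacc(100, 50), sacc(-0.5, -0.5), sacc(100, 50)]
    assert inflection_count(saccades) == 0


@pytest.mark.parametrize("seed", range(5))
def test_inflection_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    disp = [(rng.uniform(-100, 100), rng.uniform(-100, 100)) for _ in range(10)]
    saccades = [sacc(dx, dy) for dx, dy in disp]
    assert inflection_count(saccades) == oracle_inflections(disp)


# --- fixation summaries ----------------------------------------------------

def test_fixation_summary_values():
    ev = OculomotorEvents(fixations=[fix(0, 0, dur=200), fix(0, 0, dur=400)])
    assert fixation_summary(ev) == (300.0, 2)
    ev1 = OculomotorEvents(fixations=[fix(0, 0, dur=250)])
    assert fixation_summary(ev1) == (250.0, 1)
    mean, count = fixation_summary(OculomotorEvents())
    assert math.isnan(mean) and count == 0


# --- regions of interest ---------------------------------------------------

def oracle_single_linkage_rois(points_px, radius_deg, min_members):
    """Union-find connected components of the <=radius graph."""
    n = len(points_px)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = px_to_deg(points_px[i][0] - points_px[j][0],
                          points_px[i][1] - points_px[j][1], GEOM)
            if d <= radius_deg:
                parent[find(i)] = find(j)
    sizes = {}
    for i in range(n):
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return sum(1 for v in sizes.values() if v >= min_members)


def test_roi_single_tight_cluster():
    pts = [(500 + dx, 400 + dy) for dx, dy in ((0, 0), (1, 1), (-1, 2), (2, -1), (0, 3))]
    assert roi_count([fix(x, y) for x, y in pts]) == 1


def test_roi_two_clusters_plus_isolate():
    far = deg_to_px(10.0, GEOM)
    pts = [(300, 300), (305, 302), (298, 299),
           (300 + far, 300), (305 + far, 301), (302 + far, 304),
           (300, 300 + far)]
    assert roi_count([fix(x, y) for x, y in pts]) == 2


def test_roi_empty_and_singleton():
    assert roi_count([]) == 0
    assert roi_count([fix(100, 100)]) == 0


@pytest.mark.parametrize("seed", range(5))
def test_roi_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = [(rng.uniform(0, 1920), rng.uniform(0, 1080)) for _ in range(15)]
    for radius in (0.8, 1.2, 2.5):
        assert roi_count([fix(x, y) for x, y in pts], link_radius_deg=radius) == \
            oracle_single_linkage_rois(pts, radius, 2)


# --- Shannon entropy -------------------------------------------------------

def test_entropy_single_cell_zero():
    fixations = [fix(100 + i, 100 + i) for i in range(5)]
    assert shannon_entropy(fixations) == 0.0  # K=1: correction term vanishes


def test_entropy_uniform_four_cells_plugin():
    # cell size 240 x 135; four cells, two fixations each
    pts = [(10, 10), (20, 20), (300, 10), (310, 20),
           (10, 150), (20, 160), (300, 150), (310, 160)]
    fixations = [fix(x, y) for x, y in pts]
    assert shannon_entropy(fixations, bias_correction=None) == pytest.approx(2.0)
    # Miller-Madow adds (K-1)/(2 n ln 2)
    assert shannon_entropy(fixations) == pytest.approx(2.0 + 3 / (16 * math.log(2)))


def test_entropy_direct_formula_oracle():
    # counts {5, 3, 2} across three cells
    pts = [(10, 10)] * 5 + [(300, 10)] * 3 + [(10, 150)] * 2
    fixations = [fix(x, y) for x, y in pts]
    expected = -sum(p * math.log2(p) for p in (0.5, 0.3, 0.2))
    assert shannon_entropy(fixations, bias_correction=None) == pytest.approx(expected, rel=1e-12)


def test_entropy_bounded_by_log_cells():
    rng = np.random.default_rng(3)
    fixations = [fix(rng.uniform(0, 1920), rng.uniform(0, 1080)) for _ in range(40)]
    h = shannon_entropy(fixations, bias_correction=None)
    assert 0 <= h <= math.log2(64)


# --- scanpath length and area ----------------------------------------------

def test_scanpath_length_trivials():
    assert scanpath_length([fix(100, 100)]) == 0.0
    two = [fix(100, 100), fix(100 + deg_to_px(3.0, GEOM), 100)]
    assert scanpath_length(two) == pytest.approx(3.0, rel=1e-9)


def test_scanpath_length_polyline_oracle():
    rng = np.random.default_rng(4)
    pts = [(rng.uniform(0, 1920), rng.uniform(0, 1080)) for _ in range(6)]
    expected = sum(px_to_deg(b[0] - a[0], b[1] - a[1], GEOM)
                   for a, b in zip(pts, pts[1:]))
    assert scanpath_length([fix(x, y) for x, y in pts]) == pytest.approx(expected, rel=1e-12)


def test_scanpath_area_collinear_zero():
    fixations = [fix(100 + i * 50, 200 + i * 25) for i in range(3)]
    assert scanpath_area(fixations) == 0.0
    assert scanpath_area(fixations[:2]) == 0.0


def test_scanpath_area_unit_square():
    side = 1.0 / float(px_to_deg(1.0, 0.0, GEOM))  # 1 deg in linearised px
    pts = [(500, 400), (500 + side, 400), (500 + side, 400 + side), (500, 400 + side)]
    assert scanpath_area([fix(x, y) for x, y in pts]) == pytest.approx(1.0, rel=1e-9)


def oracle_hull_area(points):
    """Jarvis march + shoelace, independent of scipy."""
    pts = sorted(set(points))
    if len(pts) < 3:
        return 0.0
    start = min(pts)
    hull, current = [start], start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = ((candidate[0] - current[0]) * (p[1] - current[1]) -
                     (candidate[1] - current[1]) * (p[0] - current[0]))
            if cross < 0 or (cross == 0 and
                             math.dist(current, p) > math.dist(current, candidate)):
                candidate = p
        current = candidate
        if current == start:
            break
        hull.append(current)
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


@pytest.mark.parametrize("seed", range(5))
def test_scanpath_area_shoelace_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = [(rng.uniform(0, 1920), rng.uniform(0, 1080)) for _ in range(8)]
    got = scanpath_area([fix(x, y) for x, y in pts], units="px")
    assert got == pytest.approx(oracle_hull_area(pts), rel=1e-9)


# --- cross-feature invariants ----------------------------------------------

def test_translation_invariance():
    rng = np.random.default_rng(5)
    ev = random_events(rng, n_fix=8, n_sacc=6)
    shifted = OculomotorEvents(
        fixations=[fix(f.centroid_x + 40, f.centroid_y + 40, f.duration, f.onset)
                   for f in ev.fixations],
        saccades=ev.saccades,
    )
    a = trial_features(ev)
    b = trial_features(shifted)
    for name in ("mean_saccade_amplitude", "inflection_count", "roi_count",
                 "mean_fixation_duration", "fixation_count"):
        assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9)
    # small-angle conversion makes length/area drift negligibly under shift
    assert a.scanpath_length == pytest.approx(b.scanpath_length, rel=1e-3)
    assert a.scanpath_area == pytest.approx(b.scanpath_area, rel=5e-3)


def test_degenerate_path_implies_degenerate_area_and_roi():
    single = [fix(500, 400)]
    assert scanpath_length(single) == 0.0
    assert scanpath_area(single) == 0.0
    assert roi_count(single) <= 1
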