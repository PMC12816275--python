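"""Data-quality surfaces: fixed-AOI fixation proportions and ICC consistency.

The AOI analysis asks whether free viewing still concentrates on the core
facial features: a standardized 600 x 450 px rectangle over the eyes, nose
and mouth, with the proportion of fixation points and of total fixation
time falling inside it.

The ICC analysis asks how stable per-subject feature means are when only
the first k trials are available (k = 3, 5, 7 by default).  The default
form is ICC(3,k) — two-way mixed effects, consistency, average of the k
measures — because the statistic is used as internal consistency over a
fixed trial set; ICC(2,1) is available for absolute-agreement questions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg

from .event_detection import Fixation

__all__ = ["AoiRect", "aoi_proportions", "icc_matrix", "icc_trial_subsets"]

_ICC_TYPES = {"icc3k": "ICC(C,k)", "icc2_1": "ICC(A,1)",
              "icc2k": "ICC(A,k)", "icc3_1": "ICC(C,1)"}


@dataclass(frozen=True)
class AoiRect:
    """Axis-aligned area of interest; boundary points count as inside."""

    center_x: float
    center_y: float
    width: float = 600.0
    height: float = 450.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("AOI width and height must be positive")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        hw, hh = self.width / 2.0, self.height / 2.0
        inside = (np.abs(x - self.center_x) <= hw) & (np.abs(y - self.center_y) <= hh)
        return inside if inside.ndim else bool(inside)


def aoi_proportions(fixations: list[Fixation], aoi: AoiRect) -> tuple[float, float]:
    """(proportion of fixation points inside, proportion of fixation time inside)."""
    if not fixations:
        return (float("nan"), float("nan"))
    x = np.array([f.centroid_x for f in fixations])
    y = np.array([f.centroid_y for f in fixations])
    dur = np.array([f.duration for f in fixations])
    inside = aoi.contains(x, y)
    return (float(np.mean(inside)), float(dur[inside].sum() / dur.sum()))


def icc_matrix(matrix: np.ndarray, form: str = "icc3k") -> float:
    """ICC of a subjects x trials matrix (no missing cells).

    Degenerate inputs — identical columns (zero within-subject variance)
    — return exactly 1.0 with a warning flag; values are clipped at -1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("ICC needs a 2-D matrix with >= 2 subjects and >= 2 trials")
    if form not in _ICC_TYPES:
        raise ValueError(f"unknown ICC form {form!r}; options: {sorted(_ICC_TYPES)}")
    within = matrix - matrix.mean(axis=1, keepdims=True)
    if np.allclose(within, 0):
        warnings.warn("degenerate ICC input: identical columns; returning 1.0", stacklevel=2)
        return 1.0
    n, k = matrix.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "trial": np.tile(np.arange(k), n),
        "value": matrix.ravel(),
    })
    table = pg.intraclass_corr(data=long, targets="subject", raters="trial",
                               ratings="value")
    value = float(table.set_index("Type").loc[_ICC_TYPES[form], "ICC"])
    return float(max(value, -1.0))


def icc_trial_subsets(
    feature_matrices: dict[str, pd.DataFrame],
    subsets: tuple[int, ...] = (3, 5, 7),
    form: str = "icc3k",
) -> pd.DataFrame:
    """ICC per feature per trial-subset size.

    ``feature_matrices`` maps feature name -> subjects x trials DataFrame
    whose columns are in presentation order (post-QC: dropped trials are
    skipped, not imputed, so "first k" means the first k retained trials).
    Subjects with missing cells within a subset are excluded from that
    subset; a subset with fewer than 5 complete subjects is NaN.
    """
    rows = []
    for feature, matrix in feature_matrices.items():
        for k in subsets:
            if matrix.shape[1] < k:
                rows.append({"feature": feature, "n_trials": k, "icc": np.nan, "n_subjects": 0})
                continue
            sub = matrix.iloc[:, :k].dropna()
            if len(sub) < 5:
                rows.append({"feature": feature, "n_trials": k, "icc": np.nan,
                             "n_subjects": len(sub)})
                continue
            rows.append({"feature": feature, "n_trials": k,
                         "icc": icc_matrix(sub.to_numpy(), form),
                         "n_subjects": len(sub)})
    return pd.DataFrame(rows)
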