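"""Network comparison metrics: temporal/spatial Pearson correlation and Dice.

These are the quantities the equivalence machinery feeds on: for a network
matched in two decompositions of the same subject (before and after
residualization), the Pearson correlation of the two time-courses, the
Pearson correlation of the two spatial z maps over the analysis mask, and
the Dice overlap of the maps thresholded at z >= 3 (positive tail, since
matched components are sign-fixed toward their reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fceq.glm import DesignMatrix, t_to_z, Z_CAP
from fceq.ica import ICADecomposition, fix_sign, match_component

DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class SimilarityRecord:
    """One subject x network comparison (observed or permutation-null arm).

    ``dice`` is None when both thresholded maps are empty; the reason is
    recorded in ``dice_missing_reason``.
    """

    subject_id: str
    network_label: str
    temporal_pcc: float
    spatial_pcc: float
    dice: float | None
    condition: str = "observed"  # "observed" | "null"
    permutation_index: int | None = None
    dice_missing_reason: str | None = None


def pearson(a, b) -> float:
    """Product-moment correlation of two equal-length series (n >= 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D series")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def dice_at_z(
    map_a: np.ndarray, map_b: np.ndarray, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> tuple[float | None, str | None]:
    """Dice overlap of the suprathreshold (value >= z_threshold) voxel sets.

    Returns ``(dice, None)``, or ``(None, reason)`` when both supports are
    empty (the overlap is undefined there, not zero).
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share one grid")
    A = a >= z_threshold
    B = b >= z_threshold
    denom = int(A.sum()) + int(B.sum())
    if denom == 0:
        return None, f"no voxel reaches z >= {z_threshold} in either map"
    return 2.0 * int(np.logical_and(A, B).sum()) / denom, None


def task_correlation(
    timecourse: np.ndarray, design: DesignMatrix, condition: str
) -> tuple[float, float]:
    """Correlation of a component time-course with a task regressor, plus the
    z statistic of the corresponding simple OLS slope (dof = n - 2)."""
    col = design.column(condition)
    tc = np.asarray(timecourse, dtype=float)
    if tc.shape != col.shape:
        raise ValueError("time-course length must match the design")
    r = pearson(tc, col)
    dof = tc.size - 2
    r2 = min(r * r, 1.0)
    if 1.0 - r2 < 1e-30:
        return r, float(np.sign(r) * Z_CAP)
    t = r * np.sqrt(dof / (1.0 - r2))
    return r, float(t_to_z(np.array(t), dof))


def compare_networks(
    original: ICADecomposition,
    residualized: ICADecomposition,
    reference_map: np.ndarray,
    label: str,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    subject_id: str = "",
    condition: str = "observed",
    permutation_index: int | None = None,
) -> SimilarityRecord:
    """Similarity of one network across two decompositions of one subject.

    The labeled component is matched independently in each decomposition
    (max |spatial Pcc| with the reference, sign-fixed positive toward it),
    making the record invariant to ICA's component ordering and sign.
    """
    if original.grid != residualized.grid:
        raise ValueError("decompositions must share one grid")
    if original.n_volumes != residualized.n_volumes:
        raise ValueError(
            "time-courses of unequal length cannot be compared "
            f"({original.n_volumes} vs {residualized.n_volumes} volumes)"
        )
    rec_a = match_component(original, reference_map, label)
    rec_b = match_component(residualized, reference_map, label)
    dec_a = fix_sign(original, rec_a.component_index, reference_map)
    dec_b = fix_sign(residualized, rec_b.component_index, reference_map)
    tc_a = dec_a.timecourses[:, rec_a.component_index]
    tc_b = dec_b.timecourses[:, rec_b.component_index]
    map_a = dec_a.map_3d(rec_a.component_index)
    map_b = dec_b.map_3d(rec_b.component_index)
    mask = original.mask
    temporal = pearson(tc_a, tc_b)
    spatial = pearson(map_a[mask], map_b[mask])
    dice, reason = dice_at_z(map_a, map_b, z_threshold)
    return SimilarityRecord(
        subject_id=subject_id,
        network_label=label,
        temporal_pcc=temporal,
        spatial_pcc=spatial,
        dice=dice,
        condition=condition,
        permutation_index=permutation_index,
        dice_missing_reason=reason,
    )
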