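"""Shared domain types and exceptions.

The two containers every stage passes around: an :class:`EventSchedule`
(per-condition stimulus timing, FSL 3-column semantics) and a
:class:`VolumeSeries` (a 4D BOLD dataset with voxel geometry and TR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FceqError(Exception):
    """Base class for all package errors."""


class InfeasibleDesignError(FceqError):
    """Requested event schedule cannot fit in the scan duration."""


class DesignError(FceqError):
    """Invalid GLM design (empty condition, rank deficiency, shape mismatch)."""


class ConvergenceError(FceqError):
    """Iterative decomposition failed to converge.

    Carries the number of iterations performed in ``n_iter``.
    """

    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


class OverlapError(FceqError):
    """Network templates overlap more than the scene allows."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class EventSchedule:
    """Stimulus timing for one condition of one subject.

    Onsets and durations are in seconds from scan start.  Amplitudes default
    to 1 (zero-one boxcar convention).  An empty schedule (no events) is a
    valid degenerate value; the GLM design builder rejects it separately
    because it would produce an all-zero regressor.
    """

    condition_name: str
    onsets: np.ndarray
    durations: np.ndarray
    scan_duration: float
    amplitudes: np.ndarray | None = None

    def __post_init__(self):
        onsets = _as_float_array(self.onsets)
        durations = _as_float_array(self.durations)
        if self.amplitudes is None:
            amplitudes = np.ones_like(onsets)
        else:
            amplitudes = _as_float_array(self.amplitudes)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "amplitudes", amplitudes)
        if not (onsets.shape == durations.shape == amplitudes.shape) or onsets.ndim != 1:
            raise ValueError("onsets, durations and amplitudes must be equal-length 1D sequences")
        if self.scan_duration <= 0:
            raise ValueError("scan_duration must be positive")
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if onsets[0] < 0:
                raise ValueError("onsets must be non-negative")
            if np.any(durations <= 0):
                raise ValueError("durations must all be positive")
            if np.any(onsets + durations > self.scan_duration + 1e-9):
                raise ValueError("every event must end before scan_duration")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    @property
    def offsets(self) -> np.ndarray:
        """Event end times (onset + duration) in seconds."""
        return self.onsets + self.durations


@dataclass
class VolumeSeries:
    """A 4D BOLD dataset: ``data[x, y, z, t]`` plus voxel geometry and TR."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be a 4D (x, y, z, t) array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths in mm")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.data.shape[:3]))

    @property
    def duration(self) -> float:
        """Total scan duration in seconds."""
        return self.n_volumes * self.tr

    def flat(self) -> np.ndarray:
        """View of the data as (n_voxels, n_volumes)."""
        return self.data.reshape(-1, self.n_volumes)

    def with_data(self, data: np.ndarray) -> "VolumeSeries":
        return VolumeSeries(data=data, voxel_size=self.voxel_size, tr=self.tr)

    def copy(self) -> "VolumeSeries":
        return self.with_data(self.data.copy())
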