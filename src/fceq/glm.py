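"""First-level GLM: canonical HRF, design construction, OLS fit, residualization.

The model at each voxel is ordinary least squares on hemodynamic regressors
(one per stimulus condition, built by convolving the condition's zero-one
boxcar with a canonical HRF) plus an explicit intercept column named
``constant``.  Residualization replaces the series by its OLS residual plus
the voxel's temporal mean, i.e. it removes exactly the variance spanned by
the design while preserving the baseline image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from fceq.core import DesignError, EventSchedule, VolumeSeries

Z_CAP = 40.0
_FINE_DT = 0.01  # grid used to locate the HRF peak for normalization

HRF_NAMES = ("double-gamma", "boynton")


def _hrf_shape(t: np.ndarray, name: str) -> np.ndarray:
    """Unnormalized HRF evaluated at times t (seconds)."""
    if name == "double-gamma":
        # response gamma: delay 6 s, dispersion 1  -> shape 6, scale 1
        # undershoot gamma: delay 16 s, dispersion 1, ratio 1/6
        h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    elif name == "boynton":
        # single gamma, shape n=3, time constant tau=1.25 s
        h = stats.gamma.pdf(t, a=3.0, scale=1.25)
    else:
        raise ValueError(f"unknown HRF '{name}'; choose from {HRF_NAMES}")
    return h


def canonical_hrf(tr: float, length: float = 32.0, name: str = "double-gamma") -> np.ndarray:
    """Sample a canonical hemodynamic response function at interval ``tr``.

    The kernel is scaled so its continuous-time peak equals 1 (the peak is
    located on a 0.01 s grid, so coarse sampling never inflates the scale).

    Parameters
    ----------
    tr : sampling interval in seconds.
    length : kernel support in seconds (>= 16 s).
    name : ``"double-gamma"`` (canonical, 6 s peak / 16 s undershoot,
        undershoot ratio 1/6) or ``"boynton"`` (single gamma, shape 3,
        time constant 1.25 s, purely positive).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if length < 16.0:
        raise ValueError("HRF length must be at least 16 s")
    t_fine = np.arange(0.0, length + _FINE_DT / 2, _FINE_DT)
    peak = float(np.max(_hrf_shape(t_fine, name)))
    t = np.arange(0.0, length + tr / 2, tr)
    return _hrf_shape(t, name) / peak


@dataclass
class DesignMatrix:
    """GLM design: ``values`` is n_volumes x n_regressors, one named column each.

    Task columns are hemodynamic regressors; the intercept column is named
    ``constant`` and is excluded from "predictors of interest".
    """

    values: np.ndarray
    regressor_names: list[str]
    tr: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DesignError("design values must be 2D (n_volumes x n_regressors)")
        if self.values.shape[1] != len(self.regressor_names):
            raise DesignError("one name per design column required")
        if not np.all(np.isfinite(self.values)):
            raise DesignError("design values must be finite")
        zero = np.all(self.values == 0.0, axis=0)
        if np.any(zero):
            bad = [n for n, z in zip(self.regressor_names, zero) if z]
            raise DesignError(f"all-zero design column(s): {bad}")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]

    @property
    def task_names(self) -> list[str]:
        return [n for n in self.regressor_names if n != "constant"]

    def column(self, name: str) -> np.ndarray:
        if name not in self.regressor_names:
            raise DesignError(f"no regressor named '{name}' (have {self.regressor_names})")
        return self.values[:, self.regressor_names.index(name)]


def condition_regressor(
    schedule: EventSchedule,
    n_volumes: int,
    tr: float,
    hrf_name: str = "double-gamma",
    dt: float = 0.1,
    hrf_length: float = 32.0,
    onset_shift: float = 0.0,
) -> np.ndarray:
    """Convolve one condition's boxcar with the HRF and sample at volume times.

    The boxcar is laid out on a fine grid (default 0.1 s), convolved with the
    HRF sampled on the same grid, scaled by the grid step (so the response to
    a brief event is proportional to its duration), and read out at
    acquisition times ``t = k * tr``.  ``onset_shift`` translates every event
    in time; the simulator uses it to give individual network nodes delayed
    hemodynamics.
    """
    scan_duration = n_volumes * tr
    if schedule.n_events and np.any(schedule.offsets > scan_duration + 1e-9):
        raise DesignError(
            f"condition '{schedule.condition_name}' has an event beyond scan end"
        )
    n_fine = int(np.ceil(scan_duration / dt)) + 1
    boxcar = np.zeros(n_fine)
    for onset, dur, amp in zip(schedule.onsets, schedule.durations, schedule.amplitudes):
        lo = int(round((onset + onset_shift) / dt))
        hi = int(round((onset + onset_shift + dur) / dt))
        lo = max(lo, 0)
        if hi > lo:
            boxcar[lo : min(hi, n_fine)] += amp
    kernel = canonical_hrf(dt, length=hrf_length, name=hrf_name)
    fine = np.convolve(boxcar, kernel)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return fine[vol_idx]


def build_design_matrix(
    schedules: Mapping[str, EventSchedule],
    n_volumes: int,
    tr: float,
    hrf_name: str = "double-gamma",
    dt: float = 0.1,
    include_constant: bool = True,
) -> DesignMatrix:
    """Build the first-level design: one HRF-convolved column per condition.

    Raises :class:`DesignError` for an empty condition (an all-zero regressor
    is not allowed) or for events past the scan end.  Columns are not
    mean-centered; the intercept is an explicit ``constant`` column.
    """
    if not schedules:
        raise DesignError("at least one condition is required")
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name, schedule in schedules.items():
        if schedule.n_events == 0:
            raise DesignError(f"condition '{name}' has no events (all-zero column)")
        names.append(name)
        cols.append(condition_regressor(schedule, n_volumes, tr, hrf_name=hrf_name, dt=dt))
    if include_constant:
        names.append("constant")
        cols.append(np.ones(n_volumes))
    return DesignMatrix(values=np.column_stack(cols), regressor_names=names, tr=tr)


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Convert t statistics to z scores through tail probabilities, capped at +/-40.

    Degenerate statistics (infinite t, or tail probabilities that underflow)
    saturate at the cap.
    """
    t = np.asarray(t, dtype=float)
    p = stats.t.sf(np.abs(t), dof)
    z = np.full(t.shape, Z_CAP)
    ok = np.isfinite(t) & (p > 1e-300)
    z[ok] = stats.norm.isf(p[ok])
    z = np.minimum(z, Z_CAP)
    return np.sign(t) * z


@dataclass
class GLMResult:
    """Per-voxel OLS fit: betas, z maps, residuals, and the temporal mean volume."""

    betas: dict[str, np.ndarray]
    z_maps: dict[str, np.ndarray]
    residuals: np.ndarray  # 4D, same shape as the input series
    temporal_mean: np.ndarray  # 3D
    design: DesignMatrix

    def beta(self, name: str) -> np.ndarray:
        return self.betas[name]

    def z(self, name: str) -> np.ndarray:
        return self.z_maps[name]


def fit_glm(series: VolumeSeries, design: DesignMatrix) -> GLMResult:
    """Voxelwise ordinary least squares of the series on the design.

    z maps come from ``t = beta / SE(beta)`` with ``dof = n_volumes -
    n_regressors`` converted through the t tail probability to a normal
    quantile.  Residuals are exactly orthogonal to every design column.
    """
    X = design.values
    if X.shape[0] != series.n_volumes:
        raise DesignError(
            f"design has {X.shape[0]} rows but series has {series.n_volumes} volumes"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    Y = series.flat().T  # (T, V)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # (p, V)
    resid = Y - X @ B
    dof = X.shape[0] - X.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / dof  # (V,)
    grid = series.grid
    betas: dict[str, np.ndarray] = {}
    z_maps: dict[str, np.ndarray] = {}
    diag = np.diag(XtX_inv)
    for j, name in enumerate(design.regressor_names):
        beta_j = B[j]
        se_j = np.sqrt(sigma2 * diag[j])
        with np.errstate(divide="ignore", invalid="ignore"):
            t_j = np.where(se_j > 0, beta_j / np.where(se_j > 0, se_j, 1.0), 0.0)
        # zero residual variance with a nonzero beta: saturate rather than divide
        t_j = np.where((se_j == 0) & (beta_j != 0), np.sign(beta_j) * np.inf, t_j)
        z_j = t_to_z(t_j, dof)
        betas[name] = beta_j.reshape(grid)
        z_maps[name] = z_j.reshape(grid)
    temporal_mean = Y.mean(axis=0).reshape(grid)
    residuals = resid.T.reshape(series.data.shape)
    return GLMResult(
        betas=betas,
        z_maps=z_maps,
        residuals=residuals,
        temporal_mean=temporal_mean,
        design=design,
    )


def residualize(series: VolumeSeries, glm: GLMResult) -> VolumeSeries:
    """Residual series plus the temporal mean volume (task variance removed)."""
    if glm.residuals.shape != series.data.shape:
        raise DesignError("GLM result does not match the series shape")
    data = glm.residuals + glm.temporal_mean[..., None]
    return series.with_data(data)


def group_map(beta_maps: Sequence[np.ndarray]) -> np.ndarray:
    """One-sample t across subject beta maps, converted to a voxelwise z map.

    Degenerate voxels (zero between-subject variance) saturate at +/-40 when
    the mean is nonzero and are 0 otherwise.
    """
    maps = [np.asarray(m, dtype=float) for m in beta_maps]
    if len(maps) < 3:
        raise ValueError("group_map needs at least 3 subjects")
    grid = maps[0].shape
    for m in maps:
        if m.shape != grid:
            raise ValueError("all beta maps must share one grid")
    stack = np.stack(maps, axis=0)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
    t = np.where((se == 0) & (mean != 0), np.sign(mean) * np.inf, t)
    return t_to_z(t, dof=n - 1)
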