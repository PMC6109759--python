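"""Spatial ICA extraction of connectivity networks.

The decomposition treats voxels as samples and time points as variables:
after per-voxel demeaning and removal of the mean volume, the time dimension
is PCA-reduced to ``n_components`` and FastICA (logcosh contrast) unmixes
the voxel dimension, so each component is a maximally non-Gaussian spatial
source with one mixing time-course.  Model order can be estimated from the
PCA eigenspectrum by a Laplace (Minka) evidence approximation.  Maps are
z-scored; the map/time-course product is preserved exactly, so the
PCA-reduced data reconstructs from the stored decomposition.

ICA's inherent permutation and sign indeterminacy is handled downstream by
:func:`match_component` / :func:`fix_sign` against a reference map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from fceq.core import ConvergenceError, VolumeSeries

_LOGCOSH_GAUSS = 0.3745677  # E[log cosh X] for standard normal X


@dataclass
class ICADecomposition:
    """Spatial maps (k x n_voxels, z units) and mixing time-courses (T x k).

    ``spatial_maps[i] @ timecourses[:, i]`` summed over components
    reproduces the PCA-reduced doubly-demeaned data.  Components are ordered
    by descending explained variance.
    """

    spatial_maps: np.ndarray  # (k, V) z-scored
    timecourses: np.ndarray  # (T, k)
    explained_variance: np.ndarray  # (k,)
    mask: np.ndarray  # 3D bool
    grid: tuple[int, int, int]

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.timecourses.shape[0]

    def map_3d(self, index: int) -> np.ndarray:
        """Embed component ``index`` into the volume grid (zeros off-mask)."""
        vol = np.zeros(self.grid)
        vol[self.mask] = self.spatial_maps[index]
        return vol

    def reconstruction(self) -> np.ndarray:
        """(V, T) array: the rank-k data the decomposition represents."""
        return self.spatial_maps.T @ self.timecourses.T


@dataclass(frozen=True)
class NetworkMatch:
    """Best-matching component for a reference network map."""

    component_index: int
    sign: int
    spatial_pcc: float
    label: str


def _unwrap(series) -> VolumeSeries:
    # concatenated cohorts carry their VolumeSeries in .series
    return series.series if hasattr(series, "series") else series


def _eigenspectrum(series: VolumeSeries, mask: np.ndarray | None):
    mask = _as_mask(series, mask)
    X = series.flat()[mask.ravel()]  # (V, T)
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc -= Xc.mean(axis=0, keepdims=True)
    V = Xc.shape[0]
    G = (Xc.T @ Xc) / V
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    return Xc, np.clip(evals[order], 0.0, None), evecs[:, order], mask


def _as_mask(series: VolumeSeries, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(series.grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid:
        raise ValueError("mask must match the series grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def _laplace_evidence(spectrum: np.ndarray, n_samples: int, rank: int) -> float:
    """Minka's Laplace approximation to the log evidence of a rank-k PCA model.

    ``spectrum`` holds the descending eigenvalues of the d-dimensional sample
    covariance estimated from ``n_samples`` observations.
    """
    d = spectrum.size
    n = n_samples
    k = rank
    if k >= d:
        return -np.inf
    tail = spectrum[k:]
    v = tail.mean()
    if v <= 0 or np.any(spectrum[:k] <= 0):
        return -np.inf
    # log prior of the Stiefel manifold term
    log_pu = -k * np.log(2.0)
    for i in range(1, k + 1):
        log_pu += gammaln((d - i + 1) / 2.0) - ((d - i + 1) / 2.0) * np.log(np.pi)
    ll = -0.5 * n * np.sum(np.log(spectrum[:k])) - 0.5 * n * (d - k) * np.log(v)
    m = d * k - k * (k + 1) / 2.0
    penalty = -0.5 * (m + k) * np.log(n)
    # determinant of the Hessian (Az) over eigenvalue gaps, vectorized per row
    lam_model = np.concatenate([spectrum[:k], np.full(d - k, v)])
    log_az = 0.0
    for i in range(k):
        lam_j = lam_model[i + 1 :]
        gaps = (1.0 / lam_j - 1.0 / spectrum[i]) * (spectrum[i] - lam_j) * n
        log_az += float(np.sum(np.log(np.clip(gaps, 1e-300, None))))
    return log_pu + ll + penalty - 0.5 * log_az + 0.5 * (m + k) * np.log(2.0 * np.pi)


def estimate_model_order(
    series: VolumeSeries,
    mask: np.ndarray | None = None,
    max_order: int | None = None,
) -> int:
    """Model order from the Laplace evidence over the PCA eigenspectrum.

    Returns the argmax dimensionality, clamped to ``[2, n_volumes - 5]``.
    """
    series = _unwrap(series)
    T = series.n_volumes
    if T < 20:
        raise ValueError("model-order estimation needs at least 20 volumes")
    _, evals, _, mask = _eigenspectrum(series, mask)
    n_samples = int(mask.sum())
    hi = int(np.clip(max_order or (T - 5), 2, T - 5))
    candidates = range(1, hi + 1)
    scores = [_laplace_evidence(evals, n_samples, k) for k in candidates]
    best = int(np.argmax(scores)) + 1
    return int(np.clip(best, 2, T - 5))


def _negentropy_score(sources: np.ndarray) -> float:
    s = sources / sources.std(axis=0, keepdims=True)
    return float(np.sum((np.mean(np.log(np.cosh(s)), axis=0) - _LOGCOSH_GAUSS) ** 2))


def spatial_ica(
    series: VolumeSeries,
    n_components: int | str = "auto",
    mask: np.ndarray | None = None,
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ICADecomposition:
    """Seeded spatial ICA of a volume series.

    Runs FastICA ``restarts`` times from different seeded initializations on
    the PCA-whitened data and keeps the converged run with the largest total
    negentropy.  Raises :class:`ConvergenceError` (carrying the iteration
    count) if no restart converges.  Accepts a plain or temporally
    concatenated series.
    """
    series = _unwrap(series)
    Xc, evals, evecs, mask = _eigenspectrum(series, mask)
    V, T = Xc.shape
    if n_components == "auto":
        k = estimate_model_order(series, mask)
    else:
        k = int(n_components)
    if k < 1 or k > T:
        raise ValueError(f"n_components must be in [1, {T}]")
    lam = evals[:k]
    if np.any(lam <= 0):
        raise ValueError("data rank is below the requested number of components")
    U = evecs[:, :k]
    P = Xc @ U  # (V, k) PCA scores; column variance = lam
    Z = P / np.sqrt(lam)  # whitened

    if k == 1:
        S = Z.copy()
        W = np.ones((1, 1))
    else:
        seed_rng = np.random.default_rng(seed)
        child_seeds = seed_rng.integers(0, 2**31 - 1, size=restarts)
        best = None
        best_score = -np.inf
        last_n_iter = max_iter
        for cs in child_seeds:
            ica = FastICA(
                whiten=False,
                fun="logcosh",
                max_iter=max_iter,
                tol=tol,
                random_state=int(cs),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                S_try = ica.fit_transform(Z)
            last_n_iter = int(ica.n_iter_)
            if ica.n_iter_ >= max_iter:
                continue  # did not converge
            score = _negentropy_score(S_try)
            if score > best_score:
                best_score = score
                best = (S_try, ica.components_)
        if best is None:
            raise ConvergenceError(
                f"FastICA did not converge in {max_iter} iterations "
                f"({restarts} restarts)",
                n_iter=last_n_iter,
            )
        S, W = best

    # mixing time-courses: S = Z @ W.T so Z = S @ (W^-1).T, and
    # Xc_k = Z diag(sqrt(lam)) U.T = S @ M.T with M = U diag(sqrt(lam)) W^-1
    Winv = np.linalg.inv(W) if k > 1 else np.ones((1, 1))
    M = U @ (np.sqrt(lam)[:, None] * Winv)  # (T, k): column i is component i's time-course

    total_var = float(np.sum(Xc**2))
    evar = np.array(
        [np.sum(S[:, i] ** 2) * np.sum(M[:, i] ** 2) / total_var for i in range(k)]
    )
    order = np.argsort(evar)[::-1]
    S = S[:, order]
    M = M[:, order]
    evar = evar[order]

    sd = S.std(axis=0)
    maps = (S / sd).T  # (k, V), zero spatial mean by construction
    tcs = M * sd  # fold the scale into the time-courses: product preserved

    return ICADecomposition(
        spatial_maps=maps,
        timecourses=tcs,
        explained_variance=evar,
        mask=mask,
        grid=series.grid,
    )


def fix_sign(
    decomposition: ICADecomposition, component_index: int, reference_map: np.ndarray
) -> ICADecomposition:
    """Flip a component (map and time-course together) so its spatial
    correlation with the reference is nonnegative; ties break toward +1."""
    ref = np.asarray(reference_map, dtype=float)[decomposition.mask]
    comp = decomposition.spatial_maps[component_index]
    r = np.corrcoef(comp, ref)[0, 1] if ref.std() > 0 and comp.std() > 0 else 0.0
    if r >= 0:
        return decomposition
    maps = decomposition.spatial_maps.copy()
    tcs = decomposition.timecourses.copy()
    maps[component_index] = -maps[component_index]
    tcs[:, component_index] = -tcs[:, component_index]
    return replace(decomposition, spatial_maps=maps, timecourses=tcs)


def match_component(
    decomposition: ICADecomposition, reference_map: np.ndarray, label: str = "other"
) -> NetworkMatch:
    """The component maximizing |spatial Pearson correlation| with a reference.

    Ties break toward the lower component index; the recorded correlation is
    taken after sign fixing, hence nonnegative.  A poor best match is still
    returned — callers may threshold.
    """
    ref = np.asarray(reference_map, dtype=float)
    if ref.shape != decomposition.grid:
        raise ValueError("reference map must be on the decomposition's grid")
    ref_m = ref[decomposition.mask]
    rs = np.zeros(decomposition.n_components)
    if ref_m.std() > 0:
        for i in range(decomposition.n_components):
            comp = decomposition.spatial_maps[i]
            if comp.std() > 0:
                rs[i] = np.corrcoef(comp, ref_m)[0, 1]
    idx = int(np.argmax(np.round(np.abs(rs), 12)))  # stable tie-break: lower index
    sign = -1 if rs[idx] < 0 else 1
    return NetworkMatch(
        component_index=idx, sign=sign, spatial_pcc=abs(float(rs[idx])), label=label
    )


@dataclass
class ConcatenatedSeries:
    """Temporally concatenated, per-voxel variance-normalized cohort data."""

    series: VolumeSeries
    boundaries: list[int]  # cumulative volume counts, one per subject

    def subject_slice(self, index: int) -> slice:
        start = 0 if index == 0 else self.boundaries[index - 1]
        return slice(start, self.boundaries[index])


def concatenate_cohort(
    series_list: Sequence[VolumeSeries], mask: np.ndarray | None = None
) -> ConcatenatedSeries:
    """Stack subjects along time after per-voxel demeaning and variance
    normalization (unit temporal SD; flat voxels are left at zero)."""
    if not series_list:
        raise ValueError("empty cohort")
    grid = series_list[0].grid
    for s in series_list:
        if s.grid != grid:
            raise ValueError("all subjects must share one grid")
    blocks = []
    boundaries = []
    total = 0
    for s in series_list:
        flat = s.flat()
        mean = flat.mean(axis=1, keepdims=True)
        sd = flat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        blocks.append((flat - mean) / sd)
        total += s.n_volumes
        boundaries.append(total)
    data = np.concatenate(blocks, axis=1).reshape(grid + (total,))
    out = VolumeSeries(data=data, voxel_size=series_list[0].voxel_size, tr=series_list[0].tr)
    return ConcatenatedSeries(series=out, boundaries=boundaries)
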