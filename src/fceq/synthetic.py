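"""Seeded synthetic event-related fMRI cohorts with known ground truth.

The generator emulates a visual-motor event-related study: per subject, a
visual and an audio stimulus stream (>= 55 events each, mean inter-onset
interval 6.2 s in [4, 18] s, durations mean 1.2 s in [0.5, 3.5] s over a
360 s run) plus a motor response at each visual offset.  The scene contains
a task-coupled "visual" network (positive BOLD plus an independent
spontaneous fluctuation) and a "DMN" (negative BOLD plus an independent
spontaneous fluctuation).  Every stochastic draw is seeded, and the exact
maps and time-courses used are returned as ground truth so downstream
stages can be tested by parameter recovery.

Signal model per voxel::

    y(v, t) = baseline
              + sum_templates [ sum_nodes node_map(v) * gain * response_node(t)
                                + spatial_map(v) * spontaneous(t) ]
              + drift(t) + white noise

where ``response_node`` is the HRF-convolved condition boxcar, optionally
delayed per node: DMN nodes default to staggered hemodynamic delays, the
standing observation that each default-mode node has its own response shape,
which is what lets spatial ICA separate the deactivation from the network's
coherent spontaneous fluctuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, signal, stats

from fceq.core import (
    EventSchedule,
    InfeasibleDesignError,
    OverlapError,
    VolumeSeries,
)
from fceq.glm import condition_regressor

__all__ = [
    "NetworkTemplate",
    "SubjectGroundTruth",
    "SceneSpec",
    "generate_event_schedule",
    "derive_motor_schedule",
    "blob_template",
    "default_scene",
    "synthesize_subject",
    "generate_cohort",
    "support_dice",
]


# --------------------------------------------------------------------------
# event schedules
# --------------------------------------------------------------------------

def _truncated_exp_rate(mean: float, lo: float, hi: float) -> float:
    """Rate b of the density ~ exp(-b*(x-lo)) on [lo, hi] with the given mean."""
    span = hi - lo
    target = mean - lo

    def trunc_mean(b: float) -> float:
        if abs(b) < 1e-12:
            return span / 2.0
        ebr = np.exp(-b * span)
        return 1.0 / b - span * ebr / (1.0 - ebr)

    b_max = 500.0 / span
    return float(optimize.brentq(lambda b: trunc_mean(b) - target, -b_max, b_max, xtol=1e-12))


def _sample_truncated_exp(rng, n: int, mean: float, lo: float, hi: float) -> np.ndarray:
    b = _truncated_exp_rate(mean, lo, hi)
    u = rng.uniform(size=n)
    span = hi - lo
    if abs(b) < 1e-12:
        return lo + u * span
    y = -np.log1p(-u * (1.0 - np.exp(-b * span))) / b
    return lo + y


def _truncated_lognorm_mu(mean: float, lo: float, hi: float, sigma: float) -> float:
    def trunc_mean(mu: float) -> float:
        a = (np.log(lo) - mu) / sigma
        b = (np.log(hi) - mu) / sigma
        denom = stats.norm.cdf(b) - stats.norm.cdf(a)
        if denom < 1e-12:  # entire mass outside the window: limiting values
            return lo if mu < np.log(lo) else hi
        num = stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
        return np.exp(mu + sigma**2 / 2.0) * num / denom

    lo_mu, hi_mu = np.log(lo) - 3.0 * sigma, np.log(hi) + 3.0 * sigma
    return float(optimize.brentq(lambda m: trunc_mean(m) - mean, lo_mu, hi_mu))


def _sample_truncated_lognorm(rng, n: int, mean: float, lo: float, hi: float, sigma: float) -> np.ndarray:
    mu = _truncated_lognorm_mu(mean, lo, hi, sigma)
    a = stats.norm.cdf((np.log(lo) - mu) / sigma)
    b = stats.norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def generate_event_schedule(
    n_events: int,
    mean_gap: float = 6.2,
    gap_range: tuple[float, float] = (4.0, 18.0),
    mean_duration: float = 1.2,
    duration_range: tuple[float, float] = (0.5, 3.5),
    scan_duration: float = 360.0,
    seed=0,
    condition_name: str = "visual",
    duration_log_sigma: float = 0.5,
    max_attempts: int = 100,
) -> EventSchedule:
    """Draw a random event schedule with the study's timing statistics.

    Gaps are inter-onset intervals drawn from a truncated exponential
    rescaled to hit ``mean_gap`` exactly; durations come from a truncated
    log-normal (sigma ``duration_log_sigma`` in log-seconds) rescaled to hit
    ``mean_duration``.  Both honor their stated ranges; the skewed shapes
    match event-related jitter.  Draws are retried until the last event ends
    inside the scan; an impossible request raises
    :class:`InfeasibleDesignError`.
    """
    if n_events < 1:
        raise InfeasibleDesignError("n_events must be at least 1")
    g_lo, g_hi = gap_range
    d_lo, d_hi = duration_range
    if not (g_lo < mean_gap < g_hi):
        raise InfeasibleDesignError("gap_range must strictly contain mean_gap")
    if not (d_lo < mean_duration < d_hi):
        raise InfeasibleDesignError("duration_range must strictly contain mean_duration")
    if g_lo <= 0 or d_lo <= 0:
        raise InfeasibleDesignError("gaps and durations must be positive")
    min_span = (n_events - 1) * g_lo + d_lo
    if min_span > scan_duration:
        raise InfeasibleDesignError(
            f"{n_events} events need at least {min_span:.1f} s but the scan lasts "
            f"{scan_duration:.1f} s"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        if n_events == 1:
            dur = _sample_truncated_lognorm(rng, 1, mean_duration, d_lo, d_hi, duration_log_sigma)
            onset = rng.uniform(0.0, scan_duration - dur[0])
            return EventSchedule(condition_name, np.array([onset]), dur, scan_duration)
        first = rng.uniform(0.0, g_lo)
        gaps = _sample_truncated_exp(rng, n_events - 1, mean_gap, g_lo, g_hi)
        durations = _sample_truncated_lognorm(
            rng, n_events, mean_duration, d_lo, d_hi, duration_log_sigma
        )
        onsets = first + np.concatenate([[0.0], np.cumsum(gaps)])
        # stimuli must not overlap: inter-onset interval must exceed the duration
        if np.any(gaps <= durations[:-1]):
            continue
        if onsets[-1] + durations[-1] <= scan_duration:
            return EventSchedule(condition_name, onsets, durations, scan_duration)
    raise InfeasibleDesignError(
        f"could not place {n_events} events in {scan_duration:.1f} s after "
        f"{max_attempts} attempts; the design is too dense"
    )


def derive_motor_schedule(visual: EventSchedule, response_duration: float = 0.5) -> EventSchedule:
    """One motor (button-press) event at the offset of each visual stimulus.

    Responses that would outlast the scan are dropped with a warning.
    """
    onsets = visual.offsets
    keep = onsets + response_duration <= visual.scan_duration
    if not np.all(keep):
        warnings.warn(
            f"dropping {int(np.sum(~keep))} motor event(s) clipped at scan end",
            stacklevel=2,
        )
    onsets = onsets[keep]
    return EventSchedule(
        condition_name="motor",
        onsets=onsets,
        durations=np.full(onsets.size, float(response_duration)),
        scan_duration=visual.scan_duration,
    )


# --------------------------------------------------------------------------
# network templates
# --------------------------------------------------------------------------

@dataclass
class NetworkTemplate:
    """Where a network lives and how it behaves.

    ``spatial_map`` is a nonnegative 3D weight volume normalized to max 1;
    it carries both the network's coherent spontaneous fluctuation and, node
    by node, its task-evoked response.  ``task_coupling`` is a signed gain:
    positive for a positive BOLD response, negative for deactivation, zero
    for an uncoupled network.  ``node_maps`` partition the spatial map into
    nodes; ``node_response_delays`` (seconds) shift each node's hemodynamic
    response, modeling region-specific HRF latency.  ``hrf_name`` overrides
    the scene HRF for this template's task response (default: scene HRF).
    """

    label: str
    spatial_map: np.ndarray
    task_coupling: float
    coupled_condition: str = "visual"
    spontaneous_amplitude: float = 1.0
    spontaneous_cutoff: float = 0.1
    node_maps: list[np.ndarray] | None = None
    node_response_delays: Sequence[float] | None = None
    hrf_name: str | None = None

    def __post_init__(self):
        m = np.asarray(self.spatial_map, dtype=float)
        if m.ndim != 3:
            raise ValueError("spatial_map must be 3D")
        if np.any(m < 0):
            raise ValueError("spatial_map must be nonnegative")
        peak = m.max()
        if peak > 0:
            m = m / peak
        self.spatial_map = m
        if self.node_maps is None:
            self.node_maps = [m]
        else:
            self.node_maps = [np.asarray(n, dtype=float) / (peak if peak > 0 else 1.0)
                              for n in self.node_maps]
        if self.node_response_delays is None:
            self.node_response_delays = [0.0] * len(self.node_maps)
        self.node_response_delays = [float(d) for d in self.node_response_delays]
        if len(self.node_response_delays) != len(self.node_maps):
            raise ValueError("one response delay per node map required")

    @property
    def support(self) -> np.ndarray:
        return self.spatial_map > 0

    @property
    def core(self) -> np.ndarray:
        """Voxels carrying at least half the peak weight."""
        return self.spatial_map >= 0.5


def support_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two boolean supports (0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _blob(grid: tuple[int, int, int], center: Sequence[float], radius: float) -> np.ndarray:
    ax = [np.arange(n, dtype=float) for n in grid]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    d2 = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2) / radius**2
    return np.clip(1.0 - d2, 0.0, None)


def blob_template(
    label: str,
    grid: tuple[int, int, int],
    nodes: Sequence[tuple[Sequence[float], float]],
    task_coupling: float,
    coupled_condition: str = "visual",
    node_response_delays: Sequence[float] | None = None,
    spontaneous_amplitude: float = 1.0,
    spontaneous_cutoff: float = 0.1,
    hrf_name: str | None = None,
    task_core_scale: float = 1.0,
) -> NetworkTemplate:
    """Build a template from smooth spherical nodes ((center, radius) in voxels).

    ``task_core_scale`` < 1 concentrates the task-evoked response on a
    sharper core of each node (radius scaled by the factor) while the
    spontaneous fluctuation spans the full node: the two processes then
    occupy overlapping but linearly independent spatial profiles, so spatial
    ICA can represent them as separate sources.  At 1.0 the task response
    shares the network's full spatial map and fuses with the spontaneous
    fluctuation into a single component.
    """
    node_maps = [_blob(grid, c, r * task_core_scale) for c, r in nodes]
    spatial = np.sum([_blob(grid, c, r) for c, r in nodes], axis=0)
    return NetworkTemplate(
        label=label,
        spatial_map=spatial,
        task_coupling=task_coupling,
        coupled_condition=coupled_condition,
        spontaneous_amplitude=spontaneous_amplitude,
        spontaneous_cutoff=spontaneous_cutoff,
        node_maps=node_maps,
        node_response_delays=node_response_delays,
        hrf_name=hrf_name,
    )


def default_scene(
    grid: tuple[int, int, int] = (20, 20, 10),
    visual_coupling: float = 1.0,
    dmn_coupling: float = -0.6,
    spontaneous_amplitude: float = 1.0,
    spontaneous_cutoff: float = 0.1,
    dmn_node_delays: Sequence[float] = (-2.0, 0.0, 2.0),
    dmn_task_core_scale: float = 0.6,
) -> list[NetworkTemplate]:
    """The study scene: one visual blob (positive BOLD) and a three-node DMN
    (negative BOLD) whose deactivation has node-specific hemodynamics.

    The visual network's task response rides on the same spatial weights as
    its spontaneous fluctuation (they fuse into one ICA component), whereas
    the DMN's negative BOLD response is concentrated on sharper node cores
    with staggered per-node delays — deactivation and connectivity are
    distinct, separable sources there.  Node positions scale with the grid
    so the supports stay disjoint.
    """
    gx, gy, gz = grid
    s = np.array([gx / 20.0, gy / 20.0, gz / 10.0])
    visual = blob_template(
        "visual",
        grid,
        nodes=[((10 * s[0], 4 * s[1], 4 * s[2]), 3.2 * min(s))],
        task_coupling=visual_coupling,
        spontaneous_amplitude=spontaneous_amplitude,
        spontaneous_cutoff=spontaneous_cutoff,
    )
    dmn = blob_template(
        "dmn",
        grid,
        nodes=[
            ((10 * s[0], 16 * s[1], 5 * s[2]), 3.0 * min(s)),
            ((4 * s[0], 12 * s[1], 6 * s[2]), 3.0 * min(s)),
            ((16 * s[0], 12 * s[1], 6 * s[2]), 3.0 * min(s)),
        ],
        task_coupling=dmn_coupling,
        node_response_delays=list(dmn_node_delays),
        spontaneous_amplitude=spontaneous_amplitude,
        spontaneous_cutoff=spontaneous_cutoff,
        task_core_scale=dmn_task_core_scale,
    )
    return [visual, dmn]


# --------------------------------------------------------------------------
# subject synthesis
# --------------------------------------------------------------------------

@dataclass
class SubjectGroundTruth:
    """Everything the generator used for one subject, for parameter recovery."""

    templates: list[NetworkTemplate]
    spontaneous_timecourses: dict[str, np.ndarray]
    node_task_responses: dict[str, list[np.ndarray]]
    condition_regressors: dict[str, np.ndarray]
    schedules: dict[str, EventSchedule]
    drift: np.ndarray
    baseline: float
    tr: float
    voxel_size: tuple[float, float, float]
    seed: int

    def template(self, label: str) -> NetworkTemplate:
        for t in self.templates:
            if t.label == label:
                return t
        raise KeyError(label)

    def reconstruct(self) -> VolumeSeries:
        """The exact noise-free series (baseline + signals + drift)."""
        grid = self.templates[0].spatial_map.shape
        n_volumes = self.drift.size
        data = np.zeros(grid + (n_volumes,))
        data += self.baseline
        for tpl in self.templates:
            for node_map, resp in zip(tpl.node_maps, self.node_task_responses[tpl.label]):
                data += node_map[..., None] * resp[None, None, None, :]
            data += (
                tpl.spatial_map[..., None]
                * self.spontaneous_timecourses[tpl.label][None, None, None, :]
            )
        data += self.drift[None, None, None, :]
        return VolumeSeries(data=data, voxel_size=self.voxel_size, tr=self.tr)


def _spontaneous_timecourse(
    rng,
    n_volumes: int,
    tr: float,
    cutoff: float,
    amplitude: float,
    screen_against: Sequence[np.ndarray],
    bound: float,
    max_draws: int,
) -> np.ndarray:
    """Low-pass-filtered seeded Gaussian noise, variance-normalized, decorrelated
    from every task regressor by resampling (|r| < bound)."""
    nyq = 0.5 / tr
    b, a = signal.butter(4, min(cutoff / nyq, 0.99))
    for _ in range(max_draws):
        white = rng.standard_normal(n_volumes)
        tc = signal.filtfilt(b, a, white)
        tc = (tc - tc.mean()) / tc.std()
        ok = True
        for reg in screen_against:
            r = np.corrcoef(tc, reg)[0, 1]
            if abs(r) >= bound:
                ok = False
                break
        if ok:
            return amplitude * tc
    raise RuntimeError(
        f"could not draw a spontaneous time-course decorrelated from the task "
        f"(|r| < {bound}) in {max_draws} draws"
    )


def synthesize_subject(
    templates: Sequence[NetworkTemplate],
    schedules: Mapping[str, EventSchedule],
    grid: tuple[int, int, int] = (20, 20, 10),
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 5.5),
    tr: float = 1.0,
    n_volumes: int = 360,
    noise_sd: float = 0.5,
    drift_amplitude: float = 1.0,
    drift_period: float = 128.0,
    baseline: float = 100.0,
    seed: int = 0,
    hrf_name: str = "double-gamma",
    overlap_bound: float = 0.05,
    decorrelation_bound: float = 0.1,
    max_decorrelation_draws: int = 100,
) -> tuple[VolumeSeries, SubjectGroundTruth]:
    """Render one subject's 4D series from templates and event schedules.

    Raises :class:`OverlapError` when two templates' supports overlap with
    Dice above ``overlap_bound`` (spatial ICA assumes near-disjoint sources).
    """
    templates = list(templates)
    for tpl in templates:
        if tpl.spatial_map.shape != tuple(grid):
            raise ValueError(f"template '{tpl.label}' is not on grid {grid}")
        if tpl.task_coupling != 0.0 and tpl.coupled_condition not in schedules:
            raise ValueError(
                f"template '{tpl.label}' couples to condition "
                f"'{tpl.coupled_condition}' but no schedule covers it"
            )
    for i in range(len(templates)):
        for j in range(i + 1, len(templates)):
            d = support_dice(templates[i].support, templates[j].support)
            if d > overlap_bound:
                raise OverlapError(
                    f"templates '{templates[i].label}' and '{templates[j].label}' "
                    f"overlap with Dice {d:.3f} > {overlap_bound}"
                )

    rng = np.random.default_rng(seed)
    regressors = {
        name: condition_regressor(sch, n_volumes, tr, hrf_name=hrf_name)
        for name, sch in schedules.items()
        if sch.n_events > 0
    }
    screen = list(regressors.values())

    sponts: dict[str, np.ndarray] = {}
    node_resps: dict[str, list[np.ndarray]] = {}
    for tpl in templates:
        sponts[tpl.label] = _spontaneous_timecourse(
            rng,
            n_volumes,
            tr,
            tpl.spontaneous_cutoff,
            tpl.spontaneous_amplitude,
            screen,
            decorrelation_bound,
            max_decorrelation_draws,
        )
        resps = []
        for delay in tpl.node_response_delays:
            if tpl.task_coupling == 0.0:
                resps.append(np.zeros(n_volumes))
            else:
                resps.append(
                    tpl.task_coupling
                    * condition_regressor(
                        schedules[tpl.coupled_condition],
                        n_volumes,
                        tr,
                        hrf_name=tpl.hrf_name or hrf_name,
                        onset_shift=delay,
                    )
                )
        node_resps[tpl.label] = resps

    phase = rng.uniform(0.0, 2.0 * np.pi)
    t_sec = np.arange(n_volumes) * tr
    drift = drift_amplitude * np.cos(2.0 * np.pi * t_sec / drift_period + phase)

    ground_truth = SubjectGroundTruth(
        templates=templates,
        spontaneous_timecourses=sponts,
        node_task_responses=node_resps,
        condition_regressors=regressors,
        schedules=dict(schedules),
        drift=drift,
        baseline=float(baseline),
        tr=tr,
        voxel_size=tuple(voxel_size),
        seed=seed,
    )
    clean = ground_truth.reconstruct()
    data = clean.data
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return VolumeSeries(data=data, voxel_size=tuple(voxel_size), tr=tr), ground_truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """All knobs of the synthetic study in one serializable record.

    Defaults are the study conditions: 360 volumes at TR 1 s, 55 visual and
    55 audio events (inter-onset mean 6.2 s in [4, 18] s, durations mean
    1.2 s in [0.5, 3.5] s), a motor press at each visual offset, visual
    coupling +1.0, DMN coupling -0.6, spontaneous amplitude 1.0, white noise
    SD 0.5, on a 20 x 20 x 10 desk-scale grid.
    """

    grid: tuple[int, int, int] = (20, 20, 10)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 5.5)
    tr: float = 1.0
    n_volumes: int = 360
    n_events: int = 55
    mean_gap: float = 6.2
    gap_range: tuple[float, float] = (4.0, 18.0)
    mean_duration: float = 1.2
    duration_range: tuple[float, float] = (0.5, 3.5)
    response_duration: float = 0.5
    visual_coupling: float = 1.0
    dmn_coupling: float = -0.6
    dmn_node_delays: tuple[float, ...] = (-2.0, 0.0, 2.0)
    dmn_task_core_scale: float = 0.6
    spontaneous_amplitude: float = 1.0
    spontaneous_cutoff: float = 0.1
    noise_sd: float = 0.5
    drift_amplitude: float = 1.0
    drift_period: float = 128.0
    baseline: float = 100.0
    hrf_name: str = "double-gamma"
    overlap_bound: float = 0.05
    decorrelation_bound: float = 0.1

    def templates(self) -> list[NetworkTemplate]:
        return default_scene(
            grid=self.grid,
            visual_coupling=self.visual_coupling,
            dmn_coupling=self.dmn_coupling,
            spontaneous_amplitude=self.spontaneous_amplitude,
            spontaneous_cutoff=self.spontaneous_cutoff,
            dmn_node_delays=self.dmn_node_delays,
            dmn_task_core_scale=self.dmn_task_core_scale,
        )

    def subject_schedules(self, subject_seed: int) -> dict[str, EventSchedule]:
        scan = self.n_volumes * self.tr
        visual = generate_event_schedule(
            self.n_events,
            self.mean_gap,
            self.gap_range,
            self.mean_duration,
            self.duration_range,
            scan,
            seed=[subject_seed, 1],
            condition_name="visual",
        )
        audio = generate_event_schedule(
            self.n_events,
            self.mean_gap,
            self.gap_range,
            self.mean_duration,
            self.duration_range,
            scan,
            seed=[subject_seed, 2],
            condition_name="audio",
        )
        motor = derive_motor_schedule(visual, self.response_duration)
        return {"visual": visual, "audio": audio, "motor": motor}


def generate_cohort(
    n_subjects: int,
    master_seed: int = 0,
    scene: SceneSpec | None = None,
) -> list[tuple[VolumeSeries, SubjectGroundTruth]]:
    """Independent subjects with unique task timings (seed = master_seed + index).

    At least two subjects are required: the cross-subject permutation null
    needs a swap.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    scene = scene or SceneSpec()
    templates = scene.templates()
    cohort = []
    for i in range(n_subjects):
        subject_seed = master_seed + i
        schedules = scene.subject_schedules(subject_seed)
        series, gt = synthesize_subject(
            templates,
            schedules,
            grid=scene.grid,
            voxel_size=scene.voxel_size,
            tr=scene.tr,
            n_volumes=scene.n_volumes,
            noise_sd=scene.noise_sd,
            drift_amplitude=scene.drift_amplitude,
            drift_period=scene.drift_period,
            baseline=scene.baseline,
            seed=subject_seed,
            hrf_name=scene.hrf_name,
            overlap_bound=scene.overlap_bound,
            decorrelation_bound=scene.decorrelation_bound,
        )
        cohort.append((series, gt))
    return cohort
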