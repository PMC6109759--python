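"""The equivalency interval: permutation null and paired test.

Removing *any* regressor from a series perturbs an ICA decomposition a
little; the question is whether removing the true task perturbs it more
than removing task-irrelevant variance.  The null is built by residualizing
each subject against another subject's task timing (a seeded random
derangement, so nobody keeps their own schedule), repeating ICA, and
recording the same similarity metrics.  A paired t-test of observed vs
per-subject null means then decides, per network and metric, whether the
observed alteration exceeds the natural variability of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from fceq.core import ConvergenceError, EventSchedule, VolumeSeries
from fceq.glm import build_design_matrix, fit_glm, residualize
from fceq.ica import ICADecomposition, spatial_ica
from fceq.similarity import DEFAULT_Z_THRESHOLD, SimilarityRecord, compare_networks

T_CAP = 40.0

METRICS = ("temporal_pcc", "spatial_pcc", "dice")


def permute_assignments(
    subject_ids: Sequence[str], n_rounds: int, seed: int = 0
) -> list[dict[str, str]]:
    """Seeded uniform random derangements: subject -> donor, no fixed points.

    Rounds are kept distinct whenever the subject count permits (two
    subjects admit only the swap).
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("permutation needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    rounds: list[dict[str, str]] = []
    seen: set[tuple[int, ...]] = set()
    for _ in range(n_rounds):
        for attempt in range(10000):
            perm = rng.permutation(n)
            if np.any(perm == np.arange(n)):
                continue
            key = tuple(perm)
            if key in seen and len(seen) < _count_derangements(n):
                continue
            seen.add(key)
            rounds.append({ids[i]: ids[perm[i]] for i in range(n)})
            break
        else:
            raise RuntimeError("failed to sample a fresh derangement")
    return rounds


def _count_derangements(n: int) -> int:
    if n > 12:
        return 10**9
    d = [1, 0]
    for i in range(2, n + 1):
        d.append((i - 1) * (d[-1] + d[-2]))
    return d[n]


@dataclass
class SubjectState:
    """Everything build_null needs about one already-analyzed subject."""

    subject_id: str
    series: VolumeSeries  # preprocessed
    schedules: dict[str, EventSchedule]
    original_decomposition: ICADecomposition
    n_components: int
    ica_seed: int


@dataclass
class NullDistribution:
    """Similarity records under permuted task timing, plus bookkeeping."""

    records: list[SimilarityRecord]
    permutation_map: list[dict[str, str]]
    n_rounds: int
    seed: int


def _assert_unique_schedules(subjects: Sequence[SubjectState]) -> None:
    for i in range(len(subjects)):
        for j in range(i + 1, len(subjects)):
            a = subjects[i].schedules["visual"]
            b = subjects[j].schedules["visual"]
            if a.n_events == b.n_events and np.allclose(a.onsets, b.onsets):
                raise AssertionError(
                    f"subjects '{subjects[i].subject_id}' and "
                    f"'{subjects[j].subject_id}' share a task timing; the "
                    "permutation null requires unique schedules"
                )


def build_null(
    subjects: Sequence[SubjectState],
    references: Mapping[str, np.ndarray],
    n_rounds: int = 1,
    seed: int = 0,
    hrf_name: str = "double-gamma",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> NullDistribution:
    """Residualize each subject against a donor's task timing and re-run ICA.

    For every round and subject, the donor subject's schedules define the
    design; the GLM is fit to the subject's (preprocessed) series, the
    residualized data are decomposed with the same model order and ICA seed
    as the observed arm, and each reference network is matched and compared
    with the subject's original-data decomposition.  ICA non-convergence is
    recorded as a missing value with its reason, not raised.
    """
    subjects = list(subjects)
    _assert_unique_schedules(subjects)
    by_id = {s.subject_id: s for s in subjects}
    perms = permute_assignments([s.subject_id for s in subjects], n_rounds, seed)
    records: list[SimilarityRecord] = []
    for r, perm in enumerate(perms):
        for subject in subjects:
            donor = by_id[perm[subject.subject_id]]
            own = subject.schedules["visual"]
            don = donor.schedules["visual"]
            assert not (
                own.n_events == don.n_events and np.allclose(own.onsets, don.onsets)
            ), "donor task timing identical to the subject's own"
            design = build_design_matrix(
                donor.schedules, subject.series.n_volumes, subject.series.tr, hrf_name=hrf_name
            )
            glm = fit_glm(subject.series, design)
            resid = residualize(subject.series, glm)
            try:
                dec = spatial_ica(
                    resid,
                    n_components=subject.n_components,
                    mask=subject.original_decomposition.mask,
                    seed=subject.ica_seed,
                    restarts=restarts,
                    max_iter=max_iter,
                    tol=tol,
                )
            except ConvergenceError as err:
                for label in references:
                    records.append(
                        SimilarityRecord(
                            subject_id=subject.subject_id,
                            network_label=label,
                            temporal_pcc=np.nan,
                            spatial_pcc=np.nan,
                            dice=None,
                            condition="null",
                            permutation_index=r,
                            dice_missing_reason=f"ICA did not converge ({err.n_iter} iterations)",
                        )
                    )
                continue
            for label, ref in references.items():
                rec = compare_networks(
                    subject.original_decomposition,
                    dec,
                    ref,
                    label,
                    z_threshold=z_threshold,
                    subject_id=subject.subject_id,
                    condition="null",
                    permutation_index=r,
                )
                records.append(rec)
    return NullDistribution(records=records, permutation_map=perms, n_rounds=n_rounds, seed=seed)


@dataclass
class EquivalenceResult:
    """Paired-test verdict for one network x metric.

    ``p_value`` is one-sided for the alternative "observed similarity is
    below the null" (similarity reduction); the two-sided p is reported
    alongside.  ``verdict`` is "altered" iff p_value < alpha and the
    observed mean lies below the null mean, else "within_equivalency".
    """

    network_label: str
    metric: str
    t_stat: float
    dof: int
    p_value: float
    p_two_sided: float
    mean_observed: float
    mean_null: float
    n_pairs: int
    alpha: float
    verdict: str


def _metric_value(rec: SimilarityRecord, metric: str) -> float:
    v = getattr(rec, metric)
    return np.nan if v is None else float(v)


def equivalence_test(
    observed: Sequence[SimilarityRecord],
    null: NullDistribution,
    network_label: str,
    metric: str,
    alpha: float = 0.05,
) -> EquivalenceResult:
    """Paired t-test of per-subject observed vs null-mean similarity.

    Null records are averaged per subject across permutation rounds before
    pairing; subjects missing either side are dropped.  Needs at least 3
    complete pairs.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    obs_by_subj: dict[str, float] = {}
    for rec in observed:
        if rec.network_label == network_label and rec.condition == "observed":
            obs_by_subj[rec.subject_id] = _metric_value(rec, metric)
    null_by_subj: dict[str, list[float]] = {}
    for rec in null.records:
        if rec.network_label == network_label:
            null_by_subj.setdefault(rec.subject_id, []).append(_metric_value(rec, metric))
    pairs = []
    for sid, obs_val in obs_by_subj.items():
        null_vals = np.asarray(null_by_subj.get(sid, []), dtype=float)
        null_vals = null_vals[~np.isnan(null_vals)]
        if np.isnan(obs_val) or null_vals.size == 0:
            continue
        pairs.append((obs_val, float(null_vals.mean())))
    if len(pairs) < 3:
        raise ValueError(
            f"equivalence test needs at least 3 complete subject pairs "
            f"(got {len(pairs)} for {network_label}/{metric})"
        )
    obs_arr = np.array([p[0] for p in pairs])
    null_arr = np.array([p[1] for p in pairs])
    diffs = obs_arr - null_arr
    n = diffs.size
    dof = n - 1
    sd = diffs.std(ddof=1)
    mean_d = diffs.mean()
    if sd == 0:
        t = 0.0 if mean_d == 0 else float(np.sign(mean_d) * T_CAP)
    else:
        t = float(np.clip(mean_d / (sd / np.sqrt(n)), -T_CAP, T_CAP))
    p_one = float(stats.t.cdf(t, dof))
    p_two = float(2.0 * stats.t.sf(abs(t), dof))
    mean_obs = float(obs_arr.mean())
    mean_null = float(null_arr.mean())
    verdict = "altered" if (p_one < alpha and mean_obs < mean_null) else "within_equivalency"
    return EquivalenceResult(
        network_label=network_label,
        metric=metric,
        t_stat=t,
        dof=dof,
        p_value=p_one,
        p_two_sided=p_two,
        mean_observed=mean_obs,
        mean_null=mean_null,
        n_pairs=n,
        alpha=alpha,
        verdict=verdict,
    )
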