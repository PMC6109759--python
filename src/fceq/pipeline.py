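"""End-to-end orchestration of the two study arms.

``run_study`` ties the stages together: simulate a cohort, preprocess,
fit the first-level GLM, residualize against the subject's own task timing
(observed arm), decompose original and residualized data by spatial ICA,
record network similarities, rebuild the null arm with permuted task
timings, and run the paired equivalence test per network and metric.
Everything is seeded through the config, so a rerun with an identical
configuration reproduces all tables bitwise.

Subject-wise ICA is the default inference path; ``mode="group"`` instead
decomposes the temporally concatenated cohort (one ICA for all subjects),
slices per-subject time-courses back out at the recorded boundaries for the
temporal metric, and shares the group-level spatial metrics across
subjects.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import fceq
from fceq.config import StudyConfig
from fceq.core import VolumeSeries
from fceq.equivalence import (
    METRICS,
    NullDistribution,
    SubjectState,
    build_null,
    equivalence_test,
    permute_assignments,
)
from fceq.glm import build_design_matrix, fit_glm, residualize
from fceq.ica import (
    concatenate_cohort,
    estimate_model_order,
    fix_sign,
    match_component,
    spatial_ica,
)
from fceq.io import save_series, write_events, write_table
from fceq.preprocess import run_preprocess
from fceq.similarity import (
    SimilarityRecord,
    compare_networks,
    dice_at_z,
    pearson,
    task_correlation,
)
from fceq.synthetic import generate_cohort

log = logging.getLogger("fceq")


@dataclass
class StudyResult:
    """Result bundle: similarity tables, the null, the equivalence verdicts."""

    observed: pd.DataFrame
    null: pd.DataFrame
    equivalence: pd.DataFrame
    subjects: pd.DataFrame
    config: StudyConfig
    provenance: dict
    observed_records: list[SimilarityRecord] = field(repr=False, default_factory=list)
    null_distribution: NullDistribution | None = field(repr=False, default=None)
    timings: dict[str, float] = field(default_factory=dict)

    def verdict(self, network_label: str, metric: str) -> str:
        rows = self.equivalence
        sel = rows[(rows.network == network_label) & (rows.metric == metric)]
        if sel.empty:
            raise KeyError(f"no equivalence row for {network_label}/{metric}")
        return str(sel.iloc[0].verdict)


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "network": r.network_label,
                "condition": r.condition,
                "permutation_index": r.permutation_index,
                "temporal_pcc": r.temporal_pcc,
                "spatial_pcc": r.spatial_pcc,
                "dice": np.nan if r.dice is None else r.dice,
                "dice_missing_reason": r.dice_missing_reason or "",
            }
            for r in records
        ]
    )


@dataclass
class _PreparedSubject:
    sid: str
    pre: VolumeSeries
    resid: VolumeSeries
    design: object
    ground_truth: object


def _ica_kwargs(config: StudyConfig) -> dict:
    return dict(
        restarts=config.ica.restarts,
        max_iter=config.ica.max_iter,
        tol=config.ica.tol,
    )


def run_study(
    config: StudyConfig | None = None,
    output_dir: str | Path | None = None,
    save_intermediates: bool = False,
) -> StudyResult:
    """Run the full study described by ``config`` and return the result bundle.

    Any stage failure is re-raised with the failing subject and stage named.
    """
    config = config or StudyConfig()
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    out = Path(output_dir or config.output_dir) if (output_dir or config.output_dir) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    scene = config.scene.to_spec()
    log.info(
        "simulating cohort of %d subjects (master seed %d)",
        config.n_subjects,
        config.master_seed,
    )
    cohort = generate_cohort(config.n_subjects, config.master_seed, scene)
    templates = cohort[0][1].templates
    references = {t.label: t.spatial_map for t in templates if t.label in ("visual", "dmn")}
    timings["simulate"] = time.perf_counter() - t0

    prepared: list[_PreparedSubject] = []
    for i, (raw, gt) in enumerate(cohort):
        sid = f"sub-{i:02d}"
        stage = "preprocess"
        try:
            t1 = time.perf_counter()
            pre = run_preprocess(
                raw,
                highpass_hz=config.preprocess.highpass_hz,
                fwhm_mm=config.preprocess.fwhm_mm,
                target_median=config.preprocess.target_median,
                highpass_method=config.preprocess.highpass_method,
            )
            timings["preprocess"] = timings.get("preprocess", 0.0) + time.perf_counter() - t1

            stage = "glm"
            t1 = time.perf_counter()
            schedules = {c: gt.schedules[c] for c in config.glm.conditions}
            design = build_design_matrix(
                schedules, pre.n_volumes, pre.tr, hrf_name=config.glm.hrf_name
            )
            glm = fit_glm(pre, design)
            resid = residualize(pre, glm)
            timings["glm"] = timings.get("glm", 0.0) + time.perf_counter() - t1
            prepared.append(_PreparedSubject(sid, pre, resid, design, gt))
            if out and save_intermediates:
                save_series(resid, out / f"{sid}_residualized.nii.gz")
                for cond, sch in gt.schedules.items():
                    write_events(sch, out / f"{sid}_{cond}.txt")
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed for subject '{sid}': {err}") from err

    if config.mode == "group":
        observed_records, null, subjects_df = _group_arms(prepared, references, config, timings)
    else:
        observed_records, null, subjects_df = _subject_arms(prepared, references, config, timings)

    eq_rows = []
    for label in references:
        for metric in METRICS:
            try:
                res = equivalence_test(
                    observed_records, null, label, metric, alpha=config.equivalence.alpha
                )
            except ValueError as err:
                log.warning("equivalence test skipped for %s/%s: %s", label, metric, err)
                continue
            eq_rows.append(
                {
                    "network": res.network_label,
                    "metric": res.metric,
                    "t": res.t_stat,
                    "dof": res.dof,
                    "p_one_sided": res.p_value,
                    "p_two_sided": res.p_two_sided,
                    "mean_observed": res.mean_observed,
                    "mean_null": res.mean_null,
                    "n_pairs": res.n_pairs,
                    "verdict": res.verdict,
                }
            )
    timings["total"] = time.perf_counter() - t0

    provenance = {
        "fceq_version": fceq.__version__,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "ica_seed": config.ica.seed,
        "equivalence_seed": config.equivalence.seed,
    }
    result = StudyResult(
        observed=records_to_frame(observed_records),
        null=records_to_frame(null.records),
        equivalence=pd.DataFrame(eq_rows),
        subjects=subjects_df,
        config=config,
        provenance=provenance,
        observed_records=observed_records,
        null_distribution=null,
        timings=timings,
    )
    if out:
        write_table(result.observed, out / "observed.tsv", provenance)
        write_table(result.null, out / "null.tsv", provenance)
        write_table(result.equivalence, out / "equivalence.tsv", provenance)
        write_table(result.subjects, out / "subjects.tsv", provenance)
        config.to_yaml(out / "config.yaml")
    return result


def _subject_arms(prepared, references, config, timings):
    """Observed arm (subject-wise ICA) and the matching permutation null."""
    observed_records: list[SimilarityRecord] = []
    subject_states: list[SubjectState] = []
    subject_rows = []
    for i, sub in enumerate(prepared):
        stage = "ica"
        try:
            t1 = time.perf_counter()
            if config.ica.n_components == "auto":
                k = estimate_model_order(sub.pre, max_order=config.ica.max_auto_order)
            else:
                k = int(config.ica.n_components)
            ica_seed = config.ica.seed + i
            dec_orig = spatial_ica(sub.pre, n_components=k, seed=ica_seed, **_ica_kwargs(config))
            dec_resid = spatial_ica(sub.resid, n_components=k, seed=ica_seed, **_ica_kwargs(config))
            timings["ica"] = timings.get("ica", 0.0) + time.perf_counter() - t1

            stage = "compare"
            row = {"subject_id": sub.sid, "n_components": k, "ica_seed": ica_seed}
            for label, ref in references.items():
                rec = compare_networks(
                    dec_orig,
                    dec_resid,
                    ref,
                    label,
                    z_threshold=config.similarity.z_threshold,
                    subject_id=sub.sid,
                    condition="observed",
                )
                observed_records.append(rec)
                m = match_component(dec_orig, ref, label)
                tc = dec_orig.timecourses[:, m.component_index] * m.sign
                r, z = task_correlation(tc, sub.design, "visual")
                row[f"{label}_component"] = m.component_index
                row[f"{label}_match_pcc"] = m.spatial_pcc
                row[f"{label}_task_r"] = r
                row[f"{label}_task_z"] = z
            subject_rows.append(row)
            subject_states.append(
                SubjectState(
                    subject_id=sub.sid,
                    series=sub.pre,
                    schedules=sub.ground_truth.schedules,
                    original_decomposition=dec_orig,
                    n_components=k,
                    ica_seed=ica_seed,
                )
            )
            log.info("subject %s done (k=%d)", sub.sid, k)
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed for subject '{sub.sid}': {err}") from err

    t1 = time.perf_counter()
    log.info("building permutation null (%d round(s))", config.equivalence.n_rounds)
    null = build_null(
        subject_states,
        references,
        n_rounds=config.equivalence.n_rounds,
        seed=config.equivalence.seed,
        hrf_name=config.glm.hrf_name,
        z_threshold=config.similarity.z_threshold,
        **_ica_kwargs(config),
    )
    timings["null"] = time.perf_counter() - t1
    return observed_records, null, pd.DataFrame(subject_rows)


def _group_records(dec_a, dec_b, boundaries, references, config, sids, condition, perm_index):
    """Per-subject records from two group decompositions: temporal Pcc on the
    subject's time-course slice, spatial metrics shared at group level."""
    records = []
    for label, ref in references.items():
        ma = match_component(dec_a, ref, label)
        mb = match_component(dec_b, ref, label)
        da = fix_sign(dec_a, ma.component_index, ref)
        db = fix_sign(dec_b, mb.component_index, ref)
        tc_a = da.timecourses[:, ma.component_index]
        tc_b = db.timecourses[:, mb.component_index]
        map_a = da.map_3d(ma.component_index)
        map_b = db.map_3d(mb.component_index)
        spatial = pearson(map_a[dec_a.mask], map_b[dec_b.mask])
        dice, reason = dice_at_z(map_a, map_b, config.similarity.z_threshold)
        start = 0
        for sid, end in zip(sids, boundaries):
            records.append(
                SimilarityRecord(
                    subject_id=sid,
                    network_label=label,
                    temporal_pcc=pearson(tc_a[start:end], tc_b[start:end]),
                    spatial_pcc=spatial,
                    dice=dice,
                    condition=condition,
                    permutation_index=perm_index,
                    dice_missing_reason=reason,
                )
            )
            start = end
    return records


def _group_arms(prepared, references, config, timings):
    """Group-concatenated ICA arms (one decomposition for the whole cohort)."""
    sids = [s.sid for s in prepared]
    t1 = time.perf_counter()
    concat_orig = concatenate_cohort([s.pre for s in prepared])
    if config.ica.n_components == "auto":
        k = estimate_model_order(concat_orig, max_order=config.ica.max_auto_order)
    else:
        k = int(config.ica.n_components)
    dec_orig = spatial_ica(concat_orig, n_components=k, seed=config.ica.seed, **_ica_kwargs(config))
    concat_resid = concatenate_cohort([s.resid for s in prepared])
    dec_resid = spatial_ica(
        concat_resid, n_components=k, seed=config.ica.seed, **_ica_kwargs(config)
    )
    observed_records = _group_records(
        dec_orig, dec_resid, concat_orig.boundaries, references, config, sids, "observed", None
    )
    timings["ica"] = timings.get("ica", 0.0) + time.perf_counter() - t1

    subject_rows = [{"subject_id": s.sid, "n_components": k, "ica_seed": config.ica.seed}
                    for s in prepared]

    t1 = time.perf_counter()
    perms = permute_assignments(sids, config.equivalence.n_rounds, config.equivalence.seed)
    by_id = {s.sid: s for s in prepared}
    null_records = []
    for r, perm in enumerate(perms):
        resid_list = []
        for sub in prepared:
            donor = by_id[perm[sub.sid]]
            design = build_design_matrix(
                {c: donor.ground_truth.schedules[c] for c in config.glm.conditions},
                sub.pre.n_volumes,
                sub.pre.tr,
                hrf_name=config.glm.hrf_name,
            )
            glm = fit_glm(sub.pre, design)
            resid_list.append(residualize(sub.pre, glm))
        concat_null = concatenate_cohort(resid_list)
        dec_null = spatial_ica(
            concat_null, n_components=k, seed=config.ica.seed, **_ica_kwargs(config)
        )
        null_records.extend(
            _group_records(
                dec_orig, dec_null, concat_null.boundaries, references, config, sids, "null", r
            )
        )
    null = NullDistribution(
        records=null_records,
        permutation_map=perms,
        n_rounds=config.equivalence.n_rounds,
        seed=config.equivalence.seed,
    )
    timings["null"] = time.perf_counter() - t1
    return observed_records, null, pd.DataFrame(subject_rows)
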