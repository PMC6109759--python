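"""The full study: observed arm vs permutation null, with verdicts.

Runs the end-to-end pipeline on an 8-subject synthetic cohort: residualize
each subject against their own task timing (observed) and against another
subject's timing (null, a random derangement), re-run subject-wise spatial
ICA in both arms, and test per network and metric whether the observed
similarity drop exceeds the equivalency interval.
"""

from fceq import StudyConfig, run_study

config = StudyConfig(n_subjects=8, master_seed=1)
result = run_study(config)

print(result.equivalence.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
for _, row in result.equivalence.iterrows():
    if row.metric != "temporal_pcc":
        continue
    print(
        f"{row.network:6s} temporal Pcc: observed {row.mean_observed:.3f} vs "
        f"null {row.mean_null:.3f}, paired t({row.dof})={row.t:+.2f} -> {row.verdict}"
    )
print()
print("Removing true task variance pushes the visual network's temporal")
print("similarity below the natural variability of residualization (altered),")
print("while the DMN's stays inside the equivalency interval: the task-evoked")
print("negative BOLD response does not carry the DMN's functional connectivity.")
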