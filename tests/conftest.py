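"""Shared fixtures: one synthetic subject carried through the whole pipeline.

Session scope keeps the expensive objects (synthesis, preprocessing, GLM,
ICA) computed once and reused across test modules; every fixture is fully
seeded.
"""

import pytest

from fceq.glm import build_design_matrix, fit_glm, residualize
from fceq.ica import spatial_ica
from fceq.preprocess import run_preprocess
from fceq.synthetic import SceneSpec, generate_cohort

SUBJECT_SEED = 7


@pytest.fixture(scope="session")
def scene():
    return SceneSpec()


@pytest.fixture(scope="session")
def subject(scene):
    """(raw series, ground truth) for one default-scene subject."""
    return generate_cohort(2, SUBJECT_SEED, scene)[0]


@pytest.fixture(scope="session")
def preprocessed(subject):
    series, _ = subject
    return run_preprocess(series)


@pytest.fixture(scope="session")
def design(subject, preprocessed):
    _, gt = subject
    schedules = {c: gt.schedules[c] for c in ("visual", "audio", "motor")}
    return build_design_matrix(schedules, preprocessed.n_volumes, preprocessed.tr)


@pytest.fixture(scope="session")
def glm_result(preprocessed, design):
    return fit_glm(preprocessed, design)


@pytest.fixture(scope="session")
def residualized(preprocessed, glm_result):
    return residualize(preprocessed, glm_result)


@pytest.fixture(scope="session")
def decomposition(preprocessed):
    """Subject-wise decomposition with a pinned model order for determinism."""
    return spatial_ica(preprocessed, n_components=3, seed=0, restarts=3)


@pytest.fixture(scope="session")
def residualized_decomposition(residualized):
    return spatial_ica(residualized, n_components=3, seed=0, restarts=3)
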