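import numpy as np
import pytest

from voicerisk import (
    EmbeddingCohort,
    GeneratorConfig,
    TaskConfig,
    fit_plda,
    generate_cohort,
)
from voicerisk.experiments import vox_like_generator


@pytest.fixture(scope="session")
def vox_cohort():
    """A small single-task cohort in the study's verifier operating band."""
    return generate_cohort(vox_like_generator(n_speakers=300, dim=12, seed=5))


@pytest.fixture(scope="session")
def vox_model(vox_cohort):
    return fit_plda(vox_cohort.X, vox_cohort.speaker_ids, max_iter=50, tol=1e-3)


@pytest.fixture(scope="session")
def multitask_cohort():
    """Three tasks with distinct rotation angles, enough recordings to split."""
    cfg = GeneratorConfig(
        dim=6,
        n_speakers=60,
        tasks=(
            TaskConfig("ref", 3, rotation_angle=0.0),
            TaskConfig("mid", 2, rotation_angle=0.4),
            TaskConfig("far", 2, rotation_angle=1.2, within_scale=0.5),
        ),
        between_cov=1.0,
        within_cov=0.3,
        seed=9,
    )
    return generate_cohort(cfg)


def toy_cohort_1d():
    """The four-recording cohort used for hand ANOVA/EM checks."""
    return EmbeddingCohort(
        recording_ids=np.array(["a1", "a2", "b1", "b2"], dtype=object),
        speaker_ids=np.array(["A", "A", "B", "B"], dtype=object),
        tasks=np.array(["t"] * 4, dtype=object),
        X=np.array([[0.0], [2.0], [10.0], [12.0]]),
    )


@pytest.fixture()
def anova_toy():
    return toy_cohort_1d()
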