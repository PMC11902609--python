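"""Shared fixtures.

The trained tissue model is expensive (~20 s), so one model, one calibrated
unknown threshold and one pipeline config are built per session and shared
by the classifier, pipeline and acceptance tests.
"""

from dataclasses import replace

import numpy as np
import pytest

from busseg import classify as cl
from busseg import phantom as ph
from busseg import pipeline as pl

SESSION_SEED = 1


@pytest.fixture(scope="session")
def base_spec() -> ph.PhantomSpec:
    return ph.PhantomSpec(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def trained_model(base_spec) -> cl.TissueModel:
    frames, annotations = ph.training_bundle([base_spec.without_lesion()], 10)
    return cl.train_model(frames, annotations, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def calibrated_threshold(trained_model, base_spec) -> float:
    frames = [
        ph.generate_phantom(
            replace(base_spec.without_lesion(),
                    seed=ph._child_seed(SESSION_SEED, 900 + i))).frame
        for i in range(3)
    ]
    return cl.calibrate_unknown_threshold(trained_model, frames)


@pytest.fixture(scope="session")
def pipeline_config(calibrated_threshold) -> pl.PipelineConfig:
    return pl.PipelineConfig(unknown_threshold=calibrated_threshold)


@pytest.fixture(scope="session")
def lesioned_sample(base_spec) -> ph.PhantomSample:
    spec = replace(base_spec, seed=101)
    return ph.generate_phantom(spec)


def lesioned_spec(base_spec, k: int, rng: np.random.Generator) -> ph.PhantomSpec:
    """A lesioned phantom spec with a jittered center, distinct per k."""
    cx = base_spec.width / 2 + rng.uniform(-20, 20)
    cy = 0.51 * base_spec.height + rng.uniform(-15, 15)
    return replace(base_spec, seed=ph._child_seed(SESSION_SEED, 100 + k),
                   lesion=replace(base_spec.lesion, center=(cx, cy)))
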