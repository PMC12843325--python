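import numpy as np
import pytest

from gsigait import Layout, RunConfig, SequenceMeta, SkeletonSequence
from gsigait.simulate import CovariateSpec, GaitParams, simulate_sequence, subject_params


@pytest.fixture(scope="session")
def straight_walk():
    """Noise-free normal walk along +X at exactly 1 Hz stride frequency."""
    params = GaitParams(cadence=1.0)
    return simulate_sequence(params, CovariateSpec(view_deg=0.0), duration=4.0,
                             fps=30.0, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def subject1_params():
    return subject_params(seed=1, subject_index=1)


def make_gsi17(frames, fps=30.0, confidence=None, meta=None):
    return SkeletonSequence(layout=Layout.GSI17, frames=np.asarray(frames, float),
                            fps=fps, confidence=confidence, meta=meta or SequenceMeta())


@pytest.fixture
def default_cfg():
    return RunConfig(variant="joints", radius_px=8)


@pytest.fixture(scope="session")
def rendered_cohort10():
    """10 subjects x 10 trials, lateral view, 5 mm joint noise, rendered as
    joint-based templates at radius 8 — the reference synthetic cohort."""
    from gsigait.recognition import render_templates
    from gsigait.simulate import make_cohort

    m = make_cohort(10, 10, views=(90.0,), covariates=("NM",), seed=1, noise_sigma=0.005)
    return render_templates(m, RunConfig(variant="joints", radius_px=8))
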