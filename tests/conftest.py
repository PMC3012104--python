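"""Shared fixtures: trained toy models are expensive, so build them once."""

import numpy as np
import pytest

from ctxsal import (
    PlantedModel,
    fit_structured_ica,
    gen_structured_samples,
    make_demo_static_model,
    make_demo_video_model,
)


@pytest.fixture(scope="session")
def static_model_and_scenes():
    """Reference static model trained on Gabor-texture scenes (one per session)."""
    return make_demo_static_model(seed=0)


@pytest.fixture(scope="session")
def static_model(static_model_and_scenes):
    return static_model_and_scenes[0]


@pytest.fixture(scope="session")
def video_model():
    """Reference spatiotemporal model trained on drifting textures."""
    model, _ = make_demo_video_model(seed=0)
    return model


@pytest.fixture(scope="session")
def planted_fit():
    """Structured-ICA fit on planted-model data plus the ground truth.

    Returns (ica_model, batch, s_s, s_u, planted_model); shared by the
    recovery, sufficiency and round-trip tests.
    """
    pm = PlantedModel.random(d_c=12, d_s=16, k_s=8, k_u=4, seed=3)
    batch, s_s, s_u = gen_structured_samples(pm, 50_000, seed=7)
    ica = fit_structured_ica(batch, k_c=12, k_s=8, k_u=4, seed=1)
    return ica, batch, s_s, s_u, pm


def matched_abs_corr(U: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Absolute correlations after optimally matching recovered to planted sources."""
    from scipy.optimize import linear_sum_assignment

    k = U.shape[1]
    C = np.corrcoef(U.T, S.T)[:k, k:]
    ri, ci = linear_sum_assignment(-np.abs(C))
    return np.abs(C[ri, ci])
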