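"""Shared fixtures: tiny synthetic cohorts, a small model, and the
session-scoped end-to-end study runs reused by the slower integration tests."""

from __future__ import annotations

import numpy as np
import pytest

from pathomil.model import FusionMILModel, ModelConfig, init_params
from pathomil.pipeline import StudyResult, run_synthetic_study
from pathomil.simulate import SimConfig, simulate_cohort
from pathomil.types import OmicsSchema


@pytest.fixture(scope="session")
def tiny_cohort():
    """30 samples, small bags, narrow omics — enough to exercise every path."""
    return simulate_cohort(
        SimConfig(
            n_samples=30,
            patches_min=4,
            patches_max=8,
            feature_dim=6,
            n_mrna=12,
            n_mutations=4,
            n_immune=5,
            seed=11,
        )
    )


@pytest.fixture()
def tiny_model(tiny_cohort):
    """Small randomly-parameterized model matched to the tiny cohort."""
    config = ModelConfig(
        feature_dim=6,
        omics_schema=tiny_cohort.omics[0].schema,
        d_img=5,
        attention_hidden=4,
        dropout=0.0,
    )
    model = FusionMILModel(config, seed=3)
    rng = np.random.default_rng(7)  # heads init to zero; randomize for generic tests
    for key in ("cls_w", "cls_b", "risk_w", "risk_b", "time_w", "time_b"):
        t = model.params.tensors[key]
        t += rng.normal(scale=0.3, size=t.shape)
    return model


@pytest.fixture(scope="session")
def study_runs() -> list[StudyResult]:
    """Three full desk-scale studies (seeds 0-2): simulate, train, evaluate."""
    return [run_synthetic_study(seed) for seed in (0, 1, 2)]


@pytest.fixture(scope="session")
def default_schema():
    return OmicsSchema()
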