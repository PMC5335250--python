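"""Shared fixtures: small synthetic cohorts reused across test modules."""

import dataclasses

import numpy as np
import pytest

from holophase import pipeline, synthetic


def centered_phantom(class_label, seed, shape=(512, 512), **overrides):
    """Deterministic phantom placed at the field centre, with overrides."""
    phantom = synthetic.make_phantom(class_label, seed)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    return dataclasses.replace(phantom, center=center, **overrides)


@pytest.fixture(scope="session")
def small_cohort():
    """12-cell cohort on a 256 px detector: fast but fully representative."""
    cfg = synthetic.OpticalConfig(detector_shape=(256, 256))
    return synthetic.make_cohort((4, 4, 4), cfg=cfg, seed=11)


@pytest.fixture(scope="session")
def small_phase_maps(small_cohort):
    from holophase.reconstruct import ReconstructionParams

    params = ReconstructionParams(roi_size=220)
    return pipeline.reconstruct_cohort(small_cohort, params)


@pytest.fixture(scope="session")
def small_features(small_cohort, small_phase_maps):
    return pipeline.featurize_cohort(
        small_phase_maps, small_cohort.spectra, small_cohort.labels
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
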