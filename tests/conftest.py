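"""Shared fixtures: expensive synthetic cohorts are built once per session."""

import numpy as np
import pytest

from embryograd import compute_features, fit_profile, generate_cohort
from embryograd.synthetic import EmbryoScene, NoiseSpec, render_embryo_image


@pytest.fixture(scope="session")
def three_stage_cohort():
    """60 embryos, 20 per main stage, default noise (additive sd 2 a.u.)."""
    return generate_cohort(["cleavage", "syncytial", "cc14"], 20, seed=42)


@pytest.fixture(scope="session")
def cohort_features(three_stage_cohort):
    """2-exp fits and staging features for the three-stage cohort."""
    feats, labels = [], []
    for rec in three_stage_cohort:
        fa = fit_profile(rec.apical, "2exp", (10, 90))
        fb = fit_profile(rec.basal, "2exp", (10, 90))
        feats.append(
            compute_features(fa, fb, rec.embryo_id, stage=rec.stage)
        )
        labels.append(rec.stage)
    return feats, np.array(labels, dtype=object)


@pytest.fixture(scope="session")
def noiseless_scene_image():
    """A clean rendered sagittal section: no noise, texture or nuclei."""
    scene = EmbryoScene(noise=NoiseSpec())
    return scene, render_embryo_image(scene)
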