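"""Shared fixtures: small phantoms for unit tests, a full-size standardized
cohort (built once per session) for the end-to-end statistical checks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import torsonorm as tn

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

SMALL = 48   # grid edge for unit-test phantoms
FULL = 64    # grid edge for end-to-end cohort work


def small_config(**kw) -> tn.PhantomConfig:
    defaults = dict(grid_shape=(SMALL, SMALL, SMALL), noise_sd=0.0, seed=0)
    defaults.update(kw)
    return tn.PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def phantom_small():
    """Noiseless small phantom: (volume, truth)."""
    return tn.generate_phantom(small_config())


@pytest.fixture(scope="session")
def body_small(phantom_small):
    vol, _ = phantom_small
    return tn.extract_body_mask(vol)


@pytest.fixture(scope="session")
def planes_small(phantom_small, body_small):
    vol, _ = phantom_small
    planes, _flags = tn.detect_all_planes(vol, body_small)
    return planes


@pytest.fixture(scope="session")
def standard_small(phantom_small):
    vol, _ = phantom_small
    return tn.make_standard_body(vol)


@pytest.fixture(scope="session")
def full_base_config():
    return tn.PhantomConfig(grid_shape=(FULL, FULL, FULL), noise_sd=0.1, seed=0)


@pytest.fixture(scope="session")
def standard_full():
    """The full-size standard body: the base-physique noiseless phantom."""
    vol, truth = tn.generate_phantom(
        tn.PhantomConfig(grid_shape=(FULL, FULL, FULL), noise_sd=0.0, seed=1))
    return tn.make_standard_body(vol), vol, truth


@pytest.fixture(scope="session")
def normal_cohort(full_base_config, standard_full):
    """50 jittered normal phantoms standardized onto the standard body.

    Returns (standardized_volumes, truths, reports, standard).
    """
    standard, _vol, _truth = standard_full
    cfg = tn.PipelineConfig()
    vols, truths, reports = [], [], []
    for vol, truth in tn.phantom_population(full_base_config, 50, seed=101):
        out, rep = tn.standardize(vol, standard, cfg)
        vols.append(out)
        truths.append(truth)
        reports.append(rep)
    return vols, truths, reports, standard


@pytest.fixture(scope="session")
def normal_model(normal_cohort):
    vols, _truths, _reports, standard = normal_cohort
    return tn.build_model(vols, "male", valid_mask=standard.body_mask)
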