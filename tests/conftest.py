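"""Shared fixtures.

Heavy resources are session-scoped and lazy: the analytic template and
small phantom subjects are built once and reused.  Grid sizes are chosen
per test tier: tiny (32^3 @ 2 mm) for unit tests of numerics, small
(48^3 @ 2 mm) for pipeline integration and the cohort-level acceptance
run, and the full default scale (96^3 @ 1.5 mm) where an acceptance
criterion is tied to default study conditions.
"""

import numpy as np
import pytest
from hypothesis import settings

from amypipe.phantom import (
    PhantomParams,
    make_template,
    synthesize_cohort,
    synthesize_subject,
)
from amypipe.pipelines import PipelineRunner

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def template32():
    return make_template((32, 32, 32), 2.0)


@pytest.fixture(scope="session")
def template48():
    return make_template((48, 48, 48), 2.0)


@pytest.fixture(scope="session")
def params48():
    return PhantomParams(grid_shape=(48, 48, 48), spacing_mm=2.0)


@pytest.fixture(scope="session")
def pair48(template48, params48):
    """One AD and one HC subject at the small integration scale."""
    ad = synthesize_subject(template48, "AD", 101, params48, subject_id="AD01")
    hc = synthesize_subject(template48, "HC", 202, params48, subject_id="HC01")
    return ad, hc


@pytest.fixture(scope="session")
def clean_pair48(template48):
    """Noise-free, blur-free, perfectly aligned AD and HC subjects."""
    p = PhantomParams(
        grid_shape=(48, 48, 48), spacing_mm=2.0,
        psf_fwhm_mm=0.0, pet_noise_sd=0.0, mri_noise_sd=0.0,
        bias_field_amplitude=0.0, pet_rigid_max_mm=0.0, pet_rigid_max_deg=0.0,
    )
    ad = synthesize_subject(template48, "AD", 101, p, subject_id="AD01")
    hc = synthesize_subject(template48, "HC", 202, p, subject_id="HC01")
    return ad, hc


@pytest.fixture(scope="session")
def template96():
    return make_template((96, 96, 96), 1.5)


@pytest.fixture(scope="session")
def cohort_table48(template48, params48):
    """Full default cohort (12 AD + 16 HC) run through all 15 pipelines
    at the small CI grid.  Built once; several acceptance criteria and the
    structural checks read from it."""
    from amypipe.pipelines import enumerate_pipelines

    subjects, manifest = synthesize_cohort(template48, params48)
    runner = PipelineRunner(template48)
    specs = enumerate_pipelines(1.5) + enumerate_pipelines(1.2)
    table = runner.run_cohort(subjects, specs)
    return table, manifest


def rng(seed=0):
    return np.random.default_rng(seed)
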