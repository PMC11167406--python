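"""Shared fixtures.

Everything is generated programmatically at test time.  The expensive
session fixtures (simulated cohorts with full model inversions) are built
once and shared by the group-level and acceptance tests; their problem
sizes are deliberately desk-scale (short protocols, small cohorts).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import taskdcm as t
from taskdcm import grid as gmod
from taskdcm.config import GroupSpecConfig, PipelineConfig
from taskdcm.dcm import VLOptions
from taskdcm.protocol import ProtocolParams

#: desk-scale protocol used throughout: 6 blocks (3 per condition) keeps a
#: run near 7 minutes of scan time instead of 27
SMALL_PROTOCOL = ProtocolParams(n_blocks=6)

#: inversion options for study-scale runs: enough iterations for the noise
#: precisions to settle without burning time on tail refinement
STUDY_VL = VLOptions(max_iter=16, min_iter=4, tol_F=0.05)


@pytest.fixture(scope="session")
def small_protocol():
    return t.generate_protocol(SMALL_PROTOCOL, seed=11)


@pytest.fixture(scope="session")
def default_protocol():
    return t.generate_protocol(seed=7)


@pytest.fixture(scope="session")
def small_behavior(small_protocol):
    return t.simulate_behavior(small_protocol, error_rate=0.03, seed=12)


@pytest.fixture(scope="session")
def study_config():
    return PipelineConfig(
        protocol=SMALL_PROTOCOL,
        group=GroupSpecConfig(n_subjects=30),
        vl=STUDY_VL,
        seed=1234,
    )


@pytest.fixture(scope="session")
def study_cohort(study_config):
    """The shared synthetic cohort processed by the acceptance tests."""
    return gmod.simulate_src_cohort(study_config)


@pytest.fixture(scope="session")
def inversion_cache():
    return gmod.InversionCache()


@pytest.fixture(scope="session")
def cond_event(study_cohort, study_config, inversion_cache):
    """Event-related design condition (AllTrials, uncorrected, Anti, GSR)."""
    c = gmod.Condition("with", "AllTrials", "Anti", "uncorrected")
    return gmod.run_condition(study_cohort, c, study_config, cache=inversion_cache)


@pytest.fixture(scope="session")
def directional_config():
    """Noisier, smaller cohort for the design-comparison checks.

    Recovery checks use the cleaner cohort above (strong planted effects
    need high SNR at desk scale); the event-vs-block design comparison is
    a noise-regime phenomenon, so it runs at a more realistic noise level.
    """
    return PipelineConfig(
        protocol=SMALL_PROTOCOL,
        group=GroupSpecConfig(n_subjects=16, noise_sd=0.25),
        vl=STUDY_VL,
        seed=555,
    )


@pytest.fixture(scope="session")
def directional_cohort(directional_config):
    return gmod.simulate_src_cohort(directional_config)


@pytest.fixture(scope="session")
def cond_event_noisy(directional_cohort, directional_config, inversion_cache):
    c = gmod.Condition("with", "AllTrials", "Anti", "uncorrected")
    return gmod.run_condition(
        directional_cohort, c, directional_config, cache=inversion_cache
    )


@pytest.fixture(scope="session")
def cond_blocks_noisy(directional_cohort, directional_config, inversion_cache):
    c = gmod.Condition("with", "Blocks", "Anti", "uncorrected")
    return gmod.run_condition(
        directional_cohort, c, directional_config, cache=inversion_cache
    )


def _subcohort(cohort, n):
    sub = dataclasses.replace(cohort)
    sub.subjects = cohort.subjects[:n]
    sub.behaviors = cohort.behaviors[:n]
    return sub


@pytest.fixture(scope="session")
def cond_nogsr(study_cohort, study_config, inversion_cache):
    """No-GSR variant on a 12-subject subset (paired with cond_event)."""
    c = gmod.Condition("without", "AllTrials", "Anti", "uncorrected")
    return gmod.run_condition(
        _subcohort(study_cohort, 12), c, study_config, cache=inversion_cache
    )


@pytest.fixture(scope="session")
def cond_corrected(study_cohort, study_config, inversion_cache):
    """Cluster-corrected variant on a 12-subject subset."""
    c = gmod.Condition("with", "AllTrials", "Anti", "corrected")
    return gmod.run_condition(
        _subcohort(study_cohort, 12), c, study_config, cache=inversion_cache
    )


@pytest.fixture(scope="session")
def null_edge_cohort_result(study_cohort, study_config, inversion_cache):
    """A second cohort whose ground truth lacks the LIPS->LPMC modulation.

    Processed under the same event-related condition as ``cond_event``;
    used for the between-group planted-difference check.
    """
    import taskdcm.cohort as cmod
    from taskdcm.cohort import DCMParameters, default_group_mean

    mean = default_group_mean()
    idx = {n: i for i, n in enumerate(study_cohort.template.names)}
    B = mean.B.copy()
    B[0, idx["LPMC"], idx["LIPS"]] = 0.0
    cfgB = dataclasses.replace(
        study_config, group=GroupSpecConfig(n_subjects=24), seed=4321
    )
    groupB = cfgB.group.build(mean=DCMParameters(A=mean.A, B=B, C=mean.C))
    protocol = study_cohort.protocol
    stim = t.stimulus_functions(
        protocol, None, study_config.truth_design, study_config.truth_contrast
    )
    subjects = cmod.simulate_cohort(
        groupB, stim, study_cohort.template, protocol.tr_seconds,
        protocol.n_volumes, hparams=cfgB.hemo, seed=4321,
    )
    cohortB = gmod.CohortData(
        protocol=protocol,
        behaviors=[
            t.simulate_behavior(protocol, cfgB.error_rate, cfgB.rt, seed=5000 + i)
            for i in range(24)
        ],
        subjects=[
            dataclasses.replace(s, subject_id=f"B-{s.subject_id}")
            for s in subjects
        ],
        template=study_cohort.template,
        config=cfgB,
        seed=4321,
    )
    c = gmod.Condition("with", "AllTrials", "Anti", "uncorrected")
    return gmod.run_condition(cohortB, c, cfgB, cache=inversion_cache)
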