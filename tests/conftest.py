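"""Shared fixtures: simulated selections at unit-test and full study scale."""

from __future__ import annotations

import pytest

import csrselect as cs


@pytest.fixture(scope="session")
def two_point_library():
    return cs.build_library(cs.two_point_spec())


@pytest.fixture(scope="session")
def reference(two_point_library):
    return two_point_library.spec.reference()


@pytest.fixture(scope="session")
def small_sim(two_point_library):
    """Light 400-variant selection (5k reads/round) for unit tests."""
    lib, config = cs.default_scenario(seed=11, pre_depth=5_000, post_depth=5_000)
    return cs.simulate_dataset(lib, config)


@pytest.fixture(scope="session")
def study_sim():
    """The package's reference study conditions: 400 variants, 10 winners,
    20 cycles, 1e5 reads per round."""
    lib, config = cs.default_scenario(seed=1)
    return cs.simulate_dataset(lib, config)


@pytest.fixture(scope="session")
def study_labels(study_sim):
    """Per-read genotype labels for both rounds of the study simulation.

    Genotype calling is the slow step, so call once and share.
    """
    ref = study_sim.library.spec.reference()
    labels_r0 = cs.call_labels(study_sim.r0.sequences, ref)
    labels_r1 = cs.call_labels(study_sim.r1.sequences, ref)
    return labels_r0, labels_r1


@pytest.fixture(scope="session")
def study_classified(study_sim, study_labels):
    labels_r0, labels_r1 = study_labels
    table = cs.build_count_table(labels_r0, labels_r1)
    return cs.classify_variants(table)
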