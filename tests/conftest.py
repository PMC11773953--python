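"""Shared fixtures.

The session-scoped "study" fixtures build one desk-scale synthetic study
(8 cohorts, 60 miRNAs x 300 genes, 120 samples/cohort, 500 planted pairs)
and run the 20-models-per-rate ensemble on it once; several tests inspect
different aspects of the same run.
"""

from __future__ import annotations

import pytest

import mirtarget as mt

STUDY_SEED = 7
N_MODELS = 20
RATES = (0.01, 0.05, 0.1, 0.5, 1.0)


@pytest.fixture(scope="session")
def study():
    config = mt.SimulationConfig(seed=STUDY_SEED)
    panels, truth = mt.simulate_panels(config)
    return config, panels, truth


@pytest.fixture(scope="session")
def study_feature_table(study):
    _, panels, _ = study
    return mt.build_feature_table(panels)


@pytest.fixture(scope="session")
def study_dbs(study):
    _, _, truth = study
    training = mt.InteractionDB(
        "synthetic-training", "training", frozenset(truth.pairs_by_tier("training"))
    )
    heldout = mt.InteractionDB(
        "synthetic-heldout", "validation", frozenset(truth.pairs_by_tier("heldout"))
    )
    return training, heldout


@pytest.fixture(scope="session")
def study_labels(study_feature_table, study_dbs):
    training, _ = study_dbs
    return mt.assign_labels(study_feature_table, [training])


@pytest.fixture(scope="session")
def study_consensus(study_feature_table, study_labels):
    config = mt.EnsembleConfig(
        downsample_rates=RATES, n_models=N_MODELS, base_seed=STUDY_SEED
    )
    return mt.run_suite(study_feature_table, study_labels, config)


@pytest.fixture()
def tiny_panels():
    """A fast 4-cohort panel set with planted structure for unit tests."""
    config = mt.SimulationConfig(
        n_cohorts=4,
        n_mirnas=10,
        n_genes=40,
        samples_per_cohort=60,
        n_planted_training=15,
        n_planted_heldout=5,
        n_planted_undiscovered=5,
        seed=11,
    )
    return mt.simulate_panels(config)
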