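"""Shared fixtures: a small synthetic dataset for unit tests and the
full-size study fixture used by the acceptance suite."""

from __future__ import annotations

import pandas as pd
import pytest

from forestbind import ensemble, features, intervals, motifs, simulate

TINY_SEED = 5
STUDY_SEED = 11  # dataset seed for the full-size study fixture
TRAIN_CHROMS = {"chr1"}
TEST_CHROMS = {"chr2"}


@pytest.fixture(scope="session")
def tiny_config():
    return simulate.default_config(
        n_tissues=2, n_decoys=10, seed=TINY_SEED, genome_length=50_000,
        n_bound_sites_per_tissue=60, n_decoy_peaks_per_tissue=40)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate.simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_psems(tiny_config):
    return [motifs.pwm_to_psem(m) for m in tiny_config.all_motifs()]


def peak_feature_matrices(dataset, psems):
    return {t: features.build_peak_features(
        dataset.bins, dataset.merged_peaks(t), psems, dataset.genome,
        dataset.peak_track(t)) for t in dataset.config.tissues}


def balanced_tissue_data(dataset, matrices, seed, holdout=TEST_CHROMS):
    """Balanced per-tissue (X, y) pairs on the training chromosomes."""
    train_lab = intervals.exclude_held_out(dataset.labels, holdout)
    key = pd.MultiIndex.from_frame(train_lab[["chrom", "start", "end"]])
    out = {}
    for i, tissue in enumerate(dataset.config.tissues):
        ts = intervals.balance_sample(train_lab, tissue, seed=seed * 100 + i)
        out[tissue] = (matrices[tissue].reindex(key).iloc[ts.indices], ts.y)
    return out


def heldout_test_view(dataset, matrices, tissue, chroms=TEST_CHROMS):
    """Test rows (A excluded) and binary truth for one tissue on held-out chromosomes."""
    test_lab = intervals.select_chromosomes(dataset.labels, chroms)
    key = pd.MultiIndex.from_frame(test_lab[["chrom", "start", "end"]])
    keep = test_lab[tissue].isin(["B", "U"]).to_numpy()
    X = matrices[tissue].reindex(key)[keep]
    y = (test_lab[tissue] == "B").astype(int).to_numpy()[keep]
    return X, y


@pytest.fixture(scope="session")
def tiny_tissue_data(tiny_dataset, tiny_psems):
    mats = peak_feature_matrices(tiny_dataset, tiny_psems)
    return balanced_tissue_data(tiny_dataset, mats, seed=7)


# ---------------------------------------------------------------------------
# Full-size study fixture (3 tissues, 2 x 200 kb, 500 sites/tissue, no noise)

@pytest.fixture(scope="session")
def study_config():
    return simulate.default_config(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_dataset(study_config):
    return simulate.simulate_dataset(study_config)


@pytest.fixture(scope="session")
def study_psems(study_config):
    return [motifs.pwm_to_psem(m) for m in study_config.all_motifs()]


@pytest.fixture(scope="session")
def study_matrices(study_dataset, study_psems):
    return peak_feature_matrices(study_dataset, study_psems)


@pytest.fixture(scope="session")
def study_tissue_data(study_dataset, study_matrices):
    return balanced_tissue_data(study_dataset, study_matrices, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_model(study_tissue_data):
    """Two-step ensemble trained on all three tissues (200 trees)."""
    X, y, tags = ensemble.stack_tissue_data(study_tissue_data)
    model = ensemble.EnsembleBindingClassifier(n_estimators=200, t=20,
                                               random_state=STUDY_SEED)
    return model.fit(X, y, tissues=tags)
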