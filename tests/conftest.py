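"""Shared fixtures: one full-scale synthetic study suite with the complete
trained stack (feature pipeline, autoencoder, GPR age model, normative
model), built once per session and reused by the unit and acceptance tests."""

import warnings

import numpy as np
import pytest

import tractage as ta
from tractage.age_model import BrainAgeModel, add_sex_feature
from tractage.preprocess import TractFeaturePipeline

warnings.filterwarnings("ignore", category=FutureWarning)

SUITE_SEED = 20251


@pytest.fixture(scope="session")
def study_suite():
    """Full-scale study cohorts (300/40/524/37/18/17) at default noise."""
    return ta.make_study_suite(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def fitted_pipeline(study_suite):
    connectograms, table = study_suite["train"]
    pipe = TractFeaturePipeline()
    pipe.fit(connectograms, table["age"].to_numpy())
    return pipe


@pytest.fixture(scope="session")
def cohort_features(study_suite, fitted_pipeline):
    """Frozen-pipeline 532-feature matrices for every cohort."""
    return {
        name: (fitted_pipeline.transform(connectograms), table)
        for name, (connectograms, table) in study_suite.items()
    }


@pytest.fixture(scope="session")
def trained_encoder(cohort_features):
    """Default-architecture sparse autoencoder trained on the training set."""
    F_train, _ = cohort_features["train"]
    return ta.SparseAutoencoder(random_state=0).fit(F_train)


@pytest.fixture(scope="session")
def age_stack(cohort_features, trained_encoder):
    """Trained GPR age model plus encoded (+sex) inputs for every cohort."""
    X = {
        name: add_sex_feature(trained_encoder.transform(F), table["sex"].to_numpy())
        for name, (F, table) in cohort_features.items()
    }
    ages = cohort_features["train"][1]["age"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BrainAgeModel(random_state=0).fit(X["train"], ages)
    return {"model": model, "X": X}


@pytest.fixture(scope="session")
def normative_fit(cohort_features):
    F, table = cohort_features["normative"]
    return ta.NormativeModel().fit(F, table["age"].to_numpy(),
                                   table["sex"].to_numpy())


@pytest.fixture(scope="session")
def study_pads(age_stack, cohort_features):
    """PAD per study group from the trained model."""
    pads = {}
    for group in ("control", "lmtle", "rmtle"):
        _, table = cohort_features[group]
        predicted = age_stack["model"].predict(age_stack["X"][group])
        pads[group] = predicted - table["age"].to_numpy()
    return pads


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
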