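"""Shared fixtures: a small synthetic cohort and its feature table.

Session-scoped because cohort generation plus LSA fitting is the expensive
part of the suite and the objects are immutable from the tests' view.
"""

import pytest

from speechmarkers import (
    default_cohort_config,
    generate_cohort,
    synthetic_study_extractor,
)


@pytest.fixture(scope="session")
def cohort():
    """Default 68-transcript cohort (15 NAR / 45 AR / 8 FEP), seed 1."""
    transcripts, labels = generate_cohort(default_cohort_config(seed=1))
    return transcripts, labels


@pytest.fixture(scope="session")
def feature_table(cohort):
    """Full feature table of the default cohort under the study extractor."""
    transcripts, labels = cohort
    return synthetic_study_extractor().fit_transform(transcripts)


@pytest.fixture(scope="session")
def fitted_space(cohort):
    transcripts, _ = cohort
    extractor = synthetic_study_extractor().fit(transcripts)
    return extractor.space_
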