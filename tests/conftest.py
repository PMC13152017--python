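import numpy as np
import pandas as pd
import pytest

from kinescreen import features, posenorm, preprocess, synthetic
from kinescreen.keypoint_io import POSITIVE_LABEL


def extract_cohort_features(cohort):
    """Run the full preprocess -> normalize -> featurize path on a SynthCohort."""
    vecs = []
    labels = []
    for raw, rec in cohort.subjects:
        clean = preprocess.preprocess_pipeline(raw)
        norm = posenorm.head_up_normalize(clean)
        vecs.append(features.feature_vector(norm, label=rec.label))
        labels.append(1 if rec.label == POSITIVE_LABEL else 0)
    table = features.feature_table(vecs)
    return table, np.asarray(labels)


@pytest.fixture(scope="session")
def small_norm_seq():
    """A single preprocessed, normalized synthetic sequence (30 s at 30 FPS)."""
    raw, _ = synthetic.generate_subject(
        synthetic.TYPICAL_PARAMS, fps=30.0, duration_s=30.0, seed=7,
        subject_id="fixture0",
    )
    clean = preprocess.preprocess_pipeline(raw)
    return posenorm.head_up_normalize(clean)


@pytest.fixture(scope="session")
def signal_cohort_features():
    """Features + labels for a 900-subject separable cohort (shared by the
    heavy acceptance tests; short videos to stay inside the CI budget)."""
    config = synthetic.SynthConfig(
        n_subjects=900, prevalence=0.12, effect_size=1.0,
        duration_range_s=(20.0, 25.0), seed=11,
    )
    return extract_cohort_features(synthetic.generate_cohort(config))


@pytest.fixture(scope="session")
def null_cohort_features():
    """Features + labels for a cohort whose classes are identically distributed."""
    config = synthetic.SynthConfig(
        n_subjects=400, prevalence=0.12, effect_size=0.0,
        duration_range_s=(20.0, 25.0), seed=13,
    )
    return extract_cohort_features(synthetic.generate_cohort(config))
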