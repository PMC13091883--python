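import numpy as np
import pytest

from recallseg.classify import ClassifierSpec
from recallseg.synthetic import StoryConfig, SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced-scale study: 2 stories, 9 subjects, 12 ROIs, planted effect."""
    return SyntheticConfig(
        stories=(
            StoryConfig("alpha", 400.0, 5, 15, clip_story_onset_s=9.0, run_trs=294),
            StoryConfig("beta", 300.0, 4, 12, clip_story_onset_s=12.0),
        ),
        subjects_per_story=9,
        n_rois=12,
        effect_size=3.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def study_dir(small_study, tmp_path_factory):
    from recallseg.io import write_study

    d = tmp_path_factory.mktemp("study")
    write_study(small_study, d)
    return d


@pytest.fixture(scope="session")
def fast_classifiers():
    return (
        ClassifierSpec("logistic"),
        ClassifierSpec("random_forest", n_trees=20, seed=0),
        ClassifierSpec("svm"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
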