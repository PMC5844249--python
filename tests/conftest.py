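import pytest

from editome.pipeline import detect_study
from editome.simulate import SimConfig, simulate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The default synthetic cohort: 190 kb genome, 100 samples, depth 30."""
    outdir = tmp_path_factory.mktemp("study")
    return simulate_study(SimConfig(seed=STUDY_SEED), outdir)


@pytest.fixture(scope="session")
def detection(study):
    """Full-cascade detection over every sample of the default cohort."""
    return detect_study(study)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 6-sample cohort for cheap unit-level checks."""
    outdir = tmp_path_factory.mktemp("small_study")
    return simulate_study(SimConfig(seed=1, n_samples=6), outdir)
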