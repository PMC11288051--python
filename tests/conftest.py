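import pytest

import crisprself as cs

FIXTURE_SEED = 11
FIXTURE_LEN = 400_000


@pytest.fixture(scope="session")
def study_sg():
    """Planted-truth synthetic genome shared by the whole suite."""
    return cs.synthesize_genome(
        cs.study_fixture_config(seed=FIXTURE_SEED, contig_length=FIXTURE_LEN)
    )


@pytest.fixture(scope="session")
def study_arrays(study_sg):
    return cs.detect_arrays(study_sg.genome)


@pytest.fixture(scope="session")
def study_hits(study_sg, study_arrays):
    return cs.find_self_targets(study_sg.genome, study_arrays)
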