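import numpy as np
import pytest

from ytriage import genecopy, synthetic_data as sd
from ytriage.homology import SeedIndex, build_index


@pytest.fixture(scope="session")
def paper_fixture():
    """The full-architecture fixture study at the default seed."""
    return sd.generate_fixture(sd.paper_preset(42))


@pytest.fixture(scope="session")
def paper_y_index(paper_fixture):
    return SeedIndex(paper_fixture.y_contigs, k=15)


@pytest.fixture(scope="session")
def paper_x_index(paper_fixture):
    return build_index(
        [s for s in paper_fixture.female_reference if s.scaffold_class == "X"], k=15
    )


@pytest.fixture(scope="session")
def paper_gene_models(paper_fixture, paper_y_index):
    """Detected gene models and copy summaries for every fixture transcript."""
    out = {}
    for transcript in paper_fixture.transcripts:
        params = genecopy.GeneParams(cross_species=(transcript.id == "AMELY"))
        models = genecopy.detect_copies(transcript.id, transcript, paper_y_index, params)
        splits = genecopy.detect_split_genes(models)
        out[transcript.id] = (models, splits, genecopy.copy_summary(models, splits))
    return out


@pytest.fixture(scope="session")
def small_fixture():
    return sd.generate_fixture(sd.small_preset(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
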