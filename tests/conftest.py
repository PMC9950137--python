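import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from paleofmo import evomodel
from paleofmo.formats import Alignment, parse_newick


@pytest.fixture(scope="session")
def jtt_model():
    """The reconstruction settings used throughout: JTT, alpha=1.114, K=4."""
    return evomodel.build_model(matrix_name="JTT", alpha=1.114, K=4)


@pytest.fixture(scope="session")
def quartet_tree():
    return parse_newick("((A:0.1,B:0.25)AB:0.05,(C:0.3,D:0.15)CD:0.2)R;")


def _balanced_newick(n_leaves: int, t: float = 0.05) -> str:
    labels = [f"L{i}" for i in range(n_leaves)]

    def build(k):
        if k == 1:
            return labels.pop(0) + f":{t}"
        return f"({build(k // 2)},{build(k - k // 2)}):{t}"

    inner = build(n_leaves)
    return inner.rsplit(":", 1)[0] + "R;"


@pytest.fixture(scope="session")
def balanced16_tree():
    """16-leaf balanced tree, every branch 0.05 substitutions/site."""
    return parse_newick(_balanced_newick(16))


@pytest.fixture
def random_alignment():
    def make(ids, n_sites, seed=0):
        rng = np.random.default_rng(seed)
        seqs = [
            "".join(rng.choice(list(evomodel.AMINO_ACIDS), n_sites))
            for _ in ids
        ]
        return Alignment(list(ids), seqs)

    return make
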