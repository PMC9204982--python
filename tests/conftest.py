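import numpy as np
import pytest

from xdta.encoding import InteractionRecord
from xdta.model import AffinityCNN, NetworkSpec
from xdta.similarity import SimilarityMatrix

TINY_NETSPEC = NetworkSpec(
    prot_conv=((8, 3), (12, 3)),
    smiles_conv=((8, 3),),
    dense=(16,),
    dropout_rate=0.0,
    learning_rate=1e-3,
)


@pytest.fixture(scope="session")
def tiny_net():
    """A small untrained two-branch CNN with fixed seed."""
    return AffinityCNN(TINY_NETSPEC, prot_len=12, prot_dict_size=4,
                       smiles_len=10, smiles_dict_size=3, seed=7)


@pytest.fixture
def random_onehot():
    """Factory for random one-hot batches matching tiny_net's input shapes."""
    def make(n, rng=None):
        rng = rng or np.random.default_rng(0)
        xp = np.zeros((n, 12, 4), dtype=np.float32)
        xs = np.zeros((n, 10, 3), dtype=np.float32)
        for i in range(n):
            lp = int(rng.integers(6, 13))
            ls = int(rng.integers(5, 11))
            xp[i, np.arange(lp), rng.integers(0, 4, lp)] = 1.0
            xs[i, np.arange(ls), rng.integers(0, 3, ls)] = 1.0
        return xp, xs
    return make


def toy_records(pkds):
    """Records P0..Pn / C0..Cn with the given pKd labels."""
    out = []
    for i, pkd in enumerate(pkds):
        out.append(InteractionRecord(
            protein_id=f"P{i}", protein_seq="ACDEFGHIKL",
            compound_id=f"C{i}", smiles="CCO",
            kd_nM=10 ** (9 - pkd), pkd=pkd,
        ))
    return out


def random_similarity(ids, rng):
    """A random symmetric [0,1] similarity matrix with unit diagonal."""
    n = len(ids)
    a = rng.random((n, n))
    v = (a + a.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(ids=tuple(ids), values=v)
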