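import numpy as np
import pytest

from guideforest import duplex, qproperties
from guideforest.encode import Guide


@pytest.fixture(scope="session")
def small_enumeration():
    """All duplex k-mers up to dimers, both classes."""
    return [
        ident
        for k in (1, 2)
        for ident in duplex.enumerate_kmers(k, duplex.DUPLEX_CLASSES)
    ]


@pytest.fixture(scope="session")
def small_table(small_enumeration):
    """Synthetic quantum-property table complete over k<=2."""
    return qproperties.synth_table(small_enumeration, seed=11)


@pytest.fixture(scope="session")
def full_table():
    """Synthetic quantum-property table complete over k<=4, both classes."""
    ids = [
        ident
        for k in (1, 2, 3, 4)
        for ident in duplex.enumerate_kmers(k, duplex.DUPLEX_CLASSES)
    ]
    return qproperties.synth_table(ids, seed=11)


def random_guides(n, seed, with_context=False, efficiency=None):
    """Uniform random 20-mers, optionally with PAM/genome context."""
    rng = np.random.default_rng(seed)
    guides = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGT"), 20))
        kw = {}
        if with_context:
            kw = {
                "pam": rng.choice(list("ACGT")) + "GG",
                "distance_to_pam": int(rng.integers(0, 100)),
                "gene_location": str(rng.choice(["TSS", "Q1", "Q2", "Q3", "Q4", "TTS"])),
            }
        if efficiency is not None:
            kw["efficiency"] = float(efficiency[i])
        guides.append(Guide(seq=seq, **kw))
    return guides
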