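import numpy as np
import pytest

from butqpcr import panel, synthetic


@pytest.fixture(scope="session")
def primer_panel():
    return panel.load_primer_panel()


@pytest.fixture(scope="session")
def target_records():
    return panel.load_reference_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20210913)


@pytest.fixture(scope="session")
def two_clade_family():
    """Simulated family with two divergent clades, each primer-able."""
    spec = synthetic.clade_family_spec(2, seed=11)
    records, tree, islands = synthetic.simulate_family(spec)
    return spec, records, tree, islands


def random_degenerate(rng, min_len=1, max_len=25, max_logdeg=None):
    """Random IUPAC pattern, optionally bounded in log2 degeneracy."""
    from butqpcr.seqcore import IUPAC_SETS, DegenerateSeq

    symbols = list(IUPAC_SETS)
    while True:
        n = int(rng.integers(min_len, max_len + 1))
        s = "".join(rng.choice(symbols, size=n))
        d = DegenerateSeq(s)
        if max_logdeg is None or np.log2(d.degeneracy) <= max_logdeg:
            return d
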