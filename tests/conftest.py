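import numpy as np
import pytest

from puppred.fixtures import FixtureConfig, generate_proteins, generate_ratio_dataset


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus: 40 proteins, strong motif + GO signal."""
    cfg = FixtureConfig(n_proteins=40, seed=11)
    proteins, sites, go = generate_proteins(cfg)
    return cfg, proteins, sites, go


@pytest.fixture(scope="session")
def balanced_windows():
    """~80 labeled windows at 1:1 from a 40-protein corpus."""
    cfg = FixtureConfig(n_proteins=40, seed=23)
    windows, proteins, go = generate_ratio_dataset(cfg, ratio=1.0)
    return windows, proteins, go


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_peptides(rng, n, lengths=(10, 80), alphabet="ACDEFGHIKLMNPQRSTVWYX"):
    """Random peptides over the 21-letter alphabet (shared test helper)."""
    letters = np.asarray(list(alphabet))
    out = []
    for _ in range(n):
        L = int(rng.integers(lengths[0], lengths[1] + 1))
        out.append("".join(letters[rng.integers(0, len(letters), size=L)]))
    return out
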