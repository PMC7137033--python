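import numpy as np
import pytest

from rna5hmc.sequence_io import SiteWindow

ALPHABET = "ACGU"


def random_window(rng: np.random.Generator, L: int = 41, wid: str = "w") -> SiteWindow:
    chars = rng.choice(list(ALPHABET), size=L)
    chars[(L - 1) // 2] = "C"
    return SiteWindow(id=wid, seq="".join(chars))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def windows_41(rng):
    return [random_window(rng, wid=f"w{i}") for i in range(10)]


@pytest.fixture
def fasta_pair(tmp_path, rng):
    """Small positive/negative FASTA pair on disk (8 + 7 valid windows)."""
    from rna5hmc.sequence_io import write_fasta

    pos = [random_window(rng, wid=f"p{i}") for i in range(8)]
    neg = [random_window(rng, wid=f"n{i}") for i in range(7)]
    pos_path = tmp_path / "pos.fasta"
    neg_path = tmp_path / "neg.fasta"
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    return pos_path, neg_path
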