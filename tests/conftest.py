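import numpy as np
import pytest

from estmir import SequenceRecord, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A small, fixed-seed synthetic corpus shared across tests."""
    return generate_corpus(n_background=60, n_planted=10, n_coding=8,
                           n_duplicates=5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture()
def perfect_hairpin_candidate():
    """A constructed perfect hairpin: 20-bp stem, 5-nt loop, mature on 5'."""
    from estmir import PrecursorCandidate, fold, reverse_complement

    stem5 = "GUGCUAGCUAGCAUCGAUGC"           # 20 nt
    seq = stem5 + "AAACA" + reverse_complement(stem5)
    db, mfe = fold(seq)
    return PrecursorCandidate(est_id="x", window_start=0, sequence=seq,
                              mature_span=(0, 20), dot_bracket=db,
                              mfe_kcal_per_mol=mfe)
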