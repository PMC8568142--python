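import pytest

import mitoprofile as mp


@pytest.fixture(scope="session")
def default_genome():
    """One realized default synthetic genome shared across read-only tests."""
    record, truth = mp.generate(mp.SyntheticSpec(seed=11))
    return record, truth


@pytest.fixture()
def toy_record():
    """A 60 bp circular toy with two F genes, one R gene, and gaps."""
    seq = "ATGAAATTTGGGCCCTAAACGTACGTACGTAAATTTAAACCCGGGTTTAAACATGTTTAA"
    features = [
        mp.Feature(name="g1", category="PCG", strand="F", spans=((1, 18),)),
        mp.Feature(name="trnX", category="tRNA", strand="F", spans=((25, 34),)),
        mp.Feature(name="g2", category="PCG", strand="R", spans=((40, 54),)),
    ]
    return mp.MitogenomeRecord(
        id="toy", sequence=seq, circular=True, features=features
    )
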