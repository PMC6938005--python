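import numpy as np
import pytest

from tnwclust import (ScoringScheme, make_two_cluster_dataset, parse_pe,
                      well_separated_pair)


@pytest.fixture(scope="session")
def separated_dataset():
    """One labelled two-group CTMC dataset (the standard benchmark draw)."""
    spec1, spec2 = well_separated_pair()
    return make_two_cluster_dataset(spec1, spec2, 20, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def default_scheme():
    return ScoringScheme()


def random_pe(rng, alphabet="ABC", max_len=4, max_dur=5, min_len=1):
    """Small random PE sequence with integer durations (oracle-sized)."""
    n = int(rng.integers(min_len, max_len + 1))
    syms = rng.choice(list(alphabet), size=n)
    durs = [0] + [int(rng.integers(0, max_dur + 1)) for _ in range(n - 1)]
    text = ",".join(f"{d}.{s}" for d, s in zip(durs, syms))
    return parse_pe(text)


def random_scheme(rng):
    return ScoringScheme(
        match_score=float(rng.uniform(0.5, 2.0)),
        mismatch_score=float(rng.uniform(-2.0, 0.0)),
        gap_penalty=float(rng.uniform(0.0, 1.5)),
        temporal_penalty=float(rng.uniform(0.0, 1.0)),
    )
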