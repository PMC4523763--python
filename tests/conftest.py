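import numpy as np
import pytest

from stenobarcode import distmat, seqio

BASES = "ACGT"


@pytest.fixture(scope="session")
def published():
    """Packaged published COI matrices (percent): (k2p, p, notes)."""
    return distmat.load_published_coi_matrices()


@pytest.fixture(scope="session")
def specimens():
    from importlib import resources

    pkg = resources.files("stenobarcode") / "data"
    return seqio.read_metadata(str(pkg / "specimens.tsv"))


@pytest.fixture(scope="session")
def italian_regions():
    from importlib import resources

    pkg = resources.files("stenobarcode") / "data"
    return seqio.read_region_set(str(pkg / "italian_regions.txt"))


def random_alignment(rng, n, L, missing_rate=0.1):
    """Random alignment over ACGT with gaps and Ns sprinkled in."""
    chars = np.array(list("ACGT-N"))
    probs = np.full(6, (1 - missing_rate) / 4)
    probs[4] = probs[5] = missing_rate / 2
    rows = ["".join(rng.choice(chars, size=L, p=probs)) for _ in range(n)]
    return seqio.Alignment(
        records=[(f"s{i}", row) for i, row in enumerate(rows)]
    )


def simulate_k2p_pair(rng, d, kappa, L):
    """Two sequences at true K2P divergence ``d`` (exact per-site probs)."""
    from stenobarcode.synthetic_data import k2p_transition_probs

    root = rng.integers(0, 4, size=L, dtype=np.int8)

    def evolve(seq, dist):
        p_same, p_ts, p_tv = k2p_transition_probs(dist, kappa)
        u = rng.random(seq.size)
        out = seq.copy()
        out[(u >= p_same) & (u < p_same + p_ts)] ^= 2
        out[(u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)] ^= 1
        out[u >= p_same + p_ts + p_tv] ^= 3
        return out

    a, b = evolve(root, d / 2), evolve(root, d / 2)
    to_str = lambda s: "".join(BASES[c] for c in s)
    return seqio.Alignment(records=[("a", to_str(a)), ("b", to_str(b))])
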