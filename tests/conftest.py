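import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ssphylo.records import SequenceRecord, SequenceStructurePair
from ssphylo.simulate import SimConfig, evolve_pairs


@pytest.fixture(scope="session")
def small_dataset():
    """Eight-taxon synthetic dataset with the default four-helix root."""
    return evolve_pairs(config=SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_pair(rng: np.random.Generator, n: int, rec_id: str = "p") -> SequenceStructurePair:
    """Random valid sequence-structure pair: random nested brackets + a
    sequence whose paired positions form allowed pairs."""
    from ssphylo.records import NUCLEOTIDES
    from ssphylo.simulate import _PARTNERS

    structure = ["."] * n
    stack = []
    for i in range(n):
        if stack and rng.random() < 0.35 and i - stack[-1] - 1 >= 3:
            j = stack.pop()
            structure[j], structure[i] = "(", ")"
        elif rng.random() < 0.4:
            stack.append(i)
    struct = "".join(structure)
    seq = [""] * n
    pairs = []
    depth = []
    for i, ch in enumerate(struct):
        if ch == "(":
            depth.append(i)
        elif ch == ")":
            pairs.append((depth.pop(), i))
    partner = {}
    for i, j in pairs:
        partner[i], partner[j] = j, i
    for i in range(n):
        if seq[i]:
            continue
        nuc = NUCLEOTIDES[rng.integers(4)]
        seq[i] = nuc
        if i in partner:
            opts = _PARTNERS[nuc]
            seq[partner[i]] = opts[rng.integers(len(opts))]
    return SequenceStructurePair(
        record=SequenceRecord(id=rec_id, seq="".join(seq)), structure=struct
    )
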