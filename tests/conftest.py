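import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(20260920)


@pytest.fixture
def toy_instance():
    """A small mixed assembly + per-sex reads with some shared structure."""

    def make(seed: int, k: int):
        r = random.Random(seed)
        n_scaff = r.randint(2, 6)
        scaffolds = []
        for i in range(n_scaff):
            seq = random_dna(r, r.randint(40, 300))
            if r.random() < 0.3:  # inject an N gap now and then
                pos = r.randrange(len(seq))
                seq = seq[:pos] + "N" * r.randint(1, 5) + seq[pos:]
            scaffolds.append((f"scf{i}", seq))
        # reads: fragments of scaffolds (both strands) plus pure noise
        reads = {"female": [], "male": []}
        for sex in reads:
            for _ in range(r.randint(20, 120)):
                sid, seq = scaffolds[r.randrange(n_scaff)]
                if len(seq) <= k:
                    continue
                ln = r.randint(k, min(len(seq), 80))
                start = r.randrange(len(seq) - ln + 1)
                frag = seq[start : start + ln]
                if r.random() < 0.5:
                    from naive_oracle import revcomp

                    frag = revcomp(frag.replace("N", "A"))
                reads[sex].append(frag)
            for _ in range(r.randint(0, 20)):
                reads[sex].append(random_dna(r, r.randint(k, 60)))
        return scaffolds, reads["female"], reads["male"]

    return make
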