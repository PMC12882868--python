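import numpy as np
import pytest

import mybfunnel as mf


@pytest.fixture(scope="session")
def seed_alignment() -> dict[str, str]:
    return mf.load_seed_alignment()


@pytest.fixture(scope="session")
def pssm(seed_alignment) -> mf.RepeatPSSM:
    return mf.build_repeat_pssm(seed_alignment)


@pytest.fixture(scope="session")
def study() -> mf.SyntheticStudy:
    """One standard planted study shared by read-only tests."""
    return mf.standard_study(seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def brute_force_scan(sequence: str, pssm: mf.RepeatPSSM) -> list[mf.RepeatHit]:
    """Independent oracle: score every window explicitly, then resolve
    overlaps greedily by (descending score, ascending start)."""
    w = pssm.width
    scored = []
    for s in range(len(sequence) - w + 1):
        score = pssm.score_window(sequence[s : s + w])
        if score >= pssm.threshold:
            scored.append((s, score))
    accepted: list[tuple[int, float]] = []
    for s, score in sorted(scored, key=lambda t: (-t[1], t[0])):
        if all(s + w <= a or s >= a + w for a, _ in accepted):
            accepted.append((s, score))
    return [
        mf.RepeatHit(start=s, end=s + w, score=sc)
        for s, sc in sorted(accepted)
    ]
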