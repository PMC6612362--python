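import random

import pytest

from opiconvert import TrendTable, fixture_formulary_F1
from opiconvert.fixtures import fixture_formulary_path


@pytest.fixture(scope="session")
def f1():
    return fixture_formulary_F1()


@pytest.fixture(scope="session")
def f1_path():
    return fixture_formulary_path()


def random_survey_table(rng: random.Random, k: int = 4, wave: int = 30) -> TrendTable:
    """A plausible two-wave confidence survey: ~`wave` respondents per wave
    spread over k ordered categories, with a mild shift between waves."""
    base = [rng.uniform(0.5, 2.0) for _ in range(k)]
    shift = rng.uniform(-0.4, 0.4)
    while True:
        pre = _multinomial(rng, wave, base)
        post = _multinomial(rng, wave, [b * (2.718 ** (shift * i)) for i, b in enumerate(base)])
        # both rows non-empty and scores non-degenerate across occupied cells
        if sum(pre) and sum(post) and len({i for i in range(k) if pre[i] + post[i]}) >= 2:
            return TrendTable(scores=tuple(range(k)), pre=tuple(pre), post=tuple(post))


def _multinomial(rng: random.Random, n: int, weights: list[float]) -> list[int]:
    total = sum(weights)
    counts = [0] * len(weights)
    for _ in range(n):
        r = rng.uniform(0, total)
        acc = 0.0
        for i, w in enumerate(weights):
            acc += w
            if r <= acc:
                counts[i] += 1
                break
        else:
            counts[-1] += 1
    return counts
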