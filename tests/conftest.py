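import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rrsa

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_taxonomy():
    """entity{animal{dog:2, cat:2}, artifact{car:4}} with hand-checkable ICs."""
    return rrsa.Taxonomy(
        parents={
            "entity": (),
            "animal": ("entity",),
            "artifact": ("entity",),
            "dog": ("animal",),
            "cat": ("animal",),
            "car": ("artifact",),
        },
        counts={"entity": 0, "animal": 0, "artifact": 0, "dog": 2, "cat": 2, "car": 4},
        word_to_node={"dog": "dog", "cat": "cat", "car": "car"},
    )


@pytest.fixture(scope="session")
def small_lexicon():
    """Six sentences over four words: one repeated pair per word class."""
    return rrsa.Lexicon(
        (
            ("s0", "dog"),
            ("s1", "dog"),
            ("s2", "cat"),
            ("s3", "cat"),
            ("s4", "car"),
            ("s5", "car"),
        )
    )


@pytest.fixture(scope="session")
def small_table(small_lexicon, toy_taxonomy):
    return rrsa.build_predictor_table(small_lexicon, toy_taxonomy)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming oracle over the full edit lattice."""
    n, m = len(a), len(b)
    d = np.zeros((n + 1, m + 1), dtype=int)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d[i, j] = min(
                d[i - 1, j] + 1,
                d[i, j - 1] + 1,
                d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(d[n, m])
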