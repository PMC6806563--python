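import random
from pathlib import Path

import pytest
from hypothesis import settings

from bescan.panel import EditorSpec, PamSide, default_panel

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def be3(panel):
    return panel["BE3"]


@pytest.fixture(scope="session")
def cpf1(panel):
    return panel["dCpf1-eBE"]


@pytest.fixture(scope="session")
def toy_fixture_dir():
    return DATA


_PAM_POOL = ["NGG", "NG", "NGA", "NGAG", "NGCG", "NNGRRT", "NNNRRT",
             "TTTV", "TTV", "YG", "NNN", "NAAG", "KGG", "TTTN"]


def random_editor(rng: random.Random, name: str = "rand") -> EditorSpec:
    """A random valid editor geometry, for property tests."""
    pam = rng.choice(_PAM_POOL)
    side = rng.choice([PamSide.THREE_PRIME, PamSide.FIVE_PRIME])
    spacer = rng.randint(18, 24)
    ws = rng.randint(1, spacer)
    we = rng.randint(ws, min(spacer, ws + rng.randint(0, 12)))
    return EditorSpec(name=name, pam_pattern=pam, pam_side=side,
                      spacer_length=spacer, window_start=ws, window_end=we)


def random_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def cand_tuple(c):
    """Canonical comparable form of a GuideCandidate (matches oracle tuples)."""
    return (c.protospacer_interval[0], c.protospacer_interval[1],
            c.spacer_sequence, c.pam_observed, c.target_window_position,
            c.bystander_positions)
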