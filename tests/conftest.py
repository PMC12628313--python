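import numpy as np
import pytest

from rpsdecode.core import (
    DesignConfig,
    GameRecord,
    ResponseSymbol,
    SessionLog,
)
from rpsdecode.layout import SensorLayout
from rpsdecode.synth import PlayerPolicy, simulate_dyad

R = ResponseSymbol.ROCK
P = ResponseSymbol.PAPER
S = ResponseSymbol.SCISSORS
N = ResponseSymbol.NO_RESPONSE


def session_from_responses(pairs, pair_id="pair-01"):
    """Build a single-block session from explicit (p1, p2) response pairs."""
    games = [
        GameRecord.from_responses(pair_id, 1, i + 1, i + 1, r1, r2)
        for i, (r1, r2) in enumerate(pairs)
    ]
    return SessionLog(pair_id, games, n_blocks=1, games_per_block=len(games))


@pytest.fixture(scope="session")
def uniform_session():
    """One full-design session between two uniform random players."""
    return simulate_dyad(PlayerPolicy.uniform(), PlayerPolicy.uniform(), seed=11)


@pytest.fixture(scope="session")
def grid_layout():
    """A 3x3 synthetic layout with unit grid spacing for hand-checkable distances."""
    names = tuple(f"ch{i}" for i in range(9))
    pos = np.array([[x, y] for y in (0.0, 0.5, 1.0) for x in (0.0, 0.5, 1.0)])
    return SensorLayout(names, pos)
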