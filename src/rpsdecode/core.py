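"""Game rules, session data model and events-table I/O for dyadic Rock-Paper-Scissors.

A session is a fixed-length sequence of games played by one pair of
participants. Each game records both players' responses and the outcome
under the cyclic dominance rule (rock beats scissors, scissors beat paper,
paper beats rock). Sessions are serialized as BIDS-style ``events.tsv``
tables so behavioral and EEG stages can share one on-disk convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ResponseSymbol",
    "Outcome",
    "GameRecord",
    "SessionLog",
    "DesignConfig",
    "MatchResult",
    "compute_outcome",
    "match_winner",
    "read_events",
    "write_events",
]


class ResponseSymbol(Enum):
    """One player's move in a single game; NO_RESPONSE marks a timed-out trial."""

    ROCK = "rock"
    PAPER = "paper"
    SCISSORS = "scissors"
    NO_RESPONSE = "none"

    @property
    def answered(self) -> bool:
        return self is not ResponseSymbol.NO_RESPONSE


#: The three decodable classes, in canonical order (also the tie-break order).
ANSWERED = (ResponseSymbol.ROCK, ResponseSymbol.PAPER, ResponseSymbol.SCISSORS)

#: Dominance cycle: each symbol beats the next one ("shift-up" follows this cycle).
_BEATS = {
    ResponseSymbol.ROCK: ResponseSymbol.SCISSORS,
    ResponseSymbol.SCISSORS: ResponseSymbol.PAPER,
    ResponseSymbol.PAPER: ResponseSymbol.ROCK,
}


class Outcome(Enum):
    P1_WINS = "p1_wins"
    P2_WINS = "p2_wins"
    DRAW = "draw"


def compute_outcome(r1: ResponseSymbol, r2: ResponseSymbol) -> Outcome:
    """Outcome of one game under cyclic dominance.

    A player who responds beats one who does not; two timeouts are scored
    as a draw (symmetric, and no rule favors either player).
    """
    if r1 is ResponseSymbol.NO_RESPONSE and r2 is ResponseSymbol.NO_RESPONSE:
        return Outcome.DRAW
    if r1 is ResponseSymbol.NO_RESPONSE:
        return Outcome.P2_WINS
    if r2 is ResponseSymbol.NO_RESPONSE:
        return Outcome.P1_WINS
    if r1 is r2:
        return Outcome.DRAW
    return Outcome.P1_WINS if _BEATS[r1] is r2 else Outcome.P2_WINS


@dataclass(frozen=True)
class GameRecord:
    """One game: both players' responses plus the derived outcome."""

    pair_id: str
    block: int
    trial_in_block: int
    trial_global: int
    response_p1: ResponseSymbol
    response_p2: ResponseSymbol
    outcome: Outcome

    def __post_init__(self) -> None:
        expected = compute_outcome(self.response_p1, self.response_p2)
        if self.outcome is not expected:
            raise ValueError(
                f"game {self.trial_global}: outcome {self.outcome.value!r} "
                f"inconsistent with responses ({self.response_p1.value}, "
                f"{self.response_p2.value}); expected {expected.value!r}"
            )

    @classmethod
    def from_responses(
        cls,
        pair_id: str,
        block: int,
        trial_in_block: int,
        trial_global: int,
        response_p1: ResponseSymbol,
        response_p2: ResponseSymbol,
    ) -> "GameRecord":
        return cls(
            pair_id,
            block,
            trial_in_block,
            trial_global,
            response_p1,
            response_p2,
            compute_outcome(response_p1, response_p2),
        )


@dataclass(frozen=True)
class DesignConfig:
    """Session design: how many games, how they block, and phase timing.

    Defaults follow the study design: 480 games in 12 blocks of 40, each
    game running through a 2 s decision phase, a 2 s response phase and a
    1 s feedback phase.
    """

    n_blocks: int = 12
    games_per_block: int = 40
    phase_durations_ms: tuple[int, int, int] = (2000, 2000, 1000)

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.games_per_block < 1:
            raise ValueError("n_blocks and games_per_block must be positive")
        if any(d <= 0 for d in self.phase_durations_ms):
            raise ValueError("phase durations must be strictly positive")

    @property
    def n_games(self) -> int:
        return self.n_blocks * self.games_per_block


@dataclass
class SessionLog:
    """Ordered games of one pair's full match."""

    pair_id: str
    games: list[GameRecord]
    n_blocks: int
    games_per_block: int

    def __post_init__(self) -> None:
        if len(self.games) != self.n_blocks * self.games_per_block:
            raise ValueError(
                f"session {self.pair_id}: {len(self.games)} games != "
                f"{self.n_blocks} blocks x {self.games_per_block}"
            )
        for i, g in enumerate(self.games, start=1):
            if g.trial_global != i:
                raise ValueError(
                    f"session {self.pair_id}: trial_global not consecutive at game {i}"
                )

    def __len__(self) -> int:
        return len(self.games)

    def responses(self, player: int, answered_only: bool = False) -> list[ResponseSymbol]:
        """Per-game responses of one player (1 or 2).

        With ``answered_only`` timed-out games are dropped; otherwise the
        full, unfiltered sequence is returned.
        """
        if player not in (1, 2):
            raise ValueError("player must be 1 or 2")
        attr = "response_p1" if player == 1 else "response_p2"
        seq = [getattr(g, attr) for g in self.games]
        if answered_only:
            seq = [r for r in seq if r.answered]
        return seq

    def outcomes(self) -> list[Outcome]:
        return [g.outcome for g in self.games]


@dataclass(frozen=True)
class MatchResult:
    winner_player: int | None  # 1, 2, or None on an exact tie
    wins_p1: int
    wins_p2: int
    draws: int


def match_winner(session: SessionLog) -> MatchResult:
    """Overall match winner: the player with strictly more wins over the session.

    An exact win-count tie yields ``winner_player=None``; such sessions are
    excluded from winner/loser group analyses.
    """
    if len(session) == 0:
        raise ValueError("empty session has no winner")
    wins_p1 = sum(1 for g in session.games if g.outcome is Outcome.P1_WINS)
    wins_p2 = sum(1 for g in session.games if g.outcome is Outcome.P2_WINS)
    draws = len(session) - wins_p1 - wins_p2
    if wins_p1 > wins_p2:
        winner = 1
    elif wins_p2 > wins_p1:
        winner = 2
    else:
        winner = None
    return MatchResult(winner, wins_p1, wins_p2, draws)


_REQUIRED_COLS = ("pair_id", "block", "trial", "response_p1", "response_p2", "outcome")
_OPTIONAL_COLS = ("onset", "sample")


def write_events(session: SessionLog, path: str | Path) -> None:
    """Write a session as a tab-separated events table (one row per game)."""
    rows = [
        {
            "pair_id": g.pair_id,
            "block": g.block,
            "trial": g.trial_in_block,
            "response_p1": g.response_p1.value,
            "response_p2": g.response_p2.value,
            "outcome": g.outcome.value,
        }
        for g in session.games
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED_COLS)).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_events(path: str | Path) -> SessionLog:
    """Read an events table back into a :class:`SessionLog`.

    Raises a descriptive error naming the offending row when a response
    label is malformed or the stored outcome contradicts the responses.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    by_value = {s.value: s for s in ResponseSymbol}
    out_by_value = {o.value: o for o in Outcome}
    games: list[GameRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            r1 = by_value[str(row.response_p1)]
            r2 = by_value[str(row.response_p2)]
        except KeyError as exc:
            raise ValueError(
                f"{path}: row {idx}: unknown response label {exc.args[0]!r}"
            ) from None
        try:
            out = out_by_value[str(row.outcome)]
        except KeyError:
            raise ValueError(
                f"{path}: row {idx}: unknown outcome label {row.outcome!r}"
            ) from None
        try:
            games.append(
                GameRecord(str(row.pair_id), int(row.block), int(row.trial), idx, r1, r2, out)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from None

    n_blocks = int(df["block"].max())
    games_per_block = len(games) // n_blocks if n_blocks else 0
    return SessionLog(
        pair_id=str(df["pair_id"].iloc[0]),
        games=games,
        n_blocks=n_blocks,
        games_per_block=games_per_block,
    )
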