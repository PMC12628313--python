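"""Behavioral statistics of dyadic Rock-Paper-Scissors play.

Covers the descriptive measures used to characterize how far players are
from the optimal (uniformly random) strategy: the outcome distribution from
the match winner's perspective, response-frequency bias, outcome-conditioned
switch rates, and the predictability of each player's response sequence to
a sliding-window first-order Markov model.

Chance references: 1/3 for outcome proportions, response frequencies and
Markov prediction accuracy; 2/3 for the consecutive-game change rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ANSWERED, Outcome, ResponseSymbol, SessionLog, match_winner
from .synth import outcome_for_player

__all__ = [
    "OutcomeDistribution",
    "BiasSummary",
    "SwitchSummary",
    "MarkovConfig",
    "outcome_distribution",
    "response_bias",
    "switch_rates",
    "markov_predictability",
]


@dataclass(frozen=True)
class OutcomeDistribution:
    """Game-outcome proportions from the overall match winner's perspective."""

    winner_player: int
    winner_wins: float
    winner_loses: float
    draws: float


def outcome_distribution(session: SessionLog) -> OutcomeDistribution:
    """Proportions of (winner wins, winner loses, draw) over a session.

    Requires a defined overall match winner; an exactly tied match has no
    winner perspective and raises.
    """
    result = match_winner(session)
    if result.winner_player is None:
        raise ValueError(
            f"session {session.pair_id}: tied match, winner/loser roles unassignable"
        )
    n = len(session)
    w_wins = result.wins_p1 if result.winner_player == 1 else result.wins_p2
    w_loses = result.wins_p2 if result.winner_player == 1 else result.wins_p1
    return OutcomeDistribution(
        winner_player=result.winner_player,
        winner_wins=w_wins / n,
        winner_loses=w_loses / n,
        draws=result.draws / n,
    )


@dataclass(frozen=True)
class BiasSummary:
    """How often the most, mid and least chosen responses were played."""

    proportions_sorted: tuple[float, float, float]  # most, mid, least
    identity_sorted: tuple[ResponseSymbol, ResponseSymbol, ResponseSymbol]
    rank_ties: bool  # True when ranks were broken by the fixed symbol order


def response_bias(responses: Sequence[ResponseSymbol]) -> BiasSummary:
    """Rank-sorted response frequencies; 1/3 each means no bias.

    No-response games are excluded from the denominator. Exact frequency
    ties are broken by the fixed order rock < paper < scissors and flagged.
    """
    answered = [r for r in responses if r.answered]
    if not answered:
        raise ValueError("no answered responses to summarize")
    counts = {sym: answered.count(sym) for sym in ANSWERED}
    order = sorted(ANSWERED, key=lambda s: (-counts[s], ANSWERED.index(s)))
    n = len(answered)
    props = tuple(counts[s] / n for s in order)
    ties = len(set(counts.values())) < 3
    return BiasSummary(props, tuple(order), ties)


@dataclass(frozen=True)
class SwitchSummary:
    """Consecutive-game response-change rates, split by previous outcome.

    Rates are NaN where a stratum has no eligible game pairs; denominators
    are reported alongside. ``pooled`` is the overall change rate across
    all eligible pairs (chance for a uniform random player: 2/3).
    """

    change_rate_by_prev_outcome: dict[str, float]
    n_by_prev_outcome: dict[str, int]
    pooled: float
    n_pooled: int


def switch_rates(session: SessionLog, player: int) -> SwitchSummary:
    """Change rate between consecutive games, stratified by previous outcome.

    Pairs where either of the two responses is a no-response are excluded.
    """
    responses = session.responses(player)
    outcomes = session.outcomes()
    changed: dict[str, list[bool]] = {"win": [], "lose": [], "draw": []}
    for t in range(1, len(session)):
        prev, cur = responses[t - 1], responses[t]
        if not (prev.answered and cur.answered):
            continue
        stratum = outcome_for_player(outcomes[t - 1], player)
        changed[stratum].append(cur is not prev)
    if not any(changed.values()):
        raise ValueError("no eligible consecutive-game pairs")
    rates = {
        k: (float(np.mean(v)) if v else float("nan")) for k, v in changed.items()
    }
    ns = {k: len(v) for k, v in changed.items()}
    pooled_list = [x for v in changed.values() for x in v]
    return SwitchSummary(rates, ns, float(np.mean(pooled_list)), len(pooled_list))


@dataclass(frozen=True)
class MarkovConfig:
    """Sliding-window first-order Markov predictor settings.

    The model estimates transition counts from the previous ``w`` games
    and predicts the most likely next response given the last one, for
    every window size ``w`` in ``window_sizes``.
    """

    window_sizes: tuple[int, ...] = tuple(range(5, 101))
    order: int = 1

    def __post_init__(self) -> None:
        ws = self.window_sizes
        if any(w < 2 for w in ws) or any(b <= a for a, b in zip(ws, ws[1:])):
            raise ValueError("window_sizes must be >= 2 and strictly increasing")
        if self.order != 1:
            raise ValueError("only first-order transitions are supported")


def _encode(responses: Sequence[ResponseSymbol]) -> np.ndarray:
    # no-response games are skipped as both context and target
    index = {sym: i for i, sym in enumerate(ANSWERED)}
    return np.array([index[r] for r in responses if r.answered], dtype=int)


def markov_predictability(
    responses: Sequence[ResponseSymbol], cfg: MarkovConfig = MarkovConfig()
) -> dict[int, float]:
    """Prediction accuracy of the sliding-window Markov model per window size.

    For each window size ``w`` and each game ``t > w`` (1-based, over the
    answered sequence): first-order transition counts are estimated from
    games ``t-w .. t-1``, the response at ``t`` is predicted as the argmax
    of the transition row conditioned on the response at ``t-1``, and the
    prediction is scored against the actual response. Accuracy is the mean
    over all scored games; 1/3 means the player is unpredictable.

    Argmax ties are broken by the higher marginal frequency within the
    window, then by the fixed order rock < paper < scissors; a previous
    response unseen in the window falls back to the window-marginal argmax
    through the same rule. Window sizes exceeding the sequence length are
    reported as NaN.
    """
    seq = _encode(responses)
    n = seq.size
    out: dict[int, float] = {}

    if n >= 2:
        # pair (transition) and symbol one-hot cumulative counts
        pair_onehot = np.zeros((9, n - 1), dtype=np.int64)
        pair_onehot[seq[:-1] * 3 + seq[1:], np.arange(n - 1)] = 1
        pair_cum = np.concatenate(
            [np.zeros((9, 1), dtype=np.int64), np.cumsum(pair_onehot, axis=1)], axis=1
        )
        sym_onehot = np.zeros((3, n), dtype=np.int64)
        sym_onehot[seq, np.arange(n)] = 1
        sym_cum = np.concatenate(
            [np.zeros((3, 1), dtype=np.int64), np.cumsum(sym_onehot, axis=1)], axis=1
        )

    for w in cfg.window_sizes:
        if n < w + 1:
            out[w] = float("nan")
            continue
        t = np.arange(w, n)  # 0-based scored positions
        prev = seq[t - 1]
        # transitions within games t-w .. t-1 are pairs t-w .. t-2
        trans = pair_cum[:, t - 1] - pair_cum[:, t - w]  # (9, m)
        marg = sym_cum[:, t] - sym_cum[:, t - w]  # (3, m)
        rows = trans.reshape(3, 3, -1)[prev, :, np.arange(t.size)].T  # (3, m)
        # lexicographic argmax: transition count, then marginal, then rock<paper<scissors
        key = (
            rows * 1_000_000
            + marg * 100
            + np.array([2, 1, 0], dtype=np.int64)[:, None]
        )
        pred = np.argmax(key, axis=0)
        out[w] = float(np.mean(pred == seq[t]))
    return out
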