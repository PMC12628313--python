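"""Synthetic dyadic game behavior and multichannel EEG epochs.

The generator stands in for human recordings so the full analysis chain can
be exercised end to end. It has two parts:

* **Behavior** — each simulated player mixes independent biased sampling
  with an outcome-contingent stay/shift rule (the family spanning
  rock-bias, win-stay/lose-shift and cycling strategies that human players
  exhibit). ``memory_mix`` blends the two: 0 gives an i.i.d. player, 1 a
  fully sequential one.

* **EEG** — per game and phase, a trials x channels x samples epoch is
  synthesized as spatially correlated Gaussian noise plus, for each label
  stream scheduled in that phase, a fixed class-specific channel pattern
  scaled by the stream amplitude and the signal-to-noise ratio. Patterns
  are unit-norm, orthogonalized across streams and drawn once per seed, so
  scheduled streams are separably decodable. The class signal is zero
  during the -200..0 ms baseline window and ramps in with a 100 ms
  raised-cosine onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .core import (
    ANSWERED,
    DesignConfig,
    GameRecord,
    MatchResult,
    Outcome,
    ResponseSymbol,
    SessionLog,
    match_winner,
)
from .decode import StreamKind, stream_labels
from .layout import SensorLayout, biosemi64_layout
from .preprocess import EpochTensor, Phase, n_samples_for

__all__ = [
    "PlayerPolicy",
    "EEGGenConfig",
    "PairRecording",
    "simulate_dyad",
    "simulate_eeg",
    "make_group",
]

_CYCLE = {  # shift-up follows the dominance cycle rock -> paper -> scissors
    ResponseSymbol.ROCK: ResponseSymbol.PAPER,
    ResponseSymbol.PAPER: ResponseSymbol.SCISSORS,
    ResponseSymbol.SCISSORS: ResponseSymbol.ROCK,
}
_CYCLE_DOWN = {v: k for k, v in _CYCLE.items()}


def _check_triple(name: str, triple: tuple[float, float, float]) -> None:
    if len(triple) != 3 or any(p < 0 for p in triple):
        raise ValueError(f"{name} must be three non-negative probabilities")
    if abs(sum(triple) - 1.0) > 1e-12:
        raise ValueError(f"{name} must sum to 1 (got {sum(triple)!r})")


@dataclass(frozen=True)
class PlayerPolicy:
    """Generative model of one player's choice behavior.

    Parameters
    ----------
    base_rates
        Marginal probabilities of (rock, paper, scissors) when sampling
        independently of history. Human players over-select rock, so the
        default is mildly rock-biased.
    stay_prob_by_outcome
        Probability of repeating the previous response given the previous
        game's outcome from this player's perspective. Human players
        change more often than the chance rate of 2/3 regardless of
        outcome, so the defaults sit below 1/3.
    shift_direction_bias
        Probabilities over (stay, shift-up, shift-down) along the
        dominance cycle; consulted when the outcome rule decides not to
        stay, renormalized over the two shift directions.
    no_response_prob
        Per-game probability of a timeout (missed response).
    memory_mix
        Weight of the outcome-contingent rule vs. base-rate sampling:
        with probability ``memory_mix`` the stay/shift rule is applied,
        otherwise the response is drawn from ``base_rates``.
    """

    base_rates: tuple[float, float, float] = (0.40, 0.33, 0.27)
    stay_prob_by_outcome: Mapping[str, float] = field(
        default_factory=lambda: {"win": 0.30, "lose": 0.22, "draw": 0.27}
    )
    shift_direction_bias: tuple[float, float, float] = (0.0, 0.5, 0.5)
    no_response_prob: float = 0.005
    memory_mix: float = 0.5

    def __post_init__(self) -> None:
        _check_triple("base_rates", tuple(self.base_rates))
        _check_triple("shift_direction_bias", tuple(self.shift_direction_bias))
        missing = {"win", "lose", "draw"} - set(self.stay_prob_by_outcome)
        if missing:
            raise ValueError(f"stay_prob_by_outcome missing keys {sorted(missing)}")
        for k, p in self.stay_prob_by_outcome.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"stay_prob_by_outcome[{k!r}] out of [0, 1]")
        if not 0.0 <= self.no_response_prob <= 0.01:
            raise ValueError("no_response_prob must lie in [0, 0.01]")
        if not 0.0 <= self.memory_mix <= 1.0:
            raise ValueError("memory_mix must lie in [0, 1]")

    @classmethod
    def uniform(cls, no_response_prob: float = 0.0) -> "PlayerPolicy":
        """An i.i.d. uniform (maximally random, i.e. optimal) player."""
        third = 1.0 / 3.0
        return cls(
            base_rates=(third, third, third),
            memory_mix=0.0,
            no_response_prob=no_response_prob,
        )

    def _sample_base(self, rng: np.random.Generator) -> ResponseSymbol:
        return ANSWERED[rng.choice(3, p=np.asarray(self.base_rates) / sum(self.base_rates))]

    def next_response(
        self,
        rng: np.random.Generator,
        prev_response: ResponseSymbol | None,
        prev_outcome_for_self: str | None,
    ) -> ResponseSymbol:
        """Draw one response given the player's previous game."""
        if self.no_response_prob > 0 and rng.random() < self.no_response_prob:
            return ResponseSymbol.NO_RESPONSE
        usable_history = (
            prev_response is not None
            and prev_response.answered
            and prev_outcome_for_self is not None
        )
        if not usable_history or rng.random() >= self.memory_mix:
            return self._sample_base(rng)
        if rng.random() < self.stay_prob_by_outcome[prev_outcome_for_self]:
            return prev_response
        _, up, down = self.shift_direction_bias
        total = up + down
        p_up = up / total if total > 0 else 0.5
        return _CYCLE[prev_response] if rng.random() < p_up else _CYCLE_DOWN[prev_response]


def outcome_for_player(outcome: Outcome, player: int) -> str:
    """Map a game outcome to 'win' / 'lose' / 'draw' from one player's side."""
    if outcome is Outcome.DRAW:
        return "draw"
    won = (outcome is Outcome.P1_WINS) == (player == 1)
    return "win" if won else "lose"


def simulate_dyad(
    policy_p1: PlayerPolicy,
    policy_p2: PlayerPolicy,
    design: DesignConfig = DesignConfig(),
    seed: int = 0,
    pair_id: str = "pair-01",
) -> SessionLog:
    """Simulate one pair's full match; reproducible given the seed."""
    rng = np.random.default_rng(seed)
    games: list[GameRecord] = []
    prev: dict[int, ResponseSymbol | None] = {1: None, 2: None}
    prev_out: dict[int, str | None] = {1: None, 2: None}
    for t in range(design.n_games):
        r1 = policy_p1.next_response(rng, prev[1], prev_out[1])
        r2 = policy_p2.next_response(rng, prev[2], prev_out[2])
        block = t // design.games_per_block + 1
        rec = GameRecord.from_responses(
            pair_id, block, t % design.games_per_block + 1, t + 1, r1, r2
        )
        games.append(rec)
        prev = {1: r1, 2: r2}
        prev_out = {
            1: outcome_for_player(rec.outcome, 1),
            2: outcome_for_player(rec.outcome, 2),
        }
    return SessionLog(pair_id, games, design.n_blocks, design.games_per_block)


@dataclass(frozen=True)
class EEGGenConfig:
    """Parameters of the synthetic EEG epochs.

    ``signal_schedule`` maps ``(stream, phase)`` to a non-negative
    amplitude multiplier; omitted entries are zero. The injected class
    signal has channel-space norm ``amplitude * snr`` relative to a unit
    noise standard deviation.
    """

    n_channels: int = 64
    fs_hz: float = 256.0
    snr: float = 0.5
    noise_spatial_corr: float = 0.3
    signal_schedule: Mapping[tuple[StreamKind, Phase], float] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_spatial_corr < 1.0:
            raise ValueError("noise_spatial_corr must lie in [0, 1)")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if (self.fs_hz * 0.25) % 1.0:
            raise ValueError("fs_hz must put an integer number of samples in a 250 ms bin")
        for (stream, phase), amp in self.signal_schedule.items():
            if not isinstance(stream, StreamKind) or not isinstance(phase, Phase):
                raise ValueError(f"bad schedule key {(stream, phase)!r}")
            if amp < 0:
                raise ValueError("schedule amplitudes must be >= 0")

    @classmethod
    def with_schedule(
        cls, entries: Mapping[tuple[StreamKind, Phase], float], **kwargs
    ) -> "EEGGenConfig":
        return cls(signal_schedule=dict(entries), **kwargs)


def _class_patterns(cfg: EEGGenConfig) -> dict[StreamKind, np.ndarray]:
    """Fixed unit-norm channel patterns, one per class per stream.

    The 12 pattern vectors (4 streams x 3 classes) are orthonormalized so
    concurrently scheduled streams remain separably decodable; with fewer
    than 12 channels they are merely unit-norm.
    """
    rng = np.random.default_rng(cfg.seed)
    raw = rng.standard_normal((cfg.n_channels, 12))
    if cfg.n_channels >= 12:
        q, _ = np.linalg.qr(raw)
        vectors = q[:, :12].T
    else:
        vectors = (raw / np.linalg.norm(raw, axis=0)).T
    streams = list(StreamKind)
    return {s: vectors[3 * i : 3 * i + 3] for i, s in enumerate(streams)}


def _noise_chol(cfg: EEGGenConfig, layout: SensorLayout) -> np.ndarray:
    rho = cfg.noise_spatial_corr
    if rho == 0.0:
        return np.eye(cfg.n_channels)
    # exponential (Matern-1/2) spatial kernel: corr = rho at 0.2 normalized units
    dist = layout.distances()
    cov = rho ** (dist / 0.2)
    return np.linalg.cholesky(cov + 1e-10 * np.eye(cfg.n_channels))


def _envelope(times_ms: np.ndarray, ramp_ms: float = 100.0) -> np.ndarray:
    env = np.zeros_like(times_ms)
    ramp = (times_ms >= 0) & (times_ms < ramp_ms)
    env[ramp] = 0.5 * (1.0 - np.cos(np.pi * times_ms[ramp] / ramp_ms))
    env[times_ms >= ramp_ms] = 1.0
    return env


def _sub_layout(layout: SensorLayout, n: int) -> SensorLayout:
    return SensorLayout(layout.channel_names[:n], layout.positions[:n])


def simulate_eeg(
    session: SessionLog,
    player: int,
    cfg: EEGGenConfig = EEGGenConfig(),
    seed: int | None = None,
    layout: SensorLayout | None = None,
) -> dict[Phase, EpochTensor]:
    """Synthesize one participant's phase-locked epoch tensors.

    Every trial of every phase is unit-SD spatially correlated Gaussian
    noise; scheduled streams additionally inject their class pattern
    (scaled by ``amplitude * snr`` and the temporal onset envelope, zero
    during the baseline window). Trials whose stream label is undefined
    (first game for previous-trial streams, no-response games) receive no
    contribution from that stream.
    """
    if len(session) < 1:
        raise ValueError("session must contain at least one game")
    if layout is None:
        layout = (
            biosemi64_layout()
            if cfg.n_channels == 64
            else _sub_layout(biosemi64_layout(), cfg.n_channels)
        )
    if layout.n_channels != cfg.n_channels:
        raise ValueError("layout size does not match cfg.n_channels")

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    patterns = _class_patterns(cfg)
    chol = _noise_chol(cfg, layout)

    # per-stream class index per trial (-1 where undefined)
    n_trials = len(session)
    class_of: dict[StreamKind, np.ndarray] = {}
    for kind in StreamKind:
        arr = np.full(n_trials, -1, dtype=int)
        stream = stream_labels(session, player, kind)
        arr[stream.trial_indices] = stream.labels
        class_of[kind] = arr

    tensors: dict[Phase, EpochTensor] = {}
    for phase in Phase:
        n_samp = n_samples_for(phase, cfg.fs_hz)
        times = -200.0 + np.arange(n_samp) * (1000.0 / cfg.fs_hz)
        env = _envelope(times)
        white = rng.standard_normal((n_trials, cfg.n_channels, n_samp))
        data = np.matmul(chol, white)  # broadcasts over trials
        for kind in StreamKind:
            amp = cfg.signal_schedule.get((kind, phase), 0.0)
            if amp == 0.0 or cfg.snr == 0.0:
                continue
            cls = class_of[kind]
            ok = cls >= 0
            # (trials, channels) pattern outer (samples,) envelope
            pat = np.zeros((n_trials, cfg.n_channels))
            pat[ok] = patterns[kind][cls[ok]]
            data += amp * cfg.snr * pat[:, :, None] * env[None, None, :]
        tensors[phase] = EpochTensor(
            data=data, fs_hz=cfg.fs_hz, t0_ms=-200.0, phase=phase, layout=layout
        )
    return tensors


@dataclass(frozen=True)
class PairRecording:
    """One simulated pair: behavior, match result, and both EEG recordings."""

    session: SessionLog
    match: MatchResult
    tensors: dict[int, dict[Phase, EpochTensor]]  # player -> phase -> epochs
    cfg_by_player: dict[int, EEGGenConfig]


def make_group(
    n_pairs: int,
    winner_cfg: EEGGenConfig,
    loser_cfg: EEGGenConfig,
    policy_p1: PlayerPolicy | None = None,
    policy_p2: PlayerPolicy | None = None,
    design: DesignConfig = DesignConfig(),
    seed: int = 0,
) -> Iterator[PairRecording]:
    """Simulate a cohort whose match winners and losers differ neurally.

    The overall match winner of each pair receives epochs generated under
    ``winner_cfg``, the loser under ``loser_cfg`` — e.g. scheduling
    previous-trial streams only in the loser configuration instantiates a
    loser-specific carryover of prior-game information. Pairs whose match
    ends in an exact win-count tie have no winner/loser roles; they are
    skipped with a warning.

    Yields one :class:`PairRecording` at a time (epoch tensors are large;
    consume and reduce them pair by pair).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    policy_p1 = policy_p1 or PlayerPolicy()
    policy_p2 = policy_p2 or PlayerPolicy()
    root = np.random.default_rng(seed)
    for i in range(n_pairs):
        pair_seed = int(root.integers(2**31 - 1))
        session = simulate_dyad(
            policy_p1, policy_p2, design, seed=pair_seed, pair_id=f"pair-{i + 1:02d}"
        )
        match = match_winner(session)
        if match.winner_player is None:
            warnings.warn(
                f"{session.pair_id}: tied match ({match.wins_p1} wins each); "
                "excluded from winner/loser cohort",
                stacklevel=2,
            )
            continue
        tensors: dict[int, dict[Phase, EpochTensor]] = {}
        cfgs: dict[int, EEGGenConfig] = {}
        for player in (1, 2):
            cfg = winner_cfg if player == match.winner_player else loser_cfg
            cfgs[player] = cfg
            tensors[player] = simulate_eeg(
                session, player, cfg, seed=int(root.integers(2**31 - 1))
            )
        yield PairRecording(session, match, tensors, cfgs)
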